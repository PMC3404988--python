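"""Sequence-level building blocks for in silico T-RFLP.

This module implements degenerate (IUPAC) primer matching, in silico PCR
amplicon extraction, restriction digestion and terminal-restriction-fragment
(T-RF) prediction, enzyme screening with category merging, p-distance,
clone-library deduplication and a half-alignment chimera screen.

The T-RF of an amplicon is the distance, in bases, from the labeled 5'
terminus to the cut position at the 5'-most occurrence of the enzyme's
recognition site.  The shipped TaiI entry models cleavage immediately 3' of
its ACGT site on the labeled strand (recognition "ACGT", cut offset 4), so a
first site starting at 0-based position 302 yields a 306 bp fragment.
Coordinates are 0-based half-open internally; reported T-RF lengths are bp
counts from the labeled terminus through the last base before the cut.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import (
    ConfigError,
    InputError,
    NoAmpliconError,
    UndefinedDistanceError,
)

# IUPAC nucleotide ambiguity codes -> base sets. U is normalized to T on
# ingest, so only T appears here.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

_UNAMBIGUOUS = frozenset("ACGT")


def normalize_seq(seq: str, what: str = "sequence") -> str:
    """Uppercase, map U->T and validate against the IUPAC alphabet.

    Raises :class:`InputError` naming the first offending symbol.
    """
    s = seq.upper().replace("U", "T")
    for ch in s:
        if ch not in IUPAC_SETS:
            raise InputError(f"non-IUPAC character {ch!r} in {what}")
    return s


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (delegates to Biopython)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence, optionally tagged with its source clade."""

    id: str
    seq: str
    clade_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise InputError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "seq", normalize_seq(self.seq, f"record {self.id!r}"))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Primer:
    """A (possibly degenerate) PCR primer.

    ``labeled`` marks the fluoresceinated 5' end; exactly one primer of a
    pair must be labeled, which orients the reported terminal fragment.
    """

    name: str
    seq: str
    labeled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_seq(self.seq, f"primer {self.name!r}"))
        if len(self.seq) < 10:
            raise ConfigError(f"primer {self.name!r} shorter than 10 nt")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme as (IUPAC recognition string, cut offset).

    ``cut_offset`` is the cleavage position on the labeled strand, in bases
    from the 5' start of the recognition site; cuts outside the site are not
    supported.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "recognition", normalize_seq(self.recognition, f"enzyme {self.name!r}")
        )
        if len(self.recognition) < 4:
            raise ConfigError(f"enzyme {self.name!r}: recognition shorter than 4 nt")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ConfigError(
                f"enzyme {self.name!r}: cut_offset {self.cut_offset} outside recognition site"
            )


# Shipped catalogue: the T-RFLP primer pair (labeled forward primer) and TaiI.
TRBCL_F = Primer("trbcL-F", "CTKGCDGYDYTTMGDATGACAC", labeled=True)
TRBCL_R = Primer("trbcL-R", "MRGCWARWGAACGTCCTTCATT", labeled=False)
TAI_I = Enzyme("TaiI", "ACGT", 4)


def match_iupac(pattern: str, seq: str) -> list[int]:
    """All 0-based start positions where ``pattern`` matches ``seq``.

    A position matches when, at every offset, the base sets of the pattern
    symbol and the sequence symbol intersect.  Both strings may contain
    ambiguity codes.
    """
    p = normalize_seq(pattern, "pattern")
    s = normalize_seq(seq, "seq")
    m, n = len(p), len(s)
    if m == 0 or m > n:
        return []
    psets = [IUPAC_SETS[c] for c in p]
    ssets = [IUPAC_SETS[c] for c in s]
    hits = []
    for i in range(n - m + 1):
        if all(psets[j] & ssets[i + j] for j in range(m)):
            hits.append(i)
    return hits


def extract_amplicon(template: "SeqRecord | str", fwd: Primer, rev: Primer) -> str:
    """In silico PCR: the amplicon oriented 5'->3' from the labeled primer.

    The forward primer is matched on the given strand and the reverse primer
    as its reverse complement downstream of it.  With several sites, the
    5'-most forward and the 3'-most compatible reverse site are taken
    (maximal outer product).  Both primer footprints are included.  If the
    labeled primer is the reverse one, the amplicon is reverse-complemented
    so position 0 is the labeled 5' terminus.
    """
    t = template.seq if isinstance(template, SeqRecord) else normalize_seq(template)
    if fwd.labeled == rev.labeled:
        raise InputError("exactly one primer of the pair must be labeled")
    fwd_hits = match_iupac(fwd.seq, t)
    if not fwd_hits:
        raise NoAmpliconError(f"no amplicon: forward primer {fwd.name!r} has no site")
    rev_rc = reverse_complement(rev.seq)
    rev_hits = match_iupac(rev_rc, t)
    if not rev_hits:
        raise NoAmpliconError(f"no amplicon: reverse primer {rev.name!r} has no site")
    f0 = fwd_hits[0]
    ends = [h + len(rev_rc) for h in rev_hits if h >= f0 + len(fwd.seq)]
    if not ends:
        raise NoAmpliconError(
            f"no amplicon: reverse site for {rev.name!r} not downstream of forward site"
        )
    amp = t[f0 : max(ends)]
    if rev.labeled:
        amp = reverse_complement(amp)
    return amp


@dataclass(frozen=True)
class TRFResult:
    """Predicted terminal fragment: length in bp, and whether the enzyme cut.

    When ``uncut`` is true the length is the full amplicon length.
    """

    length: int
    uncut: bool


def predict_trf(amplicon: str, enzyme: Enzyme) -> TRFResult:
    """T-RF length from the 5'-most recognition-site match.

    The amplicon must be oriented with the labeled 5' terminus at position 0.
    """
    if not amplicon:
        raise InputError("empty amplicon")
    amp = normalize_seq(amplicon, "amplicon")
    hits = match_iupac(enzyme.recognition, amp)
    if not hits:
        return TRFResult(length=len(amp), uncut=True)
    return TRFResult(length=hits[0] + enzyme.cut_offset, uncut=False)


@dataclass(frozen=True)
class TRFPrediction:
    """One merged T-RF category: clade label(s) and their predicted length(s)."""

    clade_label: str
    trf_lengths: frozenset[int]
    category_label: str

    def __post_init__(self) -> None:
        if not self.trf_lengths or any(l < 1 for l in self.trf_lengths):
            raise InputError("T-RF lengths must be positive integers")


def group_by_clade(refs: Iterable[SeqRecord]) -> dict[str, list[SeqRecord]]:
    """Group reference records by their clade label (label required)."""
    groups: dict[str, list[SeqRecord]] = {}
    for r in refs:
        if r.clade_label is None:
            raise InputError(f"reference {r.id!r} lacks a clade label")
        groups.setdefault(r.clade_label, []).append(r)
    return groups


def predict_clade_trfs(
    refs: Iterable[SeqRecord],
    fwd: Primer = TRBCL_F,
    rev: Primer = TRBCL_R,
    enzyme: Enzyme = TAI_I,
    include_uncut: bool = False,
) -> tuple[dict[str, set[int]], int]:
    """Per-clade sets of predicted T-RF lengths.

    References without a valid amplicon are skipped; uncut amplicons are
    excluded unless ``include_uncut`` (then the full amplicon length stands
    in as a pseudo-T-RF).  Returns (clade -> lengths, number of uncut refs).
    A clade whose references yield no amplicon at all is an error.
    """
    groups = group_by_clade(refs)
    out: dict[str, set[int]] = {}
    n_uncut = 0
    for clade, records in groups.items():
        lengths: set[int] = set()
        n_amplicons = 0
        for rec in records:
            try:
                amp = extract_amplicon(rec, fwd, rev)
            except NoAmpliconError:
                continue
            n_amplicons += 1
            trf = predict_trf(amp, enzyme)
            if trf.uncut:
                n_uncut += 1
                if include_uncut:
                    lengths.add(trf.length)
            else:
                lengths.add(trf.length)
        if n_amplicons == 0:
            raise NoAmpliconError(f"clade {clade!r}: no reference yields an amplicon")
        out[clade] = lengths
    return out, n_uncut


def merge_categories(
    clade_trfs: Mapping[str, "set[int] | frozenset[int]"], tolerance: float = 1.5
) -> list[TRFPrediction]:
    """Merge clades whose T-RF sets are within 2x``tolerance`` of each other.

    Single-linkage: two clades merge when the minimum absolute difference
    between any of their lengths is <= 2*tolerance (clades separated by more
    than that from all others stay resolved).  Clades with no predicted
    length (all uncut) are dropped.  Category labels join the member clade
    labels with "/" in sorted order.
    """
    clades = sorted(c for c, ls in clade_trfs.items() if ls)
    parent = {c: c for c in clades}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for a, b in itertools.combinations(clades, 2):
        d = min(abs(x - y) for x in clade_trfs[a] for y in clade_trfs[b])
        if d <= 2 * tolerance:
            parent[find(a)] = find(b)

    members: dict[str, list[str]] = {}
    for c in clades:
        members.setdefault(find(c), []).append(c)
    predictions = []
    for group in members.values():
        group = sorted(group)
        label = "/".join(group)
        lengths = frozenset(l for c in group for l in clade_trfs[c])
        predictions.append(TRFPrediction(clade_label=label, trf_lengths=lengths, category_label=label))
    return sorted(predictions, key=lambda p: p.category_label)


@dataclass(frozen=True)
class EnzymeScreen:
    """Screening result for one enzyme: resolvable categories and uncut count."""

    enzyme: Enzyme
    n_categories: int
    categories: tuple[TRFPrediction, ...]
    n_uncut: int
    all_uncut: bool


def screen_enzymes(
    refs: Iterable[SeqRecord],
    enzymes: Sequence[Enzyme],
    fwd: Primer = TRBCL_F,
    rev: Primer = TRBCL_R,
    tolerance: float = 1.5,
) -> list[EnzymeScreen]:
    """Rank enzymes by how many merged T-RF categories they resolve.

    Ties are broken by enzyme name.  Enzymes that cut nothing are retained
    in the ranking with ``all_uncut`` set.
    """
    refs = list(refs)
    results = []
    for enz in enzymes:
        clade_trfs, n_uncut = predict_clade_trfs(refs, fwd, rev, enz)
        cats = merge_categories(clade_trfs, tolerance)
        results.append(
            EnzymeScreen(
                enzyme=enz,
                n_categories=len(cats),
                categories=tuple(cats),
                n_uncut=n_uncut,
                all_uncut=len(cats) == 0,
            )
        )
    return sorted(results, key=lambda r: (-r.n_categories, r.enzyme.name))


# ---------------------------------------------------------------------------
# Distances, deduplication, chimera screening
# ---------------------------------------------------------------------------

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes; anything outside ACGT becomes 255."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _p_distance_arrays(a: np.ndarray, b: np.ndarray) -> float:
    comparable = (a != 255) & (b != 255)
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable unambiguous columns")
    return int((a[comparable] != b[comparable]).sum()) / n


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites between two aligned sequences.

    Only columns where both symbols are unambiguous bases (ACGT) are
    compared; ambiguity codes and gaps are excluded.  Sequences must be the
    same length (pre-aligned).
    """
    if len(a) != len(b):
        raise InputError(f"length mismatch: {len(a)} vs {len(b)}")
    return _p_distance_arrays(_encode(a), _encode(b))


@dataclass(frozen=True)
class Representative:
    """Representative record of a deduplicated clone group."""

    record: SeqRecord
    count: int
    member_ids: tuple[str, ...]


def dedup_clones(clones: Sequence[SeqRecord], threshold: float = 0.001) -> list[Representative]:
    """Collapse near-identical clones (PCR error) into representatives.

    Single-linkage grouping at p-distance strictly below ``threshold``;
    sequence pairs at exactly the threshold stay separate.  Each group is
    represented by its most frequent member sequence (ties broken by the
    lexicographically smallest record id).  Idempotent on its own output.
    """
    clones = list(clones)
    if not clones:
        return []
    lengths = {len(c) for c in clones}
    if len(lengths) > 1:
        raise InputError("clones must be aligned to equal length")
    enc = [_encode(c.seq) for c in clones]
    n = len(clones)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if _p_distance_arrays(enc[i], enc[j]) < threshold:
            parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    reps = []
    for idx in groups.values():
        seq_counts = Counter(clones[i].seq for i in idx)
        best_count = max(seq_counts.values())
        best_seqs = {s for s, c in seq_counts.items() if c == best_count}
        rep_i = min(
            (i for i in idx if clones[i].seq in best_seqs), key=lambda i: clones[i].id
        )
        reps.append(
            Representative(
                record=clones[rep_i],
                count=len(idx),
                member_ids=tuple(sorted(clones[i].id for i in idx)),
            )
        )
    return sorted(reps, key=lambda r: (-r.count, r.record.id))


@dataclass(frozen=True)
class ChimeraResult:
    """Outcome of the half-alignment chimera screen.

    ``flag`` is one of "clean", "chimeric" or "unscreenable";
    ``five_prime``/``three_prime`` give the nearest clade of each half.
    """

    flag: str
    five_prime: Optional[str] = None
    three_prime: Optional[str] = None

    @property
    def is_chimeric(self) -> bool:
        return self.flag == "chimeric"


def _nearest_clade(
    query: np.ndarray, groups: Mapping[str, list[np.ndarray]], sl: slice
) -> tuple[str, dict[str, float]]:
    dists = {}
    for clade, encs in groups.items():
        d = np.inf
        for e in encs:
            try:
                d = min(d, _p_distance_arrays(query[sl], e[sl]))
            except UndefinedDistanceError:
                continue
        dists[clade] = d
    best = min(dists, key=lambda c: (dists[c], c))
    return best, dists


def chimera_screen(
    query: SeqRecord,
    refs: Iterable[SeqRecord],
    min_divergence: float = 0.005,
    min_half_len: int = 100,
) -> ChimeraResult:
    """Flag a clone whose 5' and 3' halves descend from different clades.

    The alignment is split at its midpoint and each half is assigned to the
    nearest reference clade by p-distance.  The clone is chimeric iff the
    two halves assign to different clades and those clades are themselves
    separated by at least ``min_divergence`` over each corresponding half
    (below that the halves are not distinguishable and the clone passes).
    Queries shorter than twice ``min_half_len`` are unscreenable.
    """
    refs = list(refs)
    groups_rec = group_by_clade(refs)
    L = len(query)
    for r in refs:
        if len(r) != L:
            raise InputError("query must be aligned to the references (equal length)")
    if L < 2 * min_half_len:
        return ChimeraResult(flag="unscreenable")
    mid = L // 2
    halves = [slice(0, mid), slice(mid, L)]
    groups = {c: [_encode(r.seq) for r in rs] for c, rs in groups_rec.items()}
    q = _encode(query.seq)

    assigned = [_nearest_clade(q, groups, h)[0] for h in halves]
    if assigned[0] == assigned[1]:
        return ChimeraResult(flag="clean", five_prime=assigned[0], three_prime=assigned[1])

    def clade_separation(sl: slice) -> float:
        d = np.inf
        for ea in groups[assigned[0]]:
            for eb in groups[assigned[1]]:
                try:
                    d = min(d, _p_distance_arrays(ea[sl], eb[sl]))
                except UndefinedDistanceError:
                    continue
        return d

    if all(clade_separation(h) >= min_divergence for h in halves):
        return ChimeraResult(flag="chimeric", five_prime=assigned[0], three_prime=assigned[1])
    return ChimeraResult(flag="clean", five_prime=assigned[0], three_prime=assigned[1])


def assign_to_clade(query: SeqRecord, refs: Iterable[SeqRecord]) -> str:
    """Nearest-reference clade assignment over the full alignment."""
    refs = list(refs)
    groups = {c: [_encode(r.seq) for r in rs] for c, rs in group_by_clade(refs).items()}
    best, _ = _nearest_clade(_encode(query.seq), groups, slice(0, len(query)))
    return best
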