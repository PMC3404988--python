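"""Synthetic data emulating a multi-source kleptoplast T-RFLP study.

Generators for:

* clade-structured reference sequences that carry the degenerate primer
  sites and a clade-discriminating first restriction site (so each clade has
  a known predicted T-RF, with optional engineered length collisions that
  force category merges);
* clone libraries drawn multinomially from a clade mixture, with per-base
  PCR point error and a fraction of mid-sequence chimeras;
* electropherogram peak tables with lognormal height noise and Gaussian
  size-calling jitter (plus optional out-of-window noise peaks);
* amino-acid d15N datasets obtained by inverting the trophic-position
  formula with Gaussian noise.

Sequence evolution is independent uniform substitution without indels, so
all outputs stay aligned by construction.  Every generator takes an
explicit seed (via :class:`SimConfig` or an argument) and is byte-for-byte
reproducible.  Default rates mirror the study conditions: ~700 bp
amplicons, 8 clades, within-clade divergence 0.002 against the 0.001 dedup
threshold, PCR point error 0.001/base, chimera rate 0.01 (2 chimeras were
found among 209 clones), 10% peak-height CV and 0.3 bp size jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError, InputError
from .seqlib import (
    TAI_I,
    TRBCL_F,
    TRBCL_R,
    Enzyme,
    Primer,
    SeqRecord,
    extract_amplicon,
    match_iupac,
    predict_trf,
    reverse_complement,
)
from .stats import BETA, TEF, IsotopeRecord
from .trflp import Chromatogram, Peak

_BASES = np.array(list("ACGT"))

#: Clade labels follow the study's A.. naming.
_CLADE_NAMES = [chr(ord("A") + i) for i in range(26)]


@dataclass(frozen=True)
class MixtureSpec:
    """Per-individual kleptoplast composition: clade label -> proportion."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise InputError("mixture must contain at least one clade")
        if any(w < 0 for w in self.weights.values()):
            raise InputError("mixture weights must be non-negative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"mixture weights sum to {total}, expected 1")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the simulated study, all rates per site/base/clone."""

    seed: int
    n_clades: int = 8
    seq_length: int = 700
    n_refs_per_clade: int = 3
    between_clade_divergence: float = 0.05
    within_clade_divergence: float = 0.002
    pcr_error_rate: float = 0.001
    chimera_rate: float = 0.01
    height_cv: float = 0.10
    size_jitter_sd: float = 0.3
    qv: float = 90.0

    def __post_init__(self) -> None:
        for name in (
            "between_clade_divergence",
            "within_clade_divergence",
            "pcr_error_rate",
            "chimera_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_clades < 1:
            raise ConfigError("n_clades must be >= 1")
        if self.seq_length < 300:
            raise ConfigError("seq_length must be >= 300")


def _expand_degenerate(pattern: str, rng: np.random.Generator) -> str:
    """One concrete expansion of an IUPAC pattern (random choice per code)."""
    from .seqlib import IUPAC_SETS

    return "".join(
        c if c in "ACGT" else rng.choice(sorted(IUPAC_SETS[c])) for c in pattern
    )


def _mutate(
    seq: np.ndarray, positions: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute at ``rate`` per site over ``positions``; returns a copy."""
    out = seq.copy()
    if rate <= 0 or positions.size == 0:
        return out
    hit = positions[rng.random(positions.size) < rate]
    for p in hit:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[rng.integers(3)]
    return out


def _scrub_early_sites(
    seq: np.ndarray,
    recognition: str,
    designed_start: int,
    protected: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Destroy recognition-site matches starting before the designed site.

    Mutates ``seq`` in place at unprotected positions until the 5'-most
    match is the designed one.  Raises :class:`ConfigError` if an offending
    match lies entirely inside protected positions (primer footprint).
    """
    m = len(recognition)
    for _ in range(10 * seq.size):
        hits = match_iupac(recognition, "".join(seq))
        early = [h for h in hits if h < designed_start]
        if not early:
            return
        h = early[0]
        free = [p for p in range(h, h + m) if not protected[p]]
        if not free:
            raise ConfigError(
                "recognition site unavoidably present inside a primer footprint"
            )
        p = free[rng.integers(len(free))]
        alternatives = [b for b in "ACGT" if b != seq[p]]
        seq[p] = alternatives[rng.integers(3)]
    raise ConfigError("could not scrub early recognition sites")


@dataclass(frozen=True)
class ReferenceSet:
    """Simulated reference clades with their designed T-RF truth."""

    records: tuple[SeqRecord, ...]
    trf_by_clade: dict[str, int]
    fwd: Primer
    rev: Primer
    enzyme: Enzyme

    def by_clade(self) -> dict[str, list[SeqRecord]]:
        out: dict[str, list[SeqRecord]] = {}
        for r in self.records:
            out.setdefault(r.clade_label, []).append(r)
        return out


def simulate_reference_set(
    config: SimConfig,
    fwd: Primer = TRBCL_F,
    rev: Primer = TRBCL_R,
    enzyme: Enzyme = TAI_I,
    collisions: Sequence[tuple[str, str]] = (),
) -> ReferenceSet:
    """Reference clades with embedded primer sites and designed T-RFs.

    Each clade's references share a first recognition-site position
    (hence an identical predicted T-RF); designed T-RFs of different clades
    are at least 5 bp apart unless the pair is listed in ``collisions``, in
    which case the second clade reuses the first clade's length (emulating
    indistinguishable categories).  Within-clade variation is confined to
    positions downstream of the first cut site so it cannot move it.
    """
    rng = np.random.default_rng(config.seed)
    clades = _CLADE_NAMES[: config.n_clades]
    for a, b in collisions:
        if a not in clades or b not in clades:
            raise ConfigError(f"collision ({a},{b}) names an unknown clade")

    fwd_len = len(fwd.seq)
    rev_len = len(rev.seq)
    m = len(enzyme.recognition)
    rev_start = config.seq_length - rev_len

    # Designed T-RF targets: spaced >= 5 bp, inside the interior and inside
    # the 100-1200 bp electropherogram analysis window (study T-RFs span
    # 138-366 bp).
    first = max(fwd_len + 30, 130)
    spacing = 25
    targets: dict[str, int] = {}
    merged_to: dict[str, str] = {b: a for a, b in collisions}
    k = 0
    for c in clades:
        if c in merged_to:
            continue
        targets[c] = first + spacing * k
        k += 1
    for c in clades:
        if c in merged_to:
            targets[c] = targets[merged_to[c]]
    max_site_end = max(t - enzyme.cut_offset + m for t in targets.values())
    if max_site_end >= rev_start:
        raise ConfigError(
            f"sequence length {config.seq_length} too short to place "
            f"{config.n_clades} discriminating restriction sites"
        )

    fwd_site = _expand_degenerate(fwd.seq, rng)
    rev_site = reverse_complement(_expand_degenerate(rev.seq, rng))
    interior = rng.choice(_BASES, size=config.seq_length - fwd_len - rev_len)
    ancestor = np.concatenate(
        [np.array(list(fwd_site)), interior, np.array(list(rev_site))]
    )
    protected = np.zeros(config.seq_length, dtype=bool)
    protected[:fwd_len] = True
    protected[rev_start:] = True

    records: list[SeqRecord] = []
    trf_by_clade: dict[str, int] = {}
    all_positions = np.arange(config.seq_length)
    mutable = all_positions[~protected]
    for clade in clades:
        trf = targets[clade]
        site_start = trf - enzyme.cut_offset
        root = _mutate(ancestor, mutable, config.between_clade_divergence, rng)
        site = _expand_degenerate(enzyme.recognition, rng)
        root[site_start : site_start + m] = list(site)
        prot = protected.copy()
        prot[site_start : site_start + m] = True
        _scrub_early_sites(root, enzyme.recognition, site_start, prot, rng)
        trf_by_clade[clade] = trf
        downstream = all_positions[
            (all_positions >= site_start + m) & (all_positions < rev_start)
        ]
        for i in range(config.n_refs_per_clade):
            variant = _mutate(root, downstream, config.within_clade_divergence, rng)
            records.append(
                SeqRecord(
                    id=f"{clade}_ref{i + 1}", seq="".join(variant), clade_label=clade
                )
            )
    refset = ReferenceSet(
        records=tuple(records),
        trf_by_clade=trf_by_clade,
        fwd=fwd,
        rev=rev,
        enzyme=enzyme,
    )
    # sanity: the designed T-RFs must be what the digestion machinery sees
    for rec in records:
        got = predict_trf(extract_amplicon(rec, fwd, rev), enzyme)
        if got.uncut or got.length != trf_by_clade[rec.clade_label]:
            raise ConfigError(
                f"simulated reference {rec.id} digests to {got.length} "
                f"instead of the designed {trf_by_clade[rec.clade_label]}"
            )
    return refset


@dataclass(frozen=True)
class CloneLibrary:
    """Simulated clone library with per-clone truth labels.

    Chimeric clones carry the truth label ``"chimera:X/Y"`` (5'/3' parents).
    """

    records: tuple[SeqRecord, ...]
    truth_labels: tuple[str, ...]
    n_chimeras: int


def simulate_clone_library(
    refset: ReferenceSet,
    mixture: MixtureSpec,
    n_clones: int,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> CloneLibrary:
    """Clones drawn from a clade mixture with PCR point error and chimeras.

    Clade counts are multinomial in the mixture weights; each clone is a
    randomly chosen clade reference with substitutions at the PCR error
    rate; a ``chimera_rate`` fraction is replaced by splices of two distinct
    clades at the alignment midpoint (+/-5% jitter).
    """
    if n_clones <= 0:
        raise InputError(f"n_clones must be positive, got {n_clones}")
    by_clade = refset.by_clade()
    unknown = set(mixture.weights) - set(by_clade)
    if unknown:
        raise InputError(f"mixture names unknown clades: {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clades = sorted(mixture.weights)
    weights = np.array([mixture.weights[c] for c in clades])
    counts = rng.multinomial(n_clones, weights)
    L = len(refset.records[0])
    all_pos = np.arange(L)

    def draw_clone(clade: str) -> np.ndarray:
        refs = by_clade[clade]
        base = np.array(list(refs[rng.integers(len(refs))].seq))
        return _mutate(base, all_pos, config.pcr_error_rate, rng)

    records: list[SeqRecord] = []
    labels: list[str] = []
    n_chim = 0
    i = 0
    for clade, count in zip(clades, counts):
        for _ in range(count):
            i += 1
            if len(clades) > 1 and rng.random() < config.chimera_rate:
                other = [c for c in clades if c != clade]
                mate = other[rng.integers(len(other))]
                jitter = int(round(L * 0.05))
                split = L // 2 + int(rng.integers(-jitter, jitter + 1))
                left = draw_clone(clade)
                right = draw_clone(mate)
                seq = np.concatenate([left[:split], right[split:]])
                records.append(
                    SeqRecord(id=f"clone{i:04d}", seq="".join(seq), clade_label=None)
                )
                labels.append(f"chimera:{clade}/{mate}")
                n_chim += 1
            else:
                records.append(
                    SeqRecord(
                        id=f"clone{i:04d}",
                        seq="".join(draw_clone(clade)),
                        clade_label=None,
                    )
                )
                labels.append(clade)
    return CloneLibrary(
        records=tuple(records), truth_labels=tuple(labels), n_chimeras=n_chim
    )


@dataclass(frozen=True)
class SimulatedChromatogram:
    """A simulated electropherogram and its ground-truth RA by category."""

    chromatogram: Chromatogram
    truth_ra: dict[str, float]


def simulate_electropherogram(
    refset: ReferenceSet,
    mixture: MixtureSpec,
    config: SimConfig,
    sample_id: str = "sim",
    month: str = "2005-06",
    rng: Optional[np.random.Generator] = None,
    base_height: float = 10_000.0,
    noise_peaks: bool = False,
) -> SimulatedChromatogram:
    """One peak per clade T-RF, with height and size-calling noise.

    Peak height is proportional to the mixture weight (equal chloroplast
    genome copy number assumed) with multiplicative lognormal noise of the
    configured CV; the called size gets Gaussian jitter.  Clades sharing a
    T-RF merge into a single peak whose truth label joins the clade names
    with "/".  ``noise_peaks`` adds spurious peaks outside the 100-1200 bp
    analysis window to exercise QC.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    unknown = set(mixture.weights) - set(refset.trf_by_clade)
    if unknown:
        raise InputError(f"mixture names unknown clades: {sorted(unknown)}")
    # group mixture clades by their (possibly shared) T-RF
    by_trf: dict[int, list[str]] = {}
    for clade, w in sorted(mixture.weights.items()):
        if w > 0:
            by_trf.setdefault(refset.trf_by_clade[clade], []).append(clade)

    sigma = float(np.sqrt(np.log1p(config.height_cv**2)))
    peaks: list[Peak] = []
    truth: dict[str, float] = {}
    for trf in sorted(by_trf):
        members = by_trf[trf]
        weight = sum(mixture.weights[c] for c in members)
        label = "/".join(members)
        noise = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma) if sigma > 0 else 1.0
        height = base_height * weight * noise
        size = trf + (rng.normal(0.0, config.size_jitter_sd) if config.size_jitter_sd else 0.0)
        peaks.append(Peak(size=size, height=height))
        truth[label] = weight * 100.0
    if noise_peaks:
        peaks.append(Peak(size=float(rng.uniform(60, 95)), height=base_height * 0.05))
        peaks.append(Peak(size=float(rng.uniform(1210, 1290)), height=base_height * 0.05))
    chrom = Chromatogram(
        sample_id=sample_id, collection_month=month, qv=config.qv, peaks=tuple(peaks)
    )
    return SimulatedChromatogram(chromatogram=chrom, truth_ra=truth)


def simulate_aa_isotopes(
    tp_true: float,
    n: int,
    d15n_phe_base: float = 8.0,
    noise_sd: float = 0.3,
    beta: float = BETA,
    tef: float = TEF,
    seed: Optional[int] = None,
    group_label: str = "sim",
    rng: Optional[np.random.Generator] = None,
) -> list[IsotopeRecord]:
    """Invert the TP formula with Gaussian noise to emulate CSIA-AA data.

    Per specimen: d15N_Phe ~ base + eps, d15N_Glu = d15N_Phe + beta +
    tef*(tp_true - 1) + eps', with independent N(0, noise_sd) errors.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        phe = d15n_phe_base + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        glu = (
            phe
            + beta
            + tef * (tp_true - 1.0)
            + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        )
        records.append(
            IsotopeRecord(
                specimen_id=f"{group_label}{i + 1:03d}",
                d15n_glu=float(glu),
                d15n_phe=float(phe),
                group_label=group_label,
            )
        )
    return records
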