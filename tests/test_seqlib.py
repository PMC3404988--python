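"""Degenerate matching, in silico PCR/digestion, distances, dedup, chimeras."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import expand_first
from kleptotrf.errors import (
    InputError,
    NoAmpliconError,
    UndefinedDistanceError,
)
from kleptotrf.seqlib import (
    IUPAC_SETS,
    TAI_I,
    TRBCL_F,
    TRBCL_R,
    Enzyme,
    Primer,
    SeqRecord,
    chimera_screen,
    dedup_clones,
    extract_amplicon,
    match_iupac,
    merge_categories,
    p_distance,
    predict_trf,
    reverse_complement,
    screen_enzymes,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestMatchIupac:
    @pytest.mark.parametrize(
        "pattern, seq, expected",
        [
            ("ACGT", "AACGTT", [1]),
            ("ACKT", "ACGTACTT", [0, 4]),  # K = {G,T}: brute-force gives 0 and 4
            ("NNNN", "ACGT", [0]),
            ("ACGT", "AAAA", []),
        ],
    )
    def test_examples(self, pattern, seq, expected):
        assert match_iupac(pattern, seq) == expected

    def test_degenerate_primer_matches_own_expansion(self):
        expansion = expand_first(TRBCL_F.seq)
        assert match_iupac(TRBCL_F.seq, expansion) == [0]

    def test_non_iupac_character_named_in_error(self):
        with pytest.raises(InputError, match="'Z'"):
            match_iupac("ACZT", "ACGT")

    @given(pattern=st.text(alphabet="ACGT", min_size=1, max_size=6), seq=dna)
    def test_literal_pattern_equals_substring_search(self, pattern, seq):
        expected = [
            i for i in range(len(seq) - len(pattern) + 1)
            if seq[i : i + len(pattern)] == pattern
        ]
        assert match_iupac(pattern, seq) == expected

    @given(
        pattern=st.text(alphabet="ACGTKMRYWSN", min_size=1, max_size=4),
        seq=st.text(alphabet="ACGT", min_size=1, max_size=30),
    )
    def test_degenerate_matches_expansion_union(self, pattern, seq):
        """A degenerate hit set is the union over all literal expansions."""
        expansions = itertools.product(*(sorted(IUPAC_SETS[c]) for c in pattern))
        expected = sorted(
            {
                i
                for exp in expansions
                for i in range(len(seq) - len(pattern) + 1)
                if seq[i : i + len(pattern)] == "".join(exp)
            }
        )
        assert match_iupac(pattern, seq) == expected


FWD = Primer("F", "GAGAGAGAGA", labeled=True)
REV = Primer("R", "AGAGAGAGAG", labeled=False)  # binds as CTCTCTCTCT
REV_SITE = reverse_complement(REV.seq)


class TestExtractAmplicon:
    def test_amplicon_spans_both_primer_footprints(self):
        template = FWD.seq + "AT" * 50 + REV_SITE
        amp = extract_amplicon(template, FWD, REV)
        assert amp == template
        assert len(amp) == len(FWD.seq) + 100 + len(REV.seq)

    def test_two_forward_sites_take_five_prime_most(self):
        template = FWD.seq + "AT" * 10 + FWD.seq + "AT" * 20 + REV_SITE
        amp = extract_amplicon(template, FWD, REV)
        assert len(amp) == len(template)

    def test_two_reverse_sites_take_three_prime_most(self):
        template = FWD.seq + "AT" * 10 + REV_SITE + "AT" * 10 + REV_SITE
        amp = extract_amplicon(template, FWD, REV)
        assert len(amp) == len(template)

    def test_missing_reverse_site_is_no_amplicon(self):
        with pytest.raises(NoAmpliconError, match="reverse"):
            extract_amplicon(FWD.seq + "AT" * 50, FWD, REV)

    def test_missing_forward_site_is_no_amplicon(self):
        with pytest.raises(NoAmpliconError, match="forward"):
            extract_amplicon("AT" * 50 + REV_SITE, FWD, REV)

    def test_reverse_site_upstream_is_no_amplicon(self):
        with pytest.raises(NoAmpliconError, match="downstream"):
            extract_amplicon(REV_SITE + "AT" * 5 + FWD.seq, FWD, REV)

    def test_labeled_reverse_primer_reorients_amplicon(self):
        fwd = Primer("F", "GAGAGAGAGA", labeled=False)
        rev = Primer("R", "AGAGAGAGAG", labeled=True)
        template = fwd.seq + "AT" * 50 + reverse_complement(rev.seq)
        amp = extract_amplicon(template, fwd, rev)
        assert amp == reverse_complement(template)
        assert amp.startswith(rev.seq)

    def test_both_primers_labeled_rejected(self):
        bad = Primer("R", "AGAGAGAGAG", labeled=True)
        with pytest.raises(InputError, match="labeled"):
            extract_amplicon(FWD.seq + REV_SITE, FWD, bad)


class TestPredictTrf:
    def test_uncut_amplicon_reports_full_length(self):
        res = predict_trf("AAAAAAAA", TAI_I)
        assert res.uncut and res.length == 8

    def test_first_site_plus_offset(self):
        amp = "AC" * 67 + "ACGT" + "A" * 50  # first ACGT starts at 134
        res = predict_trf(amp, TAI_I)
        assert not res.uncut and res.length == 138

    def test_empty_amplicon_rejected(self):
        with pytest.raises(InputError):
            predict_trf("", TAI_I)

    def test_trf_never_exceeds_amplicon_and_is_append_invariant(self, rng):
        for _ in range(50):
            amp = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 400))))
            res = predict_trf(amp, TAI_I)
            assert res.length <= len(amp)
            if not res.uncut:
                extended = amp + "".join(rng.choice(list("ACGT"), size=30))
                assert predict_trf(extended, TAI_I).length == res.length

    def test_matches_bruteforce_site_enumeration(self, rng):
        def oracle(amp, enzyme):
            m = len(enzyme.recognition)
            starts = [
                i
                for i in range(len(amp) - m + 1)
                if all(
                    amp[i + j] in IUPAC_SETS[enzyme.recognition[j]] for j in range(m)
                )
            ]
            return (min(starts) + enzyme.cut_offset) if starts else None

        enz = Enzyme("toy", "GANTC", 2)
        for _ in range(100):
            amp = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 300))))
            expected = oracle(amp, enz)
            got = predict_trf(amp, enz)
            if expected is None:
                assert got.uncut
            else:
                assert got.length == expected


def _toy_screen_setup():
    """Three clades and two enzymes with designed fragment lengths.

    EnzA (GGGG, offset 0) yields 100/100/200; EnzB (CCCC, offset 4) yields
    100/150/200, so EnzB resolves 3 categories to EnzA's 2.
    """
    enz_a = Enzyme("EnzA", "GGGG", 0)
    enz_b = Enzyme("EnzB", "CCCC", 4)
    targets = {"c1": (100, 100), "c2": (100, 150), "c3": (200, 200)}
    records = []
    for clade, (ta, tb) in targets.items():
        seq = list(FWD.seq + "AT" * 150 + REV_SITE)
        seq[tb - 4 : tb] = "CCCC"
        seq[ta : ta + 4] = "GGGG"
        records.append(SeqRecord(id=clade, seq="".join(seq), clade_label=clade))
    return records, enz_a, enz_b


class TestScreenEnzymes:
    def test_single_clade_yields_one_category_per_enzyme(self):
        records, enz_a, enz_b = _toy_screen_setup()
        out = screen_enzymes(records[:1], [enz_a, enz_b], FWD, REV, tolerance=1.5)
        assert [r.n_categories for r in out] == [1, 1]

    def test_more_discriminating_enzyme_ranks_first(self):
        records, enz_a, enz_b = _toy_screen_setup()
        out = screen_enzymes(records, [enz_a, enz_b], FWD, REV, tolerance=1.5)
        assert [r.enzyme.name for r in out] == ["EnzB", "EnzA"]
        assert [r.n_categories for r in out] == [3, 2]

    def test_noncutting_enzyme_flagged_but_ranked(self):
        records, enz_a, _ = _toy_screen_setup()
        nocut = Enzyme("NoCut", "TTTTTTTT", 0)
        out = screen_enzymes(records, [enz_a, nocut], FWD, REV)
        assert out[-1].enzyme.name == "NoCut"
        assert out[-1].all_uncut and out[-1].n_categories == 0

    def test_category_count_bounded_by_clades(self, refset8):
        out = screen_enzymes(refset8.records, [TAI_I], TRBCL_F, TRBCL_R)
        assert 1 <= out[0].n_categories <= len(refset8.trf_by_clade)

    def test_merge_is_single_linkage_within_twice_tolerance(self):
        cats = merge_categories({"a": {100}, "b": {102}, "c": {105}}, tolerance=1.5)
        # a-b merge (d=2 <= 3) and b-c merge (d=3 <= 3) chain into one category
        assert len(cats) == 1 and cats[0].category_label == "a/b/c"


class TestPDistance:
    def test_identity_is_zero(self):
        assert p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_two_mismatches_over_thousand(self):
        a = "A" * 1000
        b = "A" * 998 + "CC"
        assert p_distance(a, b) == pytest.approx(0.002)

    def test_ambiguous_columns_excluded(self):
        assert p_distance("ACGTAA", "ANGTAA") == 0.0
        assert p_distance("ACGTAA", "ANGTAC") == pytest.approx(1 / 5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            p_distance("ACGT", "ACG")

    def test_no_comparable_columns_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("NNNN", "ACGT")

    @given(a=dna, b=dna)
    def test_symmetric_and_bounded(self, a, b):
        if len(a) != len(b):
            a = b = a + b
        d = p_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == p_distance(b, a)


def _clone(i, seq):
    return SeqRecord(id=f"c{i:02d}", seq=seq)


class TestDedupClones:
    def test_identical_clones_collapse_with_count(self):
        reps = dedup_clones([_clone(i, "ACGT" * 100) for i in range(5)])
        assert len(reps) == 1
        assert reps[0].count == 5
        assert reps[0].record.id == "c00"

    def test_near_identical_grouped_distant_kept(self):
        base = "ACGT" * 314 + "AC"  # 1258 sites, ~1254-column alignment scale
        a = base
        b = base[:-1] + ("G" if base[-1] != "G" else "T")  # 1 diff, p ~ 0.0008
        c = "TGCA" * 2 + base[8:]  # many diffs, p ~ 0.006
        reps = dedup_clones([_clone(0, a), _clone(1, b), _clone(2, c)])
        assert len(reps) == 2
        assert sorted(r.count for r in reps) == [1, 2]

    def test_exactly_threshold_stays_separate(self):
        a = "A" * 1000
        b = "C" + "A" * 999  # p = 0.001 exactly, strict <
        reps = dedup_clones([_clone(0, a), _clone(1, b)], threshold=0.001)
        assert len(reps) == 2

    def test_most_frequent_member_represents_group(self):
        major = "A" * 2000
        minor = "C" + "A" * 1999  # within threshold of major
        reps = dedup_clones(
            [_clone(0, minor), _clone(1, major), _clone(2, major)], threshold=0.001
        )
        assert len(reps) == 1
        assert reps[0].record.seq == major
        assert reps[0].count == 3

    def test_idempotent_on_own_representatives(self, rng):
        clones = []
        base = "".join(rng.choice(list("ACGT"), size=1200))
        for i in range(20):
            seq = list(base)
            for _ in range(int(rng.integers(0, 12))):
                p = int(rng.integers(len(seq)))
                seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
            clones.append(_clone(i, "".join(seq)))
        reps = dedup_clones(clones)
        again = dedup_clones([r.record for r in reps])
        assert {r.record.id for r in again} == {r.record.id for r in reps}
        assert all(r.count == 1 for r in again)

    def test_empty_input_empty_output(self):
        assert dedup_clones([]) == []


class TestChimeraScreen:
    def test_reference_member_is_clean(self, refset8):
        query = refset8.records[0]
        res = chimera_screen(query, refset8.records)
        assert res.flag == "clean"
        assert res.five_prime == res.three_prime == "A"

    def test_half_splice_of_divergent_clades_flagged(self, refset8):
        by_clade = refset8.by_clade()
        a = by_clade["A"][0].seq
        c = by_clade["C"][0].seq
        mid = len(a) // 2
        query = SeqRecord(id="chim", seq=a[:mid] + c[mid:])
        res = chimera_screen(query, refset8.records)
        assert res.is_chimeric
        assert (res.five_prime, res.three_prime) == ("A", "C")

    def test_splice_of_near_identical_references_not_flagged(self):
        base = "ACGT" * 100
        refs = [
            SeqRecord(id="x1", seq=base, clade_label="X"),
            SeqRecord(id="y1", seq=base[:-1] + "A", clade_label="Y"),  # p ~ 0.0025
        ]
        query = SeqRecord(id="q", seq=base[:200] + refs[1].seq[200:])
        res = chimera_screen(query, refs, min_divergence=0.005)
        assert not res.is_chimeric

    def test_short_query_unscreenable(self, refset8):
        short_refs = [
            SeqRecord(id=r.id, seq=r.seq[:150], clade_label=r.clade_label)
            for r in refset8.records
        ]
        query = SeqRecord(id="q", seq=short_refs[0].seq)
        assert chimera_screen(query, short_refs).flag == "unscreenable"
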