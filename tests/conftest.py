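import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kleptotrf.seqlib import IUPAC_SETS, TAI_I, TRBCL_F, TRBCL_R, SeqRecord
from kleptotrf.synthetic import SimConfig, simulate_reference_set

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def expand_first(pattern: str) -> str:
    """Deterministic concrete expansion: alphabetically first base per code."""
    return "".join(sorted(IUPAC_SETS[c])[0] for c in pattern)


@pytest.fixture(scope="session")
def refset8():
    """An 8-clade simulated reference set with the two study-style collisions."""
    config = SimConfig(seed=7)
    return simulate_reference_set(config, collisions=[("A", "D"), ("E", "G")])


def make_standin(name: str, trf: int, length: int = 700) -> SeqRecord:
    """A synthetic stand-in reference with a designed TaiI T-RF.

    Built from a concrete expansion of the degenerate T-RFLP primer pair
    with an AC-repeat filler (which cannot contain the ACGT recognition
    site), and the single designed ACGT site placed so the labeled terminal
    fragment is exactly ``trf`` bp.  These records are synthetic: they stand
    in for deposited rbcL references that cannot be fetched here, carrying
    only the documented primer sites and fragment length, not real algal
    sequence.
    """
    fwd = expand_first(TRBCL_F.seq)
    rev_site = SeqRecord(id="tmp", seq=expand_first(TRBCL_R.seq)).seq
    from kleptotrf.seqlib import reverse_complement

    rev_rc = reverse_complement(rev_site)
    site_start = trf - TAI_I.cut_offset
    pre = "AC" * ((site_start - len(fwd)) // 2 + 1)
    pre = pre[: site_start - len(fwd)]
    mid_len = length - site_start - 4 - len(rev_rc)
    mid = ("AC" * (mid_len // 2 + 1))[:mid_len]
    seq = fwd + pre + "ACGT" + mid + rev_rc
    assert len(seq) == length
    return SeqRecord(id=name, seq=seq)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
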