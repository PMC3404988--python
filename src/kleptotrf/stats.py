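"""Permuted Brunner-Munzel test and amino-acid d15N trophic positions.

Month-to-month shifts in relative abundance are tested with the
Brunner-Munzel rank statistic, whose null distribution is obtained by
reassigning the pooled observations to the two group labels (exhaustive
enumeration for small problems, seeded Monte Carlo otherwise).  The
stochastic-superiority estimate is

    p_hat = P(X < Y) + 1/2 P(X = Y),

computed from pooled midranks, and the statistic is the studentized
difference of mean midranks with the Brunner-Munzel rank-based variance.
Complete separation makes the rank-variance estimate zero; the statistic is
then defined as +/-inf (sign of the mean-rank difference), and 0 when the
mean ranks are also equal (e.g. all values tied), so permutation p-values
remain well defined.

Trophic position is estimated from the d15N difference between glutamic
acid (trophic amino acid) and phenylalanine (source amino acid):

    TP = (d15N_Glu - d15N_Phe - beta) / TEF + 1

with the standard calibration beta = 3.4 permil and TEF = 7.6 permil per
trophic level.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import comb
from scipy.stats import rankdata

from .errors import InputError
from .trflp import Profile

#: Producer-level Glu-Phe offset (permil) and trophic enrichment factor
#: (permil per trophic level) of the standard calibration.
BETA = 3.4
TEF = 7.6

#: Exhaustive enumeration is used when C(n_x+n_y, n_x) is at most this.
MAX_EXHAUSTIVE = 20_000


@dataclass(frozen=True)
class BMResult:
    """Brunner-Munzel statistic and stochastic-superiority estimate."""

    statistic: float
    p_hat: float


def _as_sample(a: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InputError(f"sample {name} must be non-empty and one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"sample {name} contains non-finite values")
    return arr


def brunner_munzel(x: Sequence[float], y: Sequence[float]) -> BMResult:
    """Brunner-Munzel statistic W and p_hat = P(X<Y) + 0.5 P(X=Y).

    Uses midranks of the pooled data.  Zero rank variance yields W = 0 when
    the mean midranks are equal and +/-inf otherwise (complete separation).
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    nx, ny = len(xa), len(ya)
    rc = rankdata(np.concatenate([xa, ya]))
    rcx, rcy = rc[:nx], rc[nx:]
    mx, my = rcx.mean(), rcy.mean()
    p_hat = (my - (ny + 1) / 2) / nx

    rwx = rankdata(xa)
    rwy = rankdata(ya)
    sx2 = ((rcx - rwx - mx + (nx + 1) / 2) ** 2).sum() / (nx - 1) if nx > 1 else 0.0
    sy2 = ((rcy - rwy - my + (ny + 1) / 2) ** 2).sum() / (ny - 1) if ny > 1 else 0.0
    num = nx * ny * (my - mx)
    den = (nx + ny) * math.sqrt(nx * sx2 + ny * sy2)
    if den == 0.0:
        stat = 0.0 if num == 0.0 else math.copysign(math.inf, num)
    else:
        stat = num / den
    return BMResult(statistic=float(stat), p_hat=float(p_hat))


def _bm_stats_batch(pooled: np.ndarray, x_idx: np.ndarray) -> np.ndarray:
    """Vectorized |batch| of BM statistics for group assignments.

    ``pooled`` is the pooled sample (length N); ``x_idx`` is a (B, nx)
    integer array giving, per row, the indices assigned to group x.
    """
    N = pooled.size
    B, nx = x_idx.shape
    ny = N - nx
    rc = rankdata(pooled)

    is_x = np.zeros((B, N), dtype=bool)
    np.put_along_axis(is_x, x_idx, True, axis=1)
    # stable argsort of the mask puts the ny False (y) columns first
    order = np.argsort(is_x, axis=1, kind="stable")
    y_idx = order[:, :ny]

    xv = pooled[x_idx]
    yv = pooled[y_idx]
    rcx = rc[x_idx]
    rcy = rc[y_idx]
    mx = rcx.mean(axis=1)
    my = rcy.mean(axis=1)
    rwx = rankdata(xv, axis=1)
    rwy = rankdata(yv, axis=1)
    sx2 = ((rcx - rwx - mx[:, None] + (nx + 1) / 2) ** 2).sum(axis=1)
    sx2 = sx2 / (nx - 1) if nx > 1 else np.zeros(B)
    sy2 = ((rcy - rwy - my[:, None] + (ny + 1) / 2) ** 2).sum(axis=1)
    sy2 = sy2 / (ny - 1) if ny > 1 else np.zeros(B)
    num = nx * ny * (my - mx)
    den = (nx + ny) * np.sqrt(nx * sx2 + ny * sy2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stats = num / den
    degenerate = den == 0.0
    if np.any(degenerate):
        sep = num[degenerate]
        stats[degenerate] = np.where(
            sep > 0, np.inf, np.where(sep < 0, -np.inf, 0.0)
        )
    return stats


@dataclass(frozen=True)
class TestResult:
    """Permuted Brunner-Munzel test outcome."""

    statistic: float
    p_hat: float
    p_value: float
    n_perm: int
    exhaustive: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hat <= 1.0:
            raise InputError(f"p_hat {self.p_hat} outside [0, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise InputError(f"p-value {self.p_value} outside (0, 1]")


def permuted_bm_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """Two-sided permutation Brunner-Munzel test.

    The null distribution reassigns the pooled values to groups of sizes
    (n_x, n_y).  When the number of distinct assignments C(N, n_x) is at
    most ``MAX_EXHAUSTIVE`` every assignment is enumerated and the p-value
    is the exact proportion with |W*| >= |W_obs|; otherwise ``n_perm``
    seeded Monte Carlo draws are taken and p = (1 + #{|W*| >= |W_obs|}) /
    (1 + n_perm), which can never be zero.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    nx, ny = len(xa), len(ya)
    N = nx + ny
    if N < 4:
        raise InputError(
            f"total sample size {N} < 4: the permutation null is too coarse "
            "to be informative"
        )
    obs = brunner_munzel(xa, ya)
    pooled = np.concatenate([xa, ya])
    n_assign = comb(N, nx, exact=True)
    abs_obs = abs(obs.statistic)
    # small tolerance so permutations tied with the observed statistic count
    eps = 1e-12 if math.isfinite(abs_obs) else 0.0

    if n_assign <= MAX_EXHAUSTIVE:
        x_idx = np.array(list(itertools.combinations(range(N), nx)), dtype=np.intp)
        stats = _bm_stats_batch(pooled, x_idx)
        p = float(np.mean(np.abs(stats) >= abs_obs - eps))
        return TestResult(
            statistic=obs.statistic,
            p_hat=obs.p_hat,
            p_value=p,
            n_perm=n_assign,
            exhaustive=True,
        )

    if n_perm < 1:
        raise InputError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, N))
    x_idx = np.argsort(keys, axis=1, kind="stable")[:, :nx].astype(np.intp)
    stats = _bm_stats_batch(pooled, x_idx)
    hits = int(np.sum(np.abs(stats) >= abs_obs - eps))
    p = (1 + hits) / (1 + n_perm)
    return TestResult(
        statistic=obs.statistic,
        p_hat=obs.p_hat,
        p_value=p,
        n_perm=n_perm,
        exhaustive=False,
    )


@dataclass(frozen=True)
class MonthComparison:
    """Month-pair comparison of one category's relative abundances."""

    category: str
    month_a: str
    month_b: str
    n_a: int
    n_b: int
    low_power: bool
    test: TestResult


def compare_months(
    profiles: Iterable[Profile],
    category: str,
    month_a: str,
    month_b: str,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> MonthComparison:
    """Permuted BM test of a category's RA between two collection months.

    Profiles lacking the category contribute 0% (with a warning when the
    category is absent from an entire month).  Months with fewer than three
    profiles are flagged low power.
    """
    profiles = list(profiles)
    a = [p.ra.get(category, 0.0) for p in profiles if p.collection_month == month_a]
    b = [p.ra.get(category, 0.0) for p in profiles if p.collection_month == month_b]
    if not a or not b:
        raise InputError(
            f"no profiles for month {month_a if not a else month_b!r}"
        )
    for month, vals, profs in (
        (month_a, a, [p for p in profiles if p.collection_month == month_a]),
        (month_b, b, [p for p in profiles if p.collection_month == month_b]),
    ):
        if all(category not in p.ra for p in profs):
            warnings.warn(
                f"category {category!r} absent from all profiles of {month}; "
                "treated as zeros",
                stacklevel=2,
            )
    result = permuted_bm_test(a, b, n_perm=n_perm, seed=seed)
    return MonthComparison(
        category=category,
        month_a=month_a,
        month_b=month_b,
        n_a=len(a),
        n_b=len(b),
        low_power=len(a) < 3 or len(b) < 3,
        test=result,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional; raw p by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out.tolist()


# ---------------------------------------------------------------------------
# Trophic position from amino-acid d15N
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopeRecord:
    """Per-specimen d15N (permil vs air) of glutamic acid and phenylalanine."""

    specimen_id: str
    d15n_glu: float
    d15n_phe: float
    group_label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d15n_glu) and math.isfinite(self.d15n_phe)):
            raise InputError(f"non-finite d15N for specimen {self.specimen_id!r}")


def trophic_position(
    d15n_glu: float, d15n_phe: float, beta: float = BETA, tef: float = TEF
) -> float:
    """TP = (d15N_Glu - d15N_Phe - beta)/tef + 1, at full precision."""
    if tef <= 0:
        raise InputError(f"trophic enrichment factor must be positive, got {tef}")
    if not (math.isfinite(d15n_glu) and math.isfinite(d15n_phe)):
        raise InputError("d15N values must be finite")
    return (d15n_glu - d15n_phe - beta) / tef + 1.0


def display_tp(tp: float) -> float:
    """One-decimal display rounding used alongside the full-precision value."""
    return float(f"{tp:.1f}")


@dataclass(frozen=True)
class TrophicPosition:
    """Group trophic position: mean of per-specimen TPs with 1-sigma spread.

    ``sd`` is the chosen dispersion (sample by default); the population
    (divisor n) value is always carried as ``sd_population`` and the sample
    (divisor n-1) value as ``sd_sample``.  All dispersions are None for a
    single specimen.  ``tp_from_mean_deltas`` applies the formula to the
    group-averaged d15N values; because the formula is linear this equals
    the mean of per-specimen TPs on the same raw data, and the two printed
    values can only disagree when the group-mean deltas were rounded before
    the formula was applied (as happens in published summary tables).
    """

    tp: float
    sd: Optional[float]
    n: int
    tp_display: float
    sd_sample: Optional[float]
    sd_population: Optional[float]
    tp_from_mean_deltas: float

    def __post_init__(self) -> None:
        if self.sd is not None and self.sd < 0:
            raise InputError("sd must be non-negative")


def group_tp(
    records: Sequence[IsotopeRecord],
    beta: float = BETA,
    tef: float = TEF,
    ddof: int = 1,
) -> TrophicPosition:
    """Per-specimen TPs averaged into a group estimate with 1-sigma spread.

    ``ddof=1`` (sample sigma) is the default dispersion; set ``ddof=0`` for
    the population convention.  For n = 1 every dispersion is None.
    """
    records = list(records)
    if not records:
        raise InputError("no isotope records")
    tps = np.array(
        [trophic_position(r.d15n_glu, r.d15n_phe, beta, tef) for r in records]
    )
    n = len(tps)
    mean = float(tps.mean())
    sd_pop = float(tps.std(ddof=0)) if n > 1 else None
    sd_samp = float(tps.std(ddof=1)) if n > 1 else None
    chosen = sd_samp if ddof == 1 else sd_pop
    glu_mean = float(np.mean([r.d15n_glu for r in records]))
    phe_mean = float(np.mean([r.d15n_phe for r in records]))
    return TrophicPosition(
        tp=mean,
        sd=chosen,
        n=n,
        tp_display=display_tp(mean),
        sd_sample=sd_samp,
        sd_population=sd_pop,
        tp_from_mean_deltas=trophic_position(glu_mean, phe_mean, beta, tef),
    )
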