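"""Map-distance and crossover-control estimators for tetrad data.

The estimators here are the classical tetrad-genetics toolkit:

* Perkins map distance, cM = 100·(6·NPD + TT) / (2·(PD+NPD+TT)), which
  corrects single-interval map distances for four-strand double crossovers.
  Its standard error comes from the multinomial delta method (see
  :func:`perkins_cM`).
* Papazian's expected NPD frequency given the tetratype frequency fT under
  the no-interference assumption, and the NPD ratio (observed/expected NPD);
  ratios significantly below 1 indicate positive crossover interference.
* Adjacent-interval coincidence: tetrads are split by whether a reference
  interval has a crossover (AdjCO) or not (AdjPD) and the test interval is
  mapped within each subset; cM(AdjCO)/cM(AdjPD) < 1 again means positive
  interference. The reported value averages the two ratios obtained by
  swapping reference and test intervals.
* Crossover-class (E0, E1, ...) reconstruction, the exp(−mean) Poisson null
  for the zero-crossover class (crossover assurance), and purging of
  non-exchange (E0) tetrads, which removes the dilution of interference
  signals caused by an achiasmate subpopulation.

Minimal-crossover reconstruction scores PD=0, TT=1, NPD=2 crossovers per
interval; by construction this undercounts intervals harbouring more than two
crossovers, which is the standard convention for E-class tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .model import (
    NPD,
    PD,
    TT,
    UNSCORABLE,
    IntervalTally,
    MarkerMap,
    Tetrad,
    TetradError,
    interval_class_matrix,
)

__all__ = [
    "MapDistanceEstimate", "InterferenceResult", "CrossoverClassDistribution",
    "AssuranceResult", "PurgeResult",
    "perkins_cM", "papazian_expected_npd", "npd_ratio",
    "adjacent_interference", "crossover_classes", "tetrad_crossover_counts",
    "assurance_test", "cM_to_mean_CO", "purge_nonexchange", "bonferroni",
]


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values (min(1, m·p)) for per-interval tests.

    No correction is applied by default anywhere in the package — interval
    statistics are reported per interval — but family-wise control across an
    interval set is one call away.
    """
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


@dataclass(frozen=True)
class MapDistanceEstimate:
    cM: float
    se_cM: float
    n: int


@dataclass
class InterferenceResult:
    """Result of an NPD-ratio or adjacent-interval interference test.

    ``undefined`` is set when the statistic cannot be formed (expected NPD of
    zero, an empty subset, or a zero denominator); the numeric fields are then
    NaN or inf as appropriate rather than silently clamped.
    """

    intervals: tuple[tuple[str, str], ...]
    npd_ratio: float = float("nan")
    adj_ratio: float = float("nan")
    p_value: float = float("nan")
    observed_npd_freq: float = float("nan")
    expected_npd_freq: float = float("nan")
    adj_ratio_forward: float = float("nan")
    adj_ratio_reverse: float = float("nan")
    chi2_p_value: float = float("nan")
    subset_sizes: dict = field(default_factory=dict)
    n: int = 0
    undefined: bool = False


@dataclass
class CrossoverClassDistribution:
    """Counts of tetrads by reconstructed crossover number (E0, E1, ...)."""

    counts: np.ndarray  # counts[k] = number of Ek tetrads
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def e0(self) -> int:
        return int(self.counts[0]) if self.counts.size else 0

    @property
    def e0_fraction(self) -> float:
        return self.e0 / self.n if self.n else float("nan")

    @property
    def mean_CO(self) -> float:
        if self.n == 0:
            return float("nan")
        return float(np.arange(self.counts.size) @ self.counts) / self.n


@dataclass(frozen=True)
class AssuranceResult:
    n: int
    observed_e0: int
    observed_fraction: float
    expected_fraction: float
    mean_CO: float
    p_excess: float   # P(E0 >= observed | Poisson null): assurance failure
    p_deficit: float  # P(E0 <= observed | Poisson null): assurance at work


@dataclass
class PurgeResult:
    exchange: list[Tetrad]
    e0: list[Tetrad]
    unscorable: list[Tetrad]


def perkins_cM(tally: IntervalTally) -> MapDistanceEstimate:
    """Perkins map distance with a multinomial delta-method standard error.

    With frequencies p_N = NPD/n and p_T = TT/n the estimate is
    cM = 50·(6·p_N + p_T) and

        Var(cM) = 2500·[36·p_N(1−p_N) + p_T(1−p_T) − 12·p_N·p_T] / n.

    Exact through double crossovers; intervals harbouring three or more
    crossovers are undercounted (a property of the estimator, not of this
    implementation).
    """
    n = tally.n
    if n == 0:
        raise TetradError(f"no scorable tetrads for interval {tally.interval}")
    p_n = tally.NPD / n
    p_t = tally.TT / n
    cm = 50.0 * (6.0 * p_n + p_t)
    var = 2500.0 * (36.0 * p_n * (1 - p_n) + p_t * (1 - p_t) - 12.0 * p_n * p_t) / n
    return MapDistanceEstimate(cM=cm, se_cM=float(np.sqrt(max(var, 0.0))), n=n)


def papazian_expected_npd(fT: float) -> float:
    """Expected NPD frequency without interference, given tetratype frequency fT.

    NPD_exp = 0.5·[(1 − fT) − (1 − 3·fT/2)^(2/3)], defined for 0 ≤ fT ≤ 2/3.
    Values above 2/3 are inconsistent with the underlying no-interference
    model; they return NaN with a warning rather than being clamped.
    """
    if fT < 0:
        raise TetradError("tetratype frequency cannot be negative")
    if fT > 2.0 / 3.0 + 1e-12:
        warnings.warn(
            f"tetratype frequency {fT:.4f} exceeds 2/3: outside the Papazian domain",
            stacklevel=2,
        )
        return float("nan")
    fT = min(fT, 2.0 / 3.0)
    return 0.5 * ((1.0 - fT) - (1.0 - 1.5 * fT) ** (2.0 / 3.0))


def npd_ratio(tally: IntervalTally) -> InterferenceResult:
    """Observed/expected NPD ratio with a one-sided exact binomial p-value.

    The p-value is P(NPD ≤ observed) under the Papazian expectation — the
    test for *positive* interference (ratio < 1).
    """
    n = tally.n
    if n == 0:
        raise TetradError(f"no scorable tetrads for interval {tally.interval}")
    obs = tally.NPD / n
    exp = papazian_expected_npd(tally.TT / n)
    res = InterferenceResult(
        intervals=(tally.interval,), observed_npd_freq=obs, expected_npd_freq=exp, n=n
    )
    if not np.isfinite(exp):
        res.undefined = True
        return res
    if exp == 0.0:
        res.npd_ratio = float("inf") if tally.NPD > 0 else 0.0
        res.undefined = tally.NPD > 0
        res.p_value = 1.0
        return res
    res.npd_ratio = obs / exp
    res.p_value = stats.binomtest(tally.NPD, n, exp, alternative="less").pvalue
    return res


# -- adjacent-interval coincidence ------------------------------------------


def _perkins_from_counts(pd: int, tt: int, npd: int) -> float:
    n = pd + tt + npd
    if n == 0:
        return float("nan")
    return 50.0 * (6.0 * npd + tt) / n


def _adj_stat_from_table(T: np.ndarray) -> tuple[float, float, float]:
    """Averaged AdjCO/AdjPD ratio from a 3×3 (ref class × test class) table.

    Returns (mean_ratio, forward, reverse); NaN where a subset is empty or a
    denominator map distance is zero.
    """

    def one_direction(tab: np.ndarray) -> float:
        co = tab[TT] + tab[NPD]  # test-class counts among ref-CO tetrads
        pd_row = tab[PD]
        cm_co = _perkins_from_counts(co[PD], co[TT], co[NPD])
        cm_pd = _perkins_from_counts(pd_row[PD], pd_row[TT], pd_row[NPD])
        if not np.isfinite(cm_co) or not np.isfinite(cm_pd) or cm_pd == 0.0:
            return float("nan")
        return cm_co / cm_pd

    fwd = one_direction(T)
    rev = one_direction(T.T)
    vals = [v for v in (fwd, rev) if np.isfinite(v)]
    mean = float(np.mean(vals)) if vals else float("nan")
    return mean, fwd, rev


def adjacent_interference(
    tetrads: Sequence[Tetrad],
    mmap: MarkerMap,
    ref_interval: tuple[str, str],
    test_interval: tuple[str, str],
    filter_policy: str = "paper",
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> InterferenceResult:
    """Coincidence-based interference between two intervals.

    Tetrads are split by the reference interval's class (crossover: TT or
    NPD; no crossover: PD) and the test interval is Perkins-mapped within
    each subset. The reported ``adj_ratio`` is the mean of the two
    cM(AdjCO)/cM(AdjPD) ratios obtained by swapping the roles of the two
    intervals. Significance is assessed by a label-permutation test (the
    pairing between the two intervals' classes is shuffled across tetrads;
    one-sided toward interference, ratio ≤ observed), with a chi-square test
    on the 2×3 AdjCO/AdjPD × PD/TT/NPD table as a cross-check.
    """
    cls = interval_class_matrix(
        tetrads, mmap, filter_policy, pairs=[ref_interval, test_interval]
    )
    keep = (cls != UNSCORABLE).all(axis=1)
    r, t = cls[keep, 0], cls[keep, 1]
    n = int(keep.sum())
    T = np.zeros((3, 3), dtype=int)
    np.add.at(T, (r, t), 1)
    obs, fwd, rev = _adj_stat_from_table(T)
    res = InterferenceResult(
        intervals=(tuple(ref_interval), tuple(test_interval)),
        adj_ratio=obs,
        adj_ratio_forward=fwd,
        adj_ratio_reverse=rev,
        n=n,
        subset_sizes={
            "AdjCO_ref": int(T[TT].sum() + T[NPD].sum()),
            "AdjPD_ref": int(T[PD].sum()),
            "AdjCO_test": int(T[:, TT].sum() + T[:, NPD].sum()),
            "AdjPD_test": int(T[:, PD].sum()),
        },
    )
    if not np.isfinite(obs):
        res.undefined = True
        return res
    # chi-square cross-check on the collapsed 2x3 table
    two_by_three = np.vstack([T[TT] + T[NPD], T[PD]])
    if (two_by_three.sum(axis=1) > 0).all() and (two_by_three.sum(axis=0) > 0).sum() >= 2:
        nonzero_cols = two_by_three.sum(axis=0) > 0
        res.chi2_p_value = float(
            stats.chi2_contingency(two_by_three[:, nonzero_cols])[1]
        )
    if n_permutations > 0:
        # Permuting the pairing of ref and test classes across tetrads is
        # equivalent to drawing a random 3x3 table with the observed margins.
        rng = np.random.default_rng(seed)
        r_marg = T.sum(axis=1)
        t_marg = T.sum(axis=0)
        hits = 0
        valid = 0
        for _ in range(n_permutations):
            remaining = t_marg.copy()
            Tp = np.zeros((3, 3), dtype=int)
            for i in range(2):
                Tp[i] = rng.multivariate_hypergeometric(remaining, int(r_marg[i]))
                remaining -= Tp[i]
            Tp[2] = remaining
            stat, _, _ = _adj_stat_from_table(Tp)
            if np.isfinite(stat):
                valid += 1
                if stat <= obs:
                    hits += 1
        res.p_value = (hits + 1) / (valid + 1) if valid else float("nan")
    return res


# -- crossover classes, assurance, purging ----------------------------------


def tetrad_crossover_counts(
    tetrads: Sequence[Tetrad],
    mmap: MarkerMap,
    filter_policy: str = "paper",
    drop: str = "tetrad",
) -> tuple[np.ndarray, np.ndarray]:
    """Minimal crossover count per tetrad and a validity mask.

    ``drop="tetrad"`` requires every map interval scorable (the convention for
    E-class distributions); ``drop="interval"`` sums over the scorable
    intervals only, requiring at least one — useful when single-marker
    conversions would otherwise discard the tetrad.
    """
    if drop not in ("tetrad", "interval"):
        raise TetradError(f"unknown drop mode {drop!r}")
    cls = interval_class_matrix(tetrads, mmap, filter_policy)
    scorable = cls != UNSCORABLE
    if drop == "tetrad":
        valid = scorable.all(axis=1)
    else:
        valid = scorable.any(axis=1)
    counts = np.where(scorable, cls, 0).sum(axis=1)  # PD=0, TT=1, NPD=2
    return counts.astype(int), valid


def crossover_classes(
    tetrads: Sequence[Tetrad],
    mmap: MarkerMap,
    filter_policy: str = "paper",
    drop: str = "tetrad",
) -> CrossoverClassDistribution:
    """Distribution over E-classes (E0 = non-exchange tetrads)."""
    counts, valid = tetrad_crossover_counts(tetrads, mmap, filter_policy, drop)
    kept = counts[valid]
    k_max = int(kept.max()) if kept.size else 0
    hist = np.bincount(kept, minlength=k_max + 1)
    return CrossoverClassDistribution(counts=hist, n_dropped=int((~valid).sum()))


def assurance_test(
    dist: CrossoverClassDistribution, mean_CO: float | None = None
) -> AssuranceResult:
    """Observed E0 count against the Poisson zero-class expectation exp(−mean).

    ``p_excess`` is the one-sided exact binomial probability of at least the
    observed number of E0 tetrads (tests for assurance *failure*);
    ``p_deficit`` of at most that number (tests for assurance at work).
    """
    mean = dist.mean_CO if mean_CO is None else float(mean_CO)
    if mean < 0:
        raise TetradError("mean crossover number cannot be negative")
    expected = float(np.exp(-mean))
    n, e0 = dist.n, dist.e0
    if n == 0:
        raise TetradError("empty crossover-class distribution")
    return AssuranceResult(
        n=n,
        observed_e0=e0,
        observed_fraction=e0 / n,
        expected_fraction=expected,
        mean_CO=mean,
        p_excess=stats.binomtest(e0, n, expected, alternative="greater").pvalue,
        p_deficit=stats.binomtest(e0, n, expected, alternative="less").pvalue,
    )


def cM_to_mean_CO(total_cM: float) -> float:
    """Mean crossovers per bivalent per meiosis from a total map length.

    Each crossover involves two of the four chromatids and therefore
    contributes 50 cM of map length, so mean = total_cM / 50.
    """
    if total_cM < 0:
        raise TetradError("map length cannot be negative")
    return total_cM / 50.0


def purge_nonexchange(
    tetrads: Sequence[Tetrad],
    mmap: MarkerMap,
    filter_policy: str = "paper",
) -> PurgeResult:
    """Partition tetrads into exchange and non-exchange (E0) subsets.

    Re-running interference estimators on the exchange subset removes the
    dilution of interference signals caused by an achiasmate subpopulation.
    Tetrads with any unscorable interval are set aside separately.
    """
    counts, valid = tetrad_crossover_counts(tetrads, mmap, filter_policy, drop="tetrad")
    exchange = [t for t, c, v in zip(tetrads, counts, valid) if v and c > 0]
    e0 = [t for t, c, v in zip(tetrads, counts, valid) if v and c == 0]
    unscorable = [t for t, v in zip(tetrads, valid) if not v]
    if not exchange:
        warnings.warn("exchange subset is empty: every scorable tetrad is E0", stacklevel=2)
    return PurgeResult(exchange=exchange, e0=e0, unscorable=unscorable)
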