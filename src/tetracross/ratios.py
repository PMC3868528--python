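"""Arithmetic over quantified molecular-species signals.

Two-dimensional gels resolve double Holliday junctions formed between
homologs (IH-dHJ) from those formed between sister chromatids (IS-dHJ); the
IH/IS ratio r measures homolog template bias, and r/(1+r) is the fraction of
dHJs that are interhomolog. Crossover (CO) and non-crossover (NCO) products
are related the same way: a CO fraction p among interhomolog events
corresponds to a CO/NCO ratio p/(1−p).

The compensation model asks how far an increase in the CO fraction can make
up for a loss of homolog bias. Holding the number of recombination events
fixed, the predicted mutant/wild-type crossover level is

    (IHf_mut · COf_mut) / (IHf_wt · COf_wt)

with IHf = r/(1+r). On a log scale the homolog-bias defect opens a gap
log(IHf_wt/IHf_mut); the observed fold reduction in crossovers closes part of
it, and "apparent compensation" is the part closed. The share of that
compensation attributable to crossover bias is log(COf_mut/COf_wt) divided by
the apparent compensation; any remainder implies a second feedback process
(e.g. additional event formation), which this model deliberately excludes.

Censored inputs ("≤ 0.12"-style bounds) propagate as bound-typed outputs
rather than point estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "BiasSummary", "CompensationResult",
    "ih_is_ratio", "co_fraction_to_ratio", "co_ratio_to_fraction",
    "fold_change", "compensation_model",
]


class RatioError(ValueError):
    """Degenerate input to a ratio or compensation computation."""


@dataclass(frozen=True)
class BiasSummary:
    """Template-bias and crossover-outcome summary for one strain.

    ``censored`` is None for point estimates, or "upper"/"lower" when the
    underlying IH/IS ratio is a bound (one species at the detection limit).
    """

    ih_is_ratio: float
    co_fraction: float
    censored: str | None = None

    def __post_init__(self) -> None:
        if self.ih_is_ratio < 0:
            raise RatioError("IH/IS ratio cannot be negative")
        if not 0.0 <= self.co_fraction <= 1.0:
            raise RatioError("crossover fraction must lie in [0, 1]")

    @property
    def ih_fraction(self) -> float:
        r = self.ih_is_ratio
        return r / (1.0 + r) if math.isfinite(r) else 1.0

    @property
    def co_nco_ratio(self) -> float:
        p = self.co_fraction
        return p / (1.0 - p) if p < 1.0 else float("inf")

    @classmethod
    def from_signals(
        cls, ih_signal: float, is_signal: float, co_fraction: float
    ) -> "BiasSummary":
        return cls(
            ih_is_ratio=ih_is_ratio(ih_signal, is_signal).ih_is_ratio,
            co_fraction=co_fraction,
            censored=None if is_signal > 0 else "lower",
        )


def ih_is_ratio(ih_signal: float, is_signal: float) -> BiasSummary:
    """IH-dHJ/IS-dHJ ratio and the derived interhomolog fraction.

    A zero intersister signal makes the ratio a lower bound (the true ratio
    is at least the one implied by the detection limit); the result is
    flagged censored="lower" with an infinite ratio rather than failing.
    """
    if ih_signal < 0 or is_signal < 0:
        raise RatioError("signals must be non-negative")
    if is_signal == 0:
        warnings.warn("intersister signal is zero: IH/IS ratio is a lower bound", stacklevel=2)
        return BiasSummary(ih_is_ratio=float("inf"), co_fraction=0.0, censored="lower")
    return BiasSummary(ih_is_ratio=ih_signal / is_signal, co_fraction=0.0)


def co_fraction_to_ratio(p: float) -> float:
    """CO/NCO ratio implied by a crossover-associated fraction p: p/(1−p)."""
    if not 0.0 <= p < 1.0:
        raise RatioError("crossover fraction must lie in [0, 1)")
    return p / (1.0 - p)


def co_ratio_to_fraction(r: float) -> float:
    """Inverse of :func:`co_fraction_to_ratio`: r/(1+r)."""
    if r < 0:
        raise RatioError("CO/NCO ratio cannot be negative")
    return r / (1.0 + r)


def fold_change(a: float, b: float) -> float:
    """a/b, the fold difference between two non-negative quantities."""
    if a < 0 or b <= 0:
        raise RatioError("fold change needs a non-negative numerator and positive denominator")
    return a / b


@dataclass(frozen=True)
class CompensationResult:
    predicted_relative_co: float      # mutant/wild-type CO level at fixed event number
    predicted_fold_reduction: float   # 1 / predicted_relative_co
    bias_gap_log: float               # log(IHf_wt / IHf_mut), the gap to close
    co_bias_gain_log: float           # log(COf_mut / COf_wt), closed by CO bias
    fraction_of_gap: float            # CO-bias gain / bias gap
    observed_fold_reduction: float | None = None
    apparent_compensation_log: float | None = None
    fraction_of_apparent: float | None = None   # share of apparent compensation from CO bias
    unexplained_fraction: float | None = None
    censored: bool = False


def compensation_model(
    wt: BiasSummary,
    mut: BiasSummary,
    observed_fold_reduction: float | None = None,
) -> CompensationResult:
    """Predicted crossover change from bias terms alone, and its bookkeeping.

    With event number held fixed the predicted mutant/wild-type crossover
    level is (IHf_mut·COf_mut)/(IHf_wt·COf_wt). If the observed fold
    reduction in crossovers is supplied, the apparent compensation
    log(bias-fold defect) − log(observed fold) is split into the part
    attributable to crossover bias and an unexplained remainder.
    """
    for name, s in (("wt", wt), ("mut", mut)):
        if not (0.0 < s.ih_fraction < 1.0) or not (0.0 < s.co_fraction < 1.0):
            raise RatioError(f"{name} fractions must lie strictly in (0, 1)")
    bias_gap = math.log(wt.ih_fraction / mut.ih_fraction)
    co_gain = math.log(mut.co_fraction / wt.co_fraction)
    predicted = (mut.ih_fraction * mut.co_fraction) / (wt.ih_fraction * wt.co_fraction)
    res = dict(
        predicted_relative_co=predicted,
        predicted_fold_reduction=1.0 / predicted,
        bias_gap_log=bias_gap,
        co_bias_gain_log=co_gain,
        fraction_of_gap=co_gain / bias_gap if bias_gap != 0 else float("nan"),
        censored=wt.censored is not None or mut.censored is not None,
    )
    if observed_fold_reduction is not None:
        if observed_fold_reduction <= 0:
            raise RatioError("observed fold reduction must be positive")
        apparent = bias_gap - math.log(observed_fold_reduction)
        frac = co_gain / apparent if apparent != 0 else float("nan")
        res.update(
            observed_fold_reduction=observed_fold_reduction,
            apparent_compensation_log=apparent,
            fraction_of_apparent=frac,
            unexplained_fraction=1.0 - frac,
        )
    return CompensationResult(**res)
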