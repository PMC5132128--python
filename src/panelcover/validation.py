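"""Panel-validation arithmetic: concordance, sensitivity/specificity, CIs.

Concordance against an orthogonal truth technology (Sanger sequencing, a SNP
array) yields a 2x2 table; sensitivity is tp/(tp+fn) over truth-positive
variants and specificity tn/(tn+fp) over truth-negative positions. Binomial
confidence intervals are available by the Wilson score method and the exact
Clopper–Pearson method (delegated to statsmodels); both are clipped to
[0, 1]. Reproducibility across replicate libraries is the fraction of
variant keys seen in *all* replicates of their sample among keys seen in any.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from ._util import percent, percent_str


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ConcordanceTable:
    """Counts versus an orthogonal truth set."""

    tp: int  # truth-positive variants detected
    fn: int  # truth-positive variants missed
    tn: int  # truth-negative positions with no call
    fp: int  # truth-negative positions with a call

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("concordance counts must be non-negative")


@dataclass(frozen=True)
class ProportionEstimate:
    x: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    level: float

    @property
    def percent(self) -> float:
        """Point estimate as a percentage, one decimal, half-away rounding."""
        return percent(self.estimate)

    def render(self) -> str:
        return (
            f"{percent_str(self.estimate)}% "
            f"({self.level:.0%} CI {percent_str(self.ci_low)}-{percent_str(self.ci_high)}%, "
            f"{self.method}, {self.x}/{self.n})"
        )


def _unique_keys(items: Iterable[Hashable], label: str) -> set:
    keys = list(items)
    counts = Counter(keys)
    dupes = [k for k, n in counts.items() if n > 1]
    if dupes:
        raise ValidationError(f"duplicate {label} key(s): {dupes[:5]}")
    return set(keys)


def build_concordance(
    test_calls: Iterable[tuple],
    truth_calls: Iterable[tuple],
    truth_negatives: Iterable[tuple] = (),
) -> ConcordanceTable:
    """Set algebra over variant keys and truth-negative position keys.

    Variant keys are ``(chrom, pos, ref, alt)``; truth negatives are
    ``(chrom, pos)`` positions asserted variant-free by the orthogonal
    technology. A test call at a truth-negative position counts as a false
    positive.
    """
    test = _unique_keys(test_calls, "test call")
    truth = _unique_keys(truth_calls, "truth call")
    negatives = _unique_keys(truth_negatives, "truth negative")
    tp = len(truth & test)
    fn = len(truth - test)
    test_positions = {(k[0], k[1]) for k in test}
    fp = len(negatives & test_positions)
    tn = len(negatives) - fp
    return ConcordanceTable(tp=tp, fn=fn, tn=tn, fp=fp)


def binomial_ci(
    x: int, n: int, method: str = "wilson", level: float = 0.95
) -> tuple[float, float]:
    """Binomial confidence interval: Wilson score or exact Clopper–Pearson."""
    if not (0 <= x <= n) or n < 1:
        raise ValidationError(f"require 0 <= x <= n and n >= 1, got x={x}, n={n}")
    if not 0 < level < 1:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    if method not in ("wilson", "exact"):
        raise ValidationError(f"unknown CI method {method!r}")
    sm_method = "wilson" if method == "wilson" else "beta"
    low, high = proportion_confint(x, n, alpha=1 - level, method=sm_method)
    low = 0.0 if np.isnan(low) else float(low)
    high = 1.0 if np.isnan(high) else float(high)
    # boundary identities hold exactly: no successes pins the lower bound at
    # 0, all successes pins the upper bound at 1
    if x == 0:
        low = 0.0
    if x == n:
        high = 1.0
    return (max(low, 0.0), min(high, 1.0))


def _proportion(
    x: int, n: int, method: str, level: float, what: str
) -> ProportionEstimate:
    if n < 1:
        raise ValidationError(f"{what} undefined: no qualifying observations")
    low, high = binomial_ci(x, n, method=method, level=level)
    return ProportionEstimate(
        x=x, n=n, estimate=x / n, ci_low=low, ci_high=high, method=method, level=level
    )


def sensitivity(
    table: ConcordanceTable, ci_method: str = "wilson", level: float = 0.95
) -> ProportionEstimate:
    """tp / (tp + fn) with a binomial CI."""
    return _proportion(table.tp, table.tp + table.fn, ci_method, level, "sensitivity")


def specificity(
    table: ConcordanceTable, ci_method: str = "wilson", level: float = 0.95
) -> ProportionEstimate:
    """tn / (tn + fp) with a binomial CI."""
    return _proportion(table.tn, table.tn + table.fp, ci_method, level, "specificity")


def reproducibility(
    replicate_call_sets: Sequence[Sequence[Iterable[tuple]]],
) -> float:
    """Concordant fraction across replicate libraries.

    ``replicate_call_sets`` holds, per sample, the list of that sample's
    replicate call sets (each an iterable of variant keys). A key is
    concordant when present in every replicate of its sample; the returned
    fraction pools keys across samples.
    """
    seen_any = 0
    seen_all = 0
    for replicates in replicate_call_sets:
        if len(replicates) < 2:
            raise ValidationError("each sample needs >= 2 replicates")
        sets = [set(r) for r in replicates]
        union = set.union(*sets)
        inter = set.intersection(*sets)
        seen_any += len(union)
        seen_all += len(inter)
    if seen_any == 0:
        return 1.0
    return seen_all / seen_any
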