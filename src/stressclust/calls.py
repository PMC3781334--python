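"""Per-comparison fold changes, t-tests and three-state (up/down/unchanged) calls.

The four canonical comparisons contrast tunicamycin-treated animals against
their controls within the 2 genotype x 2 treatment x 2 time design:

* c1 — WT-TM vs WT-vehicle at 8 h
* c2 — KO-TM vs WT-TM at 8 h
* c3 — WT-TM vs WT-vehicle at 34 h
* c4 — KO-TM vs WT-TM at 34 h

A comparison is called "up" when the log2 fold change is at least
``log2(1.5)`` (the 1.5-fold threshold, ~0.585; 0.58 when printed to two
decimals) with two-tailed Student's t p < 0.05, "down" for the mirror image,
and "unchanged" otherwise.  Fold changes are log2 ratios of linear-scale
replicate means; a log-mean mode is available behind a flag.  No
multiple-testing correction is applied to per-gene calls — correction enters
only at the enrichment stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StressclustError
from .io import select_samples

#: log2 of the 1.5-fold threshold used throughout (displayed as 0.58).
FOLD_THRESHOLD_LOG2 = math.log2(1.5)

#: significance level for three-state calls.
CALL_ALPHA = 0.05

#: relaxed level used when timing the first suppression of a gene.
SUPPRESSION_ALPHA = 0.1

UP, DOWN, UNCHANGED = "up", "down", "unchanged"
CALL_LEVELS = (DOWN, UNCHANGED, UP)


@dataclass(frozen=True)
class ComparisonSpec:
    """A named numerator-vs-denominator contrast over the sample design."""

    name: str
    numerator: dict = field(hash=False)
    denominator: dict = field(hash=False)

    def split(self, samples: pd.DataFrame) -> tuple[list[str], list[str]]:
        num = select_samples(samples, **self.numerator)
        den = select_samples(samples, **self.denominator)
        if not num or not den:
            raise StressclustError(
                f"comparison {self.name}: empty sample selection")
        if set(num) & set(den):
            raise StressclustError(
                f"comparison {self.name}: numerator and denominator overlap")
        return num, den


def canonical_comparisons(t_early: float = 8, t_late: float = 34) -> list[ComparisonSpec]:
    """The four comparisons c1..c4 that define an expression profile."""
    return [
        ComparisonSpec("c1",
                       dict(genotype="WT", treatment="TM", time=t_early),
                       dict(genotype="WT", treatment="vehicle", time=t_early)),
        ComparisonSpec("c2",
                       dict(genotype="KO", treatment="TM", time=t_early),
                       dict(genotype="WT", treatment="TM", time=t_early)),
        ComparisonSpec("c3",
                       dict(genotype="WT", treatment="TM", time=t_late),
                       dict(genotype="WT", treatment="vehicle", time=t_late)),
        ComparisonSpec("c4",
                       dict(genotype="KO", treatment="TM", time=t_late),
                       dict(genotype="WT", treatment="TM", time=t_late)),
    ]


def log2_fold_change(values_num, values_den, log_means: bool = False) -> float:
    """log2 ratio of the two replicate groups.

    Default is the ratio of linear-scale means; ``log_means=True`` averages
    on the log2 scale instead (difference of mean logs).
    """
    a = np.asarray(values_num, dtype=float)
    b = np.asarray(values_den, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StressclustError("fold change requires non-empty replicate vectors")
    if (a <= 0).any() or (b <= 0).any():
        raise StressclustError("fold change requires strictly positive values")
    if log_means:
        return float(np.log2(a).mean() - np.log2(b).mean())
    return float(np.log2(a.mean() / b.mean()))


def two_sample_t(values_a, values_b, welch: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t-test (pooled-variance Student by default).

    Degenerate zero-variance inputs follow a documented convention:
    equal means -> (t=0, p=1); unequal means -> (t=+/-inf, p=0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StressclustError("t-test requires >=2 replicates per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def three_state_call(log2fc: float, p: float,
                     tau: float = FOLD_THRESHOLD_LOG2,
                     alpha: float = CALL_ALPHA) -> str:
    """Classify a comparison as up / down / unchanged."""
    if not 0.0 <= p <= 1.0:
        raise StressclustError(f"p-value {p} outside [0, 1]")
    if p < alpha and log2fc >= tau:
        return UP
    if p < alpha and log2fc <= -tau:
        return DOWN
    return UNCHANGED


def call_comparisons(matrix: pd.DataFrame, samples: pd.DataFrame,
                     comparisons: list[ComparisonSpec] | None = None,
                     tau: float = FOLD_THRESHOLD_LOG2,
                     alpha: float = CALL_ALPHA,
                     welch: bool = False,
                     log_means: bool = False) -> pd.DataFrame:
    """Three-state calls for every gene under every comparison.

    Returns a tidy frame (gene, comparison, log2fc, t, p, call).  The t-test
    is vectorized across genes; zero-pooled-variance rows fall back to the
    conventions of :func:`two_sample_t`.
    """
    if comparisons is None:
        comparisons = canonical_comparisons()
    if (matrix.values <= 0).any():
        raise StressclustError("expression matrix must be strictly positive for calls")
    out = []
    for spec in comparisons:
        num_ids, den_ids = spec.split(samples)
        a = matrix[num_ids].to_numpy(dtype=float)
        b = matrix[den_ids].to_numpy(dtype=float)
        if log_means:
            lfc = np.log2(a).mean(axis=1) - np.log2(b).mean(axis=1)
        else:
            lfc = np.log2(a.mean(axis=1) / b.mean(axis=1))
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
        degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
        if degenerate.any():
            eq = degenerate & (a.mean(axis=1) == b.mean(axis=1))
            ne = degenerate & ~eq
            t = np.where(eq, 0.0, t)
            p = np.where(eq, 1.0, p)
            t = np.where(ne, np.sign(a.mean(axis=1) - b.mean(axis=1)) * np.inf, t)
            p = np.where(ne, 0.0, p)
        call = np.full(len(matrix), UNCHANGED, dtype=object)
        call[(p < alpha) & (lfc >= tau)] = UP
        call[(p < alpha) & (lfc <= -tau)] = DOWN
        out.append(pd.DataFrame({
            "gene": matrix.index, "comparison": spec.name,
            "log2fc": lfc, "t": t, "p": p, "call": call}))
    return pd.concat(out, ignore_index=True)


def first_suppression_time(series, alpha: float = SUPPRESSION_ALPHA):
    """Earliest time point at which a gene is significantly downregulated.

    ``series`` is an iterable of ``(time, log2fc, p)`` with strictly
    increasing times.  Returns ``(time, sustained)`` or ``None`` when no down
    call exists.  ``sustained`` is False when the immediately following time
    point is not also a down call (a transient dip whose true timing is
    ambiguous); a down call at the final time point counts as sustained.
    """
    pts = list(series)
    if not pts:
        raise StressclustError("first_suppression_time: empty time series")
    times = [t for t, _, _ in pts]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise StressclustError("first_suppression_time: times must be strictly increasing")
    down = [(lfc < 0 and p < alpha) for _, lfc, p in pts]
    for i, is_down in enumerate(down):
        if is_down:
            sustained = down[i + 1] if i + 1 < len(down) else True
            return times[i], bool(sustained)
    return None
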