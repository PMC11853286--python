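"""Summary statistics: chi-square goodness of fit and paired t-tests.

The chi-square on the suppressed/not-suppressed SRC split uses no
continuity correction: on observed counts (26, 1) against equal expected
proportions the uncorrected statistic is 23.148 (df = 1), which is the
convention the rest of the reporting assumes.  p-values are formatted to
four decimals, with values below 1e-4 printed as "< 0.0001".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import AnalysisError


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    observed: tuple[float, ...]
    expected: tuple[float, ...]


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    n: int
    mean_difference: float
    undefined: bool = False  # zero-variance differences


def chisq_goodness_of_fit(
    observed, expected_proportions=(0.5, 0.5)
) -> ChiSquareResult:
    """Two-sided chi-square goodness-of-fit test on category counts."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.ndim != 1 or obs.size != props.size:
        raise AnalysisError("observed and expected proportions must align")
    if np.any(obs < 0):
        raise AnalysisError("negative counts")
    total = obs.sum()
    if total <= 0:
        raise AnalysisError("at least one count must be positive")
    expected = props / props.sum() * total
    stat, p = sps.chisquare(obs, f_exp=expected)
    return ChiSquareResult(
        statistic=float(stat),
        df=obs.size - 1,
        p=float(p),
        observed=tuple(obs),
        expected=tuple(expected),
    )


def paired_t(x, y) -> PairedTResult:
    """Two-tailed paired t-test; df = n - 1.

    Zero-variance differences make the statistic undefined; the result is
    flagged rather than reported as infinite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("paired samples must be equal-length 1-D")
    n = x.size
    if n < 2:
        raise AnalysisError("paired t-test needs at least 2 pairs")
    diff = x - y
    if np.std(diff, ddof=1) == 0:
        return PairedTResult(
            t=np.nan, df=n - 1, p=np.nan, n=n,
            mean_difference=float(diff.mean()), undefined=True,
        )
    res = sps.ttest_rel(x, y)
    return PairedTResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        n=n,
        mean_difference=float(diff.mean()),
    )


def format_p(p: float) -> str:
    """Report-style p-value: 4 decimals, '< 0.0001' below that."""
    if not np.isfinite(p):
        return "undefined"
    if p < 1e-4:
        return "< 0.0001"
    return f"{p:.4f}"
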