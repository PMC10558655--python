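"""Small statistical helpers shared across stages."""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as _st

__all__ = ["SummaryTTest", "ttest_from_summary"]


@dataclass
class SummaryTTest:
    t: float
    p: float
    df: float


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int,
                       equal_var: bool = False) -> SummaryTTest:
    """Two-sample t-test recomputed from printed summary statistics.

    Welch by default; useful for checking manipulation-check contrasts (e.g.
    perceived-status ratings between groups) against reported values.
    """
    t, p = _st.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                    equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return SummaryTTest(t=float(t), p=float(p), df=float(df))
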