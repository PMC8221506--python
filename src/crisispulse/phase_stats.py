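"""Phase-level sentiment summaries and significance comparisons.

For each country × period the summary reports the average positive
sentiment (APS, mean of the positive components over *all* tweets,
neutral ones included), the average negative sentiment (ANS, mean of the
negative components, reported as a negative number), and eight category
percentages:

========================  =============================================
no sentiment              pos = 0 and neg = 0
strong sentiment          pos ∈ [3, 4] or neg ∈ [−4, −3]
strong positive           pos ∈ [3, 4]
strong negative           neg ∈ [−4, −3]
only positive             pos ∈ [1, 4] and neg = 0
only negative             pos = 0 and neg ∈ [−4, −1]
positive > negative       pos > |neg|
negative > positive       |neg| > pos
========================  =============================================

Periods are compared with a two-sample t-test (Welch by default, the
pooled-variance variant available via ``equal_var=True``).  Significance
markers follow the convention ``*``/``**``/``***`` for p < 0.05/0.01/
0.001 against the pre-crisis base set and ``°``/``°°``/``°°°`` against
the previous phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import PHASES
from .errors import EmptyPhaseError, MissingPeriodError

_BASE_MARKS = ("*", "**", "***")
_PREV_MARKS = ("°", "°°", "°°°")


@dataclass(frozen=True)
class PhaseSummary:
    country: str
    phase: str
    n: int
    aps: float
    ans: float
    pct_no_sent: float
    pct_strong: float
    pct_strong_pos: float
    pct_strong_neg: float
    pct_pos_only: float
    pct_neg_only: float
    pct_pos_gt_neg: float
    pct_neg_gt_pos: float


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-sample test, with its significance marker."""

    statistic: float
    p: float
    vs: str  # "base" or "previous"
    marker: str


def summarize_phase(
    scores: pd.DataFrame, country: str, phase: str
) -> PhaseSummary:
    """Summarize the scored table restricted to one country × phase."""
    sel = scores[(scores["country"] == country) & (scores["phase"] == phase)]
    n = len(sel)
    if n == 0:
        raise EmptyPhaseError(f"no tweets for {country} phase {phase!r}")
    pos = sel["pos"].to_numpy()
    neg = sel["neg"].to_numpy()
    mag = -neg

    def pct(mask: np.ndarray) -> float:
        return 100.0 * float(mask.sum()) / n

    return PhaseSummary(
        country=country,
        phase=phase,
        n=n,
        aps=float(pos.mean()),
        ans=float(neg.mean()),
        pct_no_sent=pct((pos == 0) & (neg == 0)),
        pct_strong=pct((pos >= 3) | (mag >= 3)),
        pct_strong_pos=pct(pos >= 3),
        pct_strong_neg=pct(mag >= 3),
        pct_pos_only=pct((pos >= 1) & (neg == 0)),
        pct_neg_only=pct((pos == 0) & (mag >= 1)),
        pct_pos_gt_neg=pct(pos > mag),
        pct_neg_gt_pos=pct(mag > pos),
    )


def _marker(p: float, vs: str) -> str:
    marks = _BASE_MARKS if vs == "base" else _PREV_MARKS
    if p < 0.001:
        return marks[2]
    if p < 0.01:
        return marks[1]
    if p < 0.05:
        return marks[0]
    return ""


def compare_phases(
    scores_a,
    scores_b,
    vs: str = "base",
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sample t-test between two score vectors.

    ``scores_a`` is the phase of interest, ``scores_b`` the reference
    (base set or previous phase).  Welch's unequal-variance form is the
    default.  Two samples with identical means (including two identical
    constant vectors) give t = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise EmptyPhaseError("need at least 2 observations per sample")
    if vs not in ("base", "previous"):
        raise ValueError(f"vs must be 'base' or 'previous', got {vs!r}")
    with warnings.catch_warnings():
        # constant samples trip a precision warning; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t) and np.isclose(a.mean(), b.mean()):
        t, p = 0.0, 1.0  # zero variance, zero difference
    return ComparisonResult(statistic=t, p=p, vs=vs, marker=_marker(p, vs))


_TABLE_COLUMNS = [
    "avg_pos", "avg_neg", "no_sent", "strong", "strong_pos", "strong_neg",
    "pos_only", "neg_only", "pos_gt_neg", "neg_gt_pos",
]


def build_sentiment_table(
    scores: pd.DataFrame, country: str, equal_var: bool = False
) -> pd.DataFrame:
    """Format the detailed sentiment results for one country.

    One row per period (base, 1, 2, 3).  ``avg_pos``/``avg_neg`` are
    strings carrying APS/ANS rounded to 3 decimals plus the vs-base and
    vs-previous significance markers; category percentages are rounded
    to 2 decimals.  Raises :class:`MissingPeriodError` naming any period
    with no tweets.
    """
    vectors: dict[str, pd.DataFrame] = {}
    for phase in PHASES:
        sel = scores[(scores["country"] == country) & (scores["phase"] == phase)]
        if sel.empty:
            raise MissingPeriodError(
                f"country {country}: no tweets in period {phase!r}"
            )
        vectors[phase] = sel

    rows = []
    for k, phase in enumerate(PHASES):
        s = summarize_phase(scores, country, phase)
        marks = {"avg_pos": "", "avg_neg": ""}
        if phase != "base":
            prev = PHASES[k - 1]
            for col, comp in (("avg_pos", "pos"), ("avg_neg", "neg")):
                vb = compare_phases(
                    vectors[phase][comp], vectors["base"][comp],
                    vs="base", equal_var=equal_var,
                )
                vp = compare_phases(
                    vectors[phase][comp], vectors[prev][comp],
                    vs="previous", equal_var=equal_var,
                )
                marks[col] = vb.marker + vp.marker
        rows.append(
            {
                "period": "Base" if phase == "base" else f"Phase {phase}",
                "avg_pos": f"{s.aps:.3f}{marks['avg_pos']}",
                "avg_neg": f"{s.ans:.3f}{marks['avg_neg']}",
                "no_sent": round(s.pct_no_sent, 2),
                "strong": round(s.pct_strong, 2),
                "strong_pos": round(s.pct_strong_pos, 2),
                "strong_neg": round(s.pct_strong_neg, 2),
                "pos_only": round(s.pct_pos_only, 2),
                "neg_only": round(s.pct_neg_only, 2),
                "pos_gt_neg": round(s.pct_pos_gt_neg, 2),
                "neg_gt_pos": round(s.pct_neg_gt_pos, 2),
            }
        )
    return pd.DataFrame(rows).set_index("period")[_TABLE_COLUMNS]


def table_to_markdown(table: pd.DataFrame) -> str:
    """Render the detailed sentiment table as a markdown table."""
    header = "| Period | " + " | ".join(table.columns) + " |"
    rule = "|" + "---|" * (len(table.columns) + 1)
    lines = [header, rule]
    for period, row in table.iterrows():
        lines.append(
            "| " + period + " | " + " | ".join(str(v) for v in row) + " |"
        )
    return "\n".join(lines)
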