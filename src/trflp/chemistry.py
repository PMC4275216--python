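"""Active-chemical quantification and content-based sample grouping.

Covers the analytical-chemistry side of the study: a linear calibration
curve (response = slope * amount + intercept) fitted by ordinary least
squares and inverted to quantify an analyte; one-way ANOVA computed from
sufficient statistics (mean, SD, n per sample) because published tables
carry only summaries; Duncan's multiple range test with a compact letter
display; letter-based content groups (High / Sub-high / Intermediate /
Low when exactly four); and fold-excess summaries of a reference sample
against all others.

Duncan's test compares the range of every set of p adjacent mean-sorted
samples against the critical range

    R_p = q(1 - (1-alpha)^(p-1); p, df_within) * sqrt(MSE / n),

with q the studentized-range quantile at Duncan's protected level
(computed numerically from scipy's studentized-range distribution, not
from printed tables).  Two means differ significantly iff their span-p
range exceeds R_p and they are not contained in a wider non-significant
range.  Letters mark the maximal non-significant stretches, so they are
always contiguous over the mean-sorted order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "AnovaResult",
    "LetterDisplay",
    "GroupAssignment",
    "fit_calibration",
    "invert_calibration",
    "anova_oneway",
    "duncan_critical_range",
    "duncan_letters",
    "group_by_letters",
    "fold_excess",
    "validate_chem_table",
]

#: Canonical analytes and their units (per dried rhizome mass).
ANALYTE_UNITS = {"volatile_oil": "mg/100g", "galangin": "mg/g"}

FOUR_GROUP_LABELS = ("High", "Sub-high", "Intermediate", "Low")


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve: response = slope * amount + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def invertible(self) -> bool:
        return self.slope != 0.0

    def predict(self, amount: float) -> float:
        return self.slope * amount + self.intercept

    def invert(self, response: float) -> float:
        return invert_calibration(self, response)


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """OLS fit of (amount, response) standards."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (amount, response) pairs")
    amounts, responses = pts[:, 0], pts[:, 1]
    if np.ptp(amounts) == 0:
        raise ValueError("degenerate design: all amounts equal")
    fit = stats.linregress(amounts, responses)
    r_squared = float(fit.rvalue**2)
    if np.isnan(r_squared):  # zero response variance: the flat fit is exact
        residuals = responses - (fit.slope * amounts + fit.intercept)
        r_squared = 1.0 if np.allclose(residuals, 0.0) else 0.0
    return CalibrationCurve(float(fit.slope), float(fit.intercept), r_squared)


def invert_calibration(curve: CalibrationCurve, response: float) -> float:
    """Amount = (response - intercept) / slope."""
    if not curve.invertible:
        raise ValueError("calibration curve with zero slope is not invertible")
    return (response - curve.intercept) / curve.slope


# ---------------------------------------------------------------------------
# ANOVA from sufficient statistics

@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    ms_within: float
    ms_between: float
    p_value: float

    @property
    def degenerate(self) -> bool:
        """True when every group had zero variance and equal means (F = 0/0)."""
        return np.isnan(self.f)


def anova_oneway(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> AnovaResult:
    """One-way ANOVA computed from per-group (mean, SD, n).

    Algebraically identical to raw-data ANOVA whenever raw data realize
    the summaries (SD with ddof=1).
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (means.shape == sds.shape == ns.shape) or means.ndim != 1:
        raise ValueError("means, sds, ns must be 1-D and the same length")
    k = means.size
    if k < 2:
        raise ValueError("need at least two groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(sds < 0):
        raise ValueError("SDs must be non-negative")
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        f = np.nan if ms_between == 0.0 else np.inf
        p = np.nan if ms_between == 0.0 else 0.0
    else:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, ms_within, ms_between, p)


# ---------------------------------------------------------------------------
# Duncan's multiple range test

def duncan_critical_range(
    p: int, df_within: int, se: float, alpha: float = 0.05
) -> float:
    """R_p: Duncan's critical range for a stretch spanning p ordered means.

    The protected significance level alpha_p = 1 - (1-alpha)^(p-1) gives
    the studentized-range quantile q at cumulative probability
    (1-alpha)^(p-1)."""
    if p < 2:
        raise ValueError("span must be >= 2")
    q = stats.studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df_within)
    return float(q * se)


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: samples sharing a letter do not differ.

    ``letters`` maps sample -> sorted letter string; ``order`` is the
    mean-sorted (ascending) sample order the letters refer to.
    """

    letters: dict[str, str]
    alpha: float
    order: tuple[str, ...]

    def n_classes(self) -> int:
        """Number of distinct letter sets (content classes)."""
        return len(set(self.letters.values()))

    def partition(self) -> dict[str, tuple[str, ...]]:
        """Letter-set -> samples, in mean-sorted order."""
        out: dict[str, list[str]] = {}
        for sample in self.order:
            out.setdefault(self.letters[sample], []).append(sample)
        return {k: tuple(v) for k, v in out.items()}


def duncan_letters(
    labels: Sequence[str],
    means: Sequence[float],
    sds: Sequence[float],
    ns: Sequence[int],
    alpha: float = 0.05,
) -> LetterDisplay:
    """Duncan's multiple range test summarized as a compact letter display.

    Unbalanced designs fall back to the harmonic mean of the group sizes.
    With zero pooled error and unequal means, every distinct mean is its
    own class; with all means equal, a single class.
    """
    labels = list(map(str, labels))
    means_arr = np.asarray(means, dtype=float)
    anova = anova_oneway(means, sds, ns)
    ns_arr = np.asarray(ns, dtype=float)
    n_eff = float(len(ns_arr) / (1.0 / ns_arr).sum())  # harmonic mean
    order = np.argsort(means_arr, kind="stable")
    sorted_labels = [labels[i] for i in order]
    m = means_arr[order]
    k = len(labels)

    if anova.ms_within == 0.0:
        # zero-error contract: identical means share, distinct means differ
        intervals = []
        i = 0
        while i < k:
            j = i
            while j + 1 < k and m[j + 1] == m[i]:
                j += 1
            intervals.append((i, j))
            i = j + 1
    else:
        se = float(np.sqrt(anova.ms_within / n_eff))
        # maximal non-significant stretches: for each start, the farthest end
        # whose span-p range stays within R_p (protection: containment wins)
        ranges = {p: duncan_critical_range(p, anova.df_within, se, alpha) for p in range(2, k + 1)}
        ends = []
        for i in range(k):
            j_max = i
            for j in range(i + 1, k):
                if m[j] - m[i] <= ranges[j - i + 1]:
                    j_max = j
            ends.append(j_max)
        intervals = [
            (i, j)
            for i, j in enumerate(ends)
            if not any(i2 <= i and ends[i2] >= j and i2 != i for i2 in range(k))
        ]

    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for idx, (i, j) in enumerate(sorted(intervals)):
        letter = _letter(idx)
        for pos in range(i, j + 1):
            letters[sorted_labels[pos]].append(letter)
    return LetterDisplay(
        letters={lab: "".join(ls) for lab, ls in letters.items()},
        alpha=alpha,
        order=tuple(sorted_labels),
    )


def _letter(idx: int) -> str:
    out = ""
    idx += 1
    while idx:
        idx, rem = divmod(idx - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


@dataclass(frozen=True)
class GroupAssignment:
    """Partition of samples into content groups ordered by descending mean."""

    groups: dict[str, str]
    group_order: tuple[str, ...]

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in self.groups.items() if g == group)


def group_by_letters(
    display: LetterDisplay, means: Mapping[str, float]
) -> GroupAssignment:
    """Samples with identical letter sets form one group.

    Exactly four groups get the study's descriptive labels (High,
    Sub-high, Intermediate, Low by descending mean); otherwise ordinal
    labels G1, G2, ... are used.
    """
    classes: dict[str, list[str]] = {}
    for sample in display.order:
        classes.setdefault(display.letters[sample], []).append(sample)
    ordered = sorted(
        classes.values(),
        key=lambda members: -float(np.mean([means[s] for s in members])),
    )
    if len(ordered) == 4:
        names = list(FOUR_GROUP_LABELS)
    else:
        names = [f"G{i + 1}" for i in range(len(ordered))]
    groups = {s: name for name, members in zip(names, ordered) for s in members}
    return GroupAssignment(groups=groups, group_order=tuple(names))


# ---------------------------------------------------------------------------
# chemistry tables and fold summaries

CHEM_COLUMNS = ("sample_id", "analyte", "mean", "sd", "n")


def validate_chem_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a per-sample analyte summary table (mean, SD, n >= 2)."""
    missing = [c for c in CHEM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"chemistry table missing columns: {missing}")
    if (table["sd"] < 0).any():
        raise ValueError("negative SD in chemistry table")
    if (table["n"] < 2).any():
        raise ValueError("chemistry table requires n >= 2 per row")
    return table


def fold_excess(
    reference_sample: str, table: pd.DataFrame, analyte: str
) -> tuple[float, float]:
    """(min, max) fold excess of the reference over every other sample.

    fold = reference_mean / other_mean - 1, reported at 2-decimal
    rounding; e.g. (0.40, 3.92) reads "0.40 to 3.92 times higher".
    """
    validate_chem_table(table)
    sub = table[table["analyte"] == analyte]
    if sub.empty:
        raise KeyError(f"analyte {analyte!r} not in table")
    means = sub.set_index("sample_id")["mean"]
    if reference_sample not in means.index:
        raise KeyError(f"reference sample {reference_sample!r} not in table")
    ref = float(means.loc[reference_sample])
    others = means.drop(reference_sample)
    if (others <= 0).any():
        raise ValueError("fold excess undefined for non-positive comparator means")
    folds = ref / others - 1.0
    return (round(float(folds.min()), 2), round(float(folds.max()), 2))


def chem_letters(
    table: pd.DataFrame, analyte: str, alpha: float = 0.05
) -> LetterDisplay:
    """Duncan letter display for one analyte of a chemistry summary table."""
    validate_chem_table(table)
    sub = table[table["analyte"] == analyte]
    if sub.empty:
        raise KeyError(f"analyte {analyte!r} not in table")
    return duncan_letters(
        sub["sample_id"].tolist(),
        sub["mean"].to_numpy(),
        sub["sd"].to_numpy(),
        sub["n"].to_numpy(),
        alpha=alpha,
    )


def chem_groups(
    table: pd.DataFrame, analyte: str, alpha: float = 0.05
) -> GroupAssignment:
    """Letter-based content grouping for one analyte."""
    sub = table[table["analyte"] == analyte]
    display = chem_letters(table, analyte, alpha)
    means = sub.set_index("sample_id")["mean"].to_dict()
    return group_by_letters(display, means)
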