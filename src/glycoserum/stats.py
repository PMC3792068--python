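"""Differential screening, AUROC ratio-marker selection, and bootstrap
group comparisons for a case/control glycan cohort.

The screening recipe: per-glycan two-sided Student's t-test (equal
variance), Bonferroni family-wise control at alpha/G over the G panel
glycans, and discrimination measured by the AUROC, i.e. the Mann-Whitney
probability P(case value > control value) with ties counted one half.  The
ratio marker divides the best up-regulated significant glycan (max AUROC)
by the best down-regulated one (max 1 - AUROC); because the AUROC is a
rank statistic the selected pair and the marker's AUROC are invariant to
rescaling any glycan column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GlycanPanel

log = logging.getLogger(__name__)

__all__ = [
    "student_t_test",
    "auroc",
    "per_glycan_differential",
    "RatioMarker",
    "select_ratio_marker",
    "bootstrap_group_means",
    "strata_compare",
    "NoMarkerError",
]


class NoMarkerError(RuntimeError):
    """No significant up- or down-regulated glycan: no ratio marker selectable."""


def student_t_test(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample two-sided t-test; classic pooled-variance Student form.

    Welch's unequal-variance variant is available with ``equal_var=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    if equal_var:
        n1, n2 = len(x), len(y)
        pooled = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        if pooled <= 0:
            raise ValueError("degenerate (zero) pooled variance; t-test undefined")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def auroc(values, labels, case) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Returns P(random case value > random control value), ties counted 0.5;
    identical to the trapezoidal area under the empirical ROC curve.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    is_case = labels == case
    n1 = int(is_case.sum())
    n0 = int(len(values) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both case and control groups must be non-empty")
    ranks = sps.rankdata(values)
    u = ranks[is_case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def per_glycan_differential(
    matrix: pd.DataFrame,
    groups: pd.Series,
    case: str = "UC",
    control: str = "HLT",
    alpha: float = 0.05,
    panel: GlycanPanel | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Bonferroni-controlled per-glycan screen of case versus control.

    One row per matrix column with group means, t, two-sided p, direction
    (up if the case mean exceeds the control mean), AUROC oriented as
    P(case > control), and the significance flag p < alpha / G.
    """
    groups = groups.reindex(matrix.index)
    known = groups.isin([case, control])
    if groups.isna().any():
        missing = list(matrix.index[groups.isna()])
        raise ValueError(f"samples without group labels: {missing}")
    matrix = matrix.loc[known]
    groups = groups.loc[known]
    g = matrix.shape[1]
    if g < 1:
        raise ValueError("matrix has no glycan columns")
    threshold = alpha / g
    case_m = matrix.loc[groups == case]
    ctrl_m = matrix.loc[groups == control]
    rows = []
    for col in matrix.columns:
        x = case_m[col].to_numpy(dtype=float)
        y = ctrl_m[col].to_numpy(dtype=float)
        t, p = student_t_test(x, y, equal_var=equal_var)
        a = auroc(matrix[col], groups, case)
        rows.append(
            {
                "glycan": col,
                "label": panel.label(col) if panel is not None else pd.NA,
                "mean_case": x.mean(),
                "mean_control": y.mean(),
                "t": t,
                "p": p,
                "direction": "up" if x.mean() > y.mean() else "down",
                "auroc": a,
                "significant": p < threshold,
            }
        )
    out = pd.DataFrame(rows).set_index("glycan")
    out.attrs["alpha"] = alpha
    out.attrs["threshold"] = threshold
    out.attrs["case"] = case
    out.attrs["control"] = control
    return out


@dataclass(frozen=True)
class RatioMarker:
    """A two-glycan ratio biomarker (up-regulated over down-regulated)."""

    numerator: str
    denominator: str
    numerator_label: int | None
    denominator_label: int | None
    auroc: float
    values: pd.Series = field(repr=False, compare=False)

    @property
    def name(self) -> str:
        if self.numerator_label is not None and self.denominator_label is not None:
            return f"m/z {self.numerator_label}/{self.denominator_label}"
        return f"{self.numerator}/{self.denominator}"


def marker_ratio(
    matrix: pd.DataFrame, numerator: str, denominator: str
) -> pd.Series:
    """Per-sample numerator/denominator abundance ratio.

    Samples with non-positive denominator abundance are dropped with a
    warning — abundances are quantities and expected positive.
    """
    den = matrix[denominator].astype(float)
    bad = den <= 0
    if bad.any():
        log.warning(
            "excluding %d sample(s) with non-positive %s abundance from ratio",
            int(bad.sum()), denominator,
        )
    ratio = matrix.loc[~bad, numerator].astype(float) / den[~bad]
    ratio.name = f"{numerator}/{denominator}"
    return ratio


def select_ratio_marker(
    results: pd.DataFrame,
    matrix: pd.DataFrame,
    groups: pd.Series,
    panel: GlycanPanel | None = None,
) -> RatioMarker:
    """Pick the up/down ratio marker from a differential screen.

    Numerator: significant up-regulated glycan with the highest AUROC.
    Denominator: significant down-regulated glycan with the highest
    direction-corrected AUROC (1 - AUROC as stored).  Ties break toward
    the smaller integer label (or lexicographic code without a panel).
    """
    sig = results[results["significant"]]
    up = sig[sig["direction"] == "up"]
    down = sig[sig["direction"] == "down"]
    if up.empty or down.empty:
        raise NoMarkerError(
            f"no marker selectable: {len(up)} significant up-regulated and "
            f"{len(down)} significant down-regulated glycans"
        )

    def tiebreak(col: str):
        return panel.label(col) if panel is not None else col

    num = min(up.index, key=lambda c: (-up.loc[c, "auroc"], tiebreak(c)))
    den = min(down.index, key=lambda c: (-(1.0 - down.loc[c, "auroc"]), tiebreak(c)))
    ratio = marker_ratio(matrix, num, den)
    case = results.attrs.get("case", "UC")
    a = auroc(ratio, groups.reindex(ratio.index), case)
    return RatioMarker(
        numerator=num,
        denominator=den,
        numerator_label=panel.label(num) if panel is not None else None,
        denominator_label=panel.label(den) if panel is not None else None,
        auroc=a,
        values=ratio,
    )


def bootstrap_group_means(
    values,
    groups,
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Bootstrap point estimates of two group means and a two-sided p for
    their difference.

    Resampling is within group with replacement; the point estimate per
    group is the mean of the B bootstrap means, and the two-sided p uses
    the add-one rule 2*min(#(diff<=0)+1, #(diff>=0)+1)/(B+1), capped at 1,
    so a zero p-value is unattainable.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100 (got {B})")
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups)).astype(str)
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups (got {names})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = {g: values[groups.values == g].to_numpy() for g in names}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {g} has fewer than 2 values")
    boot = {}
    for g in names:
        arr = arrays[g]
        idx = rng.integers(0, len(arr), size=(B, len(arr)))
        boot[g] = arr[idx].mean(axis=1)
    diff = boot[names[0]] - boot[names[1]]
    n_le = int((diff <= 0).sum())
    n_ge = int((diff >= 0).sum())
    p = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (B + 1))
    return {
        "groups": names,
        "point_estimates": {g: float(boot[g].mean()) for g in names},
        "observed_means": {g: float(arrays[g].mean()) for g in names},
        "bootstrap_se": {g: float(boot[g].std(ddof=1)) for g in names},
        "p": p,
        "B": B,
    }


def strata_compare(
    marker_values: pd.Series,
    stratum: pd.Series,
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Compare a marker between the two levels of a binary clinical stratum.

    ``stratum`` is boolean (or two-level) aligned to ``marker_values``;
    samples with missing stratum are excluded (e.g. Mayo endoscopic score
    0 when comparing score 3 against 1-2).  Returns group means, Student's
    t-test, and a seeded bootstrap summary.
    """
    stratum = stratum.reindex(marker_values.index)
    keep = stratum.notna()
    marker_values = marker_values[keep]
    stratum = stratum[keep]
    levels = sorted(pd.unique(stratum), key=str)
    if len(levels) != 2:
        raise ValueError(f"stratum must have exactly 2 levels (got {levels})")
    split = {lv: marker_values[stratum == lv] for lv in levels}
    for lv, vals in split.items():
        if len(vals) == 0:
            raise ValueError(f"stratum level {lv!r} is empty")
    t, p = student_t_test(split[levels[0]], split[levels[1]])
    boot = bootstrap_group_means(
        marker_values.to_numpy(), stratum.astype(str).to_numpy(), B=B, seed=seed
    )
    return {
        "levels": [str(lv) for lv in levels],
        "n": {str(lv): int(len(split[lv])) for lv in levels},
        "means": {str(lv): float(split[lv].mean()) for lv in levels},
        "t": t,
        "p": p,
        "bootstrap": boot,
    }
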