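"""Method-comparison and reliability statistics.

Implements the comparison battery used to evaluate a dental-age method
against chronological age and against a rival method: age-by-sex bias
tables, Wilcoxon signed-rank tests on paired differences, Pearson
correlation, ordinary least-squares regression with a slope-equality test,
and intra/inter-rater reliability via the intraclass correlation
coefficient (ICC).

The Wilcoxon test is implemented here rather than delegated: the exact null
distribution is enumerated (via a rank-sum convolution) for n <= 25 *even in
the presence of midrank ties*, which reference implementations decline, and
larger samples use the normal approximation with tie and continuity
corrections.  ICC goes through ``pingouin.intraclass_corr`` (the standard
six-form Shrout-Fleiss panel); correlation/regression go through
scipy/statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "wilcoxon_signed_rank",
    "pearson_r",
    "linreg",
    "slope_equality_test",
    "icc",
    "icc_panel",
    "ICCResult",
    "rating_matrix",
    "bias_table",
    "format_p",
    "format_bias_table",
]


class WilcoxonResult(NamedTuple):
    statistic: float  # W+, sum of positive signed ranks
    p_value: float


def _exact_two_sided_p(doubled_ranks: np.ndarray, w_doubled: int) -> float:
    """Exact p by enumerating the 2^n sign assignments via convolution.

    Ranks are midranks doubled to integers; the subset-sum count table has
    at most n(n+1) + 1 entries, so this is polynomial despite the 2^n
    sample space.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()  # == 2^n
    cdf = counts[: w_doubled + 1].sum() / denom
    sf = counts[w_doubled:].sum() / denom
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(
    differences: Sequence[float],
    *,
    zero_method: str = "wilcoxon",
    method: str = "auto",
    exact_cutoff: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded (Wilcoxon's original policy; pass
    ``zero_method="pratt"`` to rank them and drop only their signs).  The
    statistic is W+ with midranks for tied magnitudes.  ``method`` is
    ``"exact"``, ``"approx"``, or ``"auto"`` (exact up to ``exact_cutoff``
    non-zero pairs, the tie- and continuity-corrected normal approximation
    beyond).
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    if zero_method not in ("wilcoxon", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if zero_method == "wilcoxon":
        d = d[d != 0]
    if d.size == 0 or np.all(d == 0):
        warnings.warn("all paired differences are zero; test is degenerate")
        return WilcoxonResult(0.0, 1.0)

    ranks = stats.rankdata(np.abs(d))
    if zero_method == "pratt":
        keep = d != 0
        d, ranks = d[keep], ranks[keep]
    w_pos = float(ranks[d > 0].sum())
    n = d.size

    if method == "auto":
        method = "exact" if n <= exact_cutoff else "approx"
    if method == "exact":
        doubled = np.round(2 * ranks).astype(int)
        p = _exact_two_sided_p(doubled, int(round(2 * w_pos)))
        return WilcoxonResult(w_pos, p)
    if method != "approx":
        raise ValueError(f"unknown method {method!r}")

    mu = ranks.sum() / 2.0
    var = (ranks**2).sum() / 4.0  # equals n(n+1)(2n+1)/24 - tie correction
    if var == 0:
        return WilcoxonResult(w_pos, 1.0)
    dev = w_pos - mu
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(w_pos, p)


class CorrelationResult(NamedTuple):
    r: float
    p_value: float


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-based p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue))


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def linreg(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x; r_squared is the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: constant x")
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept), float(res.rvalue) ** 2)


def slope_equality_test(
    x: Sequence[float], y1: Sequence[float], y2: Sequence[float]
) -> float:
    """Test whether two methods regress on x with equal slopes.

    Stacks the two outcome vectors with a method indicator and fits
    ``y ~ x * method``; the two-sided p-value of the interaction term tests
    slope equality.  Identical outcome vectors short-circuit to p = 1 (the
    interaction is identically zero).
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if not (x.size == y1.size == y2.size):
        raise ValueError("x, y1, y2 must have equal length")
    if np.array_equal(y1, y2):
        return 1.0
    xx = np.concatenate([x, x])
    yy = np.concatenate([y1, y2])
    ind = np.concatenate([np.zeros(x.size), np.ones(x.size)])
    design = sm.add_constant(np.column_stack([xx, ind, xx * ind]))
    fit = sm.OLS(yy, design).fit()
    return float(fit.pvalues[3])


@dataclass(frozen=True)
class ICCResult:
    form: str  # e.g. "ICC3"
    unit: str  # "single" or "average"
    value: float
    ci_low: float
    ci_high: float


# Shrout-Fleiss form -> McGraw-Wong label used by pingouin's panel:
# ICC1 one-way random, ICC2 two-way random absolute agreement (A),
# ICC3 two-way mixed consistency (C); ",k" = average of k raters.
_ICC_TYPES = {
    ("ICC1", "single"): "ICC(1,1)",
    ("ICC2", "single"): "ICC(A,1)",
    ("ICC3", "single"): "ICC(C,1)",
    ("ICC1", "average"): "ICC(1,k)",
    ("ICC2", "average"): "ICC(A,k)",
    ("ICC3", "average"): "ICC(C,k)",
}


def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    matrix = pd.DataFrame(matrix)
    if matrix.isna().any().any():
        raise ValueError("rating matrix contains missing cells; no imputation is done")
    if matrix.shape[1] < 2:
        raise ValueError("reliability analysis needs >= 2 raters/sessions")
    if matrix.shape[0] < 5:
        raise ValueError("reliability analysis needs >= 5 subjects")
    return matrix


def icc_panel(matrix: pd.DataFrame) -> pd.DataFrame:
    """Full six-form Shrout-Fleiss ICC panel for a subjects x raters matrix."""
    import pingouin as pg

    matrix = _check_matrix(matrix)
    long = matrix.reset_index(names="subject").melt(
        id_vars="subject", var_name="rater", value_name="rating"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        panel = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="rating"
        )
    return panel.set_index("Type")


def icc(
    matrix: pd.DataFrame, form: str = "ICC3", unit: str = "single"
) -> ICCResult:
    """One ICC form with its 95% CI.

    ICC3 (two-way mixed, consistency) single-rater is the default report:
    ratings come from fixed, named examiners and a systematic level offset
    between examiners should not count against reproducibility.  Use
    :func:`icc_panel` for the full six-form panel.
    """
    key = (form, unit)
    if key not in _ICC_TYPES:
        raise ValueError(f"unknown ICC form {form!r}/{unit!r}")
    panel = icc_panel(matrix)
    row = panel.loc[_ICC_TYPES[key]]
    ci_col = "CI95%" if "CI95%" in panel.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(form, unit, float(row["ICC"]), float(lo), float(hi))


def rating_matrix(
    estimates: pd.DataFrame,
    method: str,
    *,
    columns: str = "rater_id",
    value: str = "da_point",
) -> pd.DataFrame:
    """Pivot a tidy estimates table to subjects x raters (or x sessions)."""
    sub = estimates[estimates["method"] == method]
    if sub.empty:
        raise ValueError(f"no estimates for method {method!r}")
    return sub.pivot_table(index="subject_id", columns=columns, values=value)


# ---------------------------------------------------------------------------
# Bias tables


def _sd(x: pd.Series) -> float:
    return float(x.std(ddof=1)) if len(x) > 1 else float("nan")


def bias_table(
    estimates: pd.DataFrame,
    *,
    methods: Sequence[str] = ("becker", "demirjian"),
    by_sex: bool = True,
) -> pd.DataFrame:
    """Age-group x sex bias table comparing DA methods with CA.

    ``estimates`` is tidy: one row per (subject, method) with columns
    subject_id, sex, ca_years, method, da_point.  Age groups are
    floor(CA); every integer age in the observed span is emitted, empty
    strata with n = 0 and blank statistics.  Difference columns are computed
    from the unrounded means, and per-stratum Wilcoxon signed-rank p-values
    are attached for each method vs CA and between methods (raw, no
    multiplicity adjustment).  A totals row closes each sex block.
    """
    req = {"subject_id", "sex", "ca_years", "method", "da_point"}
    missing = req - set(estimates.columns)
    if missing:
        raise ValueError(f"estimates table missing columns {sorted(missing)}")
    if estimates.empty:
        raise ValueError("empty estimates table")

    wide = estimates.pivot_table(
        index=["subject_id", "sex", "ca_years"],
        columns="method",
        values="da_point",
        aggfunc="mean",
    ).reset_index()
    wide["age_group"] = np.floor(wide["ca_years"]).astype(int)

    present = [m for m in methods if m in wide.columns]
    lo, hi = int(wide["age_group"].min()), int(wide["age_group"].max())
    sexes = sorted(wide["sex"].unique()) if by_sex else ["all"]

    rows = []
    for sex in sexes:
        block = wide if sex == "all" else wide[wide["sex"] == sex]
        strata: list[tuple[object, pd.DataFrame]] = [
            (age, block[block["age_group"] == age]) for age in range(lo, hi + 1)
        ]
        strata.append(("total", block))
        for age, grp in strata:
            row: dict[str, object] = {"sex": sex, "age_group": age, "n": len(grp)}
            if len(grp) == 0:
                rows.append(row)
                continue
            row["ca_mean"] = grp["ca_years"].mean()
            row["ca_sd"] = _sd(grp["ca_years"])
            for m in present:
                da = grp[m].dropna()
                row[f"{m}_mean"] = da.mean()
                row[f"{m}_sd"] = _sd(da)
                row[f"{m}_minus_ca"] = grp[m].mean() - grp["ca_years"].mean()
                diffs = (grp[m] - grp["ca_years"]).dropna().to_numpy()
                if diffs.size >= 1 and np.any(diffs != 0):
                    row[f"p_{m}"] = wilcoxon_signed_rank(diffs).p_value
                else:
                    row[f"p_{m}"] = np.nan
            if len(present) == 2:
                a, b = present
                row[f"{b}_minus_{a}"] = grp[b].mean() - grp[a].mean()
                diffs = (grp[b] - grp[a]).dropna().to_numpy()
                if diffs.size >= 1 and np.any(diffs != 0):
                    row["p_methods"] = wilcoxon_signed_rank(diffs).p_value
                else:
                    row["p_methods"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """Render a p-value to 3 decimals, flooring tiny values as '<0.001'."""
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def format_bias_table(table: pd.DataFrame) -> str:
    """Plain-text report of a bias table (means (SD), differences, p-values)."""
    lines = []
    p_cols = [c for c in table.columns if c.startswith("p_")]
    mean_cols = [c for c in table.columns if c.endswith("_mean")]
    diff_cols = [c for c in table.columns if "_minus_" in c]
    for sex, block in table.groupby("sex", sort=True):
        lines.append(f"=== {sex} ===")
        header = ["age", "n"]
        for c in mean_cols:
            header.append(c.replace("_mean", " (SD)"))
        header += diff_cols + p_cols
        lines.append("\t".join(header))
        for _, row in block.iterrows():
            out = [str(row["age_group"]), str(int(row["n"]))]
            for c in mean_cols:
                sd_col = c.replace("_mean", "_sd")
                if row["n"] == 0 or pd.isna(row.get(c, np.nan)):
                    out.append("")
                elif pd.isna(row.get(sd_col, np.nan)):
                    out.append(f"{row[c]:.3f} (-)")
                else:
                    out.append(f"{row[c]:.3f} ({row[sd_col]:.3f})")
            for c in diff_cols:
                v = row.get(c, np.nan)
                out.append("" if pd.isna(v) else f"{v:.3f}")
            for c in p_cols:
                out.append(format_p(row.get(c, np.nan)))
            lines.append("\t".join(out))
    return "\n".join(lines)
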