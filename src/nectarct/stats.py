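"""Group comparison and regression stages for flower phenotype cohorts.

Two-group comparison follows a fixed decision procedure: Shapiro–Wilk
normality on each group; if both pass, Levene's homogeneity-of-variance
test decides between Student's t (equal variances) and Welch's t (unequal
variances). A significant Shapiro result only *flags* the comparison as
needing a nonparametric alternative — the procedure still reports the
t-branch result, and no nonparametric test is substituted. p-values get
the conventional star labels (* p < 0.05, ** p < 0.01, *** p < 0.001,
otherwise N.S.).

Correlation between nectar volume and gland morphometrics uses ordinary
least squares with Pearson r and its t-transform p-value; an exact
permutation p is available for very small cohorts. No multiple-testing
correction is applied across panels; results carry that note in their
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats as sps

Alpha = 0.05


@dataclass
class TestResult:
    """Outcome of the two-group comparison decision procedure."""

    test_name: Literal["student_t", "welch_t"]
    statistic: float
    p_value: float
    n: tuple[int, int]
    decision_path: list[str]
    stars: str
    shapiro_p: tuple[float, float] = (float("nan"), float("nan"))
    levene_p: float = float("nan")
    nonparametric_needed: bool = False


@dataclass
class RegressionResult:
    """Simple linear regression with Pearson correlation."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int
    dropped: int = 0
    notes: dict = field(default_factory=dict)


def significance_stars(p: float) -> str:
    """Conventional star label with strict-inequality bins.

    p < 0.001 → ``***``; p < 0.01 → ``**``; p < 0.05 → ``*``; otherwise
    ``N.S.`` (p = 0.05 exactly is not significant).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "N.S."


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = Alpha,
    levene_center: Literal["mean", "median"] = "mean",
) -> TestResult:
    """Two-group comparison via the Shapiro → Levene → Student/Welch tree.

    ``levene_center='mean'`` is the original Levene statistic (default);
    ``'median'`` gives the Brown–Forsythe variant. With identical inputs
    the t statistic is 0 and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    path = []
    sh_a = sps.shapiro(a)
    sh_b = sps.shapiro(b)
    path.append(f"shapiro(a): p={sh_a.pvalue:.4g}")
    path.append(f"shapiro(b): p={sh_b.pvalue:.4g}")
    nonparam = bool(sh_a.pvalue < alpha or sh_b.pvalue < alpha)
    if nonparam:
        path.append("shapiro significant: flagged nonparametric_needed")

    lev = sps.levene(a, b, center=levene_center)
    equal_var = bool(lev.pvalue >= alpha)
    path.append(
        f"levene({levene_center}): p={lev.pvalue:.4g} -> "
        f"{'equal' if equal_var else 'unequal'} variances"
    )
    if np.array_equal(a, b):
        # identical samples: t = 0, p = 1 by symmetry (scipy returns nan
        # when the pooled variance is 0 for constant identical vectors)
        t_stat, p = 0.0, 1.0
        name = "student_t" if equal_var else "welch_t"
        path.append(f"{name}: identical samples, t=0, p=1")
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
        name = "student_t" if equal_var else "welch_t"
        path.append(f"{name}: t={t_stat:.4g}, p={p:.4g}")

    return TestResult(
        test_name=name,
        statistic=t_stat,
        p_value=p,
        n=(len(a), len(b)),
        decision_path=path,
        stars=significance_stars(p),
        shapiro_p=(float(sh_a.pvalue), float(sh_b.pvalue)),
        levene_p=float(lev.pvalue),
        nonparametric_needed=nonparam,
    )


def linear_fit(
    x: Sequence[float],
    y: Sequence[float],
    permutation_p: bool = False,
    seed: int | None = None,
    n_permutations: int = 10000,
) -> RegressionResult:
    """OLS fit with Pearson r, R² = r², and a two-sided p for the correlation.

    The default p uses the t transform of r with n − 2 degrees of freedom;
    ``permutation_p`` replaces it with a Monte-Carlo permutation p-value,
    useful for the very small cohorts typical of per-flower phenotyping.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    r = float(res.rvalue)
    p = float(res.pvalue)
    notes = {"p_method": "t-transform", "multiple_testing_correction": "none"}
    if permutation_p:
        rng = np.random.default_rng(seed)
        obs = abs(r)
        count = 0
        for _ in range(n_permutations):
            rp = np.corrcoef(x, rng.permutation(y))[0, 1]
            if abs(rp) >= obs - 1e-15:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        notes["p_method"] = f"permutation({n_permutations})"
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        r_squared=r * r,
        p_value=p,
        n=len(x),
        notes=notes,
    )


def correlate_cohort(
    records: Iterable,
    x_field: str,
    y_field: str,
    group: Literal["male", "female", "pooled"] = "pooled",
    **fit_kwargs,
) -> RegressionResult:
    """Regress ``y_field`` on ``x_field`` over a cohort of records.

    ``records`` may be MeasurementRecords, CohortRows, or any objects /
    mappings exposing the two fields plus ``sex``. Rows missing either
    field are dropped and counted in the result.
    """
    def get(rec, name):
        if isinstance(rec, dict):
            return rec.get(name)
        return getattr(rec, name, None)

    xs, ys, dropped = [], [], 0
    for rec in records:
        if group != "pooled" and get(rec, "sex") != group:
            continue
        xv, yv = get(rec, x_field), get(rec, y_field)
        if xv is None or yv is None or not np.isfinite([xv, yv]).all():
            dropped += 1
            continue
        xs.append(float(xv))
        ys.append(float(yv))
    if len(xs) < 3:
        raise ValueError(
            f"group '{group}' has {len(xs)} usable rows; need at least 3"
        )
    result = linear_fit(xs, ys, **fit_kwargs)
    result.dropped = dropped
    return result


def regression_plot(result: RegressionResult, x, y, out_path,
                    x_label: str = "x", y_label: str = "y") -> None:
    """Scatter plot with the fitted line and the R² annotation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, float)
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.scatter(x, y, s=18, color="tab:green", alpha=0.8)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, result.slope * xs + result.intercept, color="black", lw=1)
    eq = f"y = {result.slope:.3g}x + {result.intercept:.3g}"
    ax.set_title(f"{eq}   R²={result.r_squared:.2f}", fontsize=9)
    ax.set_xlabel(x_label)
    ax.set_ylabel(y_label)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
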