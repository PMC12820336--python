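"""Group-level statistics: assumption checks, ANCOVA with adjusted means,
paired and two-sample tests, Spearman correlations, and BH-FDR control.

The layer reproduces the analysis plan of the cohort study: ANCOVA of
each imaging outcome on group controlling for age and education (with
the adjusted-mean difference beta, its 95% CI, F, p and partial eta
squared), paired hemisphere comparisons, a Spearman correlation grid
against clinical measures, and Benjamini-Hochberg step-up FDR within
the stated test families.  Demographic comparisons use a pooled t-test
when both groups pass Shapiro-Wilk normality, otherwise Mann-Whitney U.

Standard distributional machinery is delegated to scipy.stats and
statsmodels; this module owns the composition, the effect-size
arithmetic, and the report structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .core_io import CohortTable, ValidationError

__all__ = [
    "AncovaResult",
    "CorrelationResult",
    "StatsReport",
    "shapiro_wilk",
    "levene",
    "two_sample_t",
    "two_sample_t_from_summary",
    "mann_whitney",
    "paired_t",
    "ancova",
    "partial_eta_sq",
    "spearman",
    "bh_fdr",
    "build_report",
]

ALPHA = 0.05

OUTCOMES = ("alps_mean", "alps_left", "alps_right", "fw")


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro-Wilk undefined for a zero-variance sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def levene(y, g, center: str = "mean") -> tuple[float, float]:
    """Levene's homoscedasticity test across the groups in ``g``.

    ``center='mean'`` is the classic form; ``'median'`` gives the
    Brown-Forsythe variant.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    groups = [y[g == lev] for lev in pd.unique(g)]
    if len(groups) < 2:
        raise ValidationError("Levene's test needs at least two groups")
    if any(len(grp) < 2 for grp in groups):
        raise ValidationError("every group needs n >= 2 for Levene's test")
    res = stats.levene(*groups, center=center)
    return float(res.statistic), float(res.pvalue)


def _welch_df(s1: float, n1: int, s2: float, n2: int) -> float:
    a, b = s1**2 / n1, s2**2 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


def two_sample_t(x, y, variant: str = "pooled") -> tuple[float, float, float]:
    """Independent two-sample t-test; returns (t, df, p two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("both samples need n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValidationError("both samples have zero variance")
    equal_var = variant == "pooled"
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = len(x) + len(y) - 2
    else:
        df = _welch_df(x.std(ddof=1), len(x), y.std(ddof=1), len(y))
    return float(res.statistic), float(df), float(res.pvalue)


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t from printed summary statistics (mean, SD, n per group)."""
    if sd1 == 0 and sd2 == 0:
        raise ValidationError("both variances are zero")
    equal_var = variant == "pooled"
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    df = (n1 + n2 - 2) if equal_var else _welch_df(sd1, n1, sd2, n2)
    return float(res.statistic), float(df), float(res.pvalue)


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with midrank ties; exact enumeration for n1+n2 <= 12."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) + len(y) <= 12
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def paired_t(a, b) -> tuple[float, float, float]:
    """Paired t-test on matched samples; returns (t, df, p two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValidationError("paired samples must have equal length")
    if len(a) < 2:
        raise ValidationError("paired t-test needs n >= 2")
    if np.ptp(a - b) == 0:
        raise ValidationError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(len(a) - 1), float(res.pvalue)


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AncovaResult:
    """ANCOVA of one outcome on a binary group with covariates.

    ``beta`` is the group coefficient = adjusted (least-squares) mean
    difference, evaluated at the whole-sample covariate means; partial
    eta squared is SS_group / (SS_group + SS_error).
    """

    beta: float
    ci_low: float
    ci_high: float
    t: float
    F: float
    p: float
    eta_p2: float
    adjusted_means: dict  # group -> (mean, se)
    df_resid: int
    n: int

    def __post_init__(self) -> None:
        groups = list(self.adjusted_means)
        diff = self.adjusted_means[groups[0]][0] - self.adjusted_means[groups[1]][0]
        if abs(self.beta - diff) > 1e-9:
            raise ValidationError("beta does not equal the adjusted-mean difference")
        if not self.ci_low < self.beta < self.ci_high:
            raise ValidationError("CI does not bracket beta")
        if not 0 <= self.eta_p2 < 1 or self.F < 0:
            raise ValidationError("invalid effect size")


def ancova(
    y, group, covariates: pd.DataFrame | np.ndarray, reference: str | None = None
) -> AncovaResult:
    """Fit ``y ~ intercept + group + covariates`` and summarize the group term.

    ``group`` must be binary; ``beta`` is the mean difference of the
    non-reference level minus the reference level, adjusted to the
    whole-sample covariate means.  With NIHL/HC labels, HC is the
    reference so beta = NIHL - HC.
    """
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValidationError(f"group must be binary, got levels {levels}")
    if reference is None:
        reference = "HC" if "HC" in levels else sorted(map(str, levels))[-1]
    other = [lev for lev in levels if str(lev) != str(reference)][0]
    ind = (group == other).astype(float)

    n, n_cov = len(y), cov.shape[1]
    if n <= n_cov + 2:
        raise ValidationError("too few observations for the ANCOVA design")
    design = np.column_stack([np.ones(n), ind, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("collinear ANCOVA design")

    fit = sm.OLS(y, design).fit()
    beta = float(fit.params[1])
    t_val = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    ci = fit.conf_int(alpha=ALPHA)
    df_resid = int(fit.df_resid)
    F = t_val**2
    eta = partial_eta_sq(F, 1, df_resid)

    cov_means = cov.mean(axis=0)
    cov_params = np.asarray(fit.cov_params())
    adj = {}
    for label, flag in ((str(other), 1.0), (str(reference), 0.0)):
        x0 = np.concatenate([[1.0, flag], cov_means])
        mean = float(x0 @ fit.params)
        se = float(np.sqrt(x0 @ cov_params @ x0))
        adj[label] = (mean, se)
    return AncovaResult(
        beta=beta,
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        t=t_val,
        F=F,
        p=p,
        eta_p2=eta,
        adjusted_means=adj,
        df_resid=df_resid,
        n=n,
    )


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValidationError("need F >= 0 and dfs >= 1")
    return float(F * df1 / (F * df1 + df2))


# ---------------------------------------------------------------------------
# Correlation and FDR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1 or self.n < 3:
            raise ValidationError("invalid correlation result")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midrank ties; two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("Spearman needs matched samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero rank variance")
    res = stats.spearmanr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


def bh_fdr(
    pvals, alpha: float = ALPHA, families: list[list[int]] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up within each test family.

    Returns (reject flags, adjusted p-values), aligned with ``pvals``.
    ``families`` partitions the indices; default is one family.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if families is None:
        families = [list(range(len(p)))]
    reject = np.zeros(len(p), dtype=bool)
    adj = np.ones(len(p))
    for fam in families:
        if len(fam) == 0:
            raise ValidationError("empty FDR family")
        idx = np.asarray(fam)
        rej, p_adj, *_ = multipletests(p[idx], alpha=alpha, method="fdr_bh")
        reject[idx] = rej
        adj[idx] = p_adj
    return reject, adj


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class StatsReport:
    """Machine-readable analogs of the four cohort result tables."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    assumptions: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "table1": self.table1.to_dict(orient="records"),
            "table2": self.table2.to_dict(orient="records"),
            "table3": self.table3.to_dict(orient="records"),
            "table4": self.table4.to_dict(orient="records"),
            "assumptions": self.assumptions,
            "excluded": list(self.excluded),
        }


def _demographics_row(name: str, a: np.ndarray, b: np.ndarray) -> dict:
    """t or Mann-Whitney per the normality gate (Shapiro p >= 0.05 in both)."""
    try:
        norm_a = shapiro_wilk(a)[1]
        norm_b = shapiro_wilk(b)[1]
        normal = norm_a >= ALPHA and norm_b >= ALPHA
    except ValidationError:
        norm_a = norm_b = np.nan
        normal = False
    if normal:
        t, df, p = two_sample_t(a, b, variant="pooled")
        stat, test = t, "t"
    else:
        stat, p = mann_whitney(a, b)
        test = "mannwhitney"
    return {
        "characteristic": name,
        "nihl_mean": float(np.mean(a)),
        "nihl_sd": float(np.std(a, ddof=1)),
        "hc_mean": float(np.mean(b)),
        "hc_sd": float(np.std(b, ddof=1)),
        "shapiro_p_nihl": norm_a,
        "shapiro_p_hc": norm_b,
        "test": test,
        "statistic": stat,
        "p": p,
    }


def build_report(measures: pd.DataFrame, cohort: CohortTable) -> StatsReport:
    """Assemble the full statistics report from per-subject measurements.

    ``measures`` carries one row per subject with columns
    ``id, alps_mean, alps_left, alps_right, fw``.  Subjects with missing
    measurements are excluded and listed in ``excluded``.
    """
    df = cohort.frame.merge(measures, on="id", how="left", validate="one_to_one")
    needed = list(OUTCOMES)
    bad = df[df[needed].isna().any(axis=1)]
    excluded = bad["id"].tolist()
    df = df.dropna(subset=needed).reset_index(drop=True)
    nihl = df[df.group == "NIHL"]
    hc = df[df.group == "HC"]
    if len(nihl) < 3 or len(hc) < 3:
        raise ValidationError("too few complete subjects per group")

    # --- table 1: demographics ------------------------------------------
    rows1 = [
        _demographics_row(name, nihl[col].to_numpy(float), hc[col].to_numpy(float))
        for name, col in (("age", "age"), ("education", "education"), ("hama", "hama"))
    ]
    rows1.append(
        {
            "characteristic": "mtwv",
            "nihl_mean": float(nihl.mtwv.mean()),
            "nihl_sd": float(nihl.mtwv.std(ddof=1)),
            "hc_mean": np.nan,
            "hc_sd": np.nan,
            "shapiro_p_nihl": np.nan,
            "shapiro_p_hc": np.nan,
            "test": "none",
            "statistic": np.nan,
            "p": np.nan,
        }
    )
    table1 = pd.DataFrame(rows1)

    # --- table 2: ANCOVA per outcome + BH within the 4-test family -------
    cov = df[["age", "education"]]
    rows2 = []
    assumptions = {}
    for outcome in OUTCOMES:
        res = ancova(df[outcome], df.group, cov)
        resid = df[outcome] - sm.OLS(
            df[outcome], sm.add_constant(np.column_stack([(df.group == "NIHL").astype(float), cov]))
        ).fit().fittedvalues
        assumptions[outcome] = {
            "shapiro_resid_p": shapiro_wilk(resid)[1],
            "levene_p": levene(resid.to_numpy(), df.group.to_numpy())[1],
        }
        rows2.append(
            {
                "outcome": outcome,
                "nihl_raw_mean": float(nihl[outcome].mean()),
                "nihl_raw_sd": float(nihl[outcome].std(ddof=1)),
                "hc_raw_mean": float(hc[outcome].mean()),
                "hc_raw_sd": float(hc[outcome].std(ddof=1)),
                "nihl_adj_mean": res.adjusted_means["NIHL"][0],
                "nihl_adj_se": res.adjusted_means["NIHL"][1],
                "hc_adj_mean": res.adjusted_means["HC"][0],
                "hc_adj_se": res.adjusted_means["HC"][1],
                "beta": res.beta,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "F": res.F,
                "p": res.p,
                "eta_p2": res.eta_p2,
            }
        )
    table2 = pd.DataFrame(rows2)
    rej2, adj2 = bh_fdr(table2.p.to_numpy())
    table2["p_fdr"] = adj2
    table2["significant_fdr"] = rej2

    # --- table 3: paired hemisphere tests --------------------------------
    rows3 = []
    for gname, sub in (("NIHL", nihl), ("HC", hc)):
        t, dof, p = paired_t(sub.alps_left.to_numpy(), sub.alps_right.to_numpy())
        rows3.append(
            {
                "group": gname,
                "left_mean": float(sub.alps_left.mean()),
                "left_sd": float(sub.alps_left.std(ddof=1)),
                "right_mean": float(sub.alps_right.mean()),
                "right_sd": float(sub.alps_right.std(ddof=1)),
                "t": t,
                "df": dof,
                "p": p,
            }
        )
    table3 = pd.DataFrame(rows3)

    # --- table 4: Spearman grid + BH over the whole 15-test family -------
    rows4 = []
    for gname, sub in (("NIHL", nihl), ("HC", hc)):
        clin_vars = ("mtwv", "hama", "fw") if gname == "NIHL" else ("hama", "fw")
        for alps_col in ("alps_mean", "alps_left", "alps_right"):
            for clin in clin_vars:
                res = spearman(sub[alps_col].to_numpy(float), sub[clin].to_numpy(float))
                rows4.append(
                    {
                        "group": gname,
                        "alps": alps_col,
                        "clinical": clin,
                        "r": res.r,
                        "p": res.p,
                        "n": res.n,
                    }
                )
    table4 = pd.DataFrame(rows4)
    rej4, adj4 = bh_fdr(table4.p.to_numpy())
    table4["p_fdr"] = adj4
    table4["significant_fdr"] = rej4

    return StatsReport(
        table1=table1,
        table2=table2,
        table3=table3,
        table4=table4,
        assumptions=assumptions,
        excluded=excluded,
    )
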