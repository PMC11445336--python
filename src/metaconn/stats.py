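"""Cohort and degree statistics.

Covers the statistical toolkit of the study design: Shapiro-Wilk-gated
two-sample comparisons (Welch t or Mann-Whitney U), Welch t from printed
summary statistics, Holm step-down multiple-comparison correction, Spearman
severity correlations (exact for small n), the conditional-MLE odds ratio
with Fisher's exact p, cross-modal connectivity-strength association, and
the per-unit nodal-degree group comparison with its Holm family.

Conventions: t statistics are Welch (unequal variances) by default — the
pooled variant is available by flag; the Mann-Whitney U follows the
first-sample orientation; all tests are two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityResult
from .connectome import DegreeTable

__all__ = [
    "TestResult",
    "HolmFamily",
    "shapiro_gate_compare",
    "t_from_summary",
    "holm_correct",
    "spearman_severity",
    "fisher_or",
    "cross_modal_association",
    "unit_degree_comparison",
]


@dataclass
class TestResult:
    """One test's outcome: statistic, p-value, sample sizes and provenance."""

    statistic_name: str  # "t_welch" | "t_student" | "U" | "rho" | "OR" | ...
    statistic: float
    p: float
    n: tuple[int, ...]
    test_chosen_by: str = ""
    df: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class HolmFamily:
    """Holm step-down adjusted p-values for one family of hypotheses."""

    raw_p: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray
    alpha: float = 0.05


def _is_constant(x: np.ndarray) -> bool:
    return np.ptp(x) == 0


def shapiro_gate_compare(
    x, y, alpha_norm: float = 0.05, welch: bool = True
) -> TestResult:
    """Two-sample comparison gated by Shapiro-Wilk normality.

    If both samples pass Shapiro-Wilk at ``alpha_norm`` the comparison is a
    two-sample t test (Welch by default); otherwise a two-sided tie-corrected
    Mann-Whitney U.  Constant samples are treated as failing normality.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    flags: list[str] = []
    if _is_constant(x) and _is_constant(y) and x[0] == y[0]:
        return TestResult(
            "t_welch" if welch else "t_student",
            0.0,
            1.0,
            (len(x), len(y)),
            test_chosen_by="degenerate: identical constant samples",
            flags=["degenerate"],
        )
    normal = True
    for s in (x, y):
        if _is_constant(s):
            normal = False
            flags.append("constant_sample")
            break
        if sps.shapiro(s).pvalue <= alpha_norm:
            normal = False
            break
    if normal:
        res = sps.ttest_ind(x, y, equal_var=not welch)
        return TestResult(
            "t_welch" if welch else "t_student",
            float(res.statistic),
            float(res.pvalue),
            (len(x), len(y)),
            test_chosen_by=f"shapiro-wilk both p > {alpha_norm}",
            df=float(res.df),
            flags=flags,
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult(
        "U",
        float(res.statistic),
        float(res.pvalue),
        (len(x), len(y)),
        test_chosen_by="shapiro-wilk failed (or constant sample)",
        flags=flags,
    )


def t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, welch: bool = True
) -> TestResult:
    """Two-sample t statistic from summary statistics only.

    Default is the Welch statistic with Welch-Satterthwaite degrees of
    freedom, which reproduces printed cohort-table t values computed on
    unequal-variance samples.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1**2, sd2**2
    if v1 == 0 and v2 == 0:
        raise ValueError("zero pooled variance: t undefined")
    if welch:
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        name = "t_welch"
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        name = "t_student"
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(name, float(t), float(p), (n1, n2), df=float(df))


def holm_correct(raw_p, alpha: float = 0.05) -> HolmFamily:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    raw = np.asarray(raw_p, dtype=float)
    if raw.size == 0:
        return HolmFamily(raw, raw.copy(), np.zeros(0, dtype=bool), alpha)
    if ((raw < 0) | (raw > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(raw, alpha=alpha, method="holm")
    rejected = adj < alpha
    return HolmFamily(raw_p=raw, adjusted_p=adj, rejected=rejected, alpha=alpha)


@lru_cache(maxsize=4)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Null distribution of |rho| over all n! rank permutations (no ties)."""
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(base)), dtype=float)
    d2 = ((perms - base) ** 2).sum(axis=1)
    return np.abs(1.0 - 6.0 * d2 / (n * (n**2 - 1)))


def spearman_severity(values, severity) -> TestResult:
    """Spearman correlation between a subject-level measure and severity.

    Tie-corrected rho; two-sided p is exact (full permutation distribution)
    for n <= 9 with untied data, otherwise the t approximation.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(severity, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and severity must be equal-length vectors")
    if len(x) < 4:
        raise ValueError("spearman needs n >= 4")
    if _is_constant(x) or _is_constant(y):
        raise ValueError("constant input: rho undefined")
    rho, p_approx = sps.spearmanr(x, y)
    n = len(x)
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 9 and no_ties:
        null = _exact_spearman_null(n)
        p = float(np.mean(null >= abs(rho) - 1e-12))
        chosen = "exact permutation (n <= 9, no ties)"
    else:
        p = float(p_approx)
        chosen = "t approximation"
    return TestResult("rho", float(rho), p, (n,), test_chosen_by=chosen)


def _cond_expected_count(logpsi: float, x_support: np.ndarray, logw: np.ndarray) -> float:
    logterms = logw + x_support * logpsi
    logterms -= logterms.max()
    w = np.exp(logterms)
    return float((x_support * w).sum() / w.sum())


def fisher_or(table) -> TestResult:
    """Conditional maximum-likelihood odds ratio + Fisher exact two-sided p.

    The CMLE solves E[X | psi] = x11 under Fisher's noncentral hypergeometric
    model by bisection on log psi (tolerance 1e-10).  Tables where x11 sits
    at the edge of its support give a degenerate estimate (0 or inf, flagged).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 nonnegative integer counts")
    x11 = int(t[0, 0])
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    n = t.sum()
    if min(r1, r2, c1, n - c1) == 0:
        return TestResult(
            "OR", float("nan"), 1.0, tuple(int(v) for v in (r1, r2)), flags=["zero_margin"]
        )
    p = float(sps.fisher_exact(t)[1])
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logw = (
        sps.binom.logpmf(support, r1, 0.5)
        + sps.binom.logpmf(c1 - support, r2, 0.5)
    )  # proportional to log C(r1,x) + log C(r2, c1-x)
    if x11 == lo:
        return TestResult("OR", 0.0, p, (int(r1), int(r2)), flags=["at_support_min"])
    if x11 == hi:
        return TestResult(
            "OR", float("inf"), p, (int(r1), int(r2)), flags=["at_support_max"]
        )
    a, b = -50.0, 50.0
    fa = _cond_expected_count(a, support, logw) - x11
    fb = _cond_expected_count(b, support, logw) - x11
    if fa > 0 or fb < 0:  # pragma: no cover - bracket always valid off-boundary
        raise RuntimeError("CMLE bracket failure")
    while b - a > 1e-10:
        mid = 0.5 * (a + b)
        if _cond_expected_count(mid, support, logw) < x11:
            a = mid
        else:
            b = mid
    return TestResult("OR", float(np.exp(0.5 * (a + b))), p, (int(r1), int(r2)))


def cross_modal_association(
    res1: ConnectivityResult, res2: ConnectivityResult
) -> tuple[float, float, float]:
    """Pearson r and OLS fit between two modalities' edge strengths.

    Vectorizes the upper-triangle Fisher-z values of both results and
    regresses modality 2 on modality 1.  Returns (pearson_r, slope,
    intercept).
    """
    if not np.array_equal(np.asarray(res1.roi_ids), np.asarray(res2.roi_ids)):
        raise ValueError("results must share identical roi_ids")
    iu = np.triu_indices(len(res1.roi_ids), k=1)
    x, y = res1.z[iu], res2.z[iu]
    fit = sps.linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)


def unit_degree_comparison(
    deg_a: DegreeTable,
    deg_b: DegreeTable,
    roi_table: pd.DataFrame,
    alpha: float = 0.05,
    alpha_norm: float = 0.05,
    labels: tuple[str, str] = ("HC", "PD"),
) -> pd.DataFrame:
    """Per-unit group comparison of nodal degree with a Holm family.

    For each functional unit, the member regions' degrees in connectome A
    are compared with those in connectome B using the Shapiro-gated test;
    the Holm family is the set of units tested within this connectome pair.
    Returns a tidy frame (unit, test, statistic, p, p_holm, rejected,
    mean_a, mean_b).
    """
    if deg_a.by != "roi" or deg_b.by != "roi":
        raise ValueError("degree tables must be per region")
    mapping = roi_table.set_index("roi_id")["unit"]
    rows = []
    units = sorted(mapping.loc[deg_a.values.columns].unique())
    for unit in units:
        members = [c for c in deg_a.values.columns if mapping.loc[c] == unit]
        if len(members) < 3:
            continue
        a_vals = deg_a.values[members].to_numpy().ravel()
        b_vals = deg_b.values[members].to_numpy().ravel()
        res = shapiro_gate_compare(a_vals, b_vals, alpha_norm=alpha_norm)
        rows.append(
            {
                "unit": unit,
                "test": res.statistic_name,
                "statistic": res.statistic,
                "p": res.p,
                f"mean_{labels[0]}": float(np.mean(a_vals)),
                f"mean_{labels[1]}": float(np.mean(b_vals)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        fam = holm_correct(out["p"].to_numpy(), alpha=alpha)
        out["p_holm"] = fam.adjusted_p
        out["rejected"] = fam.rejected
    return out
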