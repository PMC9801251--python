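"""Cohort statistics: group comparisons, correlations, and sex-adjusted
regressions linking the imaging metrics to behavior and symptoms.

Conventions: the default two-sample test is Welch's (equal variances
not assumed), with Student's pooled-variance variant also exposed; all
p-values are two-sided by default with a configurable sidedness flag;
no multiple-comparison correction is applied by default but the battery
report always states the number of tests run and can attach
Benjamini-Hochberg adjusted values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError, ValidationError

__all__ = [
    "TestResult",
    "ttest_two_sample",
    "ttest_from_summary",
    "pearson",
    "spearman",
    "regression_adjusting_sex",
    "run_paper_battery",
    "BatteryReport",
]


@dataclass
class TestResult:
    statistic: float
    df: float
    p_two_sided: float
    estimate: float
    method: str
    flags: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def p(self, sided: str = "two") -> float:
        """One-sided p halves the two-sided value in the direction of
        the observed statistic."""
        if sided == "two":
            return self.p_two_sided
        if sided == "one":
            return self.p_two_sided / 2.0
        raise ParameterError(f"sided must be 'two' or 'one', got {sided!r}")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_two_sided": self.p_two_sided,
            "estimate": self.estimate,
            "method": self.method,
            "flags": list(self.flags),
            **{k: v for k, v in self.extras.items()},
        }


def ttest_two_sample(a, b, variant: str = "welch") -> TestResult:
    """Independent-samples t-test (Welch by default)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    flags = []
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        flags.append("zero_variance")
    if variant == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    elif variant == "student":
        res = sps.ttest_ind(a, b, equal_var=True)
        df = float(a.size + b.size - 2)
    else:
        raise ParameterError(f"variant must be 'welch' or 'student', got {variant!r}")
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p_two_sided=float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
        estimate=float(a.mean() - b.mean()),
        method=f"ttest_{variant}",
        flags=flags,
    )


def ttest_from_summary(m1, sd1, n1, m2, sd2, n2, variant: str = "welch") -> TestResult:
    """The same test evaluated from summary statistics (means, SDs, ns)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ParameterError("summary SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs n >= 2")
    equal_var = variant == "student"
    if variant not in ("welch", "student"):
        raise ParameterError(f"variant must be 'welch' or 'student', got {variant!r}")
    res = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_two_sided=float(res.pvalue),
        estimate=float(m1 - m2),
        method=f"ttest_{variant}_summary",
    )


def pearson(x, y) -> TestResult:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ParameterError("Pearson needs paired data with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(r * np.sqrt((x.size - 2) / max(1e-300, 1 - r**2))),
        df=float(x.size - 2),
        p_two_sided=float(p),
        estimate=float(r),
        method="pearson",
    )


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman's rho, no-ties case.

    Enumerates all n! pairings of the ranks; feasible for n <= 10.
    """
    n = rx.size
    count = 0
    total = 0
    chunk = []
    rx_c = rx - rx.mean()
    denom = float((rx_c**2).sum()) * float(((ry - ry.mean()) ** 2).sum())

    def flush(chunk):
        nonlocal count, total
        perm = np.array(chunk)
        ry_perm = ry[perm]
        num = (rx_c[None, :] * (ry_perm - ry_perm.mean(axis=1, keepdims=True))).sum(axis=1)
        rhos = num / np.sqrt(denom)
        count += int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
        total += perm.shape[0]

    for p in itertools.permutations(range(n)):
        chunk.append(p)
        if len(chunk) >= 200_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return count / total


def spearman(x, y, exact_max_n: int = 10) -> TestResult:
    """Spearman rank correlation.

    p-value by exact permutation enumeration for n <= ``exact_max_n``
    (no ties), t-approximation otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ParameterError("Spearman needs paired data with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    rho, p_approx = sps.spearmanr(x, y)
    flags = []
    n = x.size
    has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n <= exact_max_n and not has_ties:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        p = _spearman_exact_p(rx, ry, rho)
        method = "spearman_exact"
    else:
        p = float(p_approx)
        method = "spearman_tapprox"
        if n <= exact_max_n and has_ties:
            flags.append("ties_fell_back_to_tapprox")
    tstat = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
    return TestResult(
        statistic=float(tstat),
        df=float(n - 2),
        p_two_sided=float(min(1.0, p)),
        estimate=float(rho),
        method=method,
        flags=flags,
    )


def regression_adjusting_sex(y, x, sex) -> TestResult:
    """OLS of y on x plus a sex indicator; inference on the x coefficient.

    Returns the x coefficient's t statistic with df = n - 3 and the
    partial correlation of x with y given sex (sign-consistent with t).
    Closed-form OLS in numpy; cross-checked against statsmodels in the
    test suite.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    sex = np.asarray(sex)
    n = y.size
    if x.size != n or sex.size != n or n < 4:
        raise ParameterError("regression needs aligned columns with n >= 4")
    s = pd.factorize(sex)[0].astype(np.float64)
    if np.unique(s).size < 2:
        raise ParameterError("sex indicator must have both levels")
    flags = []
    xc, sc = x - x.mean(), s - s.mean()
    if np.std(xc) == 0 or abs(float(xc @ sc)) >= (1 - 1e-12) * np.linalg.norm(xc) * np.linalg.norm(sc):
        flags.append("x_collinear_with_sex")
    X = np.column_stack([np.ones(n), x, s])
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(f"singular design: {exc}") from exc
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - 3
    s2 = float(resid @ resid) / df
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 1e-300))
    t = float(beta[1] / se[1])
    p = float(2 * sps.t.sf(abs(t), df))
    partial_r = float(t / np.sqrt(t * t + df))
    return TestResult(
        statistic=t,
        df=float(df),
        p_two_sided=p,
        estimate=partial_r,
        method="ols_sex_adjusted",
        flags=flags,
        extras={"coef": float(beta[1]), "coef_se": float(se[1]), "intercept": float(beta[0])},
    )


BATTERY_COLUMNS = [
    "group",
    "sex",
    "vta_volume_norm",
    "vta_intensity_norm",
    "sn_intensity",
    "bias_external_z",
    "bias_internal_z",
    "sigma_external_z",
    "sigma_internal_z",
    "anhedonia_anticipatory",
    "anhedonia_consummatory",
    "anxiety_total",
    "depression",
]

_SYMPTOMS = ["anhedonia_anticipatory", "anhedonia_consummatory", "anxiety_total", "depression"]


@dataclass
class BatteryReport:
    results: dict
    n_tests: int
    alpha: float
    sided: str
    correction: str
    significant: dict
    p_adjusted: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_tests": self.n_tests,
            "alpha": self.alpha,
            "sided": self.sided,
            "correction": self.correction,
            "results": {k: v.to_dict() for k, v in self.results.items()},
            "significant": dict(self.significant),
            "p_adjusted": dict(self.p_adjusted),
        }


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, pvals[i] * m / (rank + 1))
        adj[i] = running
    return adj


def run_paper_battery(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
    sided: str = "two",
    variant: str = "welch",
) -> BatteryReport:
    """Run the full statistical battery on a cohort table.

    Tests, in order: Welch group comparisons of normalized VTA volume,
    normalized VTA intensity, and SN intensity (the specificity
    control); sex-adjusted regressions of normalized VTA intensity on
    each z-scored behavioral parameter; Spearman correlations of VTA
    intensity with each symptom scale across the cohort; the same
    Spearman correlations within the MA group alone.
    """
    missing = [c for c in BATTERY_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table is missing columns: {missing}")
    if cohort["group"].isna().any() or cohort["sex"].isna().any():
        raise ValidationError("group and sex must be non-missing for every record")

    hc = cohort[cohort["group"] == "HC"]
    ma = cohort[cohort["group"] == "MA"]
    results: dict[str, TestResult] = {}

    for col in ("vta_volume_norm", "vta_intensity_norm", "sn_intensity"):
        results[f"group_{col}"] = ttest_two_sample(ma[col], hc[col], variant=variant)

    for bcol in ("bias_external_z", "bias_internal_z", "sigma_external_z", "sigma_internal_z"):
        results[f"intensity_on_{bcol}"] = regression_adjusting_sex(
            cohort["vta_intensity_norm"], cohort[bcol], cohort["sex"]
        )

    for sym in _SYMPTOMS:
        results[f"intensity_vs_{sym}"] = spearman(cohort["vta_intensity_norm"], cohort[sym])
    for sym in _SYMPTOMS:
        results[f"ma_intensity_vs_{sym}"] = spearman(ma["vta_intensity_norm"], ma[sym])

    names = list(results)
    pvals = np.array([results[k].p(sided) for k in names])
    p_adj: dict[str, float] = {}
    if correction == "bh":
        adj = _bh_adjust(pvals)
        p_adj = {k: float(v) for k, v in zip(names, adj)}
        significant = {k: bool(v <= alpha) for k, v in zip(names, adj)}
    elif correction == "none":
        significant = {k: bool(p <= alpha) for k, p in zip(names, pvals)}
    else:
        raise ParameterError(f"correction must be 'none' or 'bh', got {correction!r}")

    return BatteryReport(
        results=results,
        n_tests=len(names),
        alpha=alpha,
        sided=sided,
        correction=correction,
        significant=significant,
        p_adjusted=p_adj,
    )
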