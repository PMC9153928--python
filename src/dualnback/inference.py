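"""The within-subject inferential battery.

Implements the statistical toolkit applied to scored outcomes: one-sample
t tests comparing mean half-block deltas with zero, Pearson correlations
between latencies and the accuracy outcomes, Friedman tests on
within-subject condition ranks, Bonferroni-adjusted pairwise paired-t
post hoc comparisons, repeated-measures ANOVA with Mauchly's sphericity
check and the Greenhouse-Geisser correction, and a random-intercept mixed
model that analyses both modalities simultaneously.

All tests are two-sided at alpha = 0.05; p values between 0.05 and 0.10
are conventionally described as marginal in reports but no decision rule
depends on that band.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "one_sample_t",
    "pearson_test",
    "friedman",
    "bonferroni_pairwise",
    "rm_anova",
    "mixed_model",
    "format_p",
]


@dataclass(frozen=True)
class TestResult:
    """One inferential comparison: statistic, df, p, and its adjustment."""

    statistic: float
    df: Union[float, Tuple[float, float]]
    p_value: float
    effect_label: str = ""
    adjustment: str = "none"  # none | bonferroni | greenhouse_geisser
    extras: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def format_p(p: float, threshold: float = 0.0005) -> str:
    """Render a p value the way the summary tables print it."""
    if np.isnan(p):
        return ""
    if p < threshold:
        return f"<{threshold:g}"
    return f"{p:.3f}"


def one_sample_t(
    mean: Optional[float] = None,
    sd: Optional[float] = None,
    n: Optional[int] = None,
    mu0: float = 0.0,
    values: Optional[Sequence[float]] = None,
    effect_label: str = "",
) -> TestResult:
    """Two-sided one-sample t test, from summary statistics or raw values.

    ``t = (mean - mu0) / (sd / sqrt(n))`` with ``df = n - 1``. A
    degenerate sample (sd = 0) yields p = 0 when the mean differs from
    ``mu0`` and p = 1 otherwise.
    """
    if values is not None:
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        n = arr.size
        if n < 2:
            raise ValueError("need at least 2 observations")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
    if mean is None or sd is None or n is None:
        raise ValueError("provide either raw values or (mean, sd, n)")
    if n < 2:
        raise ValueError("need n >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    df = n - 1
    if sd == 0:
        if mean == mu0:
            return TestResult(0.0, df, 1.0, effect_label)
        t = math.inf if mean > mu0 else -math.inf
        return TestResult(t, df, 0.0, effect_label)
    t = (mean - mu0) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), df, float(min(p, 1.0)), effect_label)


def pearson_test(
    x: Optional[Sequence[float]] = None,
    y: Optional[Sequence[float]] = None,
    r: Optional[float] = None,
    n: Optional[int] = None,
    effect_label: str = "",
) -> TestResult:
    """Pearson product-moment correlation with its two-sided t-based p.

    Accepts raw paired vectors or the summary form (r, n); in either case
    ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` df.
    """
    if x is not None and y is not None:
        xa = np.asarray(x, dtype=float)
        ya = np.asarray(y, dtype=float)
        mask = ~(np.isnan(xa) | np.isnan(ya))
        xa, ya = xa[mask], ya[mask]
        n = xa.size
        if n < 3:
            raise ValueError("need at least 3 complete pairs")
        if xa.std() == 0 or ya.std() == 0:
            raise ValueError("correlation undefined for a constant vector")
        r = float(np.corrcoef(xa, ya)[0, 1])
    if r is None or n is None:
        raise ValueError("provide either raw vectors or (r, n)")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    if abs(r) == 1.0:
        return TestResult(math.copysign(math.inf, r), df, 0.0, effect_label,
                          extras={"r": r})
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), df, float(min(p, 1.0)), effect_label,
                      extras={"r": r})


def friedman(matrix: Union[np.ndarray, pd.DataFrame],
             effect_label: str = "condition") -> TestResult:
    """Friedman chi-square test on a subjects x conditions matrix.

    Values are midranked within each subject's row; the chi-square
    statistic carries the standard tie correction, with df = k - 1.
    Rows containing missing values are excluded listwise with a warning.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("matrix must be subjects x conditions")
    complete = ~np.isnan(arr).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"friedman: excluded {dropped} incomplete row(s) listwise")
        logger.info("friedman: excluded %d incomplete rows", dropped)
    arr = arr[complete]
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 complete subjects and 2 conditions")
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    col_sums = ranks.sum(axis=0)
    chi2 = (12.0 / (n * k * (k + 1))) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction: C = 1 - sum_i sum_groups (t^3 - t) / (n k (k^2 - 1))
    tie_term = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    c = 1.0 - tie_term / (n * k * (k * k - 1))
    if c <= 0:  # every row fully tied: no evidence either way
        return TestResult(0.0, k - 1, 1.0, effect_label, extras={"n": n, "k": k})
    chi2 /= c
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return TestResult(float(chi2), k - 1, p, effect_label, extras={"n": n, "k": k})


def bonferroni_pairwise(
    wide: pd.DataFrame, m: Optional[int] = None
) -> List[TestResult]:
    """Paired-t post hoc comparisons with Bonferroni adjustment.

    ``wide`` is a subjects x levels table; every unordered level pair is
    tested with a paired t on the within-subject differences and
    ``p_adj = min(1, m * p_raw)`` with ``m = k(k-1)/2`` by default.
    """
    levels = list(wide.columns)
    k = len(levels)
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    if m is None:
        m = len(pairs)
    if m < 1:
        raise ValueError("m must be >= 1")
    results = []
    for a, b in pairs:
        diff = (wide[a] - wide[b]).dropna().to_numpy()
        res = one_sample_t(values=diff, effect_label=f"{a} vs {b}")
        results.append(
            TestResult(
                statistic=res.statistic,
                df=res.df,
                p_value=float(min(1.0, m * res.p_value)),
                effect_label=res.effect_label,
                adjustment="bonferroni",
                extras={"p_raw": res.p_value, "m": m},
            )
        )
    return results


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of the
    repeated measures; always in [1/(k-1), 1]."""
    k = wide.shape[1]
    if k < 3:
        return 1.0
    s = np.cov(wide, rowvar=False)
    mean_diag = np.trace(s) / k
    grand = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(s * s) - 2 * k * np.sum(row_means**2) + k * k * grand**2)
    if den <= 0:
        return 1.0
    eps = num / den
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Union[str, List[str]],
    subject: str,
    covariates: Optional[List[str]] = None,
    correction: str = "auto",
) -> List[TestResult]:
    """Repeated-measures ANOVA with sphericity handling.

    The balanced, covariate-free path runs a classical within-subject
    ANOVA; Mauchly's test is reported, and when sphericity is rejected
    (p < 0.05, or always under ``correction='always'``) the F test's
    degrees of freedom are multiplied by the Greenhouse-Geisser epsilon
    estimated from the sample covariance matrix of the repeated measures.

    Unbalanced layouts and covariate adjustment are routed to the
    random-intercept mixed model (with a logged note): between-subject
    covariates are confounded with fixed subject effects in the classical
    sum-of-squares decomposition, so the mixed model is the estimable
    analogue. Covariates are centred before entry.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    complete = data.dropna(subset=[dv])
    n_dropped = len(data) - len(complete)
    if n_dropped:
        logger.info("rm_anova: %d rows with missing %s excluded", n_dropped, dv)

    cell_counts = complete.groupby([subject] + within_list, observed=True)[dv].size()
    balanced = (
        cell_counts.eq(1).all()
        and len(cell_counts)
        == complete[subject].nunique()
        * int(np.prod([complete[c].nunique() for c in within_list]))
    )
    if covariates or not balanced:
        reason = "covariates requested" if covariates else "unbalanced data"
        logger.info("rm_anova: routing to mixed_model (%s)", reason)
        return _rm_via_mixed(complete, dv, within_list, subject, covariates or [])

    if complete[dv].std(ddof=0) == 0:
        k = int(np.prod([complete[c].nunique() for c in within_list]))
        nsub = complete[subject].nunique()
        return [
            TestResult(0.0, (k - 1, (k - 1) * (nsub - 1)), 1.0,
                       effect_label=" * ".join(within_list))
        ]

    aov = pg.rm_anova(
        data=complete, dv=dv, within=within_list, subject=subject,
        correction=True, detailed=True,
    )
    results: List[TestResult] = []
    for _, row in aov.iterrows():
        if str(row["Source"]).lower() in {"error", "residual"}:
            continue
        label = str(row["Source"])
        f_stat = float(row["F"]) if not pd.isna(row["F"]) else np.nan
        df1 = float(row["DF"]) if "DF" in row else float(row["DF1"])
        # find the matching error df
        if "DF" in aov.columns and (aov["Source"].str.lower() == "error").any():
            df2 = float(aov.loc[aov["Source"].str.lower() == "error", "DF"].iloc[0])
        else:
            df2 = float(row.get("DF2", np.nan))
        p_unc = float(row["p_unc"])
        extras: Dict[str, float] = {"p_unc": p_unc}
        adjustment = "none"
        p = p_unc
        df_pair: Tuple[float, float] = (df1, df2)
        if len(within_list) == 1:
            wide = complete.pivot_table(
                index=subject, columns=within_list[0], values=dv, observed=True
            ).to_numpy()
            eps = _gg_epsilon(wide)
            w, p_mauchly = _mauchly(complete, dv, within_list[0], subject)
            extras.update(epsilon=eps, mauchly_W=w, mauchly_p=p_mauchly)
            apply_gg = correction == "always" or (
                correction == "auto" and not np.isnan(p_mauchly) and p_mauchly < 0.05
            )
            if apply_gg and not np.isnan(f_stat):
                df_pair = (df1 * eps, df2 * eps)
                p = float(stats.f.sf(f_stat, *df_pair))
                adjustment = "greenhouse_geisser"
        results.append(
            TestResult(f_stat, df_pair, p, effect_label=label,
                       adjustment=adjustment, extras=extras)
        )
    return results


def _mauchly(
    data: pd.DataFrame, dv: str, within: str, subject: str
) -> Tuple[float, float]:
    try:
        sph = pg.sphericity(data=data, dv=dv, within=within, subject=subject)
        return float(sph.W), float(sph.pval)
    except Exception:  # degenerate covariance
        return np.nan, np.nan


def _rm_via_mixed(
    data: pd.DataFrame,
    dv: str,
    within: List[str],
    subject: str,
    covariates: List[str],
) -> List[TestResult]:
    work = data.copy()
    terms = []
    for w in within:
        terms.append(f"C({w})")
    if len(within) == 2:
        terms.append(f"C({within[0]}):C({within[1]})")
    for cov in covariates:
        if pd.api.types.is_numeric_dtype(work[cov]):
            work[f"{cov}_c"] = work[cov] - work[cov].mean()
            terms.append(f"{cov}_c")
        else:
            terms.append(f"C({cov})")
    formula = f"{dv} ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, work, groups=work[subject])
        res = model.fit(reml=True)
    return _wald_results(res, converged=bool(res.converged))


def _wald_results(res, converged: bool = True) -> List[TestResult]:
    out: List[TestResult] = []
    wt = res.wald_test_terms(scalar=True)
    table = wt.table
    for term, row in table.iterrows():
        if term == "Intercept":
            continue
        out.append(
            TestResult(
                statistic=float(row["statistic"]),
                df=float(row["df_constraint"]),
                p_value=float(min(max(row["pvalue"], 0.0), 1.0)),
                effect_label=str(term),
                extras={"converged": float(converged)},
            )
        )
    return out


def mixed_model(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject_id",
    condition: str = "condition",
    modality: str = "modality",
    covariates: Tuple[str, ...] = ("sex", "age", "volume"),
    condition_ref: str = "silence",
    modality_ref: str = "visuospatial",
) -> List[TestResult]:
    """Random-intercept linear model over both modalities simultaneously.

    Fixed effects: condition, modality, their interaction, and the
    subject covariates (sex, age, volume), with treatment coding against
    the silence and visuospatial references; one random intercept per
    subject. Wald chi-square tests are reported per fixed-effect term. A
    non-converged or singular fit is flagged in ``extras['converged']``
    rather than silently dropped.
    """
    work = data.dropna(subset=[dv]).copy()
    if work.groupby(subject, observed=True).size().min() < 2:
        raise ValueError("need at least 2 observations per subject")
    # factors collapsed to a single level contribute no contrast columns
    has_cond = work[condition].nunique() > 1
    has_mod = work[modality].nunique() > 1
    terms = []
    if has_cond:
        terms.append(f"C({condition}, Treatment('{condition_ref}'))")
    if has_mod:
        terms.append(f"C({modality}, Treatment('{modality_ref}'))")
    if has_cond and has_mod:
        terms.append(
            f"C({condition}, Treatment('{condition_ref}')):"
            f"C({modality}, Treatment('{modality_ref}'))"
        )
    if not terms:
        raise ValueError("need at least one factor with 2 or more levels")
    for cov in covariates:
        if cov not in work.columns:
            continue
        if pd.api.types.is_numeric_dtype(work[cov]):
            work[f"{cov}_c"] = work[cov] - work[cov].mean()
            terms.append(f"{cov}_c")
        else:
            terms.append(f"C({cov})")
    formula = f"{dv} ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, work, groups=work[subject])
        res = model.fit(reml=True)
    return _wald_results(res, converged=bool(res.converged))
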