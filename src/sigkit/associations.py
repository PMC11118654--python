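"""Exposure estimation and association models.

Individual air-pollution exposure is the mean of annual region-level
PM2.5 from the diagnosis year back to 1998 (the earliest year with data),
dichotomized at 20 ug/m3.  Signature presence/absence and driver-gene
indicators are modeled by multivariable logistic regression (odds ratios
per 10 ug/m3 for continuous PM2.5); mutation burdens (log10) and
tumor/normal telomere-length ratios (log2) by ordinary least squares,
reported as percent change per unit exposure.  Families of tests are
corrected by Benjamini-Hochberg FDR; categorical enrichments use
two-sided Fisher exact tests and group comparisons Wilcoxon rank-sum.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "ancestry", "histology", "purity")
PM25_OR_UNIT = 10.0  # ug/m3 per reported odds ratio


@dataclass
class ExposureSeries:
    """Annual region-level PM2.5 (ug/m3), 1998-2021 by convention."""

    values: pd.DataFrame  # columns: region, year, pm25

    def __post_init__(self):
        need = {"region", "year", "pm25"}
        if not need.issubset(self.values.columns):
            raise ValueError(f"exposure series needs columns {sorted(need)}")
        if (self.values["pm25"] < 0).any():
            raise ValueError("PM2.5 values must be >= 0")
        self._by_region = {
            r: g.set_index("year")["pm25"].sort_index()
            for r, g in self.values.groupby("region")
        }

    @property
    def first_year(self) -> int:
        return int(self.values["year"].min())

    @property
    def last_year(self) -> int:
        return int(self.values["year"].max())

    def region_series(self, region) -> pd.Series:
        return self._by_region[region]


@dataclass
class ModelResult:
    """One fitted association term."""

    term: str
    estimate: float  # coefficient (log-odds or slope on the log outcome)
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    fdr: float | None = None
    n: int = 0
    flags: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)


def pm25_estimate(subject, series: ExposureSeries) -> float:
    """Mean annual PM2.5 from the diagnosis year back to the series start.

    Subjects diagnosed before the series (or with unknown diagnosis year)
    receive the earliest year's value; an unknown region gives NaN, which
    excludes the subject from pollution models.  Diagnosis years beyond
    series coverage are truncated to covered years with a warning.
    """
    region = getattr(subject, "region", None) if not isinstance(subject, dict) else subject.get("region")
    diag = getattr(subject, "diagnosis_year", None) if not isinstance(subject, dict) else subject.get("diagnosis_year")
    if region is None or (isinstance(region, float) and np.isnan(region)):
        return float("nan")
    annual = series.region_series(region)
    first = int(annual.index.min())
    last = int(annual.index.max())
    if diag is None or (isinstance(diag, float) and np.isnan(diag)) or diag < first:
        return float(annual.loc[first])
    diag = int(diag)
    if diag > last:
        warnings.warn(
            f"diagnosis year {diag} beyond series coverage; truncating to {last}",
            stacklevel=2,
        )
        diag = last
    return float(annual.loc[first:diag].mean())


def dichotomize_pm25(estimate: float, threshold: float = 20.0) -> str | None:
    """'high' when the estimate is >= threshold (boundary inclusive), else 'low'."""
    if estimate is None or np.isnan(estimate):
        return None
    return "high" if estimate >= threshold else "low"


def signature_presence(
    activities: pd.DataFrame, min_samples: int = 2
) -> tuple[pd.DataFrame, list[str]]:
    """Dichotomize activities (signatures x samples) into presence calls.

    Default presence is any positive activity; for signatures active in
    more than half the cohort, presence means exceeding the cohort median
    of assigned mutations.  Signatures active in fewer than
    ``min_samples`` samples are excluded and listed.
    """
    active = activities > 0
    prevalence = active.mean(axis=1)
    presence = active.copy()
    for sig in activities.index[prevalence > 0.5]:
        median = activities.loc[sig].median()
        presence.loc[sig] = activities.loc[sig] > median
    excluded = list(activities.index[active.sum(axis=1) < min_samples])
    presence = presence.drop(index=excluded)
    return presence, excluded


def _design_matrix(exposure: pd.Series, covariates: pd.DataFrame | None) -> pd.DataFrame:
    parts = [pd.Series(np.asarray(exposure, dtype=float), index=exposure.index, name="exposure")]
    if covariates is not None and covariates.shape[1] > 0:
        numeric = covariates.select_dtypes(include=[np.number])
        categorical = covariates.drop(columns=numeric.columns)
        if categorical.shape[1]:
            dummies = pd.get_dummies(
                categorical.astype("category"), drop_first=True, dtype=float
            )
            parts.append(dummies)
        if numeric.shape[1]:
            parts.append(numeric.astype(float))
    X = pd.concat(parts, axis=1)
    return sm.add_constant(X, has_constant="add")


#: recognised positive levels of binary exposures (the reported effect is
#: for this level vs the other)
_POSITIVE_LEVELS = ("high", "exposed", "yes", "true", "1")


def _encode_exposure(exposure: pd.Series) -> pd.Series:
    if exposure.dtype == object or isinstance(exposure.dtype, pd.CategoricalDtype):
        levels = sorted(exposure.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"categorical exposure must have 2 levels, got {levels}")
        positive = [lv for lv in levels if str(lv).lower() in _POSITIVE_LEVELS]
        ref = positive[0] if positive else levels[1]  # fallback: later level
        return exposure.map(lambda v: np.nan if pd.isna(v) else float(v == ref))
    return exposure.astype(float)


def fit_logistic_model(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    or_per_unit: float | None = None,
    term: str = "exposure",
) -> ModelResult:
    """Multivariable logistic regression of a binary outcome on an exposure.

    For a continuous exposure, ``or_per_unit`` (e.g. 10 for PM2.5)
    rescales the reported odds ratio to that many exposure units.
    Complete separation or non-convergence triggers a flagged L2-penalized
    refit rather than a silent failure.
    """
    df = pd.concat([outcome.rename("y"), _encode_exposure(exposure).rename("x")], axis=1)
    if covariates is not None:
        df = pd.concat([df, covariates], axis=1)
    df = df.dropna()
    y = df["y"].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome must include both classes")
    if df["x"].nunique() < 2:
        raise ValueError("exposure is constant across samples")
    X = _design_matrix(df["x"].rename("exposure"), df.drop(columns=["y", "x"]) if covariates is not None else None)

    flags: tuple[str, ...] = ()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True) or not np.isfinite(fit.bse["exposure"]):
            raise PerfectSeparationError("non-finite standard errors")
        beta, se = fit.params["exposure"], fit.bse["exposure"]
        p = fit.pvalues["exposure"]
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        flags = ("separation_penalized",)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        beta, se, p = fit.params["exposure"], float("nan"), float("nan")

    z = scipy.stats.norm.ppf(0.975)
    lo, hi = beta - z * se, beta + z * se
    scale = or_per_unit if or_per_unit is not None else 1.0
    return ModelResult(
        term=term,
        estimate=beta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n=len(df),
        flags=flags,
        extra={
            "odds_ratio": float(np.exp(scale * beta)),
            "or_ci": (float(np.exp(scale * lo)), float(np.exp(scale * hi))),
            "or_units": scale,
        },
    )


def fit_linear_model(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    log_base: float = 10.0,
    term: str = "exposure",
) -> ModelResult:
    """OLS of a log-transformed positive outcome on an exposure.

    ``log_base`` 10 suits mutation burdens, 2 telomere-length ratios.
    The slope is reported also as percent change per exposure unit,
    ``base**beta - 1``, with the CI transformed the same way.
    Non-positive outcomes are excluded (logged).
    """
    positive = outcome > 0
    dropped = int((~positive & outcome.notna()).sum())
    if dropped:
        logger.info("fit_linear_model: excluded %d non-positive outcomes", dropped)
    df = pd.concat(
        [outcome.where(positive).rename("y"), _encode_exposure(exposure).rename("x")], axis=1
    )
    if covariates is not None:
        df = pd.concat([df, covariates], axis=1)
    df = df.dropna()
    if df["x"].nunique() < 2:
        raise ValueError("exposure is constant across samples")
    y = np.log(df["y"].astype(float)) / np.log(log_base)
    X = _design_matrix(df["x"].rename("exposure"), df.drop(columns=["y", "x"]) if covariates is not None else None)
    fit = sm.OLS(y, X).fit()
    beta, se, p = fit.params["exposure"], fit.bse["exposure"], fit.pvalues["exposure"]
    tcrit = scipy.stats.t.ppf(0.975, fit.df_resid)
    lo, hi = beta - tcrit * se, beta + tcrit * se
    return ModelResult(
        term=term,
        estimate=beta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n=len(df),
        extra={
            "percent_change_per_unit": float(log_base**beta - 1.0),
            "percent_change_ci": (float(log_base**lo - 1.0), float(log_base**hi - 1.0)),
            "log_base": log_base,
            "excluded_nonpositive": dropped,
        },
    )


def drivers_enrichment(
    driver_genes: pd.DataFrame,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    min_prevalence: float = 0.02,
    or_per_unit: float | None = None,
) -> list[ModelResult]:
    """Logistic exposure models for each driver gene above the prevalence floor.

    ``driver_genes`` is samples x genes boolean.  Genes mutated in more
    than ``min_prevalence`` of cases are fit jointly and BH-corrected as
    one family.
    """
    prevalence = driver_genes.mean(axis=0)
    keep = prevalence[prevalence > min_prevalence].index
    results = []
    for gene in keep:
        try:
            res = fit_logistic_model(
                driver_genes[gene].astype(float),
                exposure,
                covariates,
                or_per_unit=or_per_unit,
                term=gene,
            )
        except ValueError as exc:
            logger.warning("skipping %s: %s", gene, exc)
            continue
        results.append(res)
    ps = [r.p_value for r in results]
    if ps and np.isfinite(ps).all():
        adj = bh_fdr(ps)
        for r, q in zip(results, adj):
            r.fdr = float(q)
    return results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one analysis family)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cooccurrence_test(a_present, b_present) -> ModelResult:
    """Two-sided Fisher exact test of a 2x2 presence table.

    Reports the sample odds ratio (Haldane 0.5 correction, flagged, when a
    cell is zero); an empty margin leaves the odds ratio undefined.
    """
    a = np.asarray(a_present, dtype=bool)
    b = np.asarray(b_present, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("presence vectors must align")
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    table = [[n11, n10], [n01, n00]]
    _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    flags: tuple[str, ...] = ()
    if min(n11 + n10, n01 + n00, n11 + n01, n10 + n00) == 0:
        odds = float("nan")
        flags = ("empty_margin",)
    elif 0 in (n11, n10, n01, n00):
        if n10 == 0 and n01 == 0:
            odds = float("inf")
            flags = ("infinite_or",)
        else:
            odds = ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))
            flags = ("haldane_corrected",)
    else:
        odds = (n11 * n00) / (n10 * n01)
    return ModelResult(
        term="cooccurrence",
        estimate=odds,
        se=float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        p_value=float(p),
        n=a.size,
        flags=flags,
        extra={"table": table},
    )


_EXACT_MAX_N = 10


def group_difference_test(x, y) -> ModelResult:
    """Two-sided Wilcoxon rank-sum comparison of two numeric samples.

    Exact enumeration of all rank assignments (midranks, so ties are
    handled) for combined n <= 10; tie-corrected normal approximation
    otherwise.  Identical samples give p = 1 with a tie flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    flags: tuple[str, ...] = ()
    if np.all(pooled == pooled[0]):
        return ModelResult(
            term="rank_sum", estimate=float("nan"), se=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), p_value=1.0,
            n=pooled.size, flags=("all_tied",),
        )
    n, m = x.size, y.size
    if n + m <= _EXACT_MAX_N:
        ranks = scipy.stats.rankdata(pooled)
        w_obs = ranks[:n].sum()
        mean_w = n * (n + m + 1) / 2.0
        count = 0
        total = 0
        for comb in itertools.combinations(range(n + m), n):
            w = ranks[list(comb)].sum()
            total += 1
            if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
                count += 1
        p = count / total
        stat = w_obs
        flags = ("exact",)
    else:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
        flags = ("asymptotic",)
    return ModelResult(
        term="rank_sum", estimate=float(stat), se=float("nan"),
        ci_low=float("nan"), ci_high=float("nan"), p_value=float(p),
        n=pooled.size, flags=flags,
    )
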