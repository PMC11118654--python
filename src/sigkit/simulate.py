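"""Seeded synthetic cohorts with the statistical structure the analyses assume.

The generator emulates, at catalog level, a never-smoker lung-cancer
cohort: per-sample signature activities are log-normal around
signature-specific baselines, optionally log-linearly modulated by a
region-level PM2.5 exposure; a small hypermutator tail multiplies all
activities; passive smoking scales the total burden without touching the
signature mix; telomere log2 ratios decline linearly with PM2.5; driver
genes follow per-gene logistic models on exposure.  Catalogs are integer
multinomial draws from the activity-weighted mixture of panel profiles,
so sampling noise is separate from biological intensity.  Every quantity
planted is emitted in a truth manifest for recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assignment import ReferenceSignatureSet
from .associations import ExposureSeries, pm25_estimate
from .contexts import CatalogMatrix
from .schemas import SBS96, ContextSchema, get_schema

_EPS = np.finfo(np.float64).eps


def make_signature_panel(
    n_signatures: int,
    schema: ContextSchema = SBS96,
    min_pairwise_cosine_separation: float = 0.4,
    rng: np.random.Generator | None = None,
    names: list[str] | None = None,
    sparsity: float = 0.25,
    max_tries: int = 200,
) -> ReferenceSignatureSet:
    """Random sparse signature profiles with bounded pairwise similarity.

    Profiles are Dirichlet draws restricted to a random subset of
    categories; the panel is resampled until all pairwise cosines are at
    most 1 - separation.
    """
    if n_signatures < 1:
        raise ValueError("need at least one signature")
    rng = rng or np.random.default_rng()
    m = len(schema)
    k_active = max(3, int(round(sparsity * m)))
    names = names or [f"SIG{i + 1}" for i in range(n_signatures)]
    max_cos = 1.0 - min_pairwise_cosine_separation
    for _ in range(max_tries):
        P = np.zeros((m, n_signatures))
        for j in range(n_signatures):
            active = rng.choice(m, size=k_active, replace=False)
            P[active, j] = rng.dirichlet(np.full(k_active, 0.5))
        Pn = P / np.maximum(np.linalg.norm(P, axis=0), _EPS)
        G = Pn.T @ Pn
        np.fill_diagonal(G, 0.0)
        if n_signatures == 1 or G.max() <= max_cos:
            profiles = pd.DataFrame(P, index=list(schema.categories), columns=names)
            return ReferenceSignatureSet(schema, profiles)
    raise RuntimeError(
        f"could not reach pairwise separation {min_pairwise_cosine_separation} "
        f"in {max_tries} tries"
    )


@dataclass
class SimulationScenario:
    """All planted parameters of one synthetic cohort.

    Defaults approximate a large never-smoker lung-cancer cohort: median
    substitution burden of a few thousand mutations spread over a handful
    of signatures, a small hypermutator tail, ~28 recruitment regions
    spanning low to high PM2.5, and covariates matching the published
    cohort mix (79% female, mostly adenocarcinoma, mean age 64).
    """

    n_samples: int = 800
    n_signatures: int = 6
    schema_name: str = "sbs96"
    signature_names: list[str] | None = None
    separation: float = 0.4
    #: natural-log mean/sd of per-signature baseline activity
    baseline_log_activity: dict[str, tuple[float, float]] | None = None
    default_log_mean: float = float(np.log(800.0))
    default_log_sd: float = 0.5
    hypermutator_fraction: float = 0.03
    hypermutator_multiplier: float = 8.0
    #: per-signature natural-log slope per ug/m3 of PM2.5
    pm25_log_slopes: dict[str, float] = field(default_factory=dict)
    n_regions: int = 28
    pm25_region_range: tuple[float, float] = (5.0, 40.0)
    pm25_annual_sd: float = 1.0
    passive_smoking_prevalence: float = 0.55
    passive_smoking_burden_multiplier: float = 1.083
    telomere_baseline_log2: float = 0.0
    telomere_pm25_slope: float = -0.005  # log2 units per ug/m3
    telomere_noise_sd: float = 0.3
    #: gene -> (baseline prevalence, natural-log OR per ug/m3 PM2.5)
    driver_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "EGFR": (0.52, 0.0),
            "TP53": (0.30, float(np.log(1.6) / 10.0)),
            "KRAS": (0.065, 0.0),
            "CTNNB1": (0.05, float(-np.log(2.5) / 10.0)),
        }
    )
    female_fraction: float = 0.79
    age_mean: float = 64.1
    age_sd: float = 10.0
    histology_probs: dict[str, float] = field(
        default_factory=lambda: {
            "adenocarcinoma": 0.846,
            "carcinoid": 0.070,
            "squamous": 0.036,
            "other": 0.048,
        }
    )
    diagnosis_years: tuple[int, int] = (2005, 2018)
    msi_outlier: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.hypermutator_fraction <= 1):
            raise ValueError("hypermutator_fraction must lie in [0, 1]")
        if not (0 <= self.passive_smoking_prevalence <= 1):
            raise ValueError("passive_smoking_prevalence must lie in [0, 1]")
        for sd in (self.default_log_sd, self.telomere_noise_sd, self.pm25_annual_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")

    # -- presets ------------------------------------------------------------

    @classmethod
    def null(cls, **kw) -> "SimulationScenario":
        """No exposure effects anywhere."""
        return cls(**kw)

    @classmethod
    def pollution(cls, **kw) -> "SimulationScenario":
        """Log-linear PM2.5 effects on selected signatures and telomeres.

        Slopes follow the dose-response magnitudes this generator
        emulates: +12%, +2.3% and +6% mutations per ug/m3 for a
        tobacco-like, a clock-like and an indel signature respectively.
        """
        kw.setdefault("signature_names", ["SBS4", "SBS5", "SBS40a", "SBS2", "SBS13", "ID3"])
        kw.setdefault(
            "pm25_log_slopes",
            {"SBS4": float(np.log(1.12)), "SBS5": float(np.log(1.023)), "ID3": float(np.log(1.06))},
        )
        return cls(**kw)

    @classmethod
    def passive_smoking(cls, **kw) -> "SimulationScenario":
        """Burden-only passive-smoking effect (multiplier 1.083), no signature shift."""
        return cls(**kw)

    @classmethod
    def msi(cls, **kw) -> "SimulationScenario":
        """One hypermutated indel-heavy outlier to exercise the MSI rescue."""
        kw.setdefault("msi_outlier", True)
        return cls(**kw)

    @classmethod
    def preset(cls, name: str, **kw) -> "SimulationScenario":
        table = {
            "null": cls.null,
            "pollution": cls.pollution,
            "passive-smoking": cls.passive_smoking,
            "msi": cls.msi,
        }
        try:
            return table[name](**kw)
        except KeyError:
            raise KeyError(f"unknown preset {name!r}; expected one of {sorted(table)}") from None

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        preset = raw.pop("preset", None)
        for key in ("baseline_log_activity", "driver_model"):
            if key in raw and raw[key] is not None:
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        for key in ("pm25_region_range", "diagnosis_years"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if preset:
            return cls.preset(preset, **raw)
        return cls(**raw)


@dataclass
class SimulatedCohort:
    subjects: pd.DataFrame
    activities: pd.DataFrame  # signatures x samples (true, continuous)
    catalog: CatalogMatrix
    panel: ReferenceSignatureSet
    exposure_series: ExposureSeries
    truth: dict


def simulate_cohort(scenario: SimulationScenario) -> SimulatedCohort:
    """Draw one synthetic cohort; all randomness flows from ``scenario.seed``.

    Stream-splitting: each consumer (panel, regions, covariates,
    activities, catalog, telomere, drivers) gets its own child generator
    spawned from the root seed, so adding draws to one stage does not
    shift another.
    """
    root = np.random.SeedSequence(scenario.seed)
    streams = root.spawn(8)
    rng_panel, rng_region, rng_cov, rng_act, rng_cat, rng_tel, rng_drv, rng_ps = (
        np.random.default_rng(s) for s in streams
    )

    schema = get_schema(scenario.schema_name)
    panel = make_signature_panel(
        scenario.n_signatures,
        schema,
        scenario.separation,
        rng_panel,
        names=scenario.signature_names,
    )
    sigs = panel.names
    n = scenario.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]

    # regions and their annual PM2.5 series (1998-2021)
    years = np.arange(1998, 2022)
    lo, hi = scenario.pm25_region_range
    region_means = np.linspace(lo, hi, scenario.n_regions)
    rows = []
    for r, mu in enumerate(region_means):
        annual = np.clip(mu + rng_region.normal(0, scenario.pm25_annual_sd, len(years)), 0.1, None)
        for yr, v in zip(years, annual):
            rows.append((f"R{r + 1:02d}", int(yr), float(v)))
    series = ExposureSeries(pd.DataFrame(rows, columns=["region", "year", "pm25"]))

    # covariates
    region_ids = rng_cov.integers(0, scenario.n_regions, n)
    regions = [f"R{r + 1:02d}" for r in region_ids]
    # East-Asian-like ancestry more common toward high-PM regions — a graded
    # trend, so the covariate adjustment sees confounding without the
    # ancestry label becoming collinear with the exposure
    grade = region_ids / max(scenario.n_regions - 1, 1)
    p_eas = 0.25 + 0.4 * grade
    u = rng_cov.random(n)
    ancestry = np.where(u < p_eas, "EAS", np.where(u < p_eas + 0.6, "EUR", "Other"))
    age = np.clip(rng_cov.normal(scenario.age_mean, scenario.age_sd, n), 21, 92)
    sex = np.where(rng_cov.random(n) < scenario.female_fraction, "female", "male")
    hist_names = list(scenario.histology_probs)
    hist_p = np.array(list(scenario.histology_probs.values()), dtype=float)
    histology = rng_cov.choice(hist_names, size=n, p=hist_p / hist_p.sum())
    purity = np.clip(rng_cov.beta(5.0, 2.0, n), 0.1, 1.0)
    diagnosis_year = rng_cov.integers(
        scenario.diagnosis_years[0], scenario.diagnosis_years[1] + 1, n
    )
    passive = rng_ps.random(n) < scenario.passive_smoking_prevalence

    subjects = pd.DataFrame(
        {
            "sample_id": samples,
            "age": age,
            "sex": sex,
            "ancestry": ancestry,
            "histology": histology,
            "purity": purity,
            "region": regions,
            "diagnosis_year": diagnosis_year,
            "passive_smoking": np.where(passive, "exposed", "unexposed"),
        }
    ).set_index("sample_id")
    subjects["pm25"] = [
        pm25_estimate(row, series) for row in subjects.itertuples()
    ]
    pm25 = subjects["pm25"].to_numpy()

    # activities: lognormal baseline, PM2.5 log-linear shifts, hypermutators,
    # passive-smoking burden-only multiplier
    log_params = {
        s: (scenario.baseline_log_activity or {}).get(
            s, (scenario.default_log_mean, scenario.default_log_sd)
        )
        for s in sigs
    }
    A = np.zeros((len(sigs), n))
    for i, s in enumerate(sigs):
        mu, sd = log_params[s]
        slope = scenario.pm25_log_slopes.get(s, 0.0)
        A[i] = np.exp(rng_act.normal(mu + slope * pm25, sd))
    hyper = rng_act.random(n) < scenario.hypermutator_fraction
    A[:, hyper] *= scenario.hypermutator_multiplier
    A[:, passive] *= scenario.passive_smoking_burden_multiplier

    # catalogs: multinomial draws from the activity-weighted profile mixture
    P = panel.profiles.to_numpy()
    counts = np.zeros((P.shape[0], n), dtype=np.int64)
    for j in range(n):
        total = int(round(A[:, j].sum()))
        mix = P @ (A[:, j] / A[:, j].sum())
        counts[:, j] = rng_cat.multinomial(total, mix / mix.sum())
    catalog = CatalogMatrix(
        schema, pd.DataFrame(counts, index=list(schema.categories), columns=samples)
    )
    activities = pd.DataFrame(A, index=sigs, columns=samples)

    # telomere ratio (log2) and drivers
    subjects["telomere_ratio"] = np.exp2(
        scenario.telomere_baseline_log2
        + scenario.telomere_pm25_slope * pm25
        + rng_tel.normal(0, scenario.telomere_noise_sd, n)
    )
    for gene, (prev, beta) in scenario.driver_model.items():
        base_logit = np.log(prev / (1 - prev))
        centered = pm25 - pm25.mean()
        prob = 1.0 / (1.0 + np.exp(-(base_logit + beta * centered)))
        subjects[f"driver_{gene}"] = rng_drv.random(n) < prob

    if scenario.msi_outlier and n > 0:
        # force one indel-hypermutated sample (the rescue-rule exerciser)
        outlier = samples[-1]
        subjects.loc[outlier, "msi_flag"] = True
        subjects["msi_flag"] = subjects.get("msi_flag", pd.Series(False, index=subjects.index)).fillna(False)
    else:
        subjects["msi_flag"] = False

    subjects["total_burden"] = catalog.counts.sum(axis=0)

    truth = {
        "scenario": _scenario_dict(scenario),
        "signatures": sigs,
        "pm25_log_slopes": {s: scenario.pm25_log_slopes.get(s, 0.0) for s in sigs},
        "telomere_pm25_slope": scenario.telomere_pm25_slope,
        "passive_smoking_burden_multiplier": scenario.passive_smoking_burden_multiplier,
        "driver_model": {g: list(v) for g, v in scenario.driver_model.items()},
        "hypermutators": [s for s, h in zip(samples, hyper) if h],
        "baseline_log_activity": {s: list(log_params[s]) for s in sigs},
        "seed": scenario.seed,
    }
    return SimulatedCohort(subjects, activities, catalog, panel, series, truth)


def _scenario_dict(scenario: SimulationScenario) -> dict:
    d = dataclasses.asdict(scenario)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def write_fixture_bundle(cohort: SimulatedCohort, directory) -> dict[str, Path]:
    """Write a cohort as plain-text files that round-trip through the readers."""
    from . import io as sio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": directory / "catalog.tsv",
        "cohort": directory / "cohort.tsv",
        "exposure": directory / "exposure_series.tsv",
        "panel": directory / "panel.tsv",
        "activities": directory / "true_activities.tsv",
        "truth": directory / "truth.json",
    }
    sio.write_catalog_tsv(cohort.catalog, paths["catalog"])
    cohort.subjects.to_csv(paths["cohort"], sep="\t")
    cohort.exposure_series.values.to_csv(paths["exposure"], sep="\t", index=False)
    sio.write_signatures_tsv(cohort.panel.profiles, paths["panel"])
    sio.write_activities_tsv(cohort.activities, paths["activities"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2, default=str)
    return paths
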