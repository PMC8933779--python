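"""Synthetic cohorts with a latent-factor structure and planted impairments.

The generator emulates the statistical structure the analysis pipeline
assumes: each patient has one latent severity per cognitive domain; a
domain planted as *affected* (Bernoulli, per-domain prevalence) has its
latent severity displaced by ``severity_shift / 10`` standard deviations;
each battery score is a noisy indicator of its domain factor,

    T = 50 + 10 * loading * factor - severity_shift * affected + residual,

so an unaffected score is marginally ~ N(50, 10) when the residual keeps
the factor-model variance identity (the default), and every score of an
affected domain is displaced by the full ``severity_shift`` in T units (a
deficit of that size in each measured ability); loadings shape the
correlation structure, not the planted effect size. Clinical covariates are
drawn to match the cohort the pipeline targets: ~52% hospitalized,
hospitalized patients ~9 years older, ~187 days from diagnosis to
assessment, log-normal biomarkers uncorrelated with severity by default.

Ground truth (planted affected domains and latent severities) is returned
alongside the emitted tables, so classification operators can be scored
for sensitivity/specificity against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import battery as bat
from .exceptions import ConfigError

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "default_loading_pattern",
    "default_prevalence",
    "simulate_cohort",
    "recovery_experiment",
]

#: per-domain planted-impairment prevalence; chosen so the implied
#: unconditional profile mix is roughly 9% none / 30% single / 60% multi
#: (attention most prevalent, executive functioning second).
DEFAULT_PREVALENCE = {
    "Attention": 0.60,
    "EF": 0.43,
    "L+LTM": 0.30,
    "Language": 0.15,
    "ST/WM": 0.15,
    "VVA": 0.10,
    "ProcessingSpeed": 0.10,
}

#: scores with a reduced denominator in the reference cohort (n = 61 of 63)
DEFAULT_MISSING = {
    "TMT-B": 2.0 / 63.0,
    "Stroop - Color": 2.0 / 63.0,
    "Stroop - Inhibition": 2.0 / 63.0,
}

#: biomarker name -> (median, sigma of log) for log-normal draws
BIOMARKER_PARAMS = {
    "CRP": (5.0, 1.0),
    "AST": (25.0, 0.4),
    "ALT": (25.0, 0.5),
    "LDH": (220.0, 0.3),
    "CK": (90.0, 0.6),
    "Hg": (13.8, 0.1),
    "platelets": (250.0, 0.25),
    "leukocytes": (6.5, 0.3),
    "lymphocytes": (1.8, 0.35),
    "D_dimer": (500.0, 0.8),
    "ferritin": (150.0, 0.9),
    "IL6": (5.0, 1.0),
}


def default_loading_pattern() -> pd.DataFrame:
    """Scores x domains loading pattern for the reference battery.

    Each score loads on its own domain only, at its published rotated
    loading where one was printed and 0.6 otherwise."""
    L = pd.DataFrame(0.0, index=list(bat.SCORE_IDS), columns=list(bat.DOMAINS))
    for sid, _tid, domain, _prov in bat.BATTERY:
        L.loc[sid, domain] = bat.PUBLISHED_LOADINGS.get(sid, bat.DEFAULT_UNPRINTED_LOADING)
    return L


def default_prevalence() -> dict[str, float]:
    return dict(DEFAULT_PREVALENCE)


@dataclass(frozen=True)
class CovariateModel:
    """Effect-size configuration for the covariate generator."""

    hospitalized_rate: float = 0.524
    icu_rate_in_hospitalized: float = 15.0 / 33.0
    age_hospitalized: tuple[float, float] = (55.9, 11.9)
    age_non_hospitalized: tuple[float, float] = (46.7, 11.8)
    education: tuple[float, float] = (14.4, 3.1)
    days_since_diagnosis: tuple[float, float] = (187.0, 99.0)
    moca_hospitalized: tuple[float, float] = (15.8, 3.8)
    moca_non_hospitalized: tuple[float, float] = (17.8, 2.5)
    hads: tuple[float, float] = (8.0, 4.0)
    biomarkers: dict = field(default_factory=lambda: dict(BIOMARKER_PARAMS))
    #: covariate name -> coefficient linking the patient's mean latent
    #: severity to the covariate (added on the log scale for biomarkers);
    #: empty by default — associations mostly null in the target cohort.
    severity_links: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort.

    severity_shift is in T units: 20 means an affected domain's factor is
    displaced by 2 population SDs. residual_sd ``None`` keeps the
    factor-model identity sd = 10 * sqrt(1 - loading^2) per score so the
    marginal SD of unaffected scores is exactly 10; a number fixes a
    uniform residual SD in T units instead.
    """

    n_patients: int = 63
    loading_pattern: pd.DataFrame = field(default_factory=default_loading_pattern)
    impairment_prevalence: dict = field(default_factory=default_prevalence)
    severity_shift: float = 20.0
    residual_sd: float | None = None
    missing_rate: dict = field(default_factory=lambda: dict(DEFAULT_MISSING))
    covariate_model: CovariateModel = field(default_factory=CovariateModel)

    def validate(self) -> None:
        bad = []
        if not self.n_patients >= 1:
            bad.append(f"n_patients must be >= 1 (got {self.n_patients})")
        if self.severity_shift < 0:
            bad.append(f"severity_shift must be >= 0 (got {self.severity_shift})")
        if self.residual_sd is not None and not self.residual_sd > 0:
            bad.append(f"residual_sd must be > 0 (got {self.residual_sd})")
        for d, p in self.impairment_prevalence.items():
            if not 0.0 <= p <= 1.0:
                bad.append(f"impairment_prevalence[{d!r}] must be in [0, 1] (got {p})")
            if d not in self.loading_pattern.columns:
                bad.append(f"impairment_prevalence names unknown domain {d!r}")
        for s, r in self.missing_rate.items():
            if not 0.0 <= r < 1.0:
                bad.append(f"missing_rate[{s!r}] must be in [0, 1) (got {r})")
        L = self.loading_pattern
        if not np.all(np.isfinite(L.to_numpy())):
            bad.append("loading_pattern contains non-finite values")
        if bad:
            raise ConfigError("; ".join(bad))


@dataclass(frozen=True)
class SyntheticCohort:
    """Emitted tables plus generating ground truth."""

    scores: pd.DataFrame      # patients x scores, T metric, NaN = missing
    covariates: pd.DataFrame  # one row per patient
    truth: pd.DataFrame       # planted affected flags + latent severities
    config: SimConfig

    def to_long(self) -> pd.DataFrame:
        """Long cohort table (value_type 't') accepted by score_cohort."""
        builtin = {sid: tid for sid, tid, _, _ in bat.BATTERY}
        long = (
            self.scores.reset_index()
            .melt(id_vars="patient_id", var_name="score_id", value_name="value")
            .dropna(subset=["value"])
        )
        long["test_id"] = long["score_id"].map(lambda s: builtin.get(s, s))
        long["value_type"] = "t"
        return long[["patient_id", "test_id", "score_id", "value", "value_type"]]


def simulate_cohort(config: SimConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Draw one cohort under ``config`` (fully determined by ``seed``)."""
    if config is None:
        config = SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_patients
    L = config.loading_pattern
    domains = list(L.columns)
    scores = list(L.index)
    pids = [f"P{i + 1:04d}" for i in range(n)]

    prev = np.array([config.impairment_prevalence.get(d, 0.0) for d in domains])
    affected = rng.random((n, len(domains))) < prev
    factors0 = rng.standard_normal((n, len(domains)))
    factors = factors0 - affected * (config.severity_shift / 10.0)

    Lmat = L.to_numpy()  # scores x domains
    membership = (np.abs(Lmat) > 0).astype(float)
    if config.residual_sd is None:
        load_per_score = np.abs(Lmat).max(axis=1)
        resid_sd = 10.0 * np.sqrt(np.clip(1.0 - load_per_score**2, 0.0, None))
    else:
        resid_sd = np.full(len(scores), float(config.residual_sd))
    # correlation from the unshifted factors; the planted deficit displaces
    # every score of an affected domain by the full severity_shift (T units)
    T = (
        50.0
        + 10.0 * factors0 @ Lmat.T
        - config.severity_shift * (affected.astype(float) @ membership.T)
        + rng.standard_normal((n, len(scores))) * resid_sd
    )

    score_df = pd.DataFrame(T, index=pd.Index(pids, name="patient_id"), columns=scores)
    for sid, rate in config.missing_rate.items():
        if sid in score_df.columns and rate > 0:
            mask = rng.random(n) < rate
            score_df.loc[mask, sid] = np.nan

    covariates = _draw_covariates(rng, pids, affected, config)
    truth = pd.DataFrame(
        {"patient_id": pids}
        | {f"affected_{d}": affected[:, j] for j, d in enumerate(domains)}
        | {f"severity_{d}": factors[:, j] for j, d in enumerate(domains)}
    )
    truth["affected_domains"] = [
        ";".join(sorted(d for j, d in enumerate(domains) if affected[i, j]))
        for i in range(n)
    ]
    return SyntheticCohort(scores=score_df, covariates=covariates, truth=truth,
                           config=config)


def _draw_covariates(rng, pids, affected, config: SimConfig) -> pd.DataFrame:
    cm = config.covariate_model
    n = len(pids)
    mean_sev = affected.mean(axis=1) * (config.severity_shift / 10.0)

    hosp = rng.random(n) < cm.hospitalized_rate
    icu = hosp & (rng.random(n) < cm.icu_rate_in_hospitalized)
    age = np.where(
        hosp,
        rng.normal(*cm.age_hospitalized, size=n),
        rng.normal(*cm.age_non_hospitalized, size=n),
    )
    age = np.clip(age, 18.0, 95.0)
    education = np.clip(rng.normal(*cm.education, size=n), 3.0, 25.0)
    days = np.clip(rng.normal(*cm.days_since_diagnosis, size=n), 30.0, None)
    moca = np.where(
        hosp,
        rng.normal(*cm.moca_hospitalized, size=n),
        rng.normal(*cm.moca_non_hospitalized, size=n),
    )
    moca = np.clip(np.round(moca), 0, 30)
    hads_anx = np.clip(np.round(rng.normal(*cm.hads, size=n)), 0, 21)
    hads_dep = np.clip(np.round(rng.normal(*cm.hads, size=n)), 0, 21)

    out = pd.DataFrame(
        {
            "patient_id": pids,
            "age": np.round(age, 1),
            "education_years": np.round(education, 1),
            "hospitalized": hosp,
            "icu": icu,
            "days_since_diagnosis": np.round(days, 0),
            "MoCA": moca,
            "HADS_anxiety": hads_anx,
            "HADS_depression": hads_dep,
        }
    )
    for name, (median, sigma) in cm.biomarkers.items():
        logv = np.log(median) + sigma * rng.standard_normal(n)
        logv += cm.severity_links.get(name, 0.0) * mean_sev
        out[name] = np.round(np.exp(logv), 2)
    for name in ("days_since_diagnosis", "HADS_anxiety", "HADS_depression"):
        link = cm.severity_links.get(name, 0.0)
        if link:
            out[name] = out[name] + np.round(link * mean_sev, 0)
    return out


def recovery_experiment(
    config: SimConfig | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Sensitivity/specificity of the affected-domain rule vs planted truth.

    Each replicate simulates a cohort, bands its T scores, classifies every
    patient, and tallies recovered vs planted affected domains. Returns one
    row per domain plus an ``overall`` row, with normal-approximation 95%
    Monte-Carlo confidence intervals.
    """
    from .profiles import cohort_profiles
    from .scoring import score_cohort

    if config is None:
        config = SimConfig()
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    domains = list(config.loading_pattern.columns)
    tp = {d: 0 for d in domains}
    fn = {d: 0 for d in domains}
    tn = {d: 0 for d in domains}
    fp = {d: 0 for d in domains}

    for _ in range(n_replicates):
        sub = int(rng.integers(0, 2**31 - 1))
        cohort = simulate_cohort(config, seed=sub)
        scored = score_cohort(cohort.to_long())
        profiles = cohort_profiles(scored, min_coverage=min_coverage)
        truth = cohort.truth.set_index("patient_id")
        for p in profiles:
            for d in domains:
                if d in p.unevaluable:
                    continue
                planted = bool(truth.loc[p.patient_id, f"affected_{d}"])
                recovered = d in p.affected
                if planted and recovered:
                    tp[d] += 1
                elif planted:
                    fn[d] += 1
                elif recovered:
                    fp[d] += 1
                else:
                    tn[d] += 1

    rows = []
    keys = domains + ["overall"]
    for d in keys:
        if d == "overall":
            TP, FN = sum(tp.values()), sum(fn.values())
            TN, FP = sum(tn.values()), sum(fp.values())
        else:
            TP, FN, TN, FP = tp[d], fn[d], tn[d], fp[d]
        sens = TP / (TP + FN) if TP + FN else np.nan
        spec = TN / (TN + FP) if TN + FP else np.nan
        se_sens = np.sqrt(sens * (1 - sens) / (TP + FN)) if TP + FN else np.nan
        se_spec = np.sqrt(spec * (1 - spec) / (TN + FP)) if TN + FP else np.nan
        rows.append((d, TP + FN, sens, 1.96 * se_sens, TN + FP, spec, 1.96 * se_spec))
    return pd.DataFrame(
        rows,
        columns=["domain", "n_planted", "sensitivity", "sens_ci95",
                 "n_unplanted", "specificity", "spec_ci95"],
    )


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    """Convenience: dataclasses.replace with validation."""
    out = replace(config, **kwargs)
    out.validate()
    return out
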