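"""End-to-end pipeline: score -> domain map -> distribution -> profiles ->
clinical correlates, with a run log recording every option.

The pipeline is deterministic: two runs with the same configuration and
seed produce byte-identical CSV outputs. Any stage failure raises
:class:`PipelineStageError` naming the stage; outputs written before the
failure are preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .correlates import ClinicalCorrelates
from .domains import DomainFactorModel, DomainMap, default_domain_map
from .exceptions import CogprofError
from .profiles import ClassificationThresholds, ImpairmentAnalysis
from .scoring import read_cohort_long, read_cohort_wide, read_norms, score_cohort

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(CogprofError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    cohort: str
    out_dir: str = "results"
    cohort_format: str = "long"        # "long" | "wide"
    wide_value_type: str = "t"
    norms: str | None = None
    domain_map: str | None = None      # path to YAML; None -> built-in map
    derive_domains: bool = False       # derive map from the cohort instead
    n_factors: int = 5
    loading_threshold: float = 0.40
    covariates: str | None = None
    group_covariate: str = "hospitalized"
    ancova_outcome: str = "MoCA"
    ancova_covariate: str = "age"
    bins: str = "combined"
    yates_correction: bool = False
    min_coverage: float = 0.5
    thresholds: tuple[float, float, float] = (0.50, 0.30, 0.30)
    holm: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "thresholds" in payload:
            payload["thresholds"] = tuple(payload["thresholds"])
        return cls(**payload)

    def to_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            out[name] = list(v) if isinstance(v, tuple) else v
        return out


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the full pipeline; returns a dict of written artifact paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    log: dict = {
        "package_version": __version__,
        "options": config.to_dict(),
        "stages": [],
    }

    def _write_log():
        path = out_dir / "run_log.json"
        path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        artifacts["run_log"] = str(path)

    def _stage(name):
        log["stages"].append(name)

    try:
        _stage("load")
        if config.cohort_format == "long":
            cohort = read_cohort_long(config.cohort)
        elif config.cohort_format == "wide":
            cohort = read_cohort_wide(config.cohort, value_type=config.wide_value_type)
        else:
            raise ValueError(f"unknown cohort_format {config.cohort_format!r}")
        norms = read_norms(config.norms) if config.norms else None
    except Exception as exc:
        _write_log()
        raise PipelineStageError("load", exc) from exc

    try:
        _stage("score")
        scored = score_cohort(cohort, norms)
        p = out_dir / "scored.csv"
        scored.to_csv(p, index=False)
        artifacts["scored"] = str(p)
    except Exception as exc:
        _write_log()
        raise PipelineStageError("score", exc) from exc

    try:
        _stage("domain_map")
        if config.derive_domains:
            results = DomainFactorModel.from_scored(scored, n_factors=config.n_factors).fit(
                rotation_seed=config.seed
            )
            dmap = results.to_domain_map(threshold=config.loading_threshold)
            log["variance_explained"] = results.variance_explained
        elif config.domain_map:
            dmap = DomainMap.from_yaml(config.domain_map)
        else:
            dmap = default_domain_map()
        p = out_dir / "domain_map.yaml"
        dmap.to_yaml(p)
        artifacts["domain_map"] = str(p)
    except Exception as exc:
        _write_log()
        raise PipelineStageError("domain_map", exc) from exc

    try:
        _stage("profiles")
        thresholds = ClassificationThresholds(*config.thresholds)
        res = ImpairmentAnalysis(scored, dmap, thresholds, config.min_coverage).fit()
        for name, frame in (
            ("distribution", res.distribution),
            ("profiles", res.profiles),
        ):
            p = out_dir / f"{name}.csv"
            frame.to_csv(p, index=False)
            artifacts[name] = str(p)
        p = out_dir / "cooccurrence.csv"
        res.cooccurrence.to_csv(p)
        artifacts["cooccurrence"] = str(p)
        p = out_dir / "profile_summary.txt"
        p.write_text(res.summary() + "\n")
        artifacts["profile_summary"] = str(p)
        log["chi2_single_vs_multi"] = res.profile_summary.chi2_single_vs_multi
    except Exception as exc:
        _write_log()
        raise PipelineStageError("profiles", exc) from exc

    try:
        _stage("correlates")
        import pandas as pd

        covariates = pd.read_csv(config.covariates) if config.covariates else None
        cres = ClinicalCorrelates(scored, covariates, dmap, config.min_coverage).fit()
        p = out_dir / "composites.csv"
        cres.composites.to_csv(p)
        artifacts["composites"] = str(p)
        p = out_dir / "domain_correlations.csv"
        cres.domain_correlations.to_csv(p, index=False)
        artifacts["domain_correlations"] = str(p)
        if covariates is not None:
            tidy = []
            for cov in covariates.columns:
                if cov in ("patient_id", config.group_covariate, "icu"):
                    continue
                if not pd.api.types.is_numeric_dtype(covariates[cov]):
                    continue
                tab = cres.correlate_with(cov, holm=config.holm)
                tab.insert(0, "covariate", cov)
                tidy.append(tab)
            if tidy:
                p = out_dir / "covariate_correlations.csv"
                pd.concat(tidy, ignore_index=True).to_csv(p, index=False)
                artifacts["covariate_correlations"] = str(p)
            if config.group_covariate in covariates.columns:
                if config.ancova_outcome in covariates.columns:
                    F, df, pv = cres.compare_groups(
                        config.ancova_outcome, config.group_covariate,
                        config.ancova_covariate,
                    )
                    log["ancova"] = {
                        "outcome": config.ancova_outcome, "F": F,
                        "df": list(df), "p": pv,
                    }
                binned = cres.binned_tests(config.group_covariate, bins=config.bins,
                                           correction=config.yates_correction)
                p = out_dir / "binned_group_tests.csv"
                binned.to_csv(p, index=False)
                artifacts["binned_group_tests"] = str(p)
    except Exception as exc:
        _write_log()
        raise PipelineStageError("correlates", exc) from exc

    _stage("done")
    _write_log()
    return artifacts
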