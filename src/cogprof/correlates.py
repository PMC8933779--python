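"""Domain composite scores and clinical-correlate analyses.

A domain composite is the arithmetic mean of a patient's T scores over the
domain's constituent tests (all direction-harmonized, higher = better).
Composites feed Pearson correlations between domains and against clinical
covariates (disease duration, biomarkers, anxiety/depression subscores),
a one-covariate ANCOVA for group comparisons (hospitalized vs not, with
age as the covariate), and banded chi-square contingency tests per score.

Conventions: Pearson correlations with pairwise deletion and two-tailed
p-values; chi-square without continuity correction by default; no
multiple-testing correction by default, with an optional Holm column.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency, pearsonr

from .domains import DomainMap, default_domain_map
from .exceptions import DegenerateTableError, UndefinedCorrelationError

__all__ = [
    "composite_t",
    "cohort_composites",
    "correlate_composites",
    "compare_groups_ancova",
    "binned_group_test",
    "correlate_covariate",
    "ClinicalCorrelates",
    "ClinicalCorrelatesResults",
]


def composite_t(
    patient_scored: pd.DataFrame,
    domain_map: DomainMap | None = None,
    domain: str = "Attention",
    min_coverage: float = 0.5,
) -> float:
    """Mean T score over one patient's observed scores in a domain.

    Missing scores are dropped, never imputed. Returns NaN (the undefined
    flag) when fewer than ``min_coverage`` of the domain's scores are
    observed.
    """
    if domain_map is None:
        domain_map = default_domain_map()
    members = domain_map.scores_in(domain)
    if not members:
        raise KeyError(f"domain {domain!r} has no scores in the map")
    df = patient_scored.dropna(subset=["t_score"])
    vals = df.loc[df["score_id"].isin(members), "t_score"].to_numpy(dtype=float)
    if len(vals) == 0 or len(vals) / len(members) < min_coverage:
        return float("nan")
    return float(vals.mean())


def cohort_composites(
    scored: pd.DataFrame,
    domain_map: DomainMap | None = None,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Patients x domains table of composite T scores (NaN = undefined)."""
    if domain_map is None:
        domain_map = default_domain_map()
    rows = {}
    for pid, g in scored.groupby("patient_id", sort=True):
        rows[pid] = {
            d: composite_t(g, domain_map, d, min_coverage) for d in domain_map.domains
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "patient_id"
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise UndefinedCorrelationError(f"only {len(x)} complete pairs (need >= 3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    r, p = pearsonr(x, y)
    return float(r), float(p)


def correlate_composites(
    composites: pd.DataFrame, domain_pair: tuple[str, str]
) -> tuple[float, float]:
    """Pearson r and two-tailed p between two domain composites
    (pairwise deletion; p from the t distribution with n-2 df)."""
    a, b = domain_pair
    return _pearson(composites[a].to_numpy(float), composites[b].to_numpy(float))


def compare_groups_ancova(outcome, group, covariate) -> tuple[float, tuple[int, int], float]:
    """One-way ANCOVA: group effect on the outcome adjusting one covariate.

    Returns (F, (1, n - 3), p) for the group term. With a single binary
    group and one covariate the group F is the squared t of the group
    coefficient in OLS on [1, group, covariate].
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group, dtype=float)
    c = np.asarray(covariate, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g) & np.isfinite(c)
    y, g, c = y[ok], g[ok], c[ok]
    if len(np.unique(g)) < 2:
        raise ValueError("group must have two levels present")
    X = np.column_stack([np.ones_like(y), g, c])
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError("singular ANCOVA design (covariate collinear with group?)")
    fit = sm.OLS(y, X).fit()
    t_g = fit.tvalues[1]
    F = float(t_g**2)
    df = (1, int(fit.df_resid))
    return F, df, float(fit.pvalues[1])


_BIN_MODES = {
    "impaired": lambda b: b == "impaired",
    "low_average": lambda b: b == "low_average",
    "combined": lambda b: b != "average_plus",
}


def binned_group_test(
    scored: pd.DataFrame,
    score_id: str,
    group: pd.Series,
    bins: str = "combined",
    correction: bool = False,
) -> tuple[float, int, float, pd.DataFrame]:
    """Contingency chi-square of band membership x group for one score.

    ``bins`` selects the dichotomization: ``"impaired"`` (Pc <= 8 vs rest),
    ``"low_average"`` (low-average band vs rest) or ``"combined"``
    (Pc <= 24 vs above). Warns when any expected count falls below 5.
    """
    if bins not in _BIN_MODES:
        raise ValueError(f"bins must be one of {sorted(_BIN_MODES)}, got {bins!r}")
    df = scored[scored["score_id"] == score_id].dropna(subset=["band3"])
    if df.empty:
        raise DegenerateTableError(f"no observations for score {score_id!r}")
    in_bin = df["band3"].map(_BIN_MODES[bins])
    grp = df["patient_id"].map(group)
    table = pd.crosstab(in_bin, grp)
    if table.shape != (2, 2) or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            f"degenerate 2x2 table for score {score_id!r} (empty row/column)"
        )
    chi2, p, dof, expected = chi2_contingency(table.to_numpy(), correction=correction)
    if expected.min() < 5:
        import warnings

        warnings.warn(
            f"expected count below 5 in the {score_id!r} contingency table",
            stacklevel=2,
        )
    return float(chi2), int(dof), float(p), table


def correlate_covariate(
    composites: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_name: str,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-domain Pearson correlation of composites with one covariate.

    No multiple-testing correction by default; ``holm=True`` adds a
    Holm-adjusted p column. Domains where the correlation is undefined
    (constant covariate, too few pairs) get NaN and a note.
    """
    cov = covariates.set_index("patient_id")[covariate_name] if "patient_id" in covariates \
        else covariates[covariate_name]
    aligned = cov.reindex(composites.index).to_numpy(dtype=float)
    rows = []
    for d in composites.columns:
        try:
            r, p = _pearson(composites[d].to_numpy(float), aligned)
            rows.append((d, r, p, ""))
        except UndefinedCorrelationError as exc:
            rows.append((d, np.nan, np.nan, str(exc)))
    out = pd.DataFrame(rows, columns=["domain", "r", "p", "note"])
    if holm:
        from statsmodels.stats.multitest import multipletests

        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p"], method="holm")[1]
        out["p_holm"] = adj
    return out


# ---------------------------------------------------------------------------
# Model / Results wrapper


class ClinicalCorrelates:
    """Clinical-correlate analysis of a scored cohort.

    Parameters
    ----------
    scored
        Banded ScoredTest table.
    covariates
        One row per patient; ``patient_id`` column plus named covariates
        (age, hospitalized, days_since_diagnosis, MoCA, HADS subscores,
        biomarkers ...).
    """

    def __init__(self, scored: pd.DataFrame, covariates: pd.DataFrame | None = None,
                 domain_map: DomainMap | None = None, min_coverage: float = 0.5):
        self.scored = scored
        self.covariates = covariates
        self.domain_map = domain_map if domain_map is not None else default_domain_map()
        self.min_coverage = min_coverage

    def fit(self) -> "ClinicalCorrelatesResults":
        composites = cohort_composites(self.scored, self.domain_map, self.min_coverage)
        rows = []
        for a, b in combinations(composites.columns, 2):
            try:
                r, p = correlate_composites(composites, (a, b))
            except UndefinedCorrelationError:
                r, p = np.nan, np.nan
            rows.append((a, b, r, p))
        pairwise = pd.DataFrame(rows, columns=["domain_a", "domain_b", "r", "p"])
        return ClinicalCorrelatesResults(self, composites, pairwise)


@dataclass
class ClinicalCorrelatesResults:
    model: ClinicalCorrelates
    composites: pd.DataFrame
    domain_correlations: pd.DataFrame

    def _cov(self, name: str) -> pd.Series:
        if self.model.covariates is None:
            raise ValueError("no covariates table supplied")
        return self.model.covariates.set_index("patient_id")[name]

    def correlate_with(self, covariate_name: str, holm: bool = False) -> pd.DataFrame:
        return correlate_covariate(self.composites, self.model.covariates,
                                   covariate_name, holm=holm)

    def compare_groups(self, outcome_name: str, group_name: str = "hospitalized",
                       covariate_name: str = "age"):
        """ANCOVA of a covariate-table outcome (e.g. MoCA) across a binary
        group, adjusting for one covariate."""
        y = self._cov(outcome_name)
        g = self._cov(group_name).astype(float)
        c = self._cov(covariate_name)
        idx = y.index
        return compare_groups_ancova(y.loc[idx], g.loc[idx], c.loc[idx])

    def binned_tests(self, group_name: str = "hospitalized", bins: str = "combined",
                     correction: bool = False) -> pd.DataFrame:
        """Per-score contingency chi-squares of band membership x group.

        Runs one uncorrected test per battery score; treat the family of
        p-values accordingly (exploratory, multiplicity uncorrected).
        """
        group = self._cov(group_name).astype(bool)
        rows = []
        for sid in self.model.scored["score_id"].unique():
            try:
                chi2, dof, p, _ = binned_group_test(self.model.scored, sid, group,
                                                    bins=bins, correction=correction)
                rows.append((sid, chi2, dof, p, ""))
            except DegenerateTableError as exc:
                rows.append((sid, np.nan, np.nan, np.nan, str(exc)))
        return pd.DataFrame(rows, columns=["score_id", "chi2", "df", "p", "note"])

    def summary(self) -> str:
        lines = ["Domain composite correlations (Pearson, pairwise deletion)"]
        for _, r in self.domain_correlations.iterrows():
            lines.append(
                f"  {r.domain_a:<16s} x {r.domain_b:<16s} r = {r.r:+.2f}  p = {r.p:.3g}"
            )
        return "\n".join(lines)
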