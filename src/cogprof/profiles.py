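"""Score-distribution tables and rule-based domain-impairment profiles.

A cognitive domain counts as *affected* for a patient when, over the
domain's observed scores,

* at least 50% fall in the impaired band (percentile <= 8), or
* at least 30% fall in the impaired band AND at least 30% in the
  low-average band (percentile 9-24).

The rule is applied over all constituent scores of a domain regardless of
whether they come from multi-score instruments (RAVLT, CPT-II) or
single-score ones; the thresholds are inclusive ("at least"). Patients are
then labelled ``none`` / ``single`` / ``multi`` by how many domains are
affected.

Missing scores are dropped from denominators. A domain with no observed
scores — or with coverage below ``min_coverage`` — is reported as
unevaluable rather than unaffected, so sparse data cannot silently produce
a clean bill of health.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from . import battery as bat
from .domains import DomainMap, default_domain_map
from .exceptions import UnevaluableDomainError, UnmappedScoreError

__all__ = [
    "ClassificationThresholds",
    "ImpairmentProfile",
    "score_distribution_table",
    "banded_cohort_from_counts",
    "check_against_published",
    "classify_domain",
    "impairment_profile",
    "cohort_profiles",
    "cohort_profile_summary",
    "ProfileSummary",
    "ImpairmentAnalysis",
    "ImpairmentResults",
]


@dataclass(frozen=True)
class ClassificationThresholds:
    """Inclusive fractions for the affected-domain rule."""

    impaired_only: float = 0.50
    impaired_combined: float = 0.30
    low_average_combined: float = 0.30

    def __post_init__(self) -> None:
        for name in ("impaired_only", "impaired_combined", "low_average_combined"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass(frozen=True)
class ImpairmentProfile:
    """Per-patient set of affected domains."""

    patient_id: object
    affected: frozenset
    unevaluable: tuple = ()

    @property
    def n_affected(self) -> int:
        return len(self.affected)

    @property
    def profile_class(self) -> str:
        if self.n_affected == 0:
            return "none"
        return "single" if self.n_affected == 1 else "multi"


# ---------------------------------------------------------------------------
# distribution table


def _pct(count: np.ndarray, total: np.ndarray) -> np.ndarray:
    return np.round(100.0 * count / total, 2)


def score_distribution_table(scored: pd.DataFrame, domain_map: DomainMap | None = None
                             ) -> pd.DataFrame:
    """Per-score counts and percentages of the three band categories.

    One row per score, grouped by domain in map order; the per-score
    denominator is the number of non-missing values. Percentages are
    rounded to 2 decimals; ``pct_below_24`` combines impaired and
    low-average.
    """
    if domain_map is None:
        domain_map = default_domain_map()
    df = scored.dropna(subset=["band3"])
    unmapped = [s for s in df["score_id"].unique() if s not in domain_map]
    if unmapped:
        raise UnmappedScoreError(f"scores not in the domain map: {sorted(unmapped)}")

    counts = (
        df.groupby("score_id")["band3"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["impaired", "low_average", "average_plus"], fill_value=0)
    )
    # domain-grouped ordering; within a domain keep the map's own score order
    order = [s for d in domain_map.domains for s in domain_map.scores_in(d)
             if s in counts.index]
    order += [s for s in counts.index if s not in order]
    counts = counts.loc[order]

    n_imp = counts["impaired"].to_numpy()
    n_low = counts["low_average"].to_numpy()
    n_avg = counts["average_plus"].to_numpy()
    n_tot = n_imp + n_low + n_avg
    out = pd.DataFrame(
        {
            "score_id": counts.index,
            "domain": [domain_map.domain_of(s) for s in counts.index],
            "n_impaired": n_imp,
            "n_low_avg": n_low,
            "n_avg_plus": n_avg,
            "n_total": n_tot,
            "pct_impaired": _pct(n_imp, n_tot),
            "pct_low_avg": _pct(n_low, n_tot),
            "pct_avg_plus": _pct(n_avg, n_tot),
            "pct_below_24": _pct(n_imp + n_low, n_tot),
        }
    ).reset_index(drop=True)
    return out


def banded_cohort_from_counts(counts: dict[str, tuple[int, int, int]]) -> pd.DataFrame:
    """Expand per-score band counts into a minimal banded score table.

    Useful to replay a published count table through
    :func:`score_distribution_table`. Patient ids are synthetic row labels.
    """
    rows = []
    for sid, (n_imp, n_low, n_avg) in counts.items():
        bands = (["impaired"] * n_imp + ["low_average"] * n_low
                 + ["average_plus"] * n_avg)
        for i, b in enumerate(bands):
            rows.append((f"P{i + 1:03d}", sid, b))
    return pd.DataFrame(rows, columns=["patient_id", "score_id", "band3"])


def check_against_published(
    table: pd.DataFrame,
    published: dict[str, tuple[float, float, float, float]] = bat.PUBLISHED_BAND_PERCENTAGES,
    atol: float = 0.005,
) -> pd.DataFrame:
    """Compare a recomputed distribution table with published percentages.

    Returns one row per score with the maximum absolute discrepancy across
    the four percentage columns and a ``consistent`` flag. With the
    reference battery's published counts as input, every row is consistent
    except RAVLT - Recognition, whose printed percentages imply a different
    denominator than its printed counts.
    """
    cols = ["pct_impaired", "pct_low_avg", "pct_avg_plus", "pct_below_24"]
    rows = []
    for _, r in table.iterrows():
        sid = r["score_id"]
        if sid not in published:
            continue
        diffs = np.abs(np.asarray([r[c] for c in cols]) - np.asarray(published[sid]))
        rows.append((sid, float(diffs.max()), bool(diffs.max() <= atol)))
    return pd.DataFrame(rows, columns=["score_id", "max_abs_diff", "consistent"])


# ---------------------------------------------------------------------------
# domain classification


def classify_domain(
    band3_labels,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Whether a domain is affected, from its observed band-3 labels.

    Raises :class:`UnevaluableDomainError` when no labels remain after
    dropping missing values: an unobserved domain is unevaluable, never
    "unaffected".
    """
    labels = [b for b in band3_labels if isinstance(b, str)]
    if not labels:
        raise UnevaluableDomainError("no observed scores in domain")
    n = len(labels)
    frac_imp = sum(b == "impaired" for b in labels) / n
    frac_low = sum(b == "low_average" for b in labels) / n
    return bool(
        frac_imp >= thresholds.impaired_only
        or (frac_imp >= thresholds.impaired_combined
            and frac_low >= thresholds.low_average_combined)
    )


def impairment_profile(
    patient_scored: pd.DataFrame,
    domain_map: DomainMap | None = None,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    min_coverage: float = 0.5,
) -> ImpairmentProfile:
    """Classify one patient's affected domains.

    ``min_coverage`` is the minimum fraction of a domain's mapped scores
    that must be observed for the domain to be evaluated (guards against
    classifying a 12-score domain from a single observed score).
    """
    if domain_map is None:
        domain_map = default_domain_map()
    pids = patient_scored["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected a single patient, got {len(pids)}")
    df = patient_scored.dropna(subset=["band3"])
    by_score = dict(zip(df["score_id"], df["band3"]))

    affected, unevaluable = set(), []
    for domain in domain_map.domains:
        members = domain_map.scores_in(domain)
        observed = [by_score[s] for s in members if s in by_score]
        if not observed or len(observed) / len(members) < min_coverage:
            unevaluable.append(domain)
            continue
        if classify_domain(observed, thresholds):
            affected.add(domain)
    if len(unevaluable) == len(domain_map.domains):
        raise UnevaluableDomainError(f"no evaluable domain for patient {pids[0]!r}")
    return ImpairmentProfile(pids[0], frozenset(affected), tuple(unevaluable))


def cohort_profiles(
    scored: pd.DataFrame,
    domain_map: DomainMap | None = None,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    min_coverage: float = 0.5,
) -> list[ImpairmentProfile]:
    if domain_map is None:
        domain_map = default_domain_map()
    return [
        impairment_profile(g, domain_map, thresholds, min_coverage)
        for _, g in scored.groupby("patient_id", sort=True)
    ]


@dataclass
class ProfileSummary:
    """Cohort-level impairment summary."""

    n: int
    class_counts: dict
    class_freq: dict
    domain_freq: pd.Series
    single_domain_freq: pd.Series
    cooccurrence: pd.DataFrame
    chi2_single_vs_multi: float
    chi2_p: float

    def summary(self) -> str:
        lines = [
            f"Cohort impairment summary (n = {self.n})",
            "  profile classes: "
            + ", ".join(f"{k} {self.class_counts[k]} ({100 * self.class_freq[k]:.1f}%)"
                        for k in ("none", "single", "multi")),
            f"  single vs multi goodness-of-fit: chi2(1) = "
            f"{self.chi2_single_vs_multi:.2f}, p = {self.chi2_p:.3g}",
            "  affected-domain frequency:",
        ]
        for d, f in self.domain_freq.items():
            lines.append(f"    {d:<16s} {100 * f:5.1f}%")
        return "\n".join(lines)


def cohort_profile_summary(profiles: list[ImpairmentProfile],
                           domains: tuple[str, ...] | None = None) -> ProfileSummary:
    """Frequencies of profile classes, per-domain impairment, the single-domain
    breakdown, pairwise co-occurrence, and a 1-df equal-expectation
    goodness-of-fit chi-square of single vs multi among impaired patients
    (no continuity correction)."""
    if not profiles:
        raise ValueError("empty cohort")
    n = len(profiles)
    if domains is None:
        seen: dict[str, None] = {}
        for p in profiles:
            for d in sorted(p.affected) + sorted(p.unevaluable):
                seen.setdefault(d, None)
        domains = tuple(seen)

    classes = pd.Series([p.profile_class for p in profiles])
    class_counts = {c: int((classes == c).sum()) for c in ("none", "single", "multi")}
    class_freq = {c: class_counts[c] / n for c in class_counts}

    evaluable = {d: sum(d not in p.unevaluable for p in profiles) for d in domains}
    domain_freq = pd.Series(
        {d: (sum(d in p.affected for p in profiles) / evaluable[d]
             if evaluable[d] else np.nan) for d in domains}
    )
    singles = [p for p in profiles if p.profile_class == "single"]
    single_domain_freq = pd.Series(
        {d: sum(d in p.affected for p in singles) / n for d in domains}
    )
    co = pd.DataFrame(0, index=list(domains), columns=list(domains), dtype=int)
    for p in profiles:
        for a in p.affected:
            for b in p.affected:
                if a in co.index and b in co.index:
                    co.loc[a, b] += 1

    s, m = class_counts["single"], class_counts["multi"]
    if s + m == 0:
        chi2, p_val = np.nan, np.nan
    else:
        e = (s + m) / 2.0
        chi2 = (s - e) ** 2 / e + (m - e) ** 2 / e
        p_val = float(chi2_dist.sf(chi2, df=1))
    return ProfileSummary(
        n=n, class_counts=class_counts, class_freq=class_freq,
        domain_freq=domain_freq, single_domain_freq=single_domain_freq,
        cooccurrence=co, chi2_single_vs_multi=float(chi2), chi2_p=p_val,
    )


# ---------------------------------------------------------------------------
# Model / Results wrapper


class ImpairmentAnalysis:
    """Cohort impairment analysis over a banded ScoredTest table."""

    def __init__(self, scored: pd.DataFrame, domain_map: DomainMap | None = None,
                 thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
                 min_coverage: float = 0.5):
        self.scored = scored
        self.domain_map = domain_map if domain_map is not None else default_domain_map()
        self.thresholds = thresholds
        self.min_coverage = min_coverage

    def fit(self) -> "ImpairmentResults":
        profiles = cohort_profiles(self.scored, self.domain_map, self.thresholds,
                                   self.min_coverage)
        distribution = score_distribution_table(self.scored, self.domain_map)
        summary = cohort_profile_summary(profiles, self.domain_map.domains)
        return ImpairmentResults(self, profiles, distribution, summary)


@dataclass
class ImpairmentResults:
    model: ImpairmentAnalysis
    profile_objects: list
    distribution: pd.DataFrame
    profile_summary: ProfileSummary

    @property
    def profiles(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.profile_objects],
                "affected": [";".join(sorted(p.affected)) for p in self.profile_objects],
                "n_affected": [p.n_affected for p in self.profile_objects],
                "profile_class": [p.profile_class for p in self.profile_objects],
            }
        )

    @property
    def cooccurrence(self) -> pd.DataFrame:
        return self.profile_summary.cooccurrence

    def summary(self) -> str:
        return self.profile_summary.summary()
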