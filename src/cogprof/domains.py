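"""Cognitive-domain structure of a test battery.

Domains are derived empirically: a principal component analysis of the
cohort's percentile scores, an oblique (direct oblimin) rotation to allow
correlated factors, threshold assignment of each score to the factor it
loads on most, and a small set of content-based regrouping rules for scores
that load weakly or belong to an instrument whose other scores define a
domain (digit spans -> short-term/working memory; Coding and Symbol Search
-> processing speed; all CPT-II subscores -> attention; ROCFT delayed
recall -> learning/long-term memory).

The module also ships the reference 33-score battery map as
:func:`default_domain_map`, and a statsmodels-style
:class:`DomainFactorModel` / :class:`DomainFactorResults` pair wrapping the
extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment

from . import battery as bat
from ._rotation import rotate_oblimin
from .battery import normalize_score_id
from .exceptions import DegenerateDataError, UnmappedScoreError

__all__ = [
    "LoadingMatrix",
    "DomainMap",
    "extract_factors",
    "label_factors",
    "assign_by_loading",
    "apply_reassignment_rules",
    "default_domain_map",
    "DomainFactorModel",
    "DomainFactorResults",
]


@dataclass(frozen=True)
class LoadingMatrix:
    """Rotated pattern loadings (scores x factors) from a PCA + oblimin fit.

    ``variance_explained`` is the proportion of total variance captured by
    the retained components before rotation (rotation redistributes, but
    does not change, the total).
    """

    loadings: pd.DataFrame
    phi: np.ndarray
    variance_explained: float
    n_factors: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.variance_explained <= 1.0:
            raise ValueError("variance_explained must be in [0, 1]")


class DomainMap:
    """Assignment of battery scores to cognitive domains.

    Each score maps to at most one domain; ``None`` marks a provisionally
    unassigned score (below the loading threshold). Provenance records
    whether an assignment came from the factor pattern
    (``"factor_loading"``) or a regrouping rule (``"manual_override"``).
    Equality compares the score -> domain assignment only.
    """

    def __init__(self, entries):
        """entries: iterable of (score_id, test_id, domain_or_None, provenance)."""
        self._rows: dict[str, tuple[str, str | None, str]] = {}
        for score_id, test_id, domain, provenance in entries:
            sid = normalize_score_id(score_id)
            if sid in self._rows:
                raise ValueError(f"score {sid!r} assigned more than once")
            self._rows[sid] = (test_id, domain, provenance)

    # -- mapping interface -------------------------------------------------
    def __contains__(self, score_id: str) -> bool:
        return normalize_score_id(score_id) in self._rows

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DomainMap):
            return NotImplemented
        return self.assignments == other.assignments

    def domain_of(self, score_id: str) -> str:
        sid = normalize_score_id(score_id)
        try:
            domain = self._rows[sid][1]
        except KeyError:
            raise UnmappedScoreError(f"score {sid!r} is not in the domain map") from None
        if domain is None:
            raise UnmappedScoreError(f"score {sid!r} is unassigned in the domain map")
        return domain

    def test_of(self, score_id: str) -> str:
        return self._rows[normalize_score_id(score_id)][0]

    def provenance_of(self, score_id: str) -> str:
        return self._rows[normalize_score_id(score_id)][2]

    @property
    def assignments(self) -> dict[str, str | None]:
        return {sid: row[1] for sid, row in self._rows.items()}

    @property
    def domains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, domain, _ in self._rows.values():
            if domain is not None:
                seen.setdefault(domain, None)
        return tuple(seen)

    @property
    def unassigned(self) -> tuple[str, ...]:
        return tuple(sid for sid, row in self._rows.items() if row[1] is None)

    def scores_in(self, domain: str) -> tuple[str, ...]:
        return tuple(sid for sid, row in self._rows.items() if row[1] == domain)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.domains:
            out[d] = len(self.scores_in(d))
        return out

    def is_multi_score_test(self, score_id: str) -> bool:
        test = self.test_of(score_id)
        return sum(1 for row in self._rows.values() if row[0] == test) > 1

    def rows(self):
        for sid, (test_id, domain, provenance) in self._rows.items():
            yield sid, test_id, domain, provenance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows()), columns=["score_id", "test_id", "domain", "provenance"]
        )

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "scores": [
                {"score_id": sid, "test_id": t, "domain": d, "provenance": p}
                for sid, t, d, p in self.rows()
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "DomainMap":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict) or "scores" not in payload:
            raise ValueError("domain map file must contain a top-level 'scores' list")
        entries = [
            (r["score_id"], r.get("test_id", r["score_id"]), r.get("domain"),
             r.get("provenance", "factor_loading"))
            for r in payload["scores"]
        ]
        return cls(entries)


# ---------------------------------------------------------------------------
# factor extraction


def extract_factors(
    score_matrix: pd.DataFrame,
    n_factors: int = 5,
    gamma: float = 0.0,
    missing: str = "complete_case",
    max_iter: int = 500,
    tol: float = 1e-6,
    rotation_starts: int = 10,
    rotation_seed: int = 0,
) -> LoadingMatrix:
    """PCA of a patients x scores matrix followed by direct-oblimin rotation.

    Components are extracted from the correlation matrix; the retained
    components' eigenvalue share is reported as ``variance_explained``.

    Parameters
    ----------
    score_matrix
        Patients x scores (conventionally percentiles). Missing cells are
        handled per ``missing``: ``"complete_case"`` drops incomplete rows,
        ``"mean"`` imputes the column mean.
    """
    X = score_matrix.astype(float)
    if missing == "complete_case":
        X = X.dropna(axis=0, how="any")
    elif missing == "mean":
        X = X.fillna(X.mean(axis=0))
    else:
        raise ValueError(f"unknown missing-data mode {missing!r}")

    p = X.shape[1]
    if not 0 < n_factors < p:
        raise ValueError(f"n_factors must be in (0, {p}), got {n_factors}")
    if X.shape[0] <= n_factors:
        raise DegenerateDataError(
            f"only {X.shape[0]} complete rows for {n_factors} factors"
        )
    sd = X.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise DegenerateDataError(f"constant score columns: {constant}")

    R = np.corrcoef(X.to_numpy(), rowvar=False)
    if not np.all(np.isfinite(R)):
        raise DegenerateDataError("correlation matrix contains non-finite entries")
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    top = np.clip(eigval[:n_factors], 0.0, None)
    A = eigvec[:, :n_factors] * np.sqrt(top)
    variance_explained = float(np.sum(top) / p)

    L, Phi, _ = rotate_oblimin(
        A, gamma=gamma, n_starts=rotation_starts, max_iter=max_iter, tol=tol,
        seed=rotation_seed,
    )
    cols = [f"F{j + 1}" for j in range(n_factors)]
    loadings = pd.DataFrame(L, index=X.columns, columns=cols)
    return LoadingMatrix(loadings=loadings, phi=Phi, variance_explained=variance_explained,
                         n_factors=n_factors)


def label_factors(
    loadings: pd.DataFrame,
    anchors: dict[str, tuple[str, ...]] = bat.FACTOR_ANCHORS,
) -> dict[str, str]:
    """Name anonymous factors by their content.

    Each factor column is matched to the domain whose anchor scores load on
    it most strongly (maximum-weight one-to-one assignment). Anchors only
    name factors; they never move a score between domains.
    """
    domains = list(anchors)
    cols = list(loadings.columns)
    M = np.zeros((len(domains), len(cols)))
    idx = {normalize_score_id(s): i for i, s in enumerate(loadings.index)}
    for a, domain in enumerate(domains):
        present = [idx[s] for s in anchors[domain] if s in idx]
        if not present:
            raise ValueError(f"no anchor score for domain {domain!r} in the loading matrix")
        M[a] = np.abs(loadings.to_numpy()[present]).max(axis=0)
    rows, cols_ix = linear_sum_assignment(-M)
    return {cols[c]: domains[r] for r, c in zip(rows, cols_ix)}


def assign_by_loading(
    loadings: LoadingMatrix,
    threshold: float = 0.40,
    factor_labels: dict[str, str] | None = None,
    test_ids: dict[str, str] | None = None,
) -> DomainMap:
    """Provisional domain map: each score goes to the factor of its maximal
    absolute pattern loading if that loading reaches ``threshold``,
    otherwise it is flagged unassigned.

    Ties between factors break deterministically toward the lowest factor
    index, with a warning.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if factor_labels is None:
        factor_labels = label_factors(loadings.loadings)
    builtin = {sid: tid for sid, tid, _, _ in bat.BATTERY}
    if test_ids:
        builtin.update({normalize_score_id(k): v for k, v in test_ids.items()})

    entries = []
    L = loadings.loadings
    absL = L.abs().to_numpy()
    for i, sid in enumerate(L.index):
        row = absL[i]
        best = float(row.max())
        winners = np.flatnonzero(row >= best - 1e-12)
        if len(winners) > 1:
            warnings.warn(
                f"score {sid!r} ties between factors "
                f"{[L.columns[w] for w in winners]}; keeping the first",
                stacklevel=2,
            )
        j = int(winners[0])
        sid_n = normalize_score_id(sid)
        test = builtin.get(sid_n, sid_n)
        if best >= threshold:
            entries.append((sid_n, test, factor_labels[L.columns[j]], "factor_loading"))
        else:
            entries.append((sid_n, test, None, "unassigned"))
    return DomainMap(entries)


#: regrouping rules: predicate on (score_id, test_id) -> target domain
_REASSIGNMENT_RULES = (
    (lambda sid, tid: sid in ("Forward span", "Backward span"), "ST/WM"),
    (lambda sid, tid: sid in ("WAIS-IV - Coding test", "WAIS-IV - Symbol search"),
     "ProcessingSpeed"),
    (lambda sid, tid: tid == "CPT-II" or sid.startswith("CPT-II"), "Attention"),
    (lambda sid, tid: sid == "ROCFT - Delayed recall", "L+LTM"),
)


def apply_reassignment_rules(provisional: DomainMap) -> DomainMap:
    """Apply the content-based regrouping rules to a provisional map.

    Digit spans -> ST/WM, Coding and Symbol Search -> ProcessingSpeed, every
    CPT-II subscore -> Attention, ROCFT delayed recall -> L+LTM. A score the
    rules would leave where it already is keeps its original provenance, so
    the operation is idempotent.
    """
    entries = []
    for sid, test_id, domain, provenance in provisional.rows():
        target = None
        for rule, dest in _REASSIGNMENT_RULES:
            if rule(sid, test_id):
                target = dest
                break
        if target is not None and domain != target:
            entries.append((sid, test_id, target, "manual_override"))
        else:
            entries.append((sid, test_id, domain, provenance))
    return DomainMap(entries)


def default_domain_map() -> DomainMap:
    """The built-in reference battery map (33 scores, 7 domains).

    Domain sizes: L+LTM 6, VVA 4, ST/WM 2, ProcessingSpeed 2, Language 3,
    Attention 12, EF 4. The MoCA is deliberately absent (multi-domain
    screening instrument)."""
    return DomainMap(bat.BATTERY)


# ---------------------------------------------------------------------------
# Model / Results wrappers


class DomainFactorModel:
    """Factor model of a battery's domain structure.

    Parameters
    ----------
    score_matrix
        Patients x scores DataFrame (percentiles by convention).
    n_factors
        Number of oblique factors to retain (reference battery: 5).
    """

    def __init__(self, score_matrix: pd.DataFrame, n_factors: int = 5,
                 gamma: float = 0.0, missing: str = "complete_case"):
        self.score_matrix = score_matrix
        self.n_factors = n_factors
        self.gamma = gamma
        self.missing = missing

    @classmethod
    def from_scored(cls, scored: pd.DataFrame, exclude=("MoCA",), **kwargs):
        """Build from a long ScoredTest table, pivoting percentiles wide."""
        df = scored[~scored["test_id"].isin(exclude) & ~scored["score_id"].isin(exclude)]
        wide = df.pivot_table(index="patient_id", columns="score_id",
                              values="percentile", aggfunc="first")
        return cls(wide, **kwargs)

    def fit(self, rotation_starts: int = 10, rotation_seed: int = 0,
            max_iter: int = 500, tol: float = 1e-6) -> "DomainFactorResults":
        lm = extract_factors(
            self.score_matrix, n_factors=self.n_factors, gamma=self.gamma,
            missing=self.missing, max_iter=max_iter, tol=tol,
            rotation_starts=rotation_starts, rotation_seed=rotation_seed,
        )
        return DomainFactorResults(self, lm)


@dataclass
class DomainFactorResults:
    """Fitted oblique factor solution for a battery."""

    model: DomainFactorModel
    loading_matrix: LoadingMatrix
    factor_labels: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        try:
            self.factor_labels = label_factors(self.loading_matrix.loadings)
        except ValueError:
            self.factor_labels = {c: c for c in self.loading_matrix.loadings.columns}

    @property
    def loadings(self) -> pd.DataFrame:
        return self.loading_matrix.loadings

    @property
    def variance_explained(self) -> float:
        return self.loading_matrix.variance_explained

    @property
    def phi(self) -> np.ndarray:
        return self.loading_matrix.phi

    def to_domain_map(self, threshold: float = 0.40, reassign: bool = True) -> DomainMap:
        provisional = assign_by_loading(
            self.loading_matrix, threshold=threshold, factor_labels=self.factor_labels
        )
        return apply_reassignment_rules(provisional) if reassign else provisional

    def summary(self) -> str:
        lm = self.loading_matrix
        lines = [
            "Oblique factor solution (PCA + direct oblimin)",
            f"  scores: {lm.loadings.shape[0]}   factors: {lm.n_factors}   "
            f"variance explained (pre-rotation): {lm.variance_explained:.1%}",
            "  factor labels: "
            + ", ".join(f"{c} = {d}" for c, d in self.factor_labels.items()),
            "",
            lm.loadings.round(2).to_string(),
            "",
            "Factor correlations:",
            pd.DataFrame(lm.phi, index=lm.loadings.columns,
                         columns=lm.loadings.columns).round(2).to_string(),
        ]
        return "\n".join(lines)
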