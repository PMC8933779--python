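"""Normative scoring: raw -> T score -> percentile -> performance bands.

A T score is a normative standardized score with mean 50 and SD 10 in the
reference population, oriented so that higher T always means better
performance. For scores where a higher *raw* value indicates worse
performance (completion times, error counts) the transformation flips sign.

Percentiles follow the normal-distribution convention for T metrics,
``Pc = 100 * Phi((T - 50) / 10)``. Banding uses the seven consensus
performance ranges (exceptionally low < 2nd percentile up to exceptionally
high > 98th) and the collapsed three-category scheme used for impairment
classification:

* ``impaired``      Pc <= 8  (exceptionally low + below average)
* ``low_average``   8 < Pc <= 24
* ``average_plus``  Pc > 24

The printed band definitions are stated over integer percentiles and leave
the open intervals (8, 9), (24, 25), (74, 75), (90, 91) and (97, 98)
unassigned; this module closes them with right-closed intervals (the lower
band keeps its upper edge), which preserves every integer label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .battery import normalize_score_id
from .exceptions import CogprofError, NormativeLookupError, PercentileDomainError

__all__ = [
    "NormativeEntry",
    "NormativeTable",
    "BandScheme",
    "DEFAULT_BANDS",
    "BAND7_LABELS",
    "BAND3_LABELS",
    "t_from_raw",
    "percentile_from_t",
    "t_from_percentile",
    "band7",
    "band3",
    "score_cohort",
    "read_norms",
    "read_cohort_long",
    "read_cohort_wide",
]

BAND7_LABELS = (
    "exceptionally_low",
    "below_average",
    "low_average",
    "average",
    "high_average",
    "above_average",
    "exceptionally_high",
)
BAND3_LABELS = ("impaired", "low_average", "average_plus")

#: band7 -> band3 coarsening
BAND3_FROM_BAND7 = {
    "exceptionally_low": "impaired",
    "below_average": "impaired",
    "low_average": "low_average",
    "average": "average_plus",
    "high_average": "average_plus",
    "above_average": "average_plus",
    "exceptionally_high": "average_plus",
}


@dataclass(frozen=True)
class NormativeEntry:
    """Reference mean/SD converting one raw score to the T metric.

    direction is ``"higher_raw_is_better"`` for accuracy-like scores and
    ``"higher_raw_is_worse"`` for times/errors, where the T transformation
    flips sign so higher T is always better.
    """

    test_id: str
    score_id: str
    ref_mean: float
    ref_sd: float
    direction: str = "higher_raw_is_better"

    def __post_init__(self) -> None:
        if not self.ref_sd > 0:
            raise ValueError(f"ref_sd must be > 0, got {self.ref_sd!r} for {self.score_id!r}")
        if self.direction not in ("higher_raw_is_better", "higher_raw_is_worse"):
            raise ValueError(f"unknown direction {self.direction!r}")


class NormativeTable:
    """Collection of :class:`NormativeEntry` keyed by (test_id, score_id)."""

    def __init__(self, entries: Iterable[NormativeEntry]):
        self._entries: dict[tuple[str, str], NormativeEntry] = {}
        for e in entries:
            key = (e.test_id, normalize_score_id(e.score_id))
            if key in self._entries:
                raise ValueError(f"duplicate normative entry for {key}")
            self._entries[key] = e

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, test_id: str, score_id: str) -> NormativeEntry:
        key = (test_id, normalize_score_id(score_id))
        try:
            return self._entries[key]
        except KeyError:
            raise NormativeLookupError(
                f"no normative entry for test {test_id!r}, score {score_id!r}"
            ) from None


@dataclass(frozen=True)
class BandScheme:
    """Seven right-closed percentile bands partitioning [0, 100].

    ``edges`` are the six interior cut points; band i covers
    (edges[i-1], edges[i]] except the lowest band, [0, edges[0]).
    The first edge is *exclusive* on its left band (Pc < 2 is exceptionally
    low, Pc = 2 is already below average), mirrored at the top (Pc = 98 is
    still above average). band3 groups the two lowest bands as ``impaired``
    and all bands above ``low_average`` as ``average_plus``.
    """

    edges: tuple[float, ...] = (2.0, 8.0, 24.0, 74.0, 90.0, 98.0)
    labels: tuple[str, ...] = BAND7_LABELS
    coarsening: dict = field(default_factory=lambda: dict(BAND3_FROM_BAND7))

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.labels) - 1:
            raise ValueError("need exactly one fewer edge than labels")
        if list(self.edges) != sorted(self.edges):
            raise ValueError("edges must be increasing")

    def band7(self, percentile):
        """Vectorized seven-band label for percentiles in [0, 100]."""
        pc = np.asarray(percentile, dtype=float)
        if np.any((pc < 0) | (pc > 100) | np.isnan(pc)):
            raise PercentileDomainError("percentile outside [0, 100]")
        e = self.edges
        conds = [pc < e[0]]
        conds += [(pc >= e[0]) & (pc <= e[1])]
        for lo, hi in zip(e[1:-1], e[2:]):
            conds.append((pc > lo) & (pc <= hi))
        conds.append(pc > e[-1])
        out = np.select(conds, self.labels, default=self.labels[-1])
        return out.item() if np.isscalar(percentile) else out

    def band3(self, percentile):
        """Vectorized collapsed three-category label."""
        b7 = self.band7(percentile)
        if isinstance(b7, str):
            return self.coarsening[b7]
        return np.vectorize(self.coarsening.__getitem__, otypes=[object])(b7)


DEFAULT_BANDS = BandScheme()


def t_from_raw(raw: float, norm_entry: NormativeEntry) -> float:
    """Convert a raw score to the T metric (mean 50, SD 10, higher = better).

    ``t = 50 + 10 * s * (raw - ref_mean) / ref_sd`` with ``s = +1`` when a
    higher raw score is better and ``-1`` otherwise. Output is not clipped.
    """
    s = 1.0 if norm_entry.direction == "higher_raw_is_better" else -1.0
    raw = np.asarray(raw, dtype=float)
    t = 50.0 + 10.0 * s * (raw - norm_entry.ref_mean) / norm_entry.ref_sd
    return float(t) if t.ndim == 0 else t


def percentile_from_t(t_score):
    """Percentile of a T score under the normal convention, in [0, 100]."""
    t = np.asarray(t_score, dtype=float)
    pc = 100.0 * norm.cdf((t - 50.0) / 10.0)
    return float(pc) if pc.ndim == 0 else pc


def t_from_percentile(percentile):
    """Inverse of :func:`percentile_from_t` (undefined at exactly 0/100)."""
    pc = np.asarray(percentile, dtype=float)
    if np.any((pc < 0) | (pc > 100)):
        raise PercentileDomainError("percentile outside [0, 100]")
    t = 50.0 + 10.0 * norm.ppf(pc / 100.0)
    return float(t) if t.ndim == 0 else t


def band7(percentile, scheme: BandScheme = DEFAULT_BANDS):
    return scheme.band7(percentile)


def band3(percentile, scheme: BandScheme = DEFAULT_BANDS):
    return scheme.band3(percentile)


# ---------------------------------------------------------------------------
# cohort scoring


def score_cohort(
    cohort: pd.DataFrame,
    norms: NormativeTable | None = None,
    scheme: BandScheme = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Score a long-format cohort table into the banded ScoredTest table.

    Parameters
    ----------
    cohort
        Long format with columns ``patient_id, test_id, score_id, value,
        value_type`` where value_type is ``"raw"`` or ``"t"``. Raw values
        require ``norms``; T values are taken as already
        direction-harmonized (higher T = better).
    norms
        Normative table for raw -> T conversion.

    Returns
    -------
    DataFrame with columns ``patient_id, test_id, score_id, raw, t_score,
    percentile, band7, band3``. Missing values are dropped.
    """
    required = {"patient_id", "test_id", "score_id", "value", "value_type"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df = cohort.dropna(subset=["value"]).copy()
    df["score_id"] = df["score_id"].map(normalize_score_id)

    bad = set(df["value_type"]) - {"raw", "t"}
    if bad:
        raise ValueError(f"unknown value_type(s): {sorted(bad)}")

    t_scores = np.empty(len(df), dtype=float)
    raws = np.full(len(df), np.nan)
    vals = df["value"].to_numpy(dtype=float)
    kinds = df["value_type"].to_numpy()
    tests = df["test_id"].to_numpy()
    scores = df["score_id"].to_numpy()
    for i in range(len(df)):
        if kinds[i] == "t":
            t_scores[i] = vals[i]
        else:
            if norms is None:
                raise NormativeLookupError(
                    f"raw value supplied for score {scores[i]!r} but no normative table given"
                )
            entry = norms.lookup(tests[i], scores[i])
            raws[i] = vals[i]
            t_scores[i] = t_from_raw(vals[i], entry)

    pc = percentile_from_t(t_scores)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "test_id": tests,
            "score_id": scores,
            "raw": raws,
            "t_score": t_scores,
            "percentile": pc,
            "band7": scheme.band7(pc),
            "band3": scheme.band3(pc),
        }
    )
    return out


# ---------------------------------------------------------------------------
# readers


def read_norms(path) -> NormativeTable:
    """Load a normative table from CSV with columns
    test_id, score_id, ref_mean, ref_sd, direction."""
    df = pd.read_csv(path)
    required = {"test_id", "score_id", "ref_mean", "ref_sd", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"normative table missing columns: {sorted(missing)}")
    entries = [
        NormativeEntry(
            test_id=str(r.test_id),
            score_id=str(r.score_id),
            ref_mean=float(r.ref_mean),
            ref_sd=float(r.ref_sd),
            direction=str(r.direction),
        )
        for r in df.itertuples()
    ]
    return NormativeTable(entries)


def read_cohort_long(path) -> pd.DataFrame:
    """Read a long-format cohort CSV (patient_id, test_id, score_id, value,
    value_type)."""
    df = pd.read_csv(path)
    required = {"patient_id", "test_id", "score_id", "value", "value_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    return df


def read_cohort_wide(
    path,
    value_type: str = "t",
    test_ids: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a wide cohort CSV (one row per patient, one column per score)
    and melt it to the long format accepted by :func:`score_cohort`.

    ``test_ids`` maps score_id -> test_id; by default each score is its own
    test for scores outside the built-in battery, while built-in battery
    scores get their canonical instrument.
    """
    from .battery import BATTERY

    wide = pd.read_csv(path)
    if "patient_id" not in wide.columns:
        raise ValueError("wide cohort file needs a patient_id column")
    builtin = {sid: tid for sid, tid, _, _ in BATTERY}
    if test_ids:
        builtin.update({normalize_score_id(k): v for k, v in test_ids.items()})
    long = wide.melt(id_vars="patient_id", var_name="score_id", value_name="value")
    long["score_id"] = long["score_id"].map(normalize_score_id)
    long["test_id"] = long["score_id"].map(lambda s: builtin.get(s, s))
    long["value_type"] = value_type
    return long[["patient_id", "test_id", "score_id", "value", "value_type"]]
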