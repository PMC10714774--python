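"""Core data containers shared across the pipeline.

The cohort design is longitudinal and multi-site: each allo-HSCT patient is
sampled at three oral sites (gingival crevicular fluid GCF, oral mucosa OM,
supragingival biofilm SB) at up to five timepoints anchored to the stem-cell
infusion (day 0): preconditioning (P), aplasia (A), engraftment (E), and 30
and 75 days after engraftment (E30, E75).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITES: tuple[str, ...] = ("GCF", "OM", "SB")
TIMEPOINTS: tuple[str, ...] = ("P", "A", "E", "E30", "E75")
#: Default day offsets (relative to stem-cell infusion at day 0).
DEFAULT_TIMEPOINT_DAYS: dict[str, int] = {"P": -10, "A": 7, "E": 14, "E30": 44, "E75": 89}

#: Required columns of a sample-metadata table.
META_COLUMNS = ("sample_id", "patient", "site", "timepoint", "day")


class ValidationError(ValueError):
    """A table violated a structural or referential-integrity invariant."""


@dataclass
class CountTable:
    """Samples x taxa table of non-negative integer read counts.

    ``data`` is indexed by sample id (rows) with taxon ids as columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[1] == 0:
            raise ValidationError("no taxa")
        if df.shape[0] == 0:
            raise ValidationError("no samples")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dup}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # accept float only if exactly integral (e.g. parsed "5.0")
            if not np.issubdtype(arr.dtype, np.number):
                raise ValidationError("counts must be numeric integers")
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = self._first_offender(df, lambda v: not np.isfinite(v) or v != np.floor(v))
                raise ValidationError(f"non-integer count at {bad}")
            self.data = df.astype(np.int64)
            arr = self.data.to_numpy()
        if (arr < 0).any():
            bad = self._first_offender(self.data, lambda v: v < 0)
            raise ValidationError(f"negative count at {bad}")

    @staticmethod
    def _first_offender(df: pd.DataFrame, pred) -> str:
        for s in df.index:
            for t in df.columns:
                if pred(df.at[s, t]):
                    return f"sample {s!r}, taxon {t!r} (value {df.at[s, t]!r})"
        return "unknown cell"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total read count."""
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized relative abundances (rows sum to 1)."""
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            zero = list(totals.index[totals == 0])
            raise ValidationError(f"all-zero samples: {zero}")
        return self.data.div(totals, axis=0)

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)].copy())


@dataclass(frozen=True)
class AntibioticCourse:
    """One agent's administration interval, inclusive of both endpoints.

    Days are integers relative to stem-cell infusion (day 0).
    """

    patient: str
    agent: str
    abx_class: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"course {self.agent!r} for {self.patient!r}: start {self.start} > end {self.end}"
            )

    def days(self) -> set[int]:
        return set(range(self.start, self.end + 1))


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table against the closed vocabularies.

    (patient, site, timepoint) must be unique; site and timepoint must come
    from the fixed design vocabularies.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    bad_site = sorted(set(meta["site"]) - set(SITES))
    if bad_site:
        raise ValidationError(f"unknown sites: {bad_site}")
    bad_tp = sorted(set(meta["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValidationError(f"unknown timepoints: {bad_tp}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dup}")
    key = meta[["patient", "site", "timepoint"]].astype(str).agg("|".join, axis=1)
    if key.duplicated().any():
        dup = key[key.duplicated()].tolist()
        raise ValidationError(f"duplicate (patient, site, timepoint): {dup}")
    return meta


def validate_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table: time > 0 and event code in {0, 1, 2}."""
    for c in ("patient", "time", "event"):
        if c not in outcomes.columns:
            raise ValidationError(f"outcomes table missing column {c!r}")
    if (outcomes["time"] <= 0).any():
        bad = outcomes.loc[outcomes["time"] <= 0, "patient"].tolist()
        raise ValidationError(f"non-positive follow-up time for patients: {bad}")
    bad_ev = sorted(set(outcomes["event"]) - {0, 1, 2})
    if bad_ev:
        raise ValidationError(f"event codes outside {{0,1,2}}: {bad_ev}")
    return outcomes


def sample_lookup(meta: pd.DataFrame) -> dict[tuple[str, str, str], str]:
    """Map (patient, site, timepoint) -> sample_id."""
    return {
        (str(r.patient), str(r.site), str(r.timepoint)): str(r.sample_id)
        for r in meta.itertuples(index=False)
    }


@dataclass
class DepthFilterReport:
    """Outcome of the minimum-sequencing-depth inclusion filter."""

    min_reads: int
    n_input: int
    n_retained: int
    excluded: pd.DataFrame = field(repr=False)  # columns: sample_id, total

    def __str__(self) -> str:
        lines = [
            f"depth filter (cutoff {self.min_reads} reads): "
            f"{self.n_retained}/{self.n_input} samples retained"
        ]
        for r in self.excluded.itertuples(index=False):
            lines.append(f"  excluded {r.sample_id}: {r.total} reads")
        return "\n".join(lines)
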