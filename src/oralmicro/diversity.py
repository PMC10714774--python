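"""Depth normalization (SRS) and alpha-diversity dynamics.

Scaling with ranked subsampling (SRS) normalizes every library to a common
depth C_min deterministically: counts are scaled by C_min/total, integer
parts are kept, and the remaining units are assigned one each to taxa ranked
by descending fractional part. Only genuine ties in both fractional part and
scaled value fall back to a seeded random draw, so the procedure is
reproducible and far less noisy than rarefying.

Longitudinal diversity dynamics are condensed per patient and site into
three ecological indices relative to the engraftment perturbation:

* resistance  = D_E / D_P      (fraction of baseline diversity retained at E)
* resilience  = (D_E30 - D_E) / (day_E30 - day_E)   (per-day recovery rate,
  signed: negative when diversity keeps falling after engraftment)
* stability   = D_E30 / D_P    (net retention at E30, combining both)

where D is the Gini-Simpson index 1 - sum(p_i^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountTable, ValidationError

__all__ = [
    "SrsConfig",
    "srs_normalize",
    "srs_normalize_table",
    "gini_simpson",
    "diversity_trajectories",
    "StabilityIndices",
    "stability_indices",
    "stability_table",
]


@dataclass(frozen=True)
class SrsConfig:
    """SRS parameters: target depth ``c_min`` and the tie-breaking seed."""

    c_min: int
    tie_seed: int = 0

    def __post_init__(self) -> None:
        if self.c_min < 1:
            raise ValidationError("c_min must be >= 1")


def srs_normalize(counts_row: np.ndarray, cfg: SrsConfig) -> np.ndarray:
    """Normalize one sample's counts to sum exactly to ``cfg.c_min``.

    Raises if the library is shallower than ``c_min`` — such samples must be
    flagged by the caller, not silently dropped.
    """
    row = np.asarray(counts_row, dtype=np.int64)
    total = int(row.sum())
    if total < cfg.c_min:
        raise ValidationError(
            f"library size {total} below c_min {cfg.c_min}; flag the sample"
        )
    scaled = row * (cfg.c_min / total)
    ints = np.floor(scaled).astype(np.int64)
    remainder = cfg.c_min - int(ints.sum())
    if remainder == 0:
        return ints
    frac = scaled - ints
    rng = np.random.default_rng(cfg.tie_seed)
    jitter = rng.random(len(row))
    # rank by descending fractional part, ties by descending scaled value,
    # remaining ties by seeded random draw
    order = np.lexsort((jitter, -scaled, -frac))
    ints[order[:remainder]] += 1
    return ints


def srs_normalize_table(counts: CountTable, cfg: SrsConfig) -> tuple[CountTable, list[str]]:
    """SRS-normalize every sample; returns (normalized table, flagged ids).

    Samples shallower than ``c_min`` are excluded from the output and
    returned as flagged ids.
    """
    rows, kept, flagged = [], [], []
    for sid in counts.sample_ids:
        row = counts.data.loc[sid].to_numpy()
        try:
            rows.append(srs_normalize(row, cfg))
            kept.append(sid)
        except ValidationError:
            flagged.append(sid)
    if not kept:
        raise ValidationError("every sample fell below c_min")
    out = pd.DataFrame(np.vstack(rows), index=kept, columns=counts.taxon_ids)
    out.index.name = "sample_id"
    return CountTable(out), flagged


def gini_simpson(counts_row: np.ndarray) -> float:
    """Gini-Simpson index 1 - sum(p_i^2) of one sample."""
    row = np.asarray(counts_row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValidationError("cannot compute diversity of an all-zero sample")
    p = row / total
    return float(1.0 - np.dot(p, p))


def diversity_trajectories(counts: CountTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Gini-Simpson merged with patient/site/timepoint metadata."""
    values = {
        sid: gini_simpson(counts.data.loc[sid].to_numpy()) for sid in counts.sample_ids
    }
    out = meta[meta["sample_id"].isin(values)].copy()
    out["gini_simpson"] = out["sample_id"].map(values)
    return out.reset_index(drop=True)


@dataclass
class StabilityIndices:
    """Diversity resistance / resilience / stability for one patient-site."""

    patient: str
    site: str
    resistance: float = field(default=np.nan)
    resilience: float = field(default=np.nan)
    stability: float = field(default=np.nan)
    evaluable: bool = False


def stability_indices(
    patient: str,
    site: str,
    diversity_by_timepoint: dict[str, float],
    day_by_timepoint: dict[str, int],
) -> StabilityIndices:
    """Compute the three indices from a (timepoint -> diversity) map.

    Resistance needs P and E; resilience and stability additionally need
    E30. ``evaluable`` is False whenever any required timepoint is missing
    or baseline diversity is zero (all ratios undefined).
    """
    out = StabilityIndices(patient=patient, site=site)
    d = diversity_by_timepoint
    if "P" not in d or "E" not in d:
        return out
    if d["P"] == 0:
        return out
    out.resistance = d["E"] / d["P"]
    if "E30" not in d:
        return out
    gap = day_by_timepoint["E30"] - day_by_timepoint["E"]
    if gap <= 0:
        raise ValidationError(f"non-positive E->E30 day gap for {patient}/{site}")
    out.resilience = (d["E30"] - d["E"]) / gap
    out.stability = d["E30"] / d["P"]
    out.evaluable = True
    return out


def stability_table(traj: pd.DataFrame) -> pd.DataFrame:
    """Per patient-site stability indices from a diversity-trajectory table."""
    records = []
    for (patient, site), g in traj.groupby(["patient", "site"], sort=True):
        dmap = dict(zip(g["timepoint"], g["gini_simpson"]))
        days = dict(zip(g["timepoint"], g["day"]))
        idx = stability_indices(str(patient), str(site), dmap, days)
        records.append(
            {
                "patient": idx.patient,
                "site": idx.site,
                "resistance": idx.resistance,
                "resilience": idx.resilience,
                "stability": idx.stability,
                "evaluable": idx.evaluable,
            }
        )
    return pd.DataFrame(records)
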