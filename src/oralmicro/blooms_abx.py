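"""Bloom detection, antibiotic-exposure metrics, and association statistics.

A *bloom* is a taxon that is rare at preconditioning (relative abundance
strictly below 1% at P) and reaches dominance (>= 30%) at any later sampled
timepoint of the same patient and oral site. A maximal run of consecutive
dominant sampled timepoints counts as one event, dated at its first
timepoint.

Antibiotic exposure is summarised per patient over a clinical window
(default: preconditioning day to 30 days after engraftment) as
* LOT (length of therapy): number of distinct calendar days under any
  non-prophylactic antibiotic, and
* DOT (days of therapy): agent-days, i.e. the same days summed per agent so
  overlapping agents count multiply.
Routine prophylaxis agents are excluded through a configurable deny-list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import contingency

from .containers import AntibioticCourse, TIMEPOINTS, ValidationError

__all__ = [
    "BloomEvent",
    "detect_blooms",
    "AbxExposure",
    "compute_exposure",
    "exposure_table",
    "class_prevalence_filter",
    "FisherResult",
    "fisher_exact_or",
    "mannwhitney",
    "chisq_prevalence",
    "bonferroni_adjust",
    "bloom_class_association",
    "join_blooms_with_infections",
    "DEFAULT_PROPHYLAXIS_AGENTS",
]

#: Standard prophylaxis agents excluded from exposure metrics.
DEFAULT_PROPHYLAXIS_AGENTS = frozenset({"levofloxacin", "sulfamethoxazole-trimethoprim"})


@dataclass(frozen=True)
class BloomEvent:
    patient: str
    site: str
    taxon: str
    onset: str
    peak_ra: float
    run_length: int


def detect_blooms(
    ra: pd.DataFrame,
    meta: pd.DataFrame,
    baseline_max: float = 0.01,
    dominance_min: float = 0.30,
    include_timepoints: tuple[str, ...] | None = None,
) -> tuple[list[BloomEvent], list[str]]:
    """Scan per-sample relative abundances for bloom events.

    ``ra`` is samples x taxa with rows summing to 1. Baseline uses a strict
    "<" and dominance a ">=" comparison. Patient-sites without a P sample
    cannot be evaluated and are returned in the skip report.
    ``include_timepoints`` restricts which post-P timepoints may host an
    event (e.g. drop E75 when pairing blooms with a P..E30 antibiotic
    window); runs are still formed over sampled timepoints only.
    """
    events: list[BloomEvent] = []
    skipped: list[str] = []
    order = {t: i for i, t in enumerate(TIMEPOINTS)}
    for (patient, site), g in meta.groupby(["patient", "site"], sort=True):
        g = g[g["sample_id"].isin(ra.index)]
        tps = sorted(g["timepoint"], key=order.get)
        if "P" not in tps:
            skipped.append(f"{patient}/{site}: no P sample")
            continue
        by_tp = dict(zip(g["timepoint"], g["sample_id"]))
        post = [t for t in tps if order[t] > order["P"]]
        if include_timepoints is not None:
            post = [t for t in post if t in include_timepoints]
        base = ra.loc[by_tp["P"]]
        for taxon in ra.columns:
            if not base[taxon] < baseline_max:
                continue
            dominant = [ra.at[by_tp[t], taxon] >= dominance_min for t in post]
            i = 0
            while i < len(post):
                if dominant[i]:
                    j = i
                    while j + 1 < len(post) and dominant[j + 1]:
                        j += 1
                    peak = max(float(ra.at[by_tp[t], taxon]) for t in post[i : j + 1])
                    events.append(
                        BloomEvent(
                            patient=str(patient),
                            site=str(site),
                            taxon=str(taxon),
                            onset=post[i],
                            peak_ra=peak,
                            run_length=j - i + 1,
                        )
                    )
                    i = j + 1
                else:
                    i += 1
    return events, skipped


@dataclass
class AbxExposure:
    patient: str
    lot: int
    dot: int
    classes_used: set[str] = field(default_factory=set)
    window: tuple[int, int] = (0, 0)


def compute_exposure(
    courses: list[AntibioticCourse],
    window: tuple[int, int],
    prophylaxis_agents: frozenset[str] | set[str] = DEFAULT_PROPHYLAXIS_AGENTS,
) -> AbxExposure:
    """LOT/DOT and class usage for one patient's courses within a window.

    Intervals are closed on both ends; courses are clipped to the window and
    courses entirely outside it are ignored. LOT counts distinct days under
    any therapy, DOT sums days per agent (overlaps count multiply).
    """
    lo, hi = window
    if lo > hi:
        raise ValidationError(f"invalid window {window}")
    patients = {c.patient for c in courses}
    if len(patients) > 1:
        raise ValidationError(f"courses span multiple patients: {sorted(patients)}")
    patient = patients.pop() if patients else ""
    union_days: set[int] = set()
    agent_days: dict[str, set[int]] = {}
    classes: set[str] = set()
    for c in courses:
        if c.agent.lower() in {a.lower() for a in prophylaxis_agents}:
            continue
        days = {d for d in c.days() if lo <= d <= hi}
        if not days:
            continue
        union_days |= days
        agent_days.setdefault(c.agent, set()).update(days)
        classes.add(c.abx_class)
    dot = sum(len(v) for v in agent_days.values())
    return AbxExposure(
        patient=patient,
        lot=len(union_days),
        dot=dot,
        classes_used=classes,
        window=(lo, hi),
    )


def exposure_table(
    courses: list[AntibioticCourse],
    windows: dict[str, tuple[int, int]],
    prophylaxis_agents: frozenset[str] | set[str] = DEFAULT_PROPHYLAXIS_AGENTS,
) -> list[AbxExposure]:
    """Per-patient exposures; ``windows`` maps patient -> (start, end) days.

    Patients with a window but no courses get a zero-exposure record.
    """
    by_patient: dict[str, list[AntibioticCourse]] = {p: [] for p in windows}
    for c in courses:
        if c.patient in by_patient:
            by_patient[c.patient].append(c)
    out = []
    for patient, plist in by_patient.items():
        exp = compute_exposure(plist, windows[patient], prophylaxis_agents)
        exp.patient = patient
        out.append(exp)
    return out


def class_prevalence_filter(
    exposures: list[AbxExposure], min_frac: float = 0.20
) -> list[str]:
    """Classes used by at least ceil(min_frac * n_patients) patients."""
    n = len(exposures)
    if n == 0:
        return []
    need = int(np.ceil(min_frac * n))
    counts: dict[str, int] = {}
    for e in exposures:
        for c in e.classes_used:
            counts[c] = counts.get(c, 0) + 1
    return sorted(c for c, k in counts.items() if k >= need)


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    note: str = ""


def fisher_exact_or(table) -> FisherResult:
    """Fisher's exact test with the conditional-MLE odds ratio.

    The point estimate is the conditional maximum-likelihood odds ratio of
    the noncentral hypergeometric model (the estimate R's ``fisher.test``
    prints), not the sample cross-product ratio. A zero margin leaves the OR
    undefined (NaN, p = 1); a zero cell with positive margins yields the
    boundary estimate 0 or +inf.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FisherResult(odds_ratio=float("nan"), p_value=1.0, note="zero margin")
    res = contingency.odds_ratio(t, kind="conditional")
    p = stats.fisher_exact(t, alternative="two-sided")[1]
    note = ""
    if np.isinf(res.statistic) or res.statistic == 0:
        note = "zero cell: boundary estimate"
    return FisherResult(odds_ratio=float(res.statistic), p_value=float(p), note=note)


def mannwhitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (first group) with a two-sided p-value.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's ``method='auto'`` rule).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def chisq_prevalence(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2 x k prevalence
    table (rows: with/without blooms; columns: oral sites)."""
    t = np.asarray(table, dtype=float)
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni correction over the tested antibiotic classes."""
    p = np.asarray(list(p_values), dtype=float)
    return np.minimum(p * len(p), 1.0)


def bloom_class_association(
    bloomed_patients: set[str],
    exposures: list[AbxExposure],
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """Per antibiotic class: 2x2 Fisher test of class use vs blooming.

    ``classes`` defaults to those passing the 20% prevalence filter; p-values
    are Bonferroni-adjusted over the retained classes.
    """
    if classes is None:
        classes = class_prevalence_filter(exposures)
    rows = []
    for cls in classes:
        used_bloom = sum(
            1 for e in exposures if cls in e.classes_used and e.patient in bloomed_patients
        )
        used_nobloom = sum(
            1 for e in exposures if cls in e.classes_used and e.patient not in bloomed_patients
        )
        nouse_bloom = sum(
            1 for e in exposures if cls not in e.classes_used and e.patient in bloomed_patients
        )
        nouse_nobloom = sum(
            1 for e in exposures if cls not in e.classes_used and e.patient not in bloomed_patients
        )
        res = fisher_exact_or([[used_bloom, nouse_bloom], [used_nobloom, nouse_nobloom]])
        rows.append(
            {
                "abx_class": cls,
                "used_bloom": used_bloom,
                "used_nobloom": used_nobloom,
                "nouse_bloom": nouse_bloom,
                "nouse_nobloom": nouse_nobloom,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bonferroni_adjust(out["p_value"])
    return out


def join_blooms_with_infections(
    events: list[BloomEvent], infections: pd.DataFrame
) -> pd.DataFrame:
    """Join bloom events with a user-supplied infection table on patient
    (and taxon/genus when the infection table carries one). Purely a
    convenience join; no causal call is made."""
    ev = pd.DataFrame([vars(e) for e in events])
    if ev.empty or infections.empty:
        return pd.DataFrame()
    keys = ["patient"] + (["taxon"] if "taxon" in infections.columns else [])
    inf = infections.copy()
    inf["patient"] = inf["patient"].astype(str)
    ev["patient"] = ev["patient"].astype(str)
    return ev.merge(inf, on=keys, how="inner", suffixes=("_bloom", "_infection"))
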