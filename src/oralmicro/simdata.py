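"""Synthetic longitudinal multi-site cohorts with known ground truth.

The generator emulates the *processed* level of an allo-HSCT oral-microbiome
study: per patient, per oral site (GCF/OM/SB), per timepoint (P, A, E, E30,
E75) genus-level compositions with

* a diversity nadir and maximal inter-patient dispersion at engraftment
  (each patient-site drifts toward its own low-diversity dysbiotic state,
  the "many unhappy families" structure the downstream dispersion
  statistics assume),
* injected blooms (a taxon rare at P raised to dominance at one or more
  later timepoints) recorded as ground truth,
* antibiotic timelines (per-class usage probabilities and course lengths,
  plus universal prophylaxis courses that exercise the deny-list), and
* competing-risks survival outcomes in which true non-recoverers carry a
  multiplied hazard of the event of interest.

Compositions are drawn hierarchically: a site-level mean profile, a patient
baseline Dirichlet around it, and per-timepoint Dirichlet noise around the
interpolation between baseline and the patient's dysbiotic target. The
interpolation weight and the noise concentration both return to their
baseline values when ``perturbation_depth`` is zero, so the unperturbed
generator is exchangeable across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import os

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as omio
from .containers import (
    AntibioticCourse,
    CountTable,
    DEFAULT_TIMEPOINT_DAYS,
    SITES,
    ValidationError,
)

__all__ = ["CohortConfig", "CohortBundle", "generate_tree", "generate_cohort"]


#: Class usage probabilities and mean course length (days); probabilities
#: mirror the usage mix reported for allo-HSCT cohorts (cephalosporins and
#: carbapenems most frequent, glycopeptides close behind).
DEFAULT_ABX_MODEL: dict[str, tuple[float, float]] = {
    "cephalosporins": (0.73, 8.0),
    "carbapenems": (0.63, 8.0),
    "glycopeptides": (0.60, 9.0),
    "penicillins": (0.23, 6.0),
    "quinolones": (0.16, 6.0),
    "macrolides": (0.10, 5.0),
}

_CLASS_AGENT = {
    "cephalosporins": "cefepime",
    "carbapenems": "meropenem",
    "glycopeptides": "vancomycin",
    "penicillins": "piperacillin-tazobactam",
    "quinolones": "ciprofloxacin",
    "macrolides": "azithromycin",
}

#: Dysbiotic-mixing profile per timepoint. The transplant-phase values
#: (P, A, E) and the recoverers' residual displacement are scaled by
#: perturbation_depth; true non-recoverers instead *remain* in their
#: dysbiotic state after engraftment (an alternative stable state, not a
#: scaled dose of the perturbation), so their post-engraftment weights are
#: absolute.
_MIX_PROFILE = {"P": 0.0, "A": 0.6, "E": 1.0}
_MIX_POST_RECOVERER = {"E30": 0.20, "E75": 0.08}
_MIX_POST_NONRECOVERER = {"E30": 1.0, "E75": 0.90}


@dataclass(frozen=True)
class HazardModel:
    """Latent cause-specific exponential hazards with administrative
    censoring; non-recoverers multiply the event-of-interest hazard."""

    baseline_hazard: float = 1.0 / 400.0  # per day, event of interest
    log_hr_nonrecovery: float = float(np.log(5.0))
    competing_hazard: float = 1.0 / 900.0
    censor_horizon: float = 365.0


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 30
    n_taxa: int = 120
    sites: tuple[str, ...] = SITES
    timepoint_days: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINT_DAYS)
    )
    library_size_range: tuple[int, int] = (5_000, 60_000)
    #: Dirichlet noise concentration per timepoint; the low value at E
    #: encodes the engraftment perturbation (more dispersion).
    dirichlet_concentration: dict[str, float] = field(
        default_factory=lambda: {"P": 60.0, "A": 25.0, "E": 6.0, "E30": 25.0, "E75": 40.0}
    )
    perturbation_depth: float = 0.65
    bloom_rate: float = 2.6  # expected injected blooms per patient
    bloom_dominance: float = 0.5
    abx_exposure_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ABX_MODEL)
    )
    hazard_model: HazardModel = field(default_factory=HazardModel)
    p_recovery: float = 0.74
    dropout_rate: float = 0.03  # post-engraftment sample dropout
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValidationError("n_taxa must be >= 3")
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        days = [self.timepoint_days[t] for t in self.timepoints]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("timepoint day offsets must be strictly increasing")
        if not 0 <= self.perturbation_depth <= 1:
            raise ValidationError("perturbation_depth must be in [0, 1]")
        for p in (self.p_recovery, self.dropout_rate):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0, 1]")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValidationError("invalid library_size_range")
        if self.bloom_rate < 0:
            raise ValidationError("bloom_rate must be >= 0")
        if not 0.3 <= self.bloom_dominance < 1:
            raise ValidationError("bloom_dominance must be in [0.3, 1)")

    @property
    def timepoints(self) -> tuple[str, ...]:
        return tuple(self.timepoint_days.keys())


@dataclass
class CohortBundle:
    counts: CountTable
    meta: pd.DataFrame
    tree: TreeNode
    abx: list[AntibioticCourse]
    outcomes: pd.DataFrame
    truth: dict

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        omio.write_count_table(self.counts, os.path.join(outdir, "counts.tsv"))
        omio.write_metadata(self.meta, os.path.join(outdir, "metadata.csv"))
        omio.write_newick(self.tree, os.path.join(outdir, "tree.nwk"))
        omio.write_abx(self.abx, os.path.join(outdir, "antibiotics.csv"))
        omio.write_outcomes(self.outcomes, os.path.join(outdir, "outcomes.csv"))
        truth_rows = [
            {"patient": p, "kind": "recovered", "value": str(v)}
            for p, v in sorted(self.truth["recovered"].items())
        ] + [
            {
                "patient": b["patient"],
                "kind": "bloom",
                "value": f"{b['site']}|{b['taxon']}|{','.join(b['timepoints'])}",
            }
            for b in self.truth["blooms"]
        ]
        pd.DataFrame(truth_rows, columns=["patient", "kind", "value"]).to_csv(
            os.path.join(outdir, "truth.csv"), index=False
        )


def generate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Random coalescent topology over taxon_1..taxon_n with positive
    branch lengths (rooted, binary)."""
    if n_taxa < 2:
        raise ValidationError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"taxon_{i + 1}") for i in range(n_taxa)]
    heights = [0.0] * n_taxa
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        ha, hb = heights[j], heights[i]
        a.length = max(t - ha, 1e-9)
        b.length = max(t - hb, 1e-9)
        parent = TreeNode(children=[b, a])
        del nodes[j], heights[j]
        nodes[i], heights[i] = parent, t
    root = nodes[0]
    root.length = None
    return root


def _cohort_tree(n_taxa: int, seed: int) -> tuple[TreeNode, np.ndarray]:
    """Cohort phylogeny: a commensal clade and an opportunist clade joined
    at the root; returns (tree, opportunist leaf indices).

    Opportunistic dominators and bloomers (enterococci, lactobacilli,
    staphylococci in the real system) are phylogenetically coherent and
    distant from the abundant commensals; placing them in their own basal
    clade is what makes dysbiotic states register as large UniFrac
    displacements. Each clade is itself a random coalescent topology.
    """
    rng = np.random.default_rng(seed)
    s_com, s_opp = rng.integers(0, 2**31 - 1, size=2)
    n_opp = min(max(3, n_taxa // 6), n_taxa - 2)
    n_com = n_taxa - n_opp
    com = generate_tree(n_com, int(s_com))
    if n_opp >= 2:
        opp = generate_tree(n_opp, int(s_opp))
        for tip in opp.tips():
            tip.name = f"taxon_{int(tip.name.split('_')[1]) + n_com}"
    else:
        opp = TreeNode(name=f"taxon_{n_taxa}")
    com.length = 0.8
    opp.length = 0.8
    tree = TreeNode(children=[com, opp])
    return tree, np.arange(n_com, n_taxa)


def _site_profiles(
    rng: np.random.Generator, n_taxa: int, sites, pool: np.ndarray
) -> dict[str, np.ndarray]:
    """Site-level mean compositions: shared lognormal rank-abundance
    backbone with site-specific tilts (sites share core genera but differ
    in their typical profiles). Opportunist-clade taxa are near-absent from
    healthy baselines."""
    backbone = rng.lognormal(mean=0.0, sigma=1.6, size=n_taxa)
    backbone[pool] *= 1e-4
    out = {}
    for s in sites:
        tilt = rng.lognormal(mean=0.0, sigma=0.7, size=n_taxa)
        w = backbone * tilt
        out[s] = w / w.sum()
    return out


def _dysbiotic_state(
    rng: np.random.Generator, n_taxa: int, pool: np.ndarray
) -> np.ndarray:
    """Patient-specific low-diversity dysbiotic composition: a handful of
    opportunist-clade taxa carry nearly all mass."""
    k = int(rng.integers(2, min(5, len(pool) + 1)))
    chosen = pool[rng.choice(len(pool), size=k, replace=False)]
    weights = rng.dirichlet(np.full(k, 0.6))
    comp = np.full(n_taxa, 1e-5)
    comp[chosen] += weights
    return comp / comp.sum()


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Draw a complete cohort bundle; identical config+seed give identical
    bundles."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)
    tree, pool = _cohort_tree(cfg.n_taxa, int(seeds[0]))
    comp_rng = np.random.default_rng(int(seeds[1]))
    bloom_rng = np.random.default_rng(int(seeds[2]))
    abx_rng = np.random.default_rng(int(seeds[3]))
    out_rng = np.random.default_rng(int(seeds[4]))
    drop_rng = np.random.default_rng(int(seeds[5]))

    taxa = [f"taxon_{i + 1}" for i in range(cfg.n_taxa)]
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    site_means = _site_profiles(comp_rng, cfg.n_taxa, cfg.sites, pool)
    recovered = {p: bool(out_rng.random() < cfg.p_recovery) for p in patients}

    # plan bloom injections (at most one per patient-site so injected
    # dominance levels never collide within one sample)
    bloom_truth: list[dict] = []
    planned: dict[tuple[str, str], dict] = {}
    post_tps = [t for t in cfg.timepoints if t != "P" and t != "E75"]
    onset_probs = np.array(
        [{"A": 0.25, "E": 0.55, "E30": 0.20}.get(t, 0.0) for t in post_tps]
    )
    onset_probs = onset_probs / onset_probs.sum() if onset_probs.sum() else None
    for p in patients:
        n_events = min(bloom_rng.poisson(cfg.bloom_rate), len(cfg.sites))
        free_sites = list(cfg.sites)
        for _ in range(n_events):
            if not free_sites or onset_probs is None:
                break
            site = free_sites.pop(int(bloom_rng.integers(len(free_sites))))
            onset = post_tps[int(bloom_rng.choice(len(post_tps), p=onset_probs))]
            run = 1 if bloom_rng.random() < 0.8 else 2
            tps = list(cfg.timepoints)
            i0 = tps.index(onset)
            run_tps = tps[i0 : min(i0 + run, len(tps))]
            planned[(p, site)] = {"onset": onset, "run_tps": run_tps}

    # per patient-site baselines and dysbiotic targets
    baselines: dict[tuple[str, str], np.ndarray] = {}
    dysbiotic: dict[tuple[str, str], np.ndarray] = {}
    conc_p = cfg.dirichlet_concentration["P"]
    for p in patients:
        for s in cfg.sites:
            base = comp_rng.dirichlet(site_means[s] * 200.0 + 1e-3)
            baselines[(p, s)] = base
            dysbiotic[(p, s)] = _dysbiotic_state(comp_rng, cfg.n_taxa, pool)

    # choose bloom taxa: rare at baseline and absent from the dysbiotic state
    for (p, s), plan in planned.items():
        base = baselines[(p, s)]
        dys = dysbiotic[(p, s)]
        candidates = np.flatnonzero((base < 1e-3) & (dys < 1e-3))
        if candidates.size == 0:
            continue
        ti = int(candidates[bloom_rng.integers(candidates.size)])
        plan["taxon_idx"] = ti
        bloom_truth.append(
            {
                "patient": p,
                "site": s,
                "taxon": taxa[ti],
                "onset": plan["onset"],
                "timepoints": plan["run_tps"],
            }
        )

    rows, meta_rows = [], []
    sample_ids = []
    for p in patients:
        for s in cfg.sites:
            base = baselines[(p, s)]
            dys = dysbiotic[(p, s)]
            plan = planned.get((p, s), {})
            bloom_tps = set(plan.get("run_tps", [])) if "taxon_idx" in plan else set()
            for t in cfg.timepoints:
                profile = _MIX_PROFILE.get(t)
                if profile is not None:
                    w = cfg.perturbation_depth * profile
                elif recovered[p]:
                    w = cfg.perturbation_depth * _MIX_POST_RECOVERER[t]
                else:
                    # persistence of the dysbiotic state is absolute (an
                    # alternative stable state), but with no perturbation
                    # there is nothing to fail to recover from
                    w = _MIX_POST_NONRECOVERER[t] if cfg.perturbation_depth > 0 else 0.0
                mean = (1 - w) * base + w * dys
                conc = (1 - w) * conc_p + w * cfg.dirichlet_concentration[t]
                comp = comp_rng.dirichlet(np.maximum(mean * conc, 1e-6))
                ti = plan.get("taxon_idx")
                if ti is not None:
                    if t == "P" and comp[ti] > 2e-3:
                        # keep the bloom taxon genuinely rare at baseline
                        comp[ti] = 2e-4
                        comp = comp / comp.sum()
                    if t in bloom_tps:
                        dom = cfg.bloom_dominance
                        comp = comp * (1 - dom) / (1 - comp[ti]) if comp[ti] < 1 else comp
                        comp[ti] = dom
                        comp = comp / comp.sum()
                lib = int(
                    comp_rng.integers(
                        cfg.library_size_range[0], cfg.library_size_range[1] + 1
                    )
                )
                counts = comp_rng.multinomial(lib, comp / comp.sum())
                sid = f"{p}_{s}_{t}"
                # dropout only after engraftment, never a bloom-bearing sample
                droppable = (
                    cfg.timepoint_days[t] > cfg.timepoint_days.get("E", 0)
                    and t not in bloom_tps
                )
                if droppable and drop_rng.random() < cfg.dropout_rate:
                    continue
                rows.append(counts)
                sample_ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "patient": p,
                        "site": s,
                        "timepoint": t,
                        "day": cfg.timepoint_days[t],
                    }
                )

    counts = CountTable(
        pd.DataFrame(np.vstack(rows), index=sample_ids, columns=taxa).rename_axis(
            "sample_id"
        )
    )
    meta = pd.DataFrame(meta_rows)

    # antibiotic timelines
    abx: list[AntibioticCourse] = []
    window_lo = cfg.timepoint_days["P"]
    window_hi = cfg.timepoint_days.get("E30", cfg.timepoint_days[cfg.timepoints[-1]])
    for p in patients:
        # universal prophylaxis (excluded from exposure metrics by deny-list)
        abx.append(
            AntibioticCourse(p, "levofloxacin", "quinolones", window_lo, window_hi)
        )
        for cls, (prob, mean_len) in cfg.abx_exposure_model.items():
            if abx_rng.random() >= prob:
                continue
            n_courses = 1 + int(abx_rng.random() < 0.3)
            for _ in range(n_courses):
                length = 1 + int(abx_rng.poisson(max(mean_len - 1, 0.0)))
                start = int(abx_rng.integers(window_lo, max(window_hi - length, window_lo) + 1))
                abx.append(
                    AntibioticCourse(
                        p, _CLASS_AGENT[cls], cls, start, start + length - 1
                    )
                )

    # competing-risks outcomes via latent cause-specific exponentials
    hz = cfg.hazard_model
    out_rows = []
    for p in patients:
        lam1 = hz.baseline_hazard * (
            1.0 if recovered[p] else float(np.exp(hz.log_hr_nonrecovery))
        )
        t1 = out_rng.exponential(1.0 / lam1)
        t2 = out_rng.exponential(1.0 / hz.competing_hazard)
        t = min(t1, t2, hz.censor_horizon)
        event = 0 if t == hz.censor_horizon else (1 if t1 <= t2 else 2)
        out_rows.append(
            {
                "patient": p,
                "time": max(float(t), 1e-6),
                "event": event,
                "age": float(np.round(out_rng.uniform(25, 65), 1)),
            }
        )
    outcomes = pd.DataFrame(out_rows)

    return CohortBundle(
        counts=counts,
        meta=meta,
        tree=tree,
        abx=abx,
        outcomes=outcomes,
        truth={"recovered": recovered, "blooms": bloom_truth},
    )
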