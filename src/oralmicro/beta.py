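"""Compositional dissimilarity: weighted UniFrac, ordination, PERMANOVA,
and the distance-based summaries used to describe longitudinal dynamics.

Weighted UniFrac between two relative-abundance vectors p, q on a rooted
tree is the branch-length-weighted L1 difference of subtree mass:

    W_raw(p, q) = sum_b  l_b * |P_b - Q_b|

with P_b the fraction of community p descending from branch b. The
normalized form divides by D = sum_leaves depth_leaf * (p_leaf + q_leaf)
(depth = root-to-leaf path length), bounding the distance to [0, 1]; the
bounded form is the default because the downstream recovery threshold (0.5)
presupposes a bounded scale.

The kernel is vectorized: one branch x taxon incidence matrix is built per
tree and reused for every pair, which makes whole-cohort distance matrices
cheap. Group statistics (PERMANOVA pseudo-F, distance to group centroid via
the Gower identity) operate on the distance matrix directly and never
require an explicit embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .containers import CountTable, TIMEPOINTS, ValidationError, sample_lookup

__all__ = [
    "TreeKernel",
    "weighted_unifrac",
    "unifrac_distance_matrix",
    "OrdinationResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "dist_to_group_centroid",
    "pairwise_dispersion",
    "min_between_site_distance",
    "consecutive_shift_rate",
    "compositional_stability",
]


class TreeKernel:
    """Branch incidence representation of a rooted tree for fast UniFrac.

    Rows of ``incidence`` are branches (every node except the root), columns
    follow ``taxa`` order; entry 1 marks a taxon descending from the branch.
    """

    def __init__(self, tree: TreeNode, taxa: list[str]):
        leaf_index = {t: i for i, t in enumerate(taxa)}
        tree_leaves = {tip.name for tip in tree.tips()}
        missing = sorted(set(taxa) - tree_leaves)
        if missing:
            raise ValidationError(f"taxa missing from tree: {missing}")
        self.taxa = list(taxa)
        rows, lengths = [], []
        # postorder so children's leaf sets are available bottom-up
        leafsets: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            mask = np.zeros(len(taxa), dtype=bool)
            if node.is_tip():
                if node.name in leaf_index:
                    mask[leaf_index[node.name]] = True
            else:
                for child in node.children:
                    mask |= leafsets[id(child)]
            leafsets[id(node)] = mask
            if not node.is_root():
                if node.length is None or node.length < 0:
                    raise ValidationError("tree branches must have non-negative lengths")
                rows.append(mask)
                lengths.append(float(node.length))
        self.incidence = np.array(rows, dtype=float)
        self.lengths = np.asarray(lengths, dtype=float)
        # root-to-leaf depths for the normalization divisor
        self.depths = self.lengths @ self.incidence

    def branch_mass(self, abundances: np.ndarray) -> np.ndarray:
        """Subtree mass per branch for each row of relative abundances."""
        return np.atleast_2d(abundances) @ self.incidence.T


def weighted_unifrac(
    p: np.ndarray,
    q: np.ndarray,
    tree: TreeNode,
    taxa: list[str] | None = None,
    normalized: bool = True,
    _kernel: TreeKernel | None = None,
) -> float:
    """Weighted UniFrac distance between two relative-abundance vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if taxa is None:
        taxa = [tip.name for tip in tree.tips()]
    if len(p) != len(taxa) or len(q) != len(taxa):
        raise ValidationError("abundance vectors must align with the taxon list")
    kernel = _kernel if _kernel is not None else TreeKernel(tree, taxa)
    pb, qb = kernel.branch_mass(np.vstack([p, q]))
    raw = float(np.sum(kernel.lengths * np.abs(pb - qb)))
    if not normalized:
        return raw
    divisor = float(kernel.depths @ (p + q))
    if divisor == 0:
        return 0.0
    return raw / divisor


def unifrac_distance_matrix(
    counts: CountTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """All-pairs weighted UniFrac over a count table.

    Relative abundances are computed from the (unrarefied) counts; depth
    normalization is reserved for alpha diversity.
    """
    ra = counts.relative_abundance().to_numpy()
    kernel = TreeKernel(tree, counts.taxon_ids)
    mass = kernel.branch_mass(ra)  # samples x branches
    n = mass.shape[0]
    dm = np.zeros((n, n))
    if normalized:
        leaf_mass = ra @ kernel.depths  # per-sample sum depth_leaf * p_leaf
    weighted = mass * kernel.lengths
    for i in range(n):
        raw = np.abs(weighted[i] - weighted[i + 1 :]).sum(axis=1)
        if normalized:
            div = leaf_mass[i] + leaf_mass[i + 1 :]
            raw = np.divide(raw, div, out=np.zeros_like(raw), where=div > 0)
        dm[i, i + 1 :] = raw
    dm = dm + dm.T
    return DistanceMatrix(dm, ids=counts.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA coordinates on the positive-eigenvalue axes."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical scaling (Gower double-centering + eigendecomposition).

    Axes with non-positive eigenvalues are dropped; their (negative)
    eigenvalues are still visible through the scikit-bio backend if needed.
    """
    if d.shape[0] < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(d, method="eigh")
    eig = res.eigvals.to_numpy()
    tol = max(1e-12, np.abs(eig).max() * 1e-12) if eig.size else 0.0
    keep = eig > tol
    coords = res.samples.loc[:, keep].copy()
    coords.index = list(d.ids)
    eigk = eig[keep]
    total = eig[eig > 0].sum()
    prop = eigk / total if total > 0 else np.zeros_like(eigk)
    return OrdinationResult(coordinates=coords, eigenvalues=eigk, proportion_explained=prop)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int
    n_samples: int
    n_groups: int
    singleton_groups: bool = False


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with a seeded permutation p-value.

    pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)) with the sums of
    squares computed from squared distances; p uses the add-one estimator
    (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    labels = np.asarray(list(groups))
    if len(labels) != d.shape[0]:
        raise ValidationError("one group label per sample required")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    singleton = bool(np.min(np.bincount(codes)) < 2)
    d2 = np.asarray(d.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, k) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        n_samples=d.shape[0],
        n_groups=k,
        singleton_groups=singleton,
    )


def dist_to_group_centroid(d: DistanceMatrix, group_ids, x_id: str) -> float:
    """Distance from sample ``x_id`` to the centroid of ``group_ids``.

    Uses the Gower identity on squared distances, so no embedding is needed:
        d^2(x, c_G) = (1/|G|) sum_g d^2(x, g)
                      - (1/(2|G|^2)) sum_{g,g'} d^2(g, g')
    Small negative values (non-Euclidean input) are clipped to 0 with a
    warning.
    """
    group_ids = list(group_ids)
    if not group_ids:
        raise ValidationError("centroid of an empty group is undefined")
    m = len(group_ids)
    dx2 = np.array([d[x_id, g] ** 2 for g in group_ids])
    dg2 = np.array([[d[g, h] ** 2 for h in group_ids] for g in group_ids])
    sq = dx2.mean() - dg2.sum() / (2.0 * m * m)
    if sq < 0:
        if sq < -1e-10:
            warnings.warn(
                f"negative squared centroid distance ({sq:.3g}) clipped to 0; "
                "distance matrix is not Euclidean-embeddable",
                stacklevel=2,
            )
        sq = 0.0
    return float(np.sqrt(sq))


def pairwise_dispersion(d: DistanceMatrix, group_ids) -> list[float]:
    """All |G|(|G|-1)/2 within-group pairwise distances."""
    group_ids = list(group_ids)
    return [
        float(d[group_ids[i], group_ids[j]])
        for i in range(len(group_ids))
        for j in range(i + 1, len(group_ids))
    ]


def min_between_site_distance(
    d: DistanceMatrix, meta: pd.DataFrame, patient: str, timepoint: str
) -> float | None:
    """Minimum distance between oral sites of one patient at one timepoint.

    Returns None (unevaluable) when fewer than two sites were sampled.
    """
    present = set(d.ids)
    rows = meta[
        (meta["patient"].astype(str) == str(patient))
        & (meta["timepoint"] == timepoint)
        & meta["sample_id"].isin(present)
    ]
    ids = list(rows["sample_id"])
    if len(ids) < 2:
        return None
    return min(
        float(d[ids[i], ids[j]])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    )


def consecutive_shift_rate(
    d: DistanceMatrix, meta: pd.DataFrame, patient: str, site: str
) -> dict[str, float]:
    """Per-day compositional shift between consecutive sampled timepoints.

    Only canonically adjacent timepoint pairs (P-A, A-E, E-E30, E30-E75) with
    both samples present contribute; a missing middle timepoint breaks the
    chain rather than bridging it.
    """
    lookup = sample_lookup(meta)
    present = set(d.ids)
    days = {
        str(r.timepoint): int(r.day)
        for r in meta[
            (meta["patient"].astype(str) == str(patient)) & (meta["site"] == site)
        ].itertuples(index=False)
    }
    out: dict[str, float] = {}
    for t0, t1 in zip(TIMEPOINTS[:-1], TIMEPOINTS[1:]):
        s0 = lookup.get((str(patient), site, t0))
        s1 = lookup.get((str(patient), site, t1))
        if s0 is None or s1 is None or s0 not in present or s1 not in present:
            continue
        gap = days[t1] - days[t0]
        if gap == 0:
            raise ValidationError(
                f"zero-day gap between {t0} and {t1} for {patient}/{site}"
            )
        out[f"{t0}-{t1}"] = float(d[s0, s1]) / gap
    return out


def compositional_stability(
    d: DistanceMatrix, meta: pd.DataFrame, patient: str, site: str
) -> float | None:
    """Compositional stability = 1 - d(P, E30); None when either is missing."""
    lookup = sample_lookup(meta)
    present = set(d.ids)
    s_p = lookup.get((str(patient), site, "P"))
    s_e30 = lookup.get((str(patient), site, "E30"))
    if s_p is None or s_e30 is None or s_p not in present or s_e30 not in present:
        return None
    return 1.0 - float(d[s_p, s_e30])
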