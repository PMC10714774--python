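"""Readers/writers for the pipeline's external formats and the depth filter.

Formats are deliberately plain: a QIIME-style TSV feature table (taxa rows x
sample columns), CSV tables for sample metadata, antibiotic courses and
survival outcomes, and newick for the phylogeny.
"""

from __future__ import annotations

import os

import pandas as pd
from skbio import TreeNode

from .containers import (
    AntibioticCourse,
    CountTable,
    DepthFilterReport,
    ValidationError,
    validate_metadata,
    validate_outcomes,
)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "read_abx",
    "write_abx",
    "read_outcomes",
    "write_outcomes",
    "filter_min_depth",
    "check_tree_covers_taxa",
    "validate_bundle_files",
]


def read_count_table(path: str | os.PathLike) -> CountTable:
    """Read a TSV feature table with taxa as rows and samples as columns."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValidationError("no taxa") from None
    if df.shape[0] == 0:
        raise ValidationError("no taxa")
    # stored orientation is taxa x samples; in memory we use samples x taxa
    wide = df.T
    wide.index.name = "sample_id"
    for col in wide.columns:
        coerced = pd.to_numeric(wide[col], errors="coerce")
        if coerced.isna().any():
            s = wide.index[coerced.isna()][0]
            raise ValidationError(
                f"non-numeric count at sample {s!r}, taxon {col!r} "
                f"(value {wide.at[s, col]!r})"
            )
        wide[col] = coerced
    return CountTable(wide)


def write_count_table(counts: CountTable, path: str | os.PathLike) -> None:
    out = counts.data.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample_id": str, "patient": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_metadata(meta).to_csv(path, index=False)


def read_newick(path: str | os.PathLike) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"branch above {node.name or '<internal>'} has no length"
            )
    return tree


def write_newick(tree: TreeNode, path: str | os.PathLike) -> None:
    tree.write(str(path), format="newick")


def read_abx(path: str | os.PathLike) -> list[AntibioticCourse]:
    df = pd.read_csv(path, dtype={"patient": str})
    required = {"patient", "agent", "abx_class", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"antibiotic table missing columns: {sorted(missing)}")
    return [
        AntibioticCourse(
            patient=str(r.patient),
            agent=str(r.agent),
            abx_class=str(r.abx_class),
            start=int(r.start),
            end=int(r.end),
        )
        for r in df.itertuples(index=False)
    ]


def write_abx(courses: list[AntibioticCourse], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "patient": c.patient,
                "agent": c.agent,
                "abx_class": c.abx_class,
                "start": c.start,
                "end": c.end,
            }
            for c in courses
        ]
    ).to_csv(path, index=False)


def read_outcomes(path: str | os.PathLike) -> pd.DataFrame:
    return validate_outcomes(pd.read_csv(path, dtype={"patient": str}))


def write_outcomes(outcomes: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_outcomes(outcomes).to_csv(path, index=False)


def filter_min_depth(
    counts: CountTable, min_reads: int = 3000
) -> tuple[CountTable, DepthFilterReport]:
    """Apply the minimum-sequencing-depth inclusion filter.

    Samples whose library size is >= ``min_reads`` are retained (the boundary
    sample at exactly the cutoff is kept); excluded samples are listed in the
    report rather than silently dropped.
    """
    totals = counts.library_sizes
    keep = totals >= min_reads
    excluded = pd.DataFrame(
        {"sample_id": totals.index[~keep], "total": totals[~keep].to_numpy()}
    ).reset_index(drop=True)
    report = DepthFilterReport(
        min_reads=min_reads,
        n_input=len(totals),
        n_retained=int(keep.sum()),
        excluded=excluded,
    )
    if report.n_retained == 0:
        raise ValidationError("depth filter removed every sample")
    return counts.subset_samples(totals.index[keep]), report


def check_tree_covers_taxa(tree: TreeNode, counts: CountTable) -> None:
    """Require every taxon in the table to be a leaf of the tree."""
    leaves = {t.name for t in tree.tips()}
    missing = sorted(set(counts.taxon_ids) - leaves)
    if missing:
        raise ValidationError(f"taxa missing from tree: {missing}")


def validate_bundle_files(
    counts: CountTable,
    meta: pd.DataFrame,
    tree: TreeNode | None = None,
    abx: list[AntibioticCourse] | None = None,
    outcomes: pd.DataFrame | None = None,
) -> list[str]:
    """Cross-file referential-integrity report.

    Raises :class:`ValidationError` naming the first broken reference;
    returns informational notes (e.g. metadata rows without a sample, which
    is legal when samples were dropped by the depth filter).
    """
    notes: list[str] = []
    meta_ids = set(meta["sample_id"].astype(str))
    orphan_samples = sorted(set(counts.sample_ids) - meta_ids)
    if orphan_samples:
        raise ValidationError(f"samples without metadata: {orphan_samples}")
    spare = sorted(meta_ids - set(counts.sample_ids))
    if spare:
        notes.append(f"metadata rows without counts (e.g. filtered samples): {spare}")
    if tree is not None:
        check_tree_covers_taxa(tree, counts)
    patients = set(meta["patient"].astype(str))
    if abx is not None:
        orphan = sorted({c.patient for c in abx} - patients)
        if orphan:
            raise ValidationError(f"antibiotic courses for unknown patients: {orphan}")
    if outcomes is not None:
        validate_outcomes(outcomes)
        orphan = sorted(set(outcomes["patient"].astype(str)) - patients)
        if orphan:
            raise ValidationError(f"outcomes for unknown patients: {orphan}")
    return notes
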