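"""SE target-gene assignment, DEG intersection, and the TF screen.

Each consensus SE is assigned the gene with the nearest TSS; differential
SE target genes are intersected with direction-matched DEGs; candidate
transcription factors are screened by whether their binding sites occupy
the SE constituents and the target promoter, then ranked by expression
correlation with the target gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, TssRecord, overlaps, point_interval_distance


@dataclass(frozen=True)
class GeneAssignment:
    """The closest-gene target of a region.

    ``gene_id`` is None when the region's chromosome carries no annotated
    TSS (explicitly unassigned, never silently dropped).
    """

    region_id: str
    gene_id: str | None
    distance: int | None


def nearest_gene(region: GenomicInterval, tss: list[TssRecord]) -> GeneAssignment:
    """Assign the gene whose TSS is closest to the region (0 if inside).

    Distance is region-to-TSS-point, strand-agnostic; exact ties break to
    the lexicographically smallest gene_id.
    """
    region_id = region.name or str(region)
    best: tuple[int, str] | None = None
    for t in tss:
        if t.chrom != region.chrom:
            continue
        d = point_interval_distance(t.pos, region)
        key = (d, t.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return GeneAssignment(region_id, None, None)
    return GeneAssignment(region_id, best[1], best[0])


def assign_targets(
    regions: list[GenomicInterval], tss: list[TssRecord]
) -> list[GeneAssignment]:
    """Nearest-gene assignment for a list of regions."""
    return [nearest_gene(r, tss) for r in regions]


def intersect_se_targets_with_degs(
    up_se_genes: set[str], down_se_genes: set[str], degs: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Direction-matched intersection of SE target genes with DEGs.

    ``degs`` has columns gene_id, log2fc, q, direction.  Returns the
    sorted intersections (SE-up ∩ DEG-up, SE-down ∩ DEG-down).
    """
    deg_up = set(degs.loc[degs["direction"] == "up", "gene_id"])
    deg_down = set(degs.loc[degs["direction"] == "down", "gene_id"])
    return sorted(up_se_genes & deg_up), sorted(down_se_genes & deg_down)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-test p-value
    (t = r * sqrt((n-2)/(1-r^2)) on n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def tf_occupancy_funnel(
    tf_sites: dict[str, list[GenomicInterval]],
    queries: dict[str, GenomicInterval],
) -> pd.DataFrame:
    """Classify TFs by binding-site overlap with named query regions.

    A TF "hits" a query region iff any of its sites overlaps it by >= 1
    bp.  Returns one row per TF with a boolean hits_<name> column per
    query plus hits_any and hits_all.
    """
    rows = []
    for tf_id in sorted(tf_sites):
        sites = tf_sites[tf_id]
        row: dict[str, object] = {"tf_id": tf_id}
        flags = []
        for qname, region in queries.items():
            hit = any(overlaps(s, region) for s in sites)
            row[f"hits_{qname}"] = hit
            flags.append(hit)
        row["hits_any"] = any(flags)
        row["hits_all"] = all(flags)
        rows.append(row)
    return pd.DataFrame(rows).set_index("tf_id")


def rank_tf_candidates(
    tf_ids: set[str] | list[str],
    expression: pd.DataFrame,
    target_gene: str,
    sample_ids: list[str] | None = None,
) -> list[tuple[str, float, float]]:
    """Rank TFs by Pearson correlation of their expression with the
    target gene's, descending; ties break by gene id.

    ``expression`` is genes x samples; ``sample_ids`` restricts the
    correlation to a subset of samples (e.g. tumors only).
    """
    cols = sample_ids if sample_ids is not None else list(expression.columns)
    missing = [g for g in list(tf_ids) + [target_gene] if g not in expression.index]
    if missing:
        raise KeyError(f"genes missing from expression matrix: {missing}")
    target = expression.loc[target_gene, cols].to_numpy(dtype=float)
    ranked = []
    for tf in sorted(set(tf_ids)):
        r, p = pearson_correlation(expression.loc[tf, cols].to_numpy(dtype=float), target)
        ranked.append((tf, r, p))
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked
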