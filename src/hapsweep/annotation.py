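"""Candidate-gene capture, interval intersection and enrichment arithmetic.

Genes are assigned to a sweep region when they overlap the region extended
by a 75 kb flank on both sides by at least 1 bp (any-overlap, 1-based
inclusive coordinates).  Interval-track intersection follows
bedtools-intersect semantics.  DAVID-style enrichment scores are the
negative decimal log of a Fisher exact P-value (1.3 <-> P = 0.05); a term
cluster's score is the negative decimal log of the geometric mean of its
member P-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_model import GenomicInterval, HapsweepError

logger = logging.getLogger("hapsweep")


@dataclass(frozen=True)
class GeneAssignment:
    region_id: str
    gene: GenomicInterval
    overlap_bp: int  # with the flank-extended region; always >= 1


def assign_genes(
    regions: list,
    genes: list[GenomicInterval],
    flank_bp: int = 75_000,
) -> list[GeneAssignment]:
    """Assign genes overlapping each region's +/-flank_bp extension.

    `regions` may be SweepRegion objects or plain GenomicIntervals.  With
    flank_bp=0 this is plain interval intersection.  A chromosome-naming
    mismatch between the two tracks is reported as a warning, not an error.
    """
    region_ivs = [r.interval() if hasattr(r, "interval") else r for r in regions]
    r_chroms = {iv.chrom for iv in region_ivs}
    g_chroms = {g.chrom for g in genes}
    if region_ivs and genes and not (r_chroms & g_chroms):
        logger.warning(
            "no shared chromosome names between regions (%s) and genes (%s)",
            sorted(r_chroms)[:5],
            sorted(g_chroms)[:5],
        )
    out: list[GeneAssignment] = []
    for iv in region_ivs:
        flanked = GenomicInterval(
            iv.chrom, max(1, iv.start_bp - flank_bp), iv.end_bp + flank_bp, iv.id
        )
        for g in genes:
            ov = flanked.overlap_bp(g)
            if ov >= 1:
                out.append(GeneAssignment(iv.id, g, ov))
    return out


def span_of_genes(genes: list[GenomicInterval]) -> tuple[int, int, int]:
    """(min start, max end, length) of a single-chromosome gene set.

    Length is the simple coordinate difference max_end - min_start (the
    convention of published gene-cluster span arithmetic), not +1.
    """
    if not genes:
        raise HapsweepError("empty gene set")
    chroms = {g.chrom for g in genes}
    if len(chroms) > 1:
        raise HapsweepError(f"genes on multiple chromosomes: {sorted(chroms)}")
    lo = min(g.start_bp for g in genes)
    hi = max(g.end_bp for g in genes)
    return lo, hi, hi - lo


def intersect_intervals(
    track_a: list[GenomicInterval], track_b: list[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs (a, b, overlap_bp) with >= 1 bp overlap.

    Symmetric in its arguments up to pair order; coordinates are the
    internal 1-based inclusive convention.
    """
    trees: dict[str, IntervalTree] = {}
    for b in track_b:
        # half-open tree coordinates: [start, end + 1)
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start_bp, b.end_bp + 1, b)
    out = []
    for a in track_a:
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(a.start_bp, a.end_bp + 1)):
            b = hit.data
            out.append((a, b, a.overlap_bp(b)))
    return out


def enrichment_score_from_p(p: float) -> float:
    """DAVID-style enrichment score: -log10(P); 0.05 -> 1.30."""
    if not 0.0 < p <= 1.0:
        raise HapsweepError(f"P-value {p} outside (0, 1]")
    return float(-np.log10(p))


def p_from_enrichment_score(score: float) -> float:
    """Inverse transform: score -> P = 10**(-score)."""
    if score < 0:
        raise HapsweepError("enrichment score must be non-negative")
    return float(10.0 ** (-score))


def cluster_enrichment_score(p_values: list[float]) -> float:
    """Score of a term cluster: -log10 of the geometric mean of member
    P-values (equivalently the mean of the member scores)."""
    if not p_values:
        raise HapsweepError("empty cluster")
    return float(np.mean([enrichment_score_from_p(p) for p in p_values]))


# ---------------------------------------------------------------------------
# Bundled reference tables (worked examples)
# ---------------------------------------------------------------------------


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("hapsweep.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_candidate_gene_clusters() -> pd.DataFrame:
    """Sheep (Oar v3.1) and cattle (UMD3.1) coordinates of the 12 candidate
    genes in the three enriched functional clusters of the Djallonké sweep
    scan (Ensembl Genes 91)."""
    return _load_table("gene_clusters_oar31.tsv")


def cluster_genes(cluster: int, genome: str = "sheep") -> list[GenomicInterval]:
    """Gene intervals of one functional cluster (genome: sheep | cattle)."""
    df = load_candidate_gene_clusters()
    df = df[df.cluster == cluster]
    pre = "" if genome == "sheep" else "cattle_"
    return [
        GenomicInterval(
            str(row[f"{pre}chrom"]), int(row[f"{pre}start"]), int(row[f"{pre}end"]), row["gene"]
        )
        for _, row in df.iterrows()
    ]


def load_reference_region_summary() -> pd.DataFrame:
    """Published per-chromosome sweep-region summary of the Djallonké scan
    (columns chrom, n_regions, length_bp, n_snps, n_multi)."""
    df = _load_table("region_summary_reference.tsv")
    return df.astype(
        {"chrom": str, "n_regions": int, "length_bp": int, "n_snps": int, "n_multi": int}
    )
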