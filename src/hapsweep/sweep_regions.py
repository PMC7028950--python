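"""Consensus candidate-sweep-region construction from per-statistic calls.

A candidate region is seeded by cross-statistic support and grown by
window-chaining:

* rule (a): any single SNP called significant by at least two statistics
  seeds a region;
* rule (b): a pair of significant SNPs whose +/-75 kb windows overlap
  (centre distance <= 150 kb) and whose combined statistics cover at least
  two distinct statistics seeds a region;
* accretion: any significant SNP (any single statistic) whose +/-75 kb
  window intersects a region's window union joins it, repeated to closure;
* overlapping regions are merged, so regions on a chromosome are disjoint.

Because window intersection between SNPs is equivalent to a centre distance
of at most twice the flank, the closure is computed as connected components
of significant SNPs chained by <= 2 * flank gaps; a component becomes a
region iff it contains a rule-(a) SNP or a rule-(b) pair.  The region extent
is the union of the member windows, clipped at position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import GenomicInterval, HapsweepError, VariantMap


@dataclass
class RegionParams:
    flank_bp: int = 75_000
    min_statistics_seed: int = 2
    # strict rule (b): each SNP of the pair must itself be multi-statistic
    rule_b_strict: bool = False

    def __post_init__(self) -> None:
        if self.flank_bp <= 0:
            raise HapsweepError("flank_bp must be positive")


@dataclass
class SweepRegion:
    chrom: str
    start_bp: int  # union of member +/-flank windows, clipped at 1
    end_bp: int
    member_idx: list[int]  # variant-map indices, sorted by position
    member_pos: list[int]
    member_stats: list[frozenset[str]]
    seed_kind: str  # "single-multi-SNP" or "adjacent-pair"

    @property
    def n_snps(self) -> int:
        return len(self.member_idx)

    @property
    def n_multi(self) -> int:
        return sum(1 for s in self.member_stats if len(s) >= 2)

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start_bp, self.end_bp, self.id)


def build_regions(
    sig_sets: dict[str, set[int] | np.ndarray],
    vmap: VariantMap,
    params: RegionParams | None = None,
) -> list[SweepRegion]:
    """Construct disjoint consensus sweep regions from significance sets.

    sig_sets maps statistic name -> set of variant-map indices (or a boolean
    mask) called significant by that statistic.  Empty input yields an empty
    region list.  Output is deterministic: independent of the order in which
    statistics or SNPs are supplied.
    """
    params = params or RegionParams()
    stats_of: dict[int, set[str]] = {}
    for stat in sorted(sig_sets):
        members = sig_sets[stat]
        if isinstance(members, np.ndarray) and members.dtype == bool:
            members = set(np.flatnonzero(members).tolist())
        for i in members:
            stats_of.setdefault(int(i), set()).add(stat)
    if not stats_of:
        return []

    flank = params.flank_bp
    need = params.min_statistics_seed
    regions: list[SweepRegion] = []
    chroms = sorted({str(vmap.chrom[i]) for i in stats_of})
    for chrom in chroms:
        idx = sorted(
            (i for i in stats_of if str(vmap.chrom[i]) == chrom),
            key=lambda i: int(vmap.pos_bp[i]),
        )
        pos = [int(vmap.pos_bp[i]) for i in idx]
        # connected components chained by window overlap (gap <= 2 * flank)
        comps: list[list[int]] = [[0]]
        for k in range(1, len(idx)):
            if pos[k] - pos[k - 1] <= 2 * flank:
                comps[-1].append(k)
            else:
                comps.append([k])
        for comp in comps:
            members = [idx[k] for k in comp]
            mpos = [pos[k] for k in comp]
            mstats = [frozenset(stats_of[i]) for i in members]
            rule_a = any(len(s) >= need for s in mstats)
            rule_b = False
            if not rule_a:
                for u in range(len(comp)):
                    for v in range(u + 1, len(comp)):
                        if mpos[v] - mpos[u] > 2 * flank:
                            break
                        if params.rule_b_strict:
                            ok = len(mstats[u]) >= need and len(mstats[v]) >= need
                        else:
                            ok = len(mstats[u] | mstats[v]) >= need
                        if ok:
                            rule_b = True
                            break
                    if rule_b:
                        break
            if not (rule_a or rule_b):
                continue  # unassigned single-statistic SNPs never seed
            regions.append(
                SweepRegion(
                    chrom=chrom,
                    start_bp=max(1, mpos[0] - flank),
                    end_bp=mpos[-1] + flank,
                    member_idx=members,
                    member_pos=mpos,
                    member_stats=mstats,
                    seed_kind="single-multi-SNP" if rule_a else "adjacent-pair",
                )
            )
    return regions


def _chrom_sort_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def summarize_regions(regions: list[SweepRegion]) -> pd.DataFrame:
    """Per-chromosome summary: region count N, summed length, summed member
    SNPs and summed multi-statistic SNPs (chromosomes with >= 1 region)."""
    rows: dict[str, dict] = {}
    for r in regions:
        d = rows.setdefault(
            r.chrom, {"chrom": r.chrom, "n_regions": 0, "length_bp": 0, "n_snps": 0, "n_multi": 0}
        )
        d["n_regions"] += 1
        d["length_bp"] += r.length
        d["n_snps"] += r.n_snps
        d["n_multi"] += r.n_multi
    if not rows:
        return pd.DataFrame(columns=["chrom", "n_regions", "length_bp", "n_snps", "n_multi"])
    df = pd.DataFrame([rows[c] for c in sorted(rows, key=_chrom_sort_key)])
    return df


def summarize_totals(
    per_chrom: pd.DataFrame,
    genome_bp: float | None = None,
    n_top_chroms: int = 4,
) -> dict:
    """Totals over a per-chromosome summary table.

    Returns region/SNP totals plus the share of regions on the n_top_chroms
    chromosomes richest in regions and, when a genome span is given, the
    regions' share of the genome in percent.
    """
    if per_chrom.empty:
        out = {"n_regions": 0, "length_bp": 0, "n_snps": 0, "n_multi": 0}
        out["top_chrom_share_pct"] = 0.0
        if genome_bp:
            out["genome_share_pct"] = 0.0
        return out
    out = {
        "n_regions": int(per_chrom.n_regions.sum()),
        "length_bp": int(per_chrom.length_bp.sum()),
        "n_snps": int(per_chrom.n_snps.sum()),
        "n_multi": int(per_chrom.n_multi.sum()),
    }
    top = per_chrom.nlargest(n_top_chroms, "n_regions", keep="first")
    out["top_chroms"] = list(top.chrom)
    out["top_chrom_share_pct"] = 100.0 * top.n_regions.sum() / out["n_regions"]
    if genome_bp:
        out["genome_share_pct"] = 100.0 * out["length_bp"] / genome_bp
    return out


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    """1-based TSV-ready table with member lists and provenance."""
    return pd.DataFrame(
        [
            {
                "region_id": r.id,
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_bp": r.length,
                "n_snps": r.n_snps,
                "n_multi": r.n_multi,
                "seed_kind": r.seed_kind,
                "member_pos": ",".join(str(p) for p in r.member_pos),
                "member_stats": ",".join(
                    "+".join(sorted(s)) for s in r.member_stats
                ),
            }
            for r in regions
        ]
    )
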