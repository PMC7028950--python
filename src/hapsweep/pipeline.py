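"""End-to-end orchestration: QC -> scan -> normalize -> regions -> annotate.

The configuration vocabulary mirrors the scan parameters as they are
conventionally named on the selscan/norm command line (cutoff, max-extend,
max-gap, bins, threshold, flank) so a reader can map a methods section to
the config one to one.  Given identical inputs and seed the pipeline is
deterministic; the run log records every parameter, per-stage SNP counts
and every skip reason.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, normalization, qc, sweep_regions
from .ehh_stats import ScanParams, ihs_scan, nsl_scan, write_scan_tsv, xpehh_scan
from .io_model import (
    HaplotypeMatrix,
    HapsweepError,
    PopulationLabels,
    VariantMap,
    read_intervals,
    read_phased_vcf,
    read_plink_ped_map,
    read_population_labels,
    write_intervals_bed,
)
from .normalization import NormParams
from .qc import QCConfig
from .sweep_regions import RegionParams

logger = logging.getLogger("hapsweep")

VALID_STATISTICS = ("ihs", "xpehh", "nsl")


@dataclass
class PipelineConfig:
    vcf: str | None = None
    ped: str | None = None
    map: str | None = None
    populations: str | None = None
    focal_pop: str = "focal"
    ref_pop: str | None = None
    statistics: tuple[str, ...] = ("ihs", "xpehh", "nsl")
    scan: ScanParams = field(default_factory=ScanParams)
    norm: NormParams = field(default_factory=NormParams)
    region: RegionParams = field(default_factory=RegionParams)
    qc: QCConfig = field(default_factory=QCConfig)
    gene_track: str | None = None
    gene_track_format: str = "tsv1"
    flank_bp: int = 75_000  # gene-capture flank
    genome_bp: float | None = None
    out_dir: str | None = None
    seed: int = 0
    trunc_ok: bool = False

    def __post_init__(self) -> None:
        bad = set(self.statistics) - set(VALID_STATISTICS)
        if bad:
            raise HapsweepError(f"unknown statistics: {sorted(bad)}")
        if "xpehh" in self.statistics and self.ref_pop is None:
            raise HapsweepError("xpehh requires a reference population (ref_pop)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scan = ScanParams(
            cutoff=raw.pop("cutoff", 0.05),
            max_extend_bp=raw.pop("max_extend", 1_000_000),
            max_gap_bp=raw.pop("max_gap", 200_000),
            max_extend_sites_nsl=raw.pop("max_extend_sites_nsl", 100),
            maf_min_core=raw.pop("maf_min_core", 0.05),
        )
        norm = NormParams(
            n_bins=raw.pop("bins", 100), threshold=raw.pop("threshold", 2.0)
        )
        region = RegionParams(
            flank_bp=raw.pop("flank", 75_000),
            rule_b_strict=raw.pop("rule_b_strict", False),
        )
        qc_cfg = QCConfig(**raw.pop("qc", {}))
        stats = tuple(raw.pop("statistics", list(VALID_STATISTICS)))
        return cls(scan=scan, norm=norm, region=region, qc=qc_cfg, statistics=stats, **raw)


class _StageRunner:
    """Runs named stages; on failure renames outputs written so far to
    *.partial and re-raises with the stage name."""

    def __init__(self, out_dir: Path | None):
        self.out_dir = out_dir
        self.written: list[Path] = []

    def record(self, path: Path) -> Path:
        self.written.append(path)
        return path

    def fail(self, stage: str, exc: Exception):
        for p in self.written:
            if p.exists():
                p.rename(p.with_name(p.name + ".partial"))
        raise HapsweepError(f"stage {stage!r} failed: {exc}") from exc


def run_pipeline(
    config: PipelineConfig,
    hm: HaplotypeMatrix | None = None,
    vmap: VariantMap | None = None,
    labels: PopulationLabels | None = None,
) -> dict:
    """Execute the full scan; returns all in-memory artifacts.

    Inputs may be given on disk via the config or directly in memory
    (hm/vmap/labels).  When out_dir is set, TSV/BED artifacts and a run log
    are written there.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_dir / "run.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    runner = _StageRunner(out_dir)
    try:
        result = _run(config, hm, vmap, labels, runner, out_dir)
    finally:
        if out_dir:
            logger.removeHandler(fh)
            fh.close()
    return result


def _run(config, hm, vmap, labels, runner, out_dir):
    logger.info("pipeline parameters: %s", asdict(config))

    # ---- load ----
    stage = "load"
    try:
        if hm is None or vmap is None:
            if config.vcf:
                hm, vmap = read_phased_vcf(config.vcf)
            elif config.ped and config.map:
                hm, vmap = read_plink_ped_map(config.ped, config.map)
            else:
                raise HapsweepError("no input: provide vcf or ped+map (or in-memory data)")
        if labels is None:
            if config.populations:
                labels = read_population_labels(config.populations)
            else:
                labels = PopulationLabels({s: config.focal_pop for s in hm.sample_ids})
        labels.validate_against(hm)
        logger.info("loaded %d samples x %d SNPs", hm.n_samples, hm.n_sites)
    except Exception as e:  # noqa: BLE001
        runner.fail(stage, e)

    # ---- qc ----
    stage = "qc"
    try:
        geno = hm.dosage()
        _, vmap_qc, kept_samples, report = qc.apply_qc(
            geno, vmap, hm.sample_ids, config.qc
        )
        kept_site_ids = set(vmap_qc.variant_id.tolist())
        site_idx = np.asarray(
            [j for j in range(len(vmap)) if vmap.variant_id[j] in kept_site_ids]
        )
        sample_idx = [hm.sample_ids.index(s) for s in kept_samples]
        hm = hm.subset_samples(sample_idx).subset_sites(site_idx)
        vmap = vmap.subset(site_idx)
        qc.require_complete(hm.dosage())
        logger.info(
            "QC: %d SNPs and %d samples retained (%s)",
            hm.n_sites,
            hm.n_samples,
            "; ".join(f"{s['step']}:{s['n_removed']}" for s in report.steps),
        )
        if out_dir:
            report.to_frame().to_csv(
                runner.record(out_dir / "qc_report.tsv"), sep="\t", index=False
            )
    except Exception as e:  # noqa: BLE001
        runner.fail(stage, e)

    focal_rows_samples = [
        i for i, s in enumerate(hm.sample_ids) if labels.labels[s] == config.focal_pop
    ]
    if not focal_rows_samples:
        runner.fail("qc", HapsweepError(f"no samples in focal population {config.focal_pop!r}"))
    hm_focal = hm.subset_samples(focal_rows_samples)

    # ---- scan + normalize ----
    scans: dict[str, pd.DataFrame] = {}
    sig_sets: dict[str, set[int]] = {}
    for stat in config.statistics:
        stage = f"scan:{stat}"
        try:
            if stat == "ihs":
                res = ihs_scan(hm_focal, vmap, config.scan, trunc_ok=config.trunc_ok)
            elif stat == "nsl":
                res = nsl_scan(hm_focal, vmap, config.scan)
            else:
                res = xpehh_scan(
                    hm, vmap, labels, config.focal_pop, config.ref_pop,
                    config.scan, trunc_ok=config.trunc_ok,
                )
            res["standardized"] = normalization.normalize(
                res["raw"].to_numpy(), res["freq1"].to_numpy(), config.norm
            )
            res["significant"] = normalization.call_significant(
                res["standardized"].to_numpy(), config.norm
            )
            scans[stat] = res
            sig_sets[stat] = set(np.flatnonzero(res["significant"].to_numpy()).tolist())
            n_scored = int(np.isfinite(res["raw"]).sum())
            skip_counts = res.loc[res.skip_reason != "", "skip_reason"].value_counts()
            logger.info(
                "%s: %d scored, %d significant (|z| > %g); skips: %s",
                stat, n_scored, len(sig_sets[stat]), config.norm.threshold,
                skip_counts.to_dict(),
            )
            if out_dir:
                write_scan_tsv(runner.record(out_dir / f"scan_{stat}.tsv"), res)
        except Exception as e:  # noqa: BLE001
            runner.fail(stage, e)

    # ---- regions ----
    stage = "regions"
    try:
        regions = sweep_regions.build_regions(sig_sets, vmap, config.region)
        per_chrom = sweep_regions.summarize_regions(regions)
        totals = sweep_regions.summarize_totals(per_chrom, genome_bp=config.genome_bp)
        logger.info("regions: %d spanning %d bp", totals["n_regions"], totals["length_bp"])
        if out_dir:
            sweep_regions.regions_to_frame(regions).to_csv(
                runner.record(out_dir / "regions.tsv"), sep="\t", index=False
            )
            write_intervals_bed(
                runner.record(out_dir / "regions.bed"), [r.interval() for r in regions]
            )
            per_chrom.to_csv(
                runner.record(out_dir / "region_summary.tsv"), sep="\t", index=False
            )
    except Exception as e:  # noqa: BLE001
        runner.fail(stage, e)

    # ---- annotate ----
    assignments = None
    if config.gene_track:
        stage = "annotate"
        try:
            genes = read_intervals(config.gene_track, config.gene_track_format)
            assignments = annotation.assign_genes(regions, genes, config.flank_bp)
            logger.info(
                "annotation: %d gene assignments in %d regions",
                len(assignments), len({a.region_id for a in assignments}),
            )
            if out_dir:
                pd.DataFrame(
                    [
                        {
                            "region_id": a.region_id,
                            "gene_id": a.gene.id,
                            "overlap_bp": a.overlap_bp,
                        }
                        for a in assignments
                    ]
                ).to_csv(
                    runner.record(out_dir / "gene_assignments.tsv"), sep="\t", index=False
                )
        except Exception as e:  # noqa: BLE001
            runner.fail(stage, e)

    return {
        "haplotypes": hm,
        "variant_map": vmap,
        "labels": labels,
        "qc_report": report,
        "scans": scans,
        "significant": sig_sets,
        "regions": regions,
        "region_summary": per_chrom,
        "totals": totals,
        "gene_assignments": assignments,
    }
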