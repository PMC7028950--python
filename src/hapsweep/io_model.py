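"""Core data containers and on-disk formats.

The pipeline operates on phased, biallelic, complete (no-missing) haplotype
data.  Haplotypes are stored as a dense 0/1 matrix with two rows per sample
(rows ``2k`` and ``2k + 1`` belong to sample ``k``); the column order is tied
to a variant map carrying chromosome, physical (bp, 1-based) and genetic (cM)
coordinates.  Allele ``1`` plays the role of the "derived" class and allele
``0`` the "ancestral" class throughout — the scan statistics only require a
consistent arbitrary polarization, not true ancestral-state information.

All interval coordinates are handled internally as 1-based inclusive (the
convention of Ensembl gene tables); BED input/output is converted at the
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hapsweep")

_NON_AUTOSOME_LABELS = {"X", "Y", "MT", "M", "XY"}


class HapsweepError(RuntimeError):
    """Base class for pipeline errors."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantMap:
    """Per-SNP coordinates: chromosome, physical bp (1-based), genetic cM."""

    chrom: np.ndarray  # dtype object/str, length L
    variant_id: np.ndarray
    pos_bp: np.ndarray  # int64
    pos_cm: np.ndarray  # float64

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=np.float64)
        self.validate()

    def __len__(self) -> int:
        return len(self.pos_bp)

    def validate(self) -> None:
        n = len(self.pos_bp)
        if not (len(self.chrom) == len(self.variant_id) == len(self.pos_cm) == n):
            raise HapsweepError("variant map columns have unequal lengths")
        for c in np.unique(self.chrom.astype(str)):
            m = self.chrom.astype(str) == c
            bp = self.pos_bp[m]
            cm = self.pos_cm[m]
            if np.any(np.diff(bp) <= 0):
                raise HapsweepError(f"pos_bp not strictly increasing on chromosome {c}")
            if np.any(np.diff(cm) < 0):
                raise HapsweepError(f"pos_cm decreasing on chromosome {c}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom.astype(str),
                "variant_id": self.variant_id.astype(str),
                "pos_bp": self.pos_bp,
                "pos_cm": self.pos_cm,
            }
        )

    def subset(self, idx: np.ndarray) -> "VariantMap":
        idx = np.asarray(idx)
        return VariantMap(
            self.chrom[idx], self.variant_id[idx], self.pos_bp[idx], self.pos_cm[idx]
        )

    def is_autosome(self) -> np.ndarray:
        """Boolean mask of sites on autosomes (numeric or 'chrN' labels)."""
        out = np.empty(len(self), dtype=bool)
        for i, c in enumerate(self.chrom.astype(str)):
            label = c[3:] if c.lower().startswith("chr") else c
            out[i] = label.upper() not in _NON_AUTOSOME_LABELS and label.isdigit()
        return out


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes: rows = 2N haplotypes, columns = L sites."""

    alleles: np.ndarray  # uint8, values in {0, 1}
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.validate()

    def validate(self) -> None:
        if self.alleles.ndim != 2:
            raise HapsweepError("haplotype matrix must be 2-D")
        if self.alleles.shape[0] % 2 != 0:
            raise HapsweepError("haplotype row count must be even (two per sample)")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise HapsweepError("row count does not match 2 x sample count")
        if self.alleles.size and self.alleles.max() > 1:
            raise HapsweepError("haplotype entries must be 0 or 1 (no missing)")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def freq1(self) -> np.ndarray:
        """Allele-1 frequency per site."""
        return self.alleles.mean(axis=0)

    def dosage(self) -> np.ndarray:
        """N x L matrix of allele-1 counts per sample (0/1/2)."""
        a = self.alleles.astype(np.int8)
        return a[0::2] + a[1::2]

    def subset_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.alleles[:, np.asarray(idx)], list(self.sample_ids))

    def subset_samples(self, sample_idx: Sequence[int]) -> "HaplotypeMatrix":
        rows = np.repeat(np.asarray(sample_idx) * 2, 2) + np.tile([0, 1], len(sample_idx))
        return HaplotypeMatrix(
            self.alleles[rows], [self.sample_ids[i] for i in sample_idx]
        )


@dataclass
class PopulationLabels:
    """sample_id -> population name."""

    labels: dict[str, str]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.labels.values():
            seen.setdefault(p, None)
        return list(seen)

    def sample_ids(self, population: str) -> list[str]:
        return [s for s, p in self.labels.items() if p == population]

    def validate_against(self, hm: HaplotypeMatrix) -> None:
        missing = [s for s in hm.sample_ids if s not in self.labels]
        if missing:
            raise HapsweepError(f"samples without population label: {missing[:5]}")
        if not self.labels:
            raise HapsweepError("empty population table")

    def haplotype_rows(self, hm: HaplotypeMatrix, population: str) -> np.ndarray:
        """Row indices of haplotypes belonging to one population."""
        idx = [i for i, s in enumerate(hm.sample_ids) if self.labels.get(s) == population]
        if not idx:
            raise HapsweepError(f"population {population!r} has no samples in matrix")
        return np.repeat(np.asarray(idx) * 2, 2) + np.tile([0, 1], len(idx))


@dataclass(frozen=True)
class GenomicInterval:
    """A named span on a chromosome, 1-based inclusive."""

    chrom: str
    start_bp: int
    end_bp: int
    id: str = ""
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise HapsweepError(
                f"interval {self.id or '?'}: start {self.start_bp} > end {self.end_bp}"
            )

    @property
    def length(self) -> int:
        """Simple coordinate difference end - start (not +1)."""
        return self.end_bp - self.start_bp

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in bp under 1-based inclusive coordinates (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start_bp, other.start_bp)
        hi = min(self.end_bp, other.end_bp)
        return max(0, hi - lo + 1)


# ---------------------------------------------------------------------------
# Sorting helper shared by the readers
# ---------------------------------------------------------------------------


def _finalize(
    alleles: np.ndarray,
    chrom: list,
    vid: list,
    bp: list,
    cm: list,
    sample_ids: list[str],
) -> tuple[HaplotypeMatrix, VariantMap]:
    chrom_a = np.asarray(chrom, dtype=object)
    bp_a = np.asarray(bp, dtype=np.int64)
    order = np.lexsort((bp_a, chrom_a.astype(str)))
    if not np.array_equal(order, np.arange(len(order))):
        logger.info("input sites were not (chrom, pos_bp) sorted; reordering columns")
        alleles = alleles[:, order]
        chrom_a = chrom_a[order]
        vid = [vid[i] for i in order]
        bp_a = bp_a[order]
        cm = [cm[i] for i in order]
    vmap = VariantMap(chrom_a, np.asarray(vid, dtype=object), bp_a, np.asarray(cm))
    return HaplotypeMatrix(alleles, sample_ids), vmap


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_phased_vcf(path: str | Path) -> tuple[HaplotypeMatrix, VariantMap]:
    """Read a phased, biallelic-SNP VCF into a haplotype matrix.

    Haplotype rows appear in sample order, left allele then right.  Unphased
    or missing genotypes and multiallelic records are hard errors: quality
    control and phasing must happen upstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    chrom: list[str] = []
    vid: list[str] = []
    bp: list[int] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise HapsweepError(
                f"multiallelic record at {var.CHROM}:{var.POS} (ALT={var.ALT})"
            )
        col = np.empty(2 * len(sample_ids), dtype=np.uint8)
        for k, g in enumerate(var.genotypes):
            a0, a1, phased = g[0], g[1], g[2]
            if a0 < 0 or a1 < 0:
                raise HapsweepError(f"missing genotype at {var.CHROM}:{var.POS}")
            if not phased:
                raise HapsweepError(f"unphased genotype at {var.CHROM}:{var.POS}")
            col[2 * k] = a0
            col[2 * k + 1] = a1
        cols.append(col)
        chrom.append(var.CHROM)
        vid.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        bp.append(var.POS)
    vcf.close()
    if not cols:
        raise HapsweepError(f"no variant records in {path}")
    alleles = np.stack(cols, axis=1)
    cm = [p * 1e-6 for p in bp]  # 1 cM/Mb surrogate; no genetic map in VCF
    return _finalize(alleles, chrom, vid, bp, cm, sample_ids)


def write_phased_vcf(
    path: str | Path, hm: HaplotypeMatrix, vmap: VariantMap
) -> None:
    """Write haplotypes as a minimal phased VCF (REF=A, ALT=G placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(vmap.chrom.astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hm.sample_ids)
            + "\n"
        )
        a = hm.alleles
        for j in range(len(vmap)):
            gts = "\t".join(
                f"{a[2 * k, j]}|{a[2 * k + 1, j]}" for k in range(hm.n_samples)
            )
            fh.write(
                f"{vmap.chrom[j]}\t{vmap.pos_bp[j]}\t{vmap.variant_id[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# PLINK .ped / .map
# ---------------------------------------------------------------------------


def read_plink_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[HaplotypeMatrix, VariantMap]:
    """Read a PLINK text .ped/.map pair, recoding alleles to 0/1 per site.

    The allele carried by the first haplotype encountered at a site is coded
    0 (the scan is agnostic to ancestral/derived polarity, so an arbitrary
    but deterministic coding suffices).  A site with more than two alleles or
    a '0' missing code is a hard error.  When the .map cM column is all
    zeros, genetic positions fall back to pos_bp * 1e-6 (1 cM/Mb).
    """
    mp = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "variant_id", "cm", "bp"],
        dtype={"chrom": str, "variant_id": str, "cm": float, "bp": int},
    )
    L = len(mp)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    allele_code: list[dict[str, int]] = [dict() for _ in range(L)]
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * L:
                raise HapsweepError(
                    f".ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * L}"
                )
            sample_ids.append(parts[1])
            h0 = np.empty(L, dtype=np.uint8)
            h1 = np.empty(L, dtype=np.uint8)
            for j in range(L):
                for h, arr in ((parts[6 + 2 * j], h0), (parts[7 + 2 * j], h1)):
                    if h == "0":
                        raise HapsweepError(
                            f"missing allele code at site {mp.variant_id[j]}"
                        )
                    code = allele_code[j]
                    if h not in code:
                        if len(code) == 2:
                            raise HapsweepError(
                                f"more than two alleles at site {mp.variant_id[j]}: "
                                f"{sorted(code) + [h]}"
                            )
                        code[h] = len(code)
                    arr[j] = code[h]
            rows.append(h0)
            rows.append(h1)
    if not rows:
        raise HapsweepError(f"no samples in {ped_path}")
    alleles = np.stack(rows, axis=0)
    if (mp.cm == 0).all():
        logger.info("all-zero cM column in %s; using pos_bp * 1e-6 surrogate", map_path)
        cm = (mp.bp * 1e-6).tolist()
    else:
        cm = mp.cm.tolist()
    return _finalize(
        alleles,
        mp.chrom.tolist(),
        mp.variant_id.tolist(),
        mp.bp.tolist(),
        cm,
        sample_ids,
    )


# ---------------------------------------------------------------------------
# Interval tables and population labels
# ---------------------------------------------------------------------------


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read gene/QTL intervals from BED (0-based half-open) or tsv1 tables.

    tsv1 is a headered TSV with columns chrom, start, end, id in 1-based
    inclusive coordinates (the Ensembl gene-table style).  Everything is
    normalized to the internal 1-based inclusive convention.
    """
    out: list[GenomicInterval] = []
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        for _, row in df.iterrows():
            start0, end0 = int(row[1]), int(row[2])
            if end0 <= start0:
                raise HapsweepError(
                    f"zero-length BED interval {row[0]}:{start0}-{end0}"
                )
            name = str(row[3]) if len(row) > 3 and not pd.isna(row[3]) else ""
            out.append(GenomicInterval(str(row[0]), start0 + 1, end0, name))
    elif format == "tsv1":
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "start", "end", "id"}
        if not required.issubset(df.columns):
            raise HapsweepError(f"tsv1 table must have columns {sorted(required)}")
        for _, row in df.iterrows():
            out.append(
                GenomicInterval(str(row.chrom), int(row.start), int(row.end), str(row.id))
            )
    else:
        raise HapsweepError(f"unknown interval format {format!r}")
    return out


def write_intervals_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    """Write intervals as BED (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\t{iv.id}\n")


def read_population_labels(path: str | Path) -> PopulationLabels:
    """Read a two-column sample->population TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if list(df.iloc[0]) == ["sample_id", "population"]:
        df = df.iloc[1:]
    return PopulationLabels(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_population_labels(path: str | Path, labels: PopulationLabels) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in labels.labels.items():
            fh.write(f"{s}\t{p}\n")
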