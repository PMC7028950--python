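"""Marker and sample quality control for diploid SNP genotypes.

Filters follow common chip-QC practice: non-autosomal markers are dropped
first, then low-call-rate samples (< 99%), then low-call-rate SNPs (< 90%),
then SNPs with minor allele frequency below 0.05, and finally SNPs failing
the Hardy–Weinberg exact test at P <= 0.001.  Genotypes are allele-1 dosage
values 0/1/2 with -1 for missing.

The Hardy–Weinberg test is the exact conditional test of the heterozygote
count given the allele counts: the P-value is the sum of the probabilities
of all heterozygote counts whose conditional probability does not exceed the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_model import HapsweepError, VariantMap

MISSING = -1


@dataclass
class QCConfig:
    snp_call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.99
    maf_min: float = 0.05
    hwe_p_min: float = 0.001  # remove SNPs with exact-test P <= this
    autosomes_only: bool = True
    hwe_per_population: bool = False  # pooled by default

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "sample_call_rate_min", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise HapsweepError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Counts (and ids) removed at each ordered filter step."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, ids: list[str]) -> None:
        self.steps.append({"step": step, "n_removed": len(ids), "ids": ids})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": s["step"], "n_removed": s["n_removed"], "ids": ",".join(s["ids"])}
                for s in self.steps
            ]
        )

    def n_removed(self, step: str) -> int:
        for s in self.steps:
            if s["step"] == step:
                return s["n_removed"]
        raise KeyError(step)


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy–Weinberg P-value for one biallelic site.

    Conditional on the observed allele counts, a heterozygote count h under
    HWE has probability proportional to

        n! / (n_hom_minor! * h! * n_hom_major!) * 2**h

    with n the number of individuals.  The returned P is the sum over all
    admissible h (those sharing parity with the minor-allele count) of P(h)
    for which P(h) <= P(observed heterozygote count).
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0 or int(v) != v:
            raise HapsweepError("genotype counts must be non-negative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise HapsweepError("at least one individual required")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    # admissible het counts share parity with the minor-allele count
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hs) // 2
    hom_maj = n - hs - hom_min
    logp = (
        gammaln(n + 1)
        - gammaln(hom_min + 1)
        - gammaln(hs + 1)
        - gammaln(hom_maj + 1)
        + hs * np.log(2.0)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hs == n_het][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _maf(geno_col: np.ndarray) -> float:
    called = geno_col[geno_col != MISSING]
    if called.size == 0:
        return 0.0
    f = called.mean() / 2.0
    return min(f, 1.0 - f)


def apply_qc(
    geno: np.ndarray,
    vmap: VariantMap,
    sample_ids: list[str],
    config: QCConfig | None = None,
) -> tuple[np.ndarray, VariantMap, list[str], QCReport]:
    """Apply the ordered filter cascade; returns filtered data and a report.

    geno is an N x L dosage matrix (0/1/2, -1 missing).  Raises if no SNP
    survives.  The operation is idempotent: a clean dataset passes through
    unchanged with zero removals at every step.
    """
    config = config or QCConfig()
    geno = np.asarray(geno)
    if geno.ndim != 2 or geno.shape[1] != len(vmap):
        raise HapsweepError("genotype matrix shape does not match variant map")
    report = QCReport()
    site_keep = np.ones(len(vmap), dtype=bool)
    sample_keep = np.ones(len(sample_ids), dtype=bool)

    # 1. non-autosomal markers
    if config.autosomes_only:
        auto = vmap.is_autosome()
        removed = [str(v) for v in vmap.variant_id[~auto]]
        site_keep &= auto
    else:
        removed = []
    report.add("non_autosomal", removed)

    # 2. sample call rate (over currently kept sites)
    sub = geno[:, site_keep]
    if sub.shape[1] > 0:
        rate = (sub != MISSING).mean(axis=1)
        bad = rate < config.sample_call_rate_min
    else:
        bad = np.zeros(len(sample_ids), dtype=bool)
    report.add("sample_call_rate", [sample_ids[i] for i in np.where(bad)[0]])
    sample_keep &= ~bad

    # 3. SNP call rate (over kept samples)
    sub = geno[sample_keep]
    rate = (sub != MISSING).mean(axis=0) if sub.shape[0] else np.ones(len(vmap))
    bad = site_keep & (rate < config.snp_call_rate_min)
    report.add("snp_call_rate", [str(v) for v in vmap.variant_id[bad]])
    site_keep &= ~bad

    # 4. MAF
    bad = np.zeros(len(vmap), dtype=bool)
    for j in np.where(site_keep)[0]:
        if _maf(sub[:, j]) < config.maf_min:
            bad[j] = True
    report.add("maf", [str(v) for v in vmap.variant_id[bad]])
    site_keep &= ~bad

    # 5. HWE exact test (pooled samples)
    bad = np.zeros(len(vmap), dtype=bool)
    for j in np.where(site_keep)[0]:
        col = sub[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        p = hwe_exact_p(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        if p <= config.hwe_p_min:
            bad[j] = True
    report.add("hwe", [str(v) for v in vmap.variant_id[bad]])
    site_keep &= ~bad

    if not site_keep.any():
        raise HapsweepError("empty dataset after QC")
    out_geno = geno[np.ix_(sample_keep, site_keep)]
    out_samples = [s for s, k in zip(sample_ids, sample_keep) if k]
    return out_geno, vmap.subset(np.where(site_keep)[0]), out_samples, report


def require_complete(geno: np.ndarray) -> None:
    """The scan is undefined under missingness; fail loudly if any remains."""
    if np.any(np.asarray(geno) == MISSING):
        raise HapsweepError(
            "missing genotypes remain after QC; the haplotype scan requires complete data"
        )
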