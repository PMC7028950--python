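"""Population-genetic summaries: Weir–Cockerham F_ST and inbreeding F.

The differentiation estimator is the Weir & Cockerham (1984) two-allele
variance-components decomposition: per SNP, `a` (among populations), `b`
(among individuals within populations) and `c` (within individuals).  The
genome-wide "weighted" estimate is the ratio of sums Σa / Σ(a + b + c), the
quantity most variant-callers report; per-SNP ratios are also emitted for
diagnostics.  Negative estimates are reported as-is — clamping hides the
estimator's behaviour near zero differentiation.

Per-individual inbreeding follows the method-of-moments heterozygosity
deficit: F = (O - E) / (L - E), with O the observed homozygous site count,
E the expected homozygous count under Hardy–Weinberg at pooled allele
frequencies (with the 2n/(2n-1) small-sample factor on expected
heterozygosity), and L the individual's genotyped site count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import HapsweepError, PopulationLabels

MISSING = -1


@dataclass
class FstResult:
    a: np.ndarray  # per-SNP among-population component
    b: np.ndarray  # among-individual-within component
    c: np.ndarray  # within-individual component
    per_snp_fst: np.ndarray  # a / (a+b+c), NaN where undefined
    weighted_fst: float  # sum(a) / sum(a+b+c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"a": self.a, "b": self.b, "c": self.c, "fst": self.per_snp_fst}
        )


@dataclass
class InbreedingResult:
    sample_ids: list[str]
    observed_hom: np.ndarray
    expected_hom: np.ndarray
    n_sites: np.ndarray
    f: np.ndarray  # NaN where L - E == 0 (flagged undefined)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "observed_hom": self.observed_hom,
                "expected_hom": self.expected_hom,
                "n_sites": self.n_sites,
                "F": self.f,
            }
        )

    def summary_by_population(self, labels: PopulationLabels) -> pd.DataFrame:
        df = self.to_frame()
        df["population"] = [labels.labels[s] for s in self.sample_ids]
        return df.groupby("population")["F"].agg(["mean", "std", "count"]).reset_index()


def weir_cockerham_fst(
    geno: np.ndarray, sample_ids: list[str], labels: PopulationLabels
) -> FstResult:
    """Weir–Cockerham variance components from an N x L dosage matrix.

    geno holds allele-1 counts 0/1/2 with -1 for missing.  SNPs monomorphic
    across the pooled sample (or informative in fewer than two populations)
    contribute zero components.
    """
    geno = np.asarray(geno)
    pops = labels.populations()
    if len(pops) < 2:
        raise HapsweepError("F_ST requires at least two populations")
    pop_rows = {}
    for p in pops:
        rows = [i for i, s in enumerate(sample_ids) if labels.labels.get(s) == p]
        if not rows:
            raise HapsweepError(f"population {p!r} has no samples")
        pop_rows[p] = np.asarray(rows)

    L = geno.shape[1]
    a = np.zeros(L)
    b = np.zeros(L)
    c = np.zeros(L)
    for j in range(L):
        n_i, p_i, h_i = [], [], []
        for p in pops:
            col = geno[pop_rows[p], j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            n_i.append(col.size)
            p_i.append(col.mean() / 2.0)
            h_i.append((col == 1).mean())
        r = len(n_i)
        if r < 2:
            continue
        n_i = np.asarray(n_i, dtype=float)
        p_i = np.asarray(p_i)
        h_i = np.asarray(h_i)
        n_bar = n_i.mean()
        if n_bar <= 1:
            continue
        n_sum = n_i.sum()
        nc = (n_sum - (n_i**2).sum() / n_sum) / (r - 1)
        p_bar = (n_i * p_i).sum() / n_sum
        if p_bar <= 0.0 or p_bar >= 1.0:
            continue  # monomorphic overall
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / n_sum
        a[j] = (n_bar / nc) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
        )
        b[j] = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c[j] = h_bar / 2.0
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        per_snp = np.where(denom != 0, a / denom, np.nan)
    total = denom.sum()
    if total == 0:
        raise HapsweepError("no polymorphic SNPs; F_ST undefined")
    return FstResult(a, b, c, per_snp, float(a.sum() / total))


def inbreeding_f(
    geno: np.ndarray, sample_ids: list[str], unbiased: bool = True
) -> InbreedingResult:
    """Method-of-moments inbreeding coefficient per individual.

    Pooled allele frequencies are computed across all genotyped individuals
    per site.  With unbiased=True the expected heterozygosity carries the
    2n/(2n - 1) factor.  Sites monomorphic in the pooled sample contribute
    no information (expected hom = 1, observed hom = 1) and effectively
    cancel; samples with L - E = 0 get F = NaN (undefined, flagged).
    """
    geno = np.asarray(geno)
    N, L = geno.shape
    called = geno != MISSING
    n_called = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, np.where(called, geno, 0).sum(axis=0) / (2 * n_called), np.nan)
    exp_het = 2.0 * p * (1.0 - p)
    if unbiased:
        with np.errstate(invalid="ignore", divide="ignore"):
            exp_het = exp_het * (2 * n_called) / (2 * n_called - 1.0)
    exp_hom_site = 1.0 - exp_het

    obs = np.zeros(N)
    exp = np.zeros(N)
    nsite = np.zeros(N, dtype=int)
    for i in range(N):
        m = called[i] & np.isfinite(exp_hom_site)
        nsite[i] = m.sum()
        obs[i] = ((geno[i, m] == 0) | (geno[i, m] == 2)).sum()
        exp[i] = exp_hom_site[m].sum()
    denom = nsite - exp
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom != 0, (obs - exp) / denom, np.nan)
    return InbreedingResult(list(sample_ids), obs, exp, nsite, f)
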