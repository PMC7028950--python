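"""Extended haplotype homozygosity (EHH) and the iHS / XP-EHH / nSL scans.

For a core SNP and an allele class (the carriers of allele 1, of allele 0,
or the pooled sample), the EHH at an extent covering sites ``core..j`` is
the probability that two randomly drawn haplotypes of the class are
identical over all those sites:

    EHH = sum_h C(n_h, 2) / C(n_c, 2)

summed over the distinct haplotype strings ``h`` among the ``n_c`` class
members.  The integrated haplotype homozygosity (iHH) is the trapezoidal
integral of the EHH decay curve against genetic distance (cM), summed over
both directions from the core, including the final trapezoid that crosses
the decay cutoff.

Raw statistics per core SNP:

* iHS     = ln(iHH1 / iHH0), derived (allele 1) vs ancestral (allele 0)
  class within one population;
* XP-EHH  = ln(iHH_focal / iHH_reference), each population's all-haplotype
  iHH integrated over a shared extent fixed by the pooled two-population
  EHH decay;
* nSL     = ln(SL1 / SL0), where SL_c is the mean over haplotype pairs of
  the class of the number of consecutive sites (counting the core) over
  which the pair is identical — map-free, capped per direction in sites.

Extension stops at the decay cutoff, at the maximum physical extension, at
an inter-marker gap larger than the maximum allowed, or at the chromosome
end.  A chromosome end or an oversized gap reached before the cutoff leaves
the curve truncated, and truncated cores are skipped by default (their
integrals are not comparable genome-wide); stopping at the maximum
extension is normal termination of the integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import HaplotypeMatrix, HapsweepError, PopulationLabels, VariantMap


@dataclass
class ScanParams:
    """Scan parameters; defaults follow standard selscan usage."""

    cutoff: float = 0.05
    max_extend_bp: int = 1_000_000
    max_gap_bp: int = 200_000
    max_extend_sites_nsl: int = 100
    maf_min_core: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise HapsweepError("cutoff must be in (0, 1)")
        if self.max_extend_bp <= 0 or self.max_gap_bp <= 0 or self.max_extend_sites_nsl <= 0:
            raise HapsweepError("extension limits must be positive")


@dataclass
class EHHProfile:
    """One-sided EHH decay curve from a core site.

    site_idx[0] is the core itself; ehh[0] is 1 within an allele class and
    the core-site homozygosity for the pooled class.  Values are
    non-increasing moving away from the core.  truncated means the curve hit
    the chromosome end or an oversized inter-marker gap before decaying
    below the cutoff.
    """

    core: int
    direction: str  # "left" or "right"
    site_idx: np.ndarray
    ehh: np.ndarray
    truncated: bool
    stop: str = ""  # cutoff | max_extend | gap | chrom_end | site_cap | exhausted


_POOLED = "pooled"


def _chrom_bounds(vmap: VariantMap, core: int) -> tuple[int, int]:
    """[lo, hi] inclusive index range of the core's chromosome."""
    c = vmap.chrom[core]
    same = np.flatnonzero(vmap.chrom == c)
    return int(same[0]), int(same[-1])


def _npairs(n: int) -> float:
    return n * (n - 1) / 2.0


def _refine(labels: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, float]:
    """Split haplotype groups by the next site's alleles; return the new
    labels and the number of still-identical pairs."""
    _, labels = np.unique(labels * 2 + col, return_inverse=True)
    counts = np.bincount(labels)
    return labels, float((counts * (counts - 1) // 2).sum())


def _class_rows(hm: HaplotypeMatrix, core: int, allele_class, rows: np.ndarray | None):
    base = np.arange(hm.n_haplotypes) if rows is None else np.asarray(rows)
    if allele_class == _POOLED:
        return base
    return base[hm.alleles[base, core] == allele_class]


def ehh_curve(
    hm: HaplotypeMatrix,
    vmap: VariantMap,
    core: int,
    allele_class,
    params: ScanParams | None = None,
    direction: str = "right",
    rows: np.ndarray | None = None,
    use_bp_limits: bool = True,
    max_steps: int | None = None,
    cutoff_override: float | None = None,
) -> EHHProfile:
    """EHH decay curve from `core` in one direction for one allele class.

    allele_class is 0, 1 or "pooled".  `rows` restricts the computation to a
    subset of haplotype rows (used for per-population curves).  With
    use_bp_limits=False the physical max-extend/max-gap limits are not
    applied (the site-count mode used by nSL); max_steps then caps the
    number of extension steps.  cutoff_override replaces the decay cutoff
    (0.0 extends until no identical pair remains, as nSL requires).
    """
    params = params or ScanParams()
    carriers = _class_rows(hm, core, allele_class, rows)
    n_c = len(carriers)
    if n_c < 2:
        raise HapsweepError(
            f"degenerate allele class {allele_class!r} at core {core} (n={n_c})"
        )
    H = hm.alleles
    npairs = _npairs(n_c)
    if allele_class == _POOLED:
        labels, ident = _refine(np.zeros(n_c, dtype=np.int64), H[carriers, core])
    else:
        labels, ident = np.zeros(n_c, dtype=np.int64), npairs
    sites = [core]
    values = [ident / npairs]
    lo, hi = _chrom_bounds(vmap, core)
    step = 1 if direction == "right" else -1
    pos = vmap.pos_bp
    cutoff = params.cutoff if cutoff_override is None else cutoff_override
    truncated = True  # until the curve decays below the cutoff
    stop = ""
    j = core
    steps = 0
    while True:
        nxt = j + step
        if nxt < lo or nxt > hi:
            stop = "chrom_end"  # truncated
            break
        if max_steps is not None and steps >= max_steps:
            truncated, stop = False, "site_cap"
            break
        if use_bp_limits:
            if abs(int(pos[nxt]) - int(pos[j])) > params.max_gap_bp:
                stop = "gap"  # truncated
                break
            if abs(int(pos[nxt]) - int(pos[core])) > params.max_extend_bp:
                truncated, stop = False, "max_extend"
                break
        labels, ident = _refine(labels, H[carriers, nxt])
        ehh = ident / npairs
        sites.append(nxt)
        values.append(ehh)
        j = nxt
        steps += 1
        if ehh < cutoff:
            truncated, stop = False, "cutoff"
            break
        if ident == 0:
            truncated, stop = False, "exhausted"
            break
    return EHHProfile(
        core, direction, np.asarray(sites), np.asarray(values), truncated, stop
    )


def ihh(
    profile_left: EHHProfile, profile_right: EHHProfile, vmap: VariantMap
) -> tuple[float, bool]:
    """Integrated haplotype homozygosity over both directions.

    Trapezoidal integral of EHH against genetic distance (cM) from the core,
    including the final trapezoid crossing the cutoff.  Returns
    (value, unreliable) where unreliable flags a truncated profile.
    """
    if profile_left.core != profile_right.core:
        raise HapsweepError("profiles from different cores")
    total = 0.0
    for prof in (profile_left, profile_right):
        x = np.abs(vmap.pos_cm[prof.site_idx] - vmap.pos_cm[prof.core])
        total += float(np.trapezoid(prof.ehh, x))
    return total, (profile_left.truncated or profile_right.truncated)


def _core_candidates(hm: HaplotypeMatrix, params: ScanParams, rows=None) -> np.ndarray:
    H = hm.alleles if rows is None else hm.alleles[rows]
    f = H.mean(axis=0)
    maf = np.minimum(f, 1.0 - f)
    return maf >= params.maf_min_core


def ihs_scan(
    hm: HaplotypeMatrix,
    vmap: VariantMap,
    params: ScanParams | None = None,
    trunc_ok: bool = False,
) -> pd.DataFrame:
    """Raw iHS per SNP: ln(iHH1 / iHH0) within a single population.

    Cores are skipped (with a reason, never silently) when the core MAF is
    below maf_min_core, either allele class has fewer than two haplotypes,
    any of the four decay curves is truncated (unless trunc_ok), or either
    iHH is zero.
    """
    params = params or ScanParams()
    f1 = hm.freq1()
    ok_maf = _core_candidates(hm, params)
    records = []
    for core in range(hm.n_sites):
        rec = {
            "chrom": vmap.chrom[core],
            "variant_id": vmap.variant_id[core],
            "pos_bp": int(vmap.pos_bp[core]),
            "freq1": float(f1[core]),
            "comp1": np.nan,
            "comp0": np.nan,
            "raw": np.nan,
            "skip_reason": "",
        }
        if not ok_maf[core]:
            rec["skip_reason"] = "low_maf"
            records.append(rec)
            continue
        n1 = int(hm.alleles[:, core].sum())
        n0 = hm.n_haplotypes - n1
        if n1 < 2 or n0 < 2:
            rec["skip_reason"] = "degenerate_class"
            records.append(rec)
            continue
        profs = {
            (a, d): ehh_curve(hm, vmap, core, a, params, direction=d)
            for a in (1, 0)
            for d in ("left", "right")
        }
        ihh1, t1 = ihh(profs[(1, "left")], profs[(1, "right")], vmap)
        ihh0, t0 = ihh(profs[(0, "left")], profs[(0, "right")], vmap)
        rec["comp1"], rec["comp0"] = ihh1, ihh0
        if (t1 or t0) and not trunc_ok:
            rec["skip_reason"] = "truncated"
        elif ihh1 <= 0 or ihh0 <= 0:
            rec["skip_reason"] = "zero_ihh"
        else:
            rec["raw"] = float(np.log(ihh1 / ihh0))
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    out["statistic"] = "ihs"
    return out


def xpehh_scan(
    hm: HaplotypeMatrix,
    vmap: VariantMap,
    labels: PopulationLabels,
    focal_pop: str,
    ref_pop: str,
    params: ScanParams | None = None,
    trunc_ok: bool = False,
) -> pd.DataFrame:
    """Raw XP-EHH per SNP: ln(iHH_focal / iHH_reference).

    The extension extent per core is fixed by the pooled two-population EHH
    decay against the cutoff; each population's all-haplotype EHH is then
    integrated over exactly that extent.  freq1 is the focal-population
    allele-1 frequency (used downstream for frequency binning).
    """
    params = params or ScanParams()
    labels.validate_against(hm)
    rows_a = labels.haplotype_rows(hm, focal_pop)
    rows_b = labels.haplotype_rows(hm, ref_pop)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise HapsweepError("both populations need >= 2 haplotypes")
    rows_pooled = np.concatenate([rows_a, rows_b])
    pooled_ok = _core_candidates(hm, params, rows_pooled)
    f1_a = hm.alleles[rows_a].mean(axis=0)
    records = []
    for core in range(hm.n_sites):
        rec = {
            "chrom": vmap.chrom[core],
            "variant_id": vmap.variant_id[core],
            "pos_bp": int(vmap.pos_bp[core]),
            "freq1": float(f1_a[core]),
            "comp1": np.nan,
            "comp0": np.nan,
            "raw": np.nan,
            "skip_reason": "",
        }
        if not pooled_ok[core]:
            rec["skip_reason"] = "low_maf"
            records.append(rec)
            continue
        truncated = False
        ihh_ab = {"a": 0.0, "b": 0.0}
        for direction in ("left", "right"):
            pooled = ehh_curve(
                hm, vmap, core, _POOLED, params, direction=direction, rows=rows_pooled
            )
            truncated |= pooled.truncated
            for key, rows in (("a", rows_a), ("b", rows_b)):
                ihh_ab[key] += _ihh_over_sites(hm, vmap, core, pooled.site_idx, rows)
        rec["comp1"], rec["comp0"] = ihh_ab["a"], ihh_ab["b"]
        if truncated and not trunc_ok:
            rec["skip_reason"] = "truncated"
        elif ihh_ab["a"] <= 0 or ihh_ab["b"] <= 0:
            rec["skip_reason"] = "zero_ihh"
        else:
            rec["raw"] = float(np.log(ihh_ab["a"] / ihh_ab["b"]))
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    out["statistic"] = "xpehh"
    return out


def _ihh_over_sites(
    hm: HaplotypeMatrix,
    vmap: VariantMap,
    core: int,
    site_idx: np.ndarray,
    rows: np.ndarray,
) -> float:
    """One population's all-haplotype EHH integrated over a fixed extent."""
    carriers = np.asarray(rows)
    npairs = _npairs(len(carriers))
    labels, ident = _refine(
        np.zeros(len(carriers), dtype=np.int64), hm.alleles[carriers, core]
    )
    values = [ident / npairs]
    for j in site_idx[1:]:
        labels, ident = _refine(labels, hm.alleles[carriers, j])
        values.append(ident / npairs)
    x = np.abs(vmap.pos_cm[site_idx] - vmap.pos_cm[core])
    return float(np.trapezoid(values, x))


def _mean_run_length(
    hm: HaplotypeMatrix,
    vmap: VariantMap,
    core: int,
    allele: int,
    direction: str,
    cap: int,
    params: ScanParams,
) -> float:
    """Mean (over class pairs) count of consecutive identical sites beyond
    the core in one direction, capped at `cap` sites."""
    prof = ehh_curve(
        hm, vmap, core, allele, params, direction=direction,
        use_bp_limits=False, max_steps=cap, cutoff_override=0.0,
    )
    # sum over extents d>=1 of P(pair identical through extent d)
    return float(prof.ehh[1:].sum())


def nsl_scan(
    hm: HaplotypeMatrix,
    vmap: VariantMap,
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """Raw nSL per SNP: ln(SL1 / SL0), haplotype length in segregating sites.

    SL_c is the mean over haplotype pairs of class c of the number of
    consecutive sites (counting the core) over which the pair is identical,
    extended in both directions and capped at max_extend_sites_nsl sites per
    direction.  No recombination map or physical-distance limit is used.
    """
    params = params or ScanParams()
    f1 = hm.freq1()
    ok_maf = _core_candidates(hm, params)
    cap = params.max_extend_sites_nsl
    records = []
    for core in range(hm.n_sites):
        rec = {
            "chrom": vmap.chrom[core],
            "variant_id": vmap.variant_id[core],
            "pos_bp": int(vmap.pos_bp[core]),
            "freq1": float(f1[core]),
            "comp1": np.nan,
            "comp0": np.nan,
            "raw": np.nan,
            "skip_reason": "",
        }
        if not ok_maf[core]:
            rec["skip_reason"] = "low_maf"
            records.append(rec)
            continue
        n1 = int(hm.alleles[:, core].sum())
        n0 = hm.n_haplotypes - n1
        if n1 < 2 or n0 < 2:
            rec["skip_reason"] = "degenerate_class"
            records.append(rec)
            continue
        sl = {}
        for a in (1, 0):
            sl[a] = 1.0 + sum(
                _mean_run_length(hm, vmap, core, a, d, cap, params)
                for d in ("left", "right")
            )
        rec["comp1"], rec["comp0"] = sl[1], sl[0]
        rec["raw"] = float(np.log(sl[1] / sl[0]))
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    out["statistic"] = "nsl"
    return out


def write_scan_tsv(path, result: pd.DataFrame) -> None:
    """Per-statistic TSV mirroring the selscan column layout."""
    cols = [
        "chrom", "variant_id", "pos_bp", "freq1", "comp1", "comp0", "raw",
    ]
    extra = [c for c in ("standardized", "significant") if c in result.columns]
    result[cols + extra + ["skip_reason", "statistic"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
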