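# hapsweep

Selection-sweep scanning for phased SNP-chip data from small, weakly
structured livestock populations — the setting of the Djallonké (West
African Dwarf) sheep, where drift is strong, differentiation from
neighbouring populations is low (weighted F_ST ≈ 0.066), and extended
haplotype homozygosity (EHH) statistics are the tool of choice because they
do not require well-separated populations.

The package implements, end to end:

* **Haplotype statistics** — iHS, XP-EHH and nSL from phased biallelic
  haplotypes.  For a core SNP and allele class, EHH(x) is the probability
  that two random class haplotypes are identical over all markers from the
  core out to x; iHH is the trapezoidal integral of the decay curve against
  genetic distance.  Raw scores are iHS = ln(iHH₁/iHH₀) within one
  population, XP-EHH = ln(iHH_A/iHH_B) between populations over a shared
  extent, and nSL = ln(SL₁/SL₀) with haplotype length counted in
  segregating sites (map-free).  Decay cutoff 0.05, maximum extension 1 Mb,
  maximum marker gap 200 kb.
* **Standardization** — genome-wide z-scoring within 100 equal-width
  allele-frequency bins; SNPs with |z| > 2 (strict) are called significant,
  both signs retained.
* **Consensus sweep regions** — seeded by (a) single SNPs significant in
  ≥ 2 statistics or (b) pairs of significant SNPs whose ±75 kb windows
  overlap and jointly cover ≥ 2 statistics; any significant SNP whose
  window chains into a region joins it (closure); overlapping regions
  merge.  Region extent is the union of member windows.
* **Annotation** — candidate-gene capture in 75 kb flanks, bedtools-style
  interval intersection with QTL tracks, gene-cluster span arithmetic, and
  the DAVID enrichment-score ↔ Fisher-P conversion (score = −log₁₀ P;
  1.3 ↔ 0.05).
* **Population-genetic summaries** — Weir–Cockerham (1984) F_ST with the
  weighted ratio-of-sums estimator, and method-of-moments inbreeding F.
* **Chip-style QC** — call-rate, MAF and exact Hardy–Weinberg filters with
  a per-step report.
* **Synthetic data** — a Li–Stephens founder-mosaic simulator producing
  chip-density haplotypes with decaying LD, planted hard/soft sweeps and a
  calibrated low-F_ST second population, so the whole pipeline is testable
  without any external dataset.

## Worked example

Simulate a two-population dataset with a hard sweep planted at derived
frequency 0.7 in the focal population, then run the full scan:

```sh
cat > simcfg.yaml <<EOF
n_samples: 30
n_samples_ref: 12
n_sites: 400
divergence_drift: 0.05
sweep:
  core_index: 200
  target_derived_freq: 0.7
  tract_scale_bp: 2000000
EOF
hapsweep simulate --config simcfg.yaml --seed 17 -o simout
hapsweep run --vcf simout/synthetic.vcf --populations simout/populations.tsv \
    --focal-pop focal --ref-pop reference -o runout --seed 17
```

which prints

```
wrote 42 samples x 360 SNPs to simout
4 sweep regions spanning 769264 bp (6 member SNPs, 4 multi-statistic)
```

360 of the 400 simulated markers survive the 5% MAF floor; the scan calls
four consensus regions totalling ~0.77 Mb, defined by six significant SNPs
of which four are supported by at least two of the three statistics — the
largest region covers the planted sweep.  `runout/` holds the per-statistic
score tables (`scan_*.tsv`, selscan-style columns with raw and standardized
scores and skip reasons), the region list as TSV and BED, the per-chromosome
summary, the QC report and a full run log.

The same operations are available as a library:

```python
import hapsweep as hs

hm, vmap = hs.read_phased_vcf("phased.vcf")
res = hs.ihs_scan(hm, vmap)
res["z"] = hs.normalize(res["raw"].to_numpy(), res["freq1"].to_numpy())
```

## Layout

| module | contents |
|---|---|
| `hapsweep.io_model` | data containers; VCF / PLINK ped-map / BED / TSV readers and writers |
| `hapsweep.synthetic_data` | founder-mosaic simulator, sweep planting, divergence calibration |
| `hapsweep.qc` | HWE exact test, marker/sample filter cascade |
| `hapsweep.ehh_stats` | EHH curves, iHH, iHS / XP-EHH / nSL scans |
| `hapsweep.normalization` | frequency-binned standardization, significance calls |
| `hapsweep.sweep_regions` | consensus region construction and summaries |
| `hapsweep.annotation` | gene capture, interval intersection, enrichment scores, bundled tables |
| `hapsweep.popgen` | Weir–Cockerham F_ST, inbreeding F |
| `hapsweep.pipeline` / `hapsweep.cli` | orchestration and the `hapsweep` command |

See `docs/methods.md` for the models, parameter choices and limitations.
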