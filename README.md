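# rankset

A dual-contrast, rank-based gene-set enrichment pipeline for bulk
RNA-seq count data, built around a 2×2 (glucose × drug) replicated
design:

1. **simdata** — negative-binomial count simulator (mean λ, variance
   λ + φλ², φ = φ₀ + a/λ) for a four-group (LG, LGV, HG, HGV) design
   with variable library sizes, planted coordinated log2FC shifts in
   selected gene sets, and exact ground truth.
2. **formats** — validating readers/writers for GMT gene sets,
   count/design tables, DE tables, ranked profiles and a flat
   key=value config file. Gene IDs are upper-cased on ingestion.
3. **diffexpr** — low-count filter (mean < 10 reads/sample removed),
   log2-CPM with pseudo-count, a moderated two-group t-test with an
   empirically estimated variance prior, and Benjamini–Hochberg FDR.
4. **rankmetric** — directional significance score
   `s = sign(log2FC) · (−log10 p)` and centered scaled ranks
   `(rank − (N+1)/2)/N` in (−0.5, 0.5).
5. **gsea1d** — classic-mode (unweighted KS) pre-ranked GSEA with a
   gene-tag permutation null, NES, signed FDR and leading-edge genes.
6. **enrich2d** — the headline procedure: join two contrasts into a 2D
   rank space, score each set's displacement (`s_d = 2·mean(r_d)`),
   test it with a two-group MANOVA of ranks (Pillai's trace, exact
   two-group F ≡ Hotelling's T²), BH-correct across sets, and export
   rank–rank density grids.
7. **qpcr** — comparative 2^−ΔΔCt relative quantification and
   ChIP-qPCR percent-of-input arithmetic.

## CLI

Everything is reachable through the `rankset` entry point:

```sh
# simulate a demonstration experiment (3 planted + 20 null sets),
# run both contrasts, GSEA and the 2D test:
rankset run-all --out-dir out/

# or stage by stage on your own data:
rankset de --counts counts.tsv --design design.tsv --contrast HG,LG --out de1.tsv
rankset de --counts counts.tsv --design design.tsv --contrast HGV,HG --out de2.tsv
rankset rank --de de1.tsv --out ranked1.tsv
rankset gsea --ranked ranked1.tsv --gmt sets.gmt --nperm 1000 --seed 1 --out gsea1.tsv
rankset enrich2d --de1 de1.tsv --de2 de2.tsv --gmt sets.gmt \
    --out enrich2d.tsv --grid-out grid.tsv
rankset qpcr --ct ct.tsv --reference H3F3 --calibrator LG --out rq.tsv
```

Contrasts are given as `treatment,control`; log2FC is treatment minus
control. A flat `key = value` config file can be passed with
`--config`; explicit CLI flags win on conflict.

## Notes and limitations

- The DE stage is a documented stand-in (limma-style moderated t on
  log-CPM), not a reimplementation of edgeR/limma; external DE tables
  can be supplied to every downstream stage.
- Normalization is total-count CPM; TMM-style compositional factors
  are deliberately omitted.
- The literal score variant `sign(log2FC)/log10(p)` is available for
  audit via `rankset rank --literal-formula`; it is non-monotone and
  not recommended.
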