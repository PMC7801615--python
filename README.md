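# compdecon

Composition-aware analysis of paired bulk RNA-seq via single-cell
deconvolution, built for experiments like ethanol-vs-vehicle exposure of
colon crypt organoids: the same subjects contribute one treated and one
control culture, and an apparent transcriptional response can be a change in
*which cells are present* rather than in what any cell expresses. The
package separates those explanations.

It is aimed at bioinformaticians analyzing paired bulk designs who have (or
can simulate) a labeled single-cell reference of the constituent cell types —
here the six colon-crypt epithelial populations: stem, transit-amplifying
(TA), immature colonocyte, immature goblet, enteroendocrine, and tuft cells.

## What it computes

1. **Signature matrix** `S` (genes × cell types): mean CPM of candidate
   markers chosen by a one-vs-rest Welch test (BH q < 0.001, positive
   log2FC), taking the per-type top-G whose union minimizes the condition
   number κ(S) over G ∈ [100, 600].
2. **Cell scores** per bulk sample: ν-SVR regression of the z-scored mixture
   `m` on the z-scored signature (ν ∈ {0.25, 0.5, 0.75}, best RMSE), clamped
   and normalized to fractions `f` with Σ_k f_k = 1; absolute scores
   `a_k = f_k · median(m over signature genes) / median(S)` so totals can
   differ between arms; NNLS as the exact convex oracle.
3. **Composition shifts**: per cell type, paired t-test on per-subject
   differences d_i = score(control_i) − score(treated_i) with a 95%
   t-interval (positive = higher in control), plus a total-score test.
4. **Differential expression**: per-gene NB GLMs with log size-factor
   offsets —
   unadjusted `y ~ pair + treatment`; composition-adjusted
   `y ~ pair + scores + treatment`; and cell-type-specific response via a
   likelihood-ratio test of `treatment:score_k` (χ², 1 df), one cell type at
   a time, BH-corrected at q < 0.1.
5. **Marker enrichment**: direction × cell-type overlap grids and one-sided
   (hypergeometric tail) Fisher tests against the tested-gene universe.

A first-class synthetic-data module generates the whole study with known
ground truth — labeled single-cell references (including cells planted to
fail QC) and paired bulk mixtures whose compositions respond to treatment on
the log-proportion scale with location-dependent strength — which is how the
package validates itself end to end.

## Worked example

```python
import numpy as np
import compdecon as cd

cfg = cd.SimulationConfig(seed=7)          # 34 subject pairs, 16 left / 18 right
ref, truth = cd.simulate_reference(cfg)
ref = cd.normalize_reference(cd.qc_filter_cells(ref))
sig = cd.build_signature(ref)
print(f"signature: {len(sig.genes)} genes x {len(sig.cell_types)} cell types, "
      f"chosen G = {sig.chosen_g}, condition number = {sig.condition_number:.2f}")

exp, btruth = cd.simulate_paired_bulk(cfg, truth.profiles)
scores = cd.deconvolve_experiment(exp, sig)
r = np.corrcoef(scores.fractions["TA"], btruth.proportions["TA"])[0, 1]
print(f"TA fraction: estimated vs true Pearson r = {r:.3f}")
print(cd.paired_score_test(scores, exp.metadata).round(3).to_string())
```

prints

```
signature: 726 genes x 6 cell types, chosen G = 121, condition number = 2.18
TA fraction: estimated vs true Pearson r = 0.999
                    mean_difference  ci_low  ci_high  statistic  p_value  n_pairs
cell_type
Enteroendocrine               0.001  -0.003    0.006      0.693    0.493       34
ImmatureColonocyte            0.066   0.051    0.082      8.699    0.000       34
ImmatureGoblet                0.033   0.021    0.044      5.752    0.000       34
Stem                          0.010  -0.002    0.022      1.665    0.105       34
TA                           -0.078  -0.096   -0.060     -8.780    0.000       34
Tuft                          0.011   0.002    0.020      2.477    0.019       34
```

The generator's default treatment expands the TA compartment at the expense
of the immature colonocyte/goblet lineages; under the control − treated
convention that is exactly what the table shows: TA negative (expanded by
treatment, CI excluding zero), the immature lineages positive (depleted).
The signature's condition number (2.18) says the six cell-type columns are
well separated, and the near-unit correlation confirms the SVR fractions
track the true mixing proportions.

The same stages are available from the shell:

```bash
compdecon pipeline --outdir run --seed 7     # simulate -> QC -> signature ->
                                             # deconvolve -> composition -> DE -> enrichment
compdecon simulate --outdir data --seed 7    # or drive stages individually
compdecon dge --counts run/bulk_counts.tsv --tpm run/bulk_tpm.tsv \
  --metadata run/bulk_metadata.tsv --model paired --out de.tsv
```

Every run directory contains a `manifest.yaml` (versions, per-stage seeds,
parameter echo) sufficient to reproduce it byte-for-byte.

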