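# diauxflux

Constraint-based model comparison and untargeted-metabolomics analysis
of the yeast diauxic shift.

When a *Saccharomyces cerevisiae* batch culture exhausts its glucose, it
pauses and rewires its metabolism to respire the ethanol it fermented
earlier — the diauxic shift. Competing genome-scale regulatory models
make different predictions about which regulatory-gene deletions perturb
that transition, and untargeted LC-MS metabolomics of deletion strains
can arbitrate between them. `diauxflux` implements that full analysis
chain for systems biologists who want to run it, test it, or study its
statistical behavior on synthetic data with known ground truth:

1. **Strain selection by simulation** — knockout-constrained flux
   balance analysis (FBA, maximize biomass c·v subject to S·v = 0 and
   bounds) and dynamic FBA across the shift, ranking deletions by the
   absolute post-shift growth-rate discrepancy |μ_B − μ_A| between two
   regulatory rule-set variants (labelled M1 and M1Smart).
2. **Metabolomics preprocessing** — blank / fill (< 0.1) /
   signal-to-noise (< 10) / detection (two-thirds per batch) filtering,
   QC-based robust LOESS drift correction (QC-RLSC), batch concatenation
   at ±0.01 Da and ±0.75 min, and Bolstad quantile normalization.
3. **Differential analysis** — per-feature covariate-adjusted linear
   models on log2 intensities (raw p < 0.1, fold change > 1.5), OPLS-DA
   phase discrimination, Pearson-correlation strain clustering.
4. **Pathway context** — diffusion enrichment on a typed
   metabolite–pathway graph: scores solve (L + λI)f = b, significance by
   permutation p-scores.
5. **Model validation** — flux-sums Φ_i = ½ Σ_j |S_ij v_j| as proxies of
   metabolite turnover, Wilcoxon/Spearman comparison of 13 replicate
   simulations per variant, and balanced accuracy
   (sensitivity + specificity)/2 of flux-sum predictions against
   observed accumulation changes.

Every input the pipeline needs — toy model pairs with planted regulatory
differences, diauxic growth curves, structured peak tables, knowledge
graphs — is produced by the `synthetic_data` module with ground truth
attached, so each stage's recovery behavior is testable end to end.

## Worked example

```python
from diauxflux import synthetic_data as sd, fba_engine as fe

model, m1, m1smart, truth = sd.make_toy_model_pair(seed=1)
print(fe.rank_strains(model, m1, m1smart, list(model.regulator_genes)))

traj = fe.run_dfba(model, m1smart, None)
print(f"shift={traj.shift_time:.1f} h  pre={traj.pre_rate:.3f}/h  "
      f"post={traj.post_rate:.4f}/h")
```

prints

```
gene  growth_a  growth_b  abs_diff
REG1      0.15  0.000000  0.150000
REG5      0.15  0.096621  0.053379
REG2      0.15  0.150000  0.000000
...
shift=4.3 h  pre=0.835/h  post=0.0048/h
```

The two planted discriminating genes top the ranking: deleting `REG1`
abolishes post-shift growth only under the revised variant
(M1Smart knows it is required for ethanol transport after the shift,
|Δμ| = 0.15 h⁻¹), and `REG5` merely throttles respiration
(|Δμ| ≈ 0.05 h⁻¹); the other regulators have no planted mechanism and
their discrepancy is exactly zero. The wild-type dFBA trajectory shows
the diauxie itself: fast fermentative growth (0.84 h⁻¹), glucose
depletion at 4.3 h, then slow growth on the accumulated ethanol.

The whole study replica — generation, ranking, preprocessing,
differential statistics, enrichment and closed-loop validation — runs
from one config:

```bash
diauxflux run --seed 1 --out runs/demo
```

and writes tables (`strain_ranking.csv`, `peaks_normalized.csv`,
`diff_phase.csv`, `enrichment.csv`, `model_validation.csv`), a log and a
manifest. Each stage also has its own subcommand (`diauxflux growth
detect`, `fba rank`, `metab preprocess`, `stats diff`, `enrich`,
`validate`).

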