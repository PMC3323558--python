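# apmscan

Nonparametric genetic linkage scans for **exceptional human longevity** on
extended pedigrees.

Mapping longevity genes with families rather than case/control cohorts
sidesteps the intergenerational biases of GWAS designs, but the pedigrees
that make such studies powerful — deep genealogies with large sibships and
many ungenotyped connecting relatives — defeat exact multipoint IBD
software. `apmscan` implements the pragmatic alternative: an
affected-pedigree-member (APM) allele-sharing scan whose null distribution
comes from gene-dropping Monte Carlo simulation on the very pedigree under
study. It is aimed at statistical geneticists working with
multigenerational cohorts (and at anyone who wants a fully synthetic,
reproducible test bed for this class of methods).

## What it computes

* **Phenotypes** — excess longevity `EL = observed − expected lifespan`
  (sex- and birth-cohort-adjusted) and familial excess longevity
  `FEL_i = Σ_j 2φ(i,j) EL_j / Σ_j 2φ(i,j)`, the kinship-weighted mean EL of
  i's relatives. "Affected" = top quartile of both (closed thresholds,
  e.g. EL ≥ 3.0 and FEL ≥ 1.75 years), or an attained-age cutoff for
  sensitivity analyses.
* **The APM statistic** — for each affected relative pair at each marker,
  `S_ij = ¼ Σ_a Σ_b δ(G_ia, G_jb) f(q(G_ia))` with `f(q) = 1/√q` by
  default (sharing a rare allele counts for more), summed over pairs.
* **The null** — founder alleles drawn from population frequencies and
  dropped through the pedigree by Mendelian segregation; linked markers
  travel on chromosomes with Haldane recombination
  `θ = (1 − e^(−2d))/2`. Z-scores, asymptotic and empirical p-values per
  locus; degenerate (monomorphic) nulls are reported, not scored.
* **Multipoint** — window sums over adjacent markers against the linked
  null, and a 1-cM grid interpolating flanking markers with weights
  inverse to their recombination probability.
* **Experiment-wise adjustment** — each null replicate yields a
  genome-wide Z curve; the adjusted p at a locus is the fraction of
  replicates whose genome-wide maximum Z reaches the observed Z.
* **Meta-analysis** — cross-study combination by the (un)weighted mean
  Z-score rule `Z_meta = Σ w_k Z_k / √(Σ w_k²)`.
* **Synthetic studies** — multigeneration kindreds, microsatellite-like
  panels (2–38 alleles, ~3.4 cM spacing), a dominant longevity allele
  with a Gompertz proportional-hazards effect on lifespan (default:
  frequency 0.01, all-cause mortality hazard ratio 0.5), genotyping
  missingness, and ascertainment-design evaluation (PPV / sensitivity of
  selection rules).

## Worked example

Simulate a small study (12 kindreds, ~500 members, a causal allele at
40 cM with hazard ratio 0.5) and scan it:

```sh
cat > sim.yaml <<'YAML'
n_founder_couples: 12
n_generations: 3
mean_offspring: 5.0
causal_allele_freq: 0.1
hazard_ratio: 0.5
chrom_lengths_cm: [100.0]
causal_chrom: '1'
causal_position_cm: 40.0
YAML
apmscan simulate --config sim.yaml --seed 7 --out study
# -> wrote study to study: 505 individuals, 30 markers, 90 carriers

printf 'n_reps: 200\nselection_mode: el_fel_quartile\n' > scan.yaml
apmscan run --ped study/study.ped --map study/study.map \
  --phen study/study.phen.tsv --expected study/study.expected.tsv \
  --freq study/study.freq.tsv --config scan.yaml --seed 11 --out results
# -> seed=11 n_reps=200 weight=inverse_sqrt
# -> affected=40 pairs=135 markers=30 degenerate=0
```

`results/singlepoint.tsv` holds one row per marker (first lines shown):

```
chrom  marker  position_cM  observed  null_mean  null_sd  Z         p_asymptotic  p_empirical  n_pairs  n_reps  p_adjusted
1      C1M1    0.00         79.6872   107.075    24.9614  -1.09722  0.863727      0.935        128      200     1
1      C1M2    3.45         98.2601   96.8797    17.9191  0.0770336 0.469298      0.39         121      200     1
```

Reading a row: at marker C1M2, 121 of the 135 affected pairs were typed;
their summed sharing score (98.3) sits 0.08 null SDs above the mean of 200
gene-drop replicates, i.e. no evidence of linkage there. The grid file
gives the same quantities at 1-cM steps; in this run its top score is
Z = 2.48 at 9 cM (nominal p = 0.0066, empirical p = 0.03) but the
experiment-wise adjusted p of 0.54 says a null genome of this size tops
Z = 2.48 somewhere about half the time — a textbook illustration of why
the adjustment matters. `results/regions.tsv` summarises contiguous grid
runs below the nominal-p threshold (here 9–10 cM, max Z 2.48, adjusted
p 0.54), and `results/qc.tsv` the marker call-rate filter (≥ 50% typed).

A run this small has little power; the causal locus at 40 cM is not
detected. `docs/methods.md` quantifies what sample sizes this design needs
and why — the candid answer is that top-quartile ascertainment caps the
carrier fraction among affecteds near 30%, so reliable localization needs
thousands of individuals.

Cross-study meta-analysis takes per-study TSVs of `position_cM` and `Z`:

```sh
apmscan meta --inputs study_a_grid.tsv --inputs study_b_grid.tsv --out meta.tsv
```

## Library use

Everything the CLI does is a thin wrapper over importable functions:
`apmscan.pedigree` (validation, kinship, pair enumeration),
`apmscan.phenotype` (EL/FEL/selection), `apmscan.genedrop` (Haldane map,
vectorised gene dropping, IBD oracle), `apmscan.linkage` (sharing
statistic, nulls, multipoint, adjustment, meta), `apmscan.simulate`
(synthetic studies), `apmscan.pipeline` (`read_study_inputs` → `run_scan`
→ `write_report`), and `apmscan.evaluation` (standard calibration and
power studies).

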