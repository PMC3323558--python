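# Methods

`apmscan` implements a nonparametric linkage scan for exceptional human
longevity on extended pedigrees: survival-based phenotype construction,
affected-relative-pair selection, the simplified affected-pedigree-member
(APM) allele-sharing statistic with a gene-dropping Monte Carlo null,
recombination-aware multipoint scoring, genome-wide empirical adjustment,
and cross-study Z-score meta-analysis. This note records the model, the
defaults and why they are what they are, the numerical choices, and the
known limitations — in particular what the synthetic-data experiments do
and do not establish.

## Phenotypes

**Excess longevity (EL)** is observed lifespan minus the expected lifespan
for an individual's sex and birth cohort, taken from a user-supplied table
(sex × cohort band → years). EL is deliberately table-driven rather than
re-fitted from survival models: the linkage stage treats EL as given, and a
table keeps it deterministic and testable. Queries inside a band return the
band value; gaps between bands of the same sex are linearly interpolated
between band midpoints; uncovered cohorts are an error rather than a silent
extrapolation.

**Familial excess longevity (FEL)** is a kinship-weighted average of EL
over an individual's relatives:

    FEL_i = Σ_{j≠i} w_ij EL_j / Σ_{j≠i} w_ij,   w_ij = 2 φ(i,j),

with φ the kinship coefficient. The weight 2φ (expected IBD-sharing
proportion for non-inbred pairs) and the normalisation by Σw are design
choices: "kinship-weighted average" is underdetermined, and normalising
makes FEL a years-scale quantity comparable with years-scale thresholds
(e.g. FEL ≥ 1.75). An individual with no positive-kinship relative carrying
a defined EL has FEL = null, never 0.

**Affected status** is either (a) EL ≥ el_min AND FEL ≥ fel_min with closed
thresholds (defaults 3.0 and 1.75 years, the top-quartile cutoffs of the
source population; `el_fel_quartile` mode re-derives both as 75th
percentiles of the data at hand, linear-interpolation quantile), or (b) an
attained-age cutoff (95/98/100) applied regardless of sex or family
history, used for sensitivity analyses. Raising any threshold can only
shrink the affected set (tested property).

## Pedigrees and kinship

Pedigrees are validated parent-offspring DAGs. Kinship is computed by the
classical recursion on a topological order (recurse on the individual that
cannot be an ancestor of the other), memoized; this handles multiple lines
of descent without path enumeration. Unknown-sex parents are allowed — the
opposite-sex check fires only when both parents' sexes are recorded —
because real genealogies have gaps and gene-dropping needs only two
distinct parents. Affected pairs are unordered, deduplicated, and carry the
full summed-path φ; by default any pair with φ > 0 counts (the source
design sets no minimum kinship), with an explicit `min_kinship` available.
The independent check on all of this is `genedrop.estimate_ibd`: dropping a
fully informative locus and counting shared alleles converges to 2φ, and
the test suite requires agreement within 3 Monte Carlo SE for
parent-offspring, sib, avuncular, first-cousin, and double-first-cousin
pairs.

## The APM statistic and its null

For a pair (i, j) at a marker with genotypes (G_i1, G_i2), (G_j1, G_j2) and
allele frequencies q(·),

    S_ij = 1/4 Σ_a Σ_b δ(G_ia, G_jb) · f(q(G_ia)),

with δ the Kronecker delta. The weight f is configurable: `constant`
(f = 1, S bounded in [0, 1]), `inverse_sqrt` (f = 1/√q, the classical
Weeks-Lange choice and the default — sharing a rare allele is more
surprising), or `inverse` (f = 1/q). The marker score is the sum of S_ij
over affected pairs with complete genotypes; a pair missing either
genotype at a marker is excluded at that marker, in the observed data and
in every null replicate alike, so the null reflects the observed
information pattern.

The null is **gene dropping**: founder alleles drawn i.i.d. from q
(linkage equilibrium), transmitted by Mendelian segregation; for linked
markers whole chromosomes are transmitted with switches between the two
parental haplotypes at inter-marker recombination fractions given by
Haldane's map function θ = (1 − e^(−2d))/2 (d in Morgans; no
interference). Unlinked markers are the θ = ½ special case, which lets one
vectorised engine serve both modes: a single call simulates all replicates
for the whole pedigree at once. Streams are seeded hierarchically per
chromosome (`numpy` `SeedSequence.spawn`), with all replicates of a
chromosome drawn from that one stream — identical seeds give identical
ensembles, and chromosomes are independent.

Scores are standardised as Z = (observed − null mean)/null SD, signed so
that excess sharing is positive. Asymptotic p is the upper-tail normal
probability; the empirical p is #{null ≥ observed}/n by default (plug-in,
matching the original procedure), with (k+1)/(n+1) selectable to avoid
exact zeros. A marker whose null replicates are all equal (effectively
monomorphic) is a degenerate-null error, not a Z of ±∞; the pipeline drops
such markers and lists them in the results.

Default replication is 500 drops per chromosome, and one linked ensemble
per chromosome serves every locus on it (singlepoint marginals equal the
unlinked law, so nothing is lost, and per-replicate genome-wide Z curves
are well defined — needed for the experiment-wise adjustment).

## Multipoint and the cM grid

The multipoint statistic is the plain sum of per-marker scores over a
window of adjacent markers (default: all markers within 10 cM of the focal
marker — spacing-adaptive, and a window of one marker reduces exactly to
the singlepoint statistic). Its null is the identical sum over linked
replicates, which is what accounts for inter-marker dependence.

Between adjacent markers L and R, scores are interpolated on a 1-cM grid
with weights inverse to the recombination probability with each flank:
w_L ∝ 1/θ(d_L), normalised; at a marker the weight collapses to that
marker. The same linear combination is applied to every null replicate
before standardisation, so grid Z values are properly calibrated.

## Genome-wide (experiment-wise) adjustment

Each null replicate is converted to a genome-wide Z curve over all scored
loci (markers, windows, grid positions); the adjusted p at a locus is the
proportion of replicates whose genome-wide maximum Z reaches the observed
Z there. Ties count against the observed value (conservative). Replicates
are standardised with pooled moments (all replicates) rather than
leave-one-out: with pooled moments the standardisation is the same affine
map applied to observed and null scores at each locus, so score ranks and
Z ranks coincide and a single-locus genome collapses exactly to the
empirical p; leave-one-out (available as an option) breaks that identity
for a negligible reduction in self-contamination at n ≥ 100 replicates.
Fewer than 20 replicates triggers an instability warning.

## Meta-analysis

Z curves from independent studies are combined by the weighted mean
Z-score rule, Z_meta = Σ w_k Z_k / √(Σ w_k²) (unweighted default:
(Z₁+Z₂)/√2 for two studies), after linear interpolation onto a shared cM
grid restricted to the overlap of the studies' maps.

## Marker QC and allele frequencies

Markers typed in at least 50% of subjects are analysed (closed threshold,
configurable). Allele frequencies are estimated by simple counting over
control subjects; a marker with no typed control falls back to all-subject
counting with a warning. Alleles observed in the panel but absent among
controls receive a pseudocount of one before renormalising — without this,
a single rare allele in a case genotype makes the sharing statistic
undefined.

## The synthetic-study generator

The generator emulates the statistical structure the analysis assumes,
not any particular population's demography:

* **Pedigrees**: `n_founder_couples` kindreds, each a founder couple whose
  lineage members marry new married-in founders each generation (kindreds
  stay connected and non-inbred); offspring counts are Poisson
  (negative-binomial or deterministic selectable). Birth years advance
  ~28 years per generation from 1850.
* **Markers**: per-chromosome grids targeting 3.4 cM mean spacing; allele
  counts uniform in a configurable range (default 2–38); frequencies
  Dirichlet-distributed, floored at 0.005 — alleles rarer than about one
  copy in a control sample's chromosomes would never be estimable by
  counting, and 1/√q weights on phantom-rare alleles make null scores
  wildly heavy-tailed.
* **Causal locus**: biallelic, default frequency 0.01, dominant, inserted
  at its map position and transmitted linked with the panel, then removed
  from the panel; truth labels (copy numbers, carrier status) are kept
  separately and are never masked by genotyping missingness (default 5%
  per call).
* **Lifespans**: Gompertz proportional hazards by inverse-transform
  sampling. Defaults a = 1e-4/yr, b = 0.085/yr for females, male hazard
  ×1.35 — this puts non-carrier modal ages in the mid-80s, so selected
  "affected" individuals attain ages from the high 80s into the 100s, the
  regime longevity studies sample. Carriers' hazards are multiplied by
  the hazard ratio
  (default 0.5) — under dominance for ≥1 copy; additive applies HR per
  copy; recessive requires 2 copies. A useful identity: a Gompertz
  proportional-hazard factor HR shifts the lifespan distribution by
  ln(1/HR)/b years (≈8.2 yr at HR 0.5), while the lifespan SD is ≈1.28/b,
  so the effect size in SD units (≈0.54) is independent of b.
* **Expected-lifespan table**: the non-carrier Gompertz mean per sex, one
  all-cohort band (the simulation has no secular mortality trend).

`evaluate_selection_design` scores an ascertainment rule by simulation:
PPV = P(carrier | selected) and sensitivity = P(selected | carrier), with
binomial SEs, optionally re-deriving quartile thresholds per study.

What the generator does **not** model: founder linkage disequilibrium,
assortative mating, secular mortality trends, genotyping error (as opposed
to missingness), sex-specific maps, and interference (Kosambi). Passing
tests on this data therefore validate the statistical machinery — null
calibration, IBD bookkeeping, recombination modelling, determinism — not
robustness to those real-data features.

## Standard evaluation conditions

`apmscan.evaluation` fixes the problem sizes used by the test suite and
the reproduction script (all chosen to run in minutes on one CPU):

* **Null calibration**: 20 kindreds (4 generations, mean sibship 2.8;
  ~600–950 individuals seed-depending), HR = 1, 100 unlinked markers with
  4–14 alleles, 500 drops per marker, top-quartile EL∧FEL selection. The
  observed genotypes are themselves one drop replicate, so empirical
  p-values must be uniform up to Monte Carlo granularity.
* **Power/localization**: 30 kindreds of 3 generations with mean sibship 6
  (~1,300 individuals, several hundred affected pairs), one 150 cM
  chromosome, dominant causal allele at 50 cM with frequency 0.05 and
  HR 0.5, 250 drops, 20 signal replicates and 20 matched HR = 1 replicates.
* **Oracle equivalence**: 10,000 gene-drop replicates per pair class in
  the fixture pedigree, with the MC SE taken from the per-replicate
  variance of the shared proportion.
* **Monotonicity**: one fixed 40-kindred study, attained-age thresholds
  95/98/100.
* **Determinism**: a 12-kindred study written to disk, scanned twice with
  identical seeds, outputs compared byte-for-byte.

## Power of the scaled-down design (a candid account)

The power run recovers the causal location only in a minority of
replicates (≈40% within 20 cM in our runs, with median genome-peak Z ≈ 2.9
against an HR = 1 genome-peak 95th percentile ≈ 4.2). This is a property
of the design, not a defect of the machinery, and the test suite reports
it honestly rather than relaxing the check. The accounting:

* Top-quartile EL∧FEL selection against a 0.54 SD lifespan shift caps the
  carrier fraction among affecteds near 0.30 (measured 0.24–0.37 versus
  ~0.10 prevalence; the enrichment bound is ≈2.9×, and the shift/SD ratio
  cannot be improved by rescaling the Gompertz slope).
* Only both-carrier pairs whose alleles descend from a single founder
  origin contribute linked sharing; at frequency 0.05 multiple founder
  origins within a kindred are common, diluting per-pair information.
* Replacing quartile selection with oracle selection (true carriers)
  raises the median causal-flank Z only to ≈3 at this scale; reaching a
  median Z ≈ 4 under quartile selection would need on the order of 300
  kindreds (~15,000 individuals), an order of magnitude beyond a
  minutes-scale run.
* The APM score is right-skewed (pairs cluster within sibships, and rare
  shared alleles carry large 1/√q weights), so the genome-wide maximum
  null Z has a heavy right tail; empirical and experiment-wise p-values —
  which the pipeline uses for inference — are calibrated against this
  skew, but raw Z comparisons are not.

This is consistent with the method's standing in the field: APM-style
scans on a few hundred affected pairs typically yield suggestive rather
than genome-wide-significant peaks, and corroboration is sought through
cross-study meta-analysis rather than single-study significance — which
is exactly the workflow this package's meta-analysis stage supports.

## Numerical conventions

* Quantiles: linear interpolation (so threshold tests are exact).
* Empirical p: plug-in k/n; ties count as exceedances.
* Degenerate nulls: errors at the statistic level, dropped-and-reported at
  the pipeline level.
* Grid weights at a marker: exactly (1, 0); two coincident markers: (½, ½).
* Coordinates are sex-averaged cM, reported at 2-decimal precision;
  physical positions in `.map` column 4 are accepted and ignored.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence`; reruns are byte-identical.
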