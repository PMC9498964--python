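# Methods

This note records the models behind each analysis module, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that matter for reproducibility.

## Screen representation

### Model

A pooled CRISPRi library (~400 sgRNAs, one fifth nontargeting controls,
typically 2–4 guides per target gene) is sequenced in the pre-injection
culture and in tumors. Each guide's count is normalized to the summed
nontargeting counts within its sample — this anchors every sample to a
set of guides assumed fitness-neutral, removing depth and global-growth
differences — and representation is the percentage ratio of this
frequency in a tumor to its mean in the reference pool. The reference is
the mean over all pre-injection replicates, not per-replicate pairing,
because the culture is a single common pool.

Aggregation defaults to experiment-then-guide (mean of per-experiment
means), matching a design of independent replicate experiments; pooled
averaging is available. Classes are compared on per-guide means by
one-way ANOVA with Tukey HSD. Metastases are normalized to the matched
primary from the same animal; cross-metastasis agreement within a
functional class is summarized by a two-sided Pearson correlation of the
normalized representations (the correlation statistic is a package
choice; a rank correlation would be a reasonable alternative and can be
obtained by transforming the inputs).

### Parameters

- `pseudocount` — default policy adds 1 to all counts only when any
  sample contains a zero-count guide; dense data are untouched and ratios
  remain defined for dropout guides.
- Tie-breaks in depletion ranking are lexicographic on guide id, making
  output ordering platform-independent.

### Estimator properties worth knowing

Representation is a ratio estimator. Its expectation is
100·(1 + CV²(reference) + …): with overdispersed counts (negative-binomial
dispersion α and few reference replicates) every class inflates by a few
percent, *identically across classes*, so between-class comparisons are
unaffected but absolute calibration to 100 % is only asymptotic in read
depth and reference replication. All guides also share the
nontargeting-sum normalization noise, so per-guide standard errors
understate the uncertainty of a class mean; calibration checks in the test
suite therefore estimate class-mean uncertainty empirically across
independent simulation replicates, at high depth (1e7) where the
O(1/depth) ratio bias is negligible.

## Isotope tracing

Natural ¹³C (p¹³ = 0.0107 per carbon, configurable) contaminates observed
isotopologue distributions. The forward model is the binomial convolution
matrix C (columns sum to 1; upper triangle zero because natural abundance
can only add label). Correction solves observed = C·true by nonnegative
least squares rather than unconstrained inversion: with noise, plain
inversion routinely produces negative isotopologues, while NNLS is exact
whenever the observation lies in the image of C and otherwise returns the
closest physical solution. Only carbon is corrected (no ²H/¹⁵N or tracer
purity terms). Correction is applied before all summaries and before PCA
inputs.

Summaries: relative pool size = isotopologue sum divided by the
normalizer (cell count in vitro, µg protein in vivo); percent labeled =
1 − M₀ fraction. The flux-ratio statistic ρ = (M₆/M₀ of F16BP under
glucose tracer) / (M₅/M₀ of glutamate under glutamine tracer) is a
label-incorporation ratio, not a fitted flux: it is computed per matched
replicate and averaged, is invariant to rescaling either vector, and is
undefined when an M₀ is zero (the code directs the user to a
pseudo-intensity or replicate exclusion rather than guessing). Metabolite
carbon counts ship as a versioned in-package table; unknown metabolites
are a hard error rather than a silent guess.

## Metabolic PCA

Inputs are samples × metabolites matrices of fractional labeling (in
[0, 1]) or relative amounts. Missing-value policy (the upstream data
carry no stated policy): a feature missing in more than 20 % of samples
is dropped, the rest are mean-imputed; published variance fractions are
sensitive to this choice, which is why it is explicit and logged.
Unit scaling divides each centered feature by its ddof = 1 standard
deviation, i.e. correlation-matrix PCA, making scores invariant to
positive rescaling of any feature. Zero-variance features are dropped
with a warning. Determinism: full-SVD solver plus a sign convention that
makes the largest-magnitude loading of each component positive. ΔPC
vectors are differences of condition score means per genotype within one
fitted space; genotypes missing a condition are skipped with a warning
rather than silently imputed.

## Preranked enrichment

The ranked list is collapsed to unique genes keeping the entry with the
largest |metric| (the collapse rule is otherwise unspecified upstream),
sorted descending with a lexicographic tie-break. ES is the signed
maximum deviation of the weighted running sum (hit weights
|metric|^w / Σ, miss penalty 1/(N − N_h)); weight defaults to 1, the
cited method's convention. The null permutes gene labels: random
same-size sets, or exhaustive enumeration of all C(N, k) subsets whenever
there are no more of them than `n_perm` — on small universes the nominal
p-value is therefore exact. p uses the same-sign tail of the null;
NES divides ES by the mean |null ES| of that sign. A simple permutation p
is reported (no adaptive multilevel refinement), and is floored at
1/(n_perm + 1) so it is never zero. Defaults: 1000 permutations, set
sizes 10–500.

The pathway overlay assigns each node of a shipped minimal
glycolysis/TCA map (KEGG-style gene and compound ids) the mean
replicate-averaged log₂ fold change of its mapped genes or metabolites;
unmapped nodes are listed, never dropped silently.

## Assay readouts

OCR runs measure baseline, FCCP-uncoupled and rotenone-inhibited phases;
ECAR runs baseline, oligomycin and rotenone. The post-rotenone
(non-mitochondrial) floor is subtracted from basal and maximal
respiration by default — the field convention — with a flag to report raw
phase values, since published basal/maximal numbers do not state the
subtraction; both modes are computed in the analysis driver. ATP-linked
respiration requires an oligomycin phase in the OCR run and is NaN
otherwise. All values are per cell. NAD⁺ is read from the acid-treated
fraction, NADH from the untreated one; replicates with NADH ≤ 0 are
excluded with a warning. 2^−ΔΔCT averages replicate CTs before
differencing. Chest-thirds radiance splits a rectangular grid into three
equal-area column strips; widths not divisible by 3 give the remainder
columns left-to-right, so the partition is deterministic and conserves
the total exactly on integer grids.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (config, seed) and return their
ground truth. Study-condition defaults: 400 guides, 20 % nontargeting,
2–4 guides/gene cycling, class proportions 0.30/0.25/0.25/0.20
(glycolytic / mito protein synthesis / respiratory chain / other mito)
among targeting guides, day-0 pool ~ Dirichlet(5) (library skew), read
depth 1e6, negative-binomial dispersion 0.1 (realistic screen
overdispersion), 2 experiments × 6 tumors with 2 pre-injection
replicates. In vivo fitness effects per macro class: flank
1.0/0.63/0.42/0.85, orthotopic 1.0/0.72/0.48/0.85, metastasis all 1.0
(seeded from the primary through a chained multinomial bottleneck of 200
founders, which by itself inflates met/primary ratios); early timepoints
use day-4 effects 1.0/0.95/1.25/1.0 and day-7 1.0/0.90/0.70/0.95
(transient mito-respiratory enrichment before depletion). The engraftment
bottleneck is a single multinomial draw of N_b founders (default none).

Tracing truths place ~87 % glutamine-derived labeling on TCA metabolites
at baseline and give the knockdown lines a flux ratio several-fold above
control under 2DG; observation = convolution with natural abundance ×
lognormal noise (CV 0.05, 4 replicates). Expression tables draw null
log₂FC ~ Normal(0, 0.5) with z-derived two-sided p-values and plant a
+2σ shift on the canonical glycolysis genes. Assay traces scale a
genotype's mitochondrial OCR and ECAR multiplicatively over a fixed
non-mitochondrial floor; radiance triplets use configurable
central/left = 0.2 and right/left = 0.1 ratios.

Not emulated: PCR jackpotting and guide-specific amplification bias,
guide-level (as opposed to class-level) effect heterogeneity, metabolite
detection limits and retention-time artifacts, batch effects, and any
mechanistic tumor growth or pharmacokinetics. Passing recovery tests
therefore demonstrates estimator correctness under the assumed noise
model, not robustness to every artifact of real sequencing or mass
spectrometry.

## Numerical notes and limitations

- Dunnett-adjusted p-values require a multivariate-t integral that scipy
  (and R's mvtnorm) evaluate by quasi-Monte-Carlo; the implementation
  pins the integrator's rng so results are reproducible, and
  cross-implementation agreement is limited to ~1e-4 regardless of
  library. F statistics, ANOVA p, Tukey p and Dunnett t statistics are
  deterministic and agree with an independent implementation to < 1e-8.
- The permutation null and all simulators are bit-reproducible under a
  fixed seed (numpy Generator; no global state).
- Class-level omnibus tests require at least two classes with at least
  two guides each; smaller designs return the per-guide results with no
  omnibus test rather than an unstable one.
- The published-data loaders take explicit column roles because
  supplementary workbook layouts vary; they hard-fail when the workbook
  is absent instead of fabricating a stand-in.
- Problem sizes in the test suite and acceptance script (depth 1e6–1e7,
  8 calibration replicates, 1000 permutations, 200 round-trip cases) were
  chosen as the smallest sizes at which the statistical guarantees are
  cleanly separated from their tolerances.
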