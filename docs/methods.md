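# Methods

## Study model

The pipeline models a cross-sectional four-phenotype transcriptomics
design: healthy controls (HC) and three patient states along a treatment
arc — active disease untreated (ADU), active disease on therapy (ADT), and
inactive disease on therapy (ID). Input expression is assumed to be
RMA-style log2 summaries (features × samples); a `linear_input` flag
applies log2 for linear-scale matrices. Genes measured by several probe
sets or isoforms are collapsed by the arithmetic mean of their log2
summaries within each sample, which is the natural reading of "average
expression" on summary values; note this is the mean of logs, not the log
of mean intensities.

## Differential expression and the rank-based q-value

Each patient phenotype is contrasted against HC feature-by-feature with a
two-sample t-test. Welch's unequal-variance form is the default because
group variances cannot be assumed equal across disease states; a pooled
Student's t is available (`equal_var`). Features with zero variance in
both groups carry no evidence either way in a t framework; they are
assigned t = 0, p = 1 with a logged warning rather than propagating NaNs.

Multiple testing uses the rank-based quotient q_i = N·p_i/R_i with N the
number of features in the contrast and R_i the ascending rank of p_i.
Ties take the maximum rank of their tie group so that tied p-values share
one q. The raw quotient is not monotone in p; by default each value is
replaced by the minimum quotient at its rank or any larger rank (step-up
monotonization), after which the statistic is exactly the
Benjamini–Hochberg adjusted p-value — the test suite verifies agreement
with an independent implementation to 1e-12. A `monotonize=False` mode
retains the literal quotient for fidelity experiments. Each contrast is
corrected independently with its own N. DEGs are features with q ≤ 0.05
(inclusive); direction is the fold-change sign, with an exactly-zero
log2FC mapped to "up" by convention and logged (a measure-zero event on
real data).

## Overlap statistics

Overlap significance between two DEG sets is the exact upper
hypergeometric tail P(X ≥ k) for the observed intersection k given the
set sizes and a universe of N tested features. The universe defaults to
the number of features tested in DE and is overridable — published overlap
p-values from comparable studies are not reproducible without knowing the
universe their authors used, which is why this package always reports it.
Percentages are reported against the smaller set and, in unique-fraction
summaries, against the first set's size, matching the way such results are
conventionally phrased; reports carry both counts so neither convention is
ambiguous.

## Direction-pattern clustering

Every gene differential in at least one phenotype receives a three-letter
pattern over (ADU, ADT, ID): U if its log2FC vs HC is positive, else D.
Significance in a particular phenotype is deliberately not required for
its letter — the union gene must carry a complete dynamic profile, and
fold-change signs are defined for all contrasts. The 8 patterns form three
dynamic groups: persistent (UUU/DDD), late response (UUD/DDU — flipped
only in inactive disease), early response (UDD/DUU/UDU/DUD — flipped
already in treated-active disease). UUU/DDD genes with |log2FC_ID| <
|log2FC_ADU| (strict, on absolute log2 fold changes) attenuate toward the
healthy level and are written UUu/DDd; these sub-clusters are the natural
candidates for therapy-tracking genes. Whether attenuation should be
judged on linear or log fold change is not settled by convention; log2
absolute values are used because the whole pipeline operates on the log2
scale, and the comparison is monotone-invariant either way.

## Regulator enrichment

For each cluster and each miRNA/TF target set (GMT input; set members
outside the tested-gene universe are dropped and logged), the one-sided
"greater" Fisher exact p-value is computed on the 2×2 table of cluster
membership × target membership — equivalently the upper hypergeometric
tail, which the tests verify against exhaustive enumeration. The screen is
deliberately low-stringency: uncorrected p < 0.01, because the output
feeds network construction rather than standing as inference. The
background universe is all genes tested after collapsing (overridable).
All tests are reported with a significance flag, not only the hits.

## miRNA consistency and qPCR validation

A miRNA credibly regulating a cluster should move opposite to it: for each
enriched miRNA with an expression profile, per-phenotype "opposite" flags
compare the miRNA's fold-change sign to the cluster letter. All three
flags → `all_opposite` (regulation throughout the arc); flags in ADT and
ID only → `treated_opposite` (therapy-induced regulation); anything else →
`inconsistent`. A zero miRNA fold change is never counted as opposite.

qPCR Ct tables are reduced with the comparative-Ct model: per-row
ΔCt = Ct_target − Ct_reference, group means of ΔCt per phenotype,
ΔΔCt = ΔCt_case − ΔCt_control, fold change = 2^−ΔΔCt. Group-mean ordering
(average the per-sample ΔCt, then difference) is used; for balanced
designs it is identical to differencing averaged Cts and it is more robust
to unbalanced replication. Amplification efficiency is fixed at 2 per
cycle — no efficiency correction, consistent with assays validated near
100% efficiency. Cross-platform "similar change" is operationalized as
sign agreement between the array log2FC and log2 of the qPCR fold change;
no magnitude criterion is imposed because none is standard.

## Co-regulatory networks

Per cluster, the significant regulators (after collapsing miRNA families
to their best-p member, ties broken lexicographically) are joined to their
targets inside the cluster; regulators left without in-cluster targets are
dropped with a warning rather than appearing as orphans. PPI edges are
restricted to pairs of cluster genes so networks stay cluster-scoped; a
flag re-admits first-neighbor interactors of included genes. Gene nodes
unreachable by any regulator or PPI edge are omitted. Node types (gene,
miRNA, TF), edge types (mirna_target, tf_target, ppi), no self-loops, and
one-miRNA-per-family are enforced by a validator at build time. Networks
export to SIF and GraphML (Cytoscape-loadable); connected-component counts
are reported but single-connectedness is an observation, not a constraint.

## Synthetic data generator

The generator emulates a four-phenotype log-normal-noise array study:
value = baseline + phenotype effect + N(0, noise_sd) on the log2 scale,
with HC and null genes at zero effect. Defaults are chosen as study
conditions, not tuning knobs:

- group sizes 35/35/26/14 (HC/ADU/ADT/ID) — a realistic mRNA-profiling
  cohort for this design;
- baseline 8.0 log2 units (typical RMA intensity), additive Gaussian noise
  with SD 0.5 log2 units — a standard magnitude for residual variation in
  RMA summaries;
- planted |log2FC| 1.5 with signs following the pattern letters; UUU/DDD
  halve their ID effect so the planted truth contains the UUu/DDd
  attenuation sub-clusters;
- 20% of genes differentially expressed, split across the 8 patterns in
  the proportions observed for a treated-arthritis DEG union (~45% each
  same-direction cluster, a few percent late response, <1% each early
  response), 80% exact nulls. Nulls are exactly zero-effect — no
  small-effect contamination — so that realized-FDR calibration against
  the planted truth is interpretable.

Anti-correlated miRNA regulators are planted at the phenotype-mean level:
each gets the letter-wise opposite direction triple of its target cluster,
with the same effect magnitudes. This encodes the direction-opposition
assumption directly rather than a mechanistic titration model, which is
all the consistency classifier consumes. Target sets draw a configurable
fraction (default 0.8) of their members from the regulator's planted
cluster and the rest uniformly elsewhere; uniform decoy sets calibrate the
false-enrichment rate. qPCR tables are generated with per-sample Ct
offsets on both target and reference assays (cancelled exactly by
normalization) and a zero-effect reference; naming a planted gene as the
reference is rejected.

All randomness flows from the explicit config seed (child streams are
spawned with fixed offsets per artifact), so identical configs are
byte-identical after serialization. The generator does not model probe
effects, batch structure, correlated genes, dropout, or heavy-tailed
noise; passing tests demonstrate correctness of the analysis logic under
an idealized independent-Gaussian regime, not robustness to real-array
artifacts.

## Numerical and design notes

- Config invariants require noise_sd > 0; "zero-noise" contract checks run
  at noise_sd = 1e-12, which is exact for sign and pattern recovery.
- Gene-to-pattern allocation uses largest-remainder rounding, so planted
  compositions are exact rather than multinomially noisy.
- Fisher/hypergeometric p-values come from exact tail summation
  (scipy's hypergeometric survival function), cross-checked in the tests
  by brute-force enumeration on small universes.
- The pipeline's per-run manifest hashes the scientific config (output
  directory excluded) so reruns can be verified byte-identical.
- Test/acceptance problem sizes (hundreds to a couple thousand features,
  10–20 samples per group, tens to hundreds of replicate simulations) are
  chosen so the full suite completes in well under a minute of compute per
  property while keeping Monte-Carlo standard errors small relative to the
  asserted bounds.

## Known limitations

- The q-value's literal (un-monotonized) mode can rank-invert; it exists
  for fidelity comparisons only.
- Enrichment results depend strongly on the target-set database and its
  version; counts of enriched regulators are not comparable across
  databases.
- The consistency classifier uses direction only; it cannot distinguish
  direct repression from shared upstream drivers.
- No covariate adjustment, paired designs, or moderated-variance tests;
  contrasts are strictly two-group.
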