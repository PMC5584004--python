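# Methods

This note records the models, numerical choices and design decisions
behind `chicogs`, and what the synthetic-data tests do and do not show
about behaviour on real data.

## Coordinates and data model

Internally everything is 0-based half-open (BED convention).  GWAS
positions are read as 1-based and converted on ingest: a variant at
1-based position `p` belongs to fragment `[start, end)` iff
`p − 1 ∈ [start, end)`, so a variant exactly on a restriction cut site
belongs to the downstream fragment.  Chromosome names are normalised to
the `chr`-prefixed form.  Strand is ignored throughout; interactions and
variants are unstranded.  Interaction tables use the wide CHiCAGO "peak
matrix" layout (bait id, other-end id, one score column per cell state);
a long 4-column dialect is accepted on read.  A fragment is a called PIR
in a state when any interaction reaching it scores strictly above 5.

LD blocks partition each chromosome at multiples of the block width in
cumulative genetic distance (linear inverse interpolation of the map,
flat extrapolation outside it): 1 cM blocks for enrichment-oriented
posteriors, 0.1 cM for gene-score-oriented posteriors, both exposed in
`FineMapConfig`.

## Fine-mapping

Per block, the log approximate Bayes factor for a variant is
`½ ln(V/(V+W)) + (z²/2)·W/(V+W)`; it depends on z² only, so unsigned
p-value input is sufficient.  `|z|` is recovered from two-sided p-values
through the inverse of the *log* normal CDF (`ndtri_exp`), which is exact
down to log-underflow scale; p-values are required to be strictly
positive.  `V` is approximated from study design when no standard error
is given — case-control `V = 1/(2N f(1−f) s(1−s))` with case fraction
`s`, quantitative `V = 1/(2N f(1−f))`; a supplied `se` takes precedence
(`V = se²`).  The exact approximation used by the original analysis code
is not published; this is the standard summary-statistic approximation
and is flagged as an assumption.

Posteriors over {no causal} ∪ {variant *i* causal} use exact binomial
prior weights — `w₀ = (1−π)ⁿ`, `wᵢ = π(1−π)ⁿ⁻¹` — rather than the ≈1
approximation, so `pp_null + Σ ppi = 1` to 1e-12 by construction; the
normalisation runs in log space (log-sum-exp).  Defaults `W = 0.04`
(95% prior RR interval ≈ 0.68–1.48) and `π = 10⁻⁴`.

Input filters: genome-wide significant variants (`p < 5×10⁻⁸`) are
dropped unless supported by another variant with `p < 10⁻⁵` within 50 kb
or in LD at `r² > 0.6`; the extended MHC (GRCh37 chr6:25–35 Mb) is
masked.  Multi-causal model-posterior tables from an external
fine-mapper are consumed, not produced: the aggregation over models
containing a variant in a target set, and the binomial model prior
`π^k(1−π)^(n−k)`, are provided.

PMI ("poor man's imputation") gives each unobserved panel variant the
p-value of its nearest observed proxy with `r² > 0.6`; "nearest" means
smallest base-pair distance by default (ties: higher r², then
lexicographic id), with highest-r² available as an alternative since the
original tie-break is not documented.  Observed records are never
overwritten, and observed variants absent from the panel are discarded.

## Blockshifter

The statistic is the difference in mean ppi between variants in test-
and control-labelled PIR fragments; fragments in both sets carry the
"both" label and contribute to both means; variants outside labelled
fragments are excluded (the test contrasts PIR sets, not PIR versus
genome).  The null moves labels, not signal: PIR fragments are grouped
left-to-right into superblocks, breaking whenever more than `gap`
consecutive non-PIR fragments intervene; mixed superblocks are
circularised and their per-fragment label sequence rotated by a uniform
offset; unmixed superblocks have the multiset of block-level labels
randomly reassigned, preserving the observed counts.  The one-sided
empirical p uses the +1 correction, `p = (1 + #{null ≥ obs})/(1 + n)`;
a two-sided variant doubles the smaller tail.  Permutations that empty
one side's variant set count toward the upper tail (conservative) and
are excluded from the null moments.

Two membership decisions matter and were settled by simulation against
the label-blind placement measure the null must match:

* **Non-PIR (gap) fragments are not rotation positions.**  The
  alternative — rotating labels across interior gap fragments — lets the
  null park labels on positions the alternative hypothesis can never
  occupy, and measurably inflates the test as `gap` grows.
* **PIR fragments containing no panel variants are likewise excluded.**
  They carry no information about the ppi distribution; keeping them as
  rotation positions distorts the permutation measure whenever variant
  coverage is sparse relative to the fragment map.

The permutation engine precomputes, per mixed block, the contribution of
all L distinct rotations (an L×L boolean matrix product), making each
permutation a table lookup; unmixed reassignment is vectorised by
ranking uniforms.  The engine path is verified against the direct
`permute_labels` + `enrichment_statistic` path in the tests.

The naive comparator (2×2 Fisher's exact on PIR overlap × ppi > 0.01)
is included to demonstrate what ignoring correlation does.  At the
desk-scale simulation conditions used here its pathology mostly shows as
mis-calibration rather than the dramatic inflation seen at full scale,
because single-causal posteriors concentrate mass on few variants.

## Simulation and calibration study

GWAS Z scores over a block with LD correlation Σ are multivariate normal
with covariance Σ; an alt block with causal variant *i* and
non-centrality `ncp = 80` has mean `μ_j = √(ncp·r²_ij)` (the
construction squares r, discarding its sign; the signed alternative
`μ_j = √ncp·r_ij` is available behind a flag).  Sampling uses a
symmetric eigendecomposition with eigenvalues below −1e-8 rejected and
tiny negative ones clipped.  Fine-mapping inside the simulation loop
uses a vectorised implementation verified against the reference one.

Scenario design mirrors the published simulation study: 20% of blocks
carry one causal each (6 of 30 at desk scale, as 50 of 269 at full
scale); each causal lies in a PIR with probability 0.5; PIR-localised
causals are drawn from any PIR regardless of set (*null*), from the test
set with probability 0.5 (*power1*) or always (*power2*).  "Test set"
includes fragments shared with the control set — such causals are
uninformative for the contrast, as in real data.  Case-control sizes
5,539/20,169 (a large rheumatoid-arthritis meta-analysis) feed the
variance approximation.  Genotyping-density conditions thin the panel to
synthetic stand-in retention fractions (hapmap-like 0.3, array-like
0.15) and refill it with PMI.  Within a simulated GWAS the
standard-normal noise is shared across scenarios (common random
numbers), so power comparisons are paired.  Alt-block eligibility is
scenario-specific: requiring test-PIR variants under the null would skew
placement toward test-rich blocks and corrupt the type-1-error study.

**Why the calibration study pools genome replicates.**  The rotation
test is exact marginally over genome draws, but its genome-conditional
size at desk scale varies (we measured roughly 0.01–0.19 across
realizations at nominal 0.05): with ~100 variants per Mb, whether the
observed label configuration is an orbit-typical element with respect to
per-fragment variant counts is frozen into each genome, and six causal
variants are too few to average it out.  `calibration_study` therefore
pools 25 independent genome replicates × 40 simulated GWAS (1000
simulations, 200 permutations each); pooled null rejection sits at
0.04–0.06 across master seeds with the expected power ordering
(power2 > power1 > null) at every gap in {1, 5, 10}, and power is
maximal near gap 5, the operating default.

## Synthetic genomes

One chromosome at 1 cM/Mb, 30 Mb by default; lognormal fragment lengths
(median 4 kb); ~3% of fragments baited (200 genes), matching the scale
of a promoter-capture design; ~8 PIRs per gene; 55% of CD4 interactions
shared between activation states, the rest split between
activated-only and non-activated-only; control-cell interactions
comprise a shared fraction plus control-only contact regions, so neither
PIR set contains the other.  Panel variants are uniform within blocks
with MAF ~ U(0.05, 0.5); LD is AR(1) (ρ = 0.9) by default, with a
coalescent haplotype model (msprime, MAF ≥ 0.01) as an alternative.
These realism targets are generator defaults, not assertions.

PIR spatial clustering (`mean_pir_clump_len`) defaults to 1: label
clusters comparable in length to desk-scale superblocks break the
rotation null's exchangeability (measured inflation up to ~0.16),
whereas real-scale superblocks are long enough to absorb clustering.
The clustered mode remains available for sensitivity analysis.

What passing tests show — and don't.  The synthetic genome has the
methods' assumed structure: block-diagonal LD, label-blind signal
placement, independent interaction calls.  It does not emulate real
human LD maps, capture-design bias, score correlation between cell
types, or assortative PIR topology; calibration on it demonstrates
internal consistency of the permutation scheme, not robustness to every
failure mode of real data (the clustering sensitivity above being the
documented example).

## COGS

Variants are assigned per gene to the first matching category —
coding > promoter (bait fragment ± one flanking fragment, truncated at
chromosome ends) > PIR — with PIR assignments recording the supporting
states.  Block scores aggregate single-causal ppi (a sum over the
category's variants) or multi-causal model posteriors (total mass of
models intersecting the set); blocks combine as `1 − Π(1 − s)` under
cross-block independence.  A shared PIR credits every interacting gene,
so prioritisation can be one-variant-to-many-genes.

The decision tree compares genic (coding + promoter, combined by the
same rule) against all-state PIR scores at the root, then coding vs
promoter or activated vs non-activated per-state PIR scores, descending
only when the winner exceeds threefold the competitor (ratio on the raw
scores by default; a log10-ratio reading of the threshold is exposed as
a flag since the published description is ambiguous between the two).
A zero competitor with a positive score counts as an infinite ratio;
both zero at the root yields "unresolved".  Reporting uses score > 0.01,
prioritisation score > 0.5; genes prioritised for several traits
contribute fractional counts per node in the reporting layer.

## Known limitations

* Single-causal posteriors are biased in blocks genuinely harbouring
  multiple causal variants; multi-causal input is supported only via
  external model-posterior tables.
* PMI transfers p-values, not effect sizes or standard errors.
* Genome-conditional blockshifter size at sparse variant coverage varies
  around the nominal level (see the calibration discussion); inference on
  a single dataset is approximate to that extent.
* The V approximation assumes the standard summary-statistic form; if
  the original analysis used a different variance, lABFs shift by a
  smooth monotone factor but posteriors change little at these scales.
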