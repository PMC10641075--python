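# Methods

## Scope and data model

The package covers the computational side of a barcoded 3′UTR reporter
assay: library design, count simulation, activity quantification,
differential testing, barcode-effect power analysis, sequence
classification and QC. The central objects are a `DesignManifest`
(variants, elements, barcodes, assembled oligos), a `CountTable`
(barcode × sample non-negative integers with DNA/Input/TRAP sample
metadata), long-form per-barcode activity tables, and per-element /
per-comparison result frames.

## Library design

Elements are 120-nt windows centered on a variant. For substitutions the
variant base sits at 0-based offset 60 (60-nt left flank, 59-nt right
flank for a 1-nt allele) — an even window forces an asymmetric convention
and this one fixes it. For indels the flanks are capped so the longer
allele still fits in 120 nt; both allele contexts then share identical
flanks and may be shorter than 120 nt. Windows are clipped at chromosome
ends without error, keeping the variant at its computed offset.

Shuffled controls are uniform random permutations of a reference element's
letters, so length, nucleotide composition and GC content are conserved
exactly. Barcodes (9 nt) are drawn by seeded rejection sampling with greedy
screening: candidates are rejected for homopolymer runs > 3, for
containing a cloning site (NheI `GCTAGC`, KpnI `GGTACC`), or for lying at
Hamming distance < 2 from any accepted barcode (tested via membership of
the candidate's Hamming-1 ball in the accepted set, O(27) hash lookups per
candidate). An attempt budget turns infeasible requests into a capacity
error that reports the barcodes found.

Oligos concatenate `primer5 (24) | NheI (6) | element (≤120) | linker (20)
| barcode (9) | KpnI (6) | primer3 (25)` to a fixed 210 nt. Elements
shorter than the slot are padded with an `AT` repeat placed between the 5′
primer and the 5′ cut site — outside the cloned insert, so the reporter
transcript is unaffected; the spacer sequence itself is a package choice
(any low-complexity, site-free sequence would do). Primer sequences and
lengths are configurable; only the slot widths are structural.

Expected cloning coverage uses the Poisson approximation
`1 − (1 − 1/N)^(colonies × (1 − error_rate))`. At N = 9744, 71,000
colonies and a 50% synthesis error rate this is ≈ 0.974 — an expected
*fraction* of the design captured. We note that no all-members-captured
probability reproduces a "95% confidence" statement at these numbers, so
the expected-fraction reading is the one implemented.

## Generative count model

Per barcode *i* of element *e* (allele *a*), replicate *r*:

* plasmid copies `p_i ~ LogNormal(0, plasmid_abundance_sd)`;
* DNA counts per DNA replicate `~ Multinomial(depth_dna, p/Σp)` — DNA is
  pure copy-number sampling, matching the observation that reporter
  abundance is dominated by DNA copy number;
* expression `x_i = p_i · 2^(μ_e + β_v·[a=alt] + b_i)` with element mean
  `μ_e ~ N(0, element_effect_sd²)` shared between a ref element and its
  alt partner, allelic shift β per variant, and barcode effect
  `b_i ~ N(0, barcode_effect_sd²)` fixed across replicates;
* transduction bottleneck `m_ir ~ Poisson(bottleneck_lambda)`; the RNA
  rate is `x_i · m_ir/λ` (zero when no copy is transduced). λ = ∞ disables
  it. This is the minimal mechanism for jackpotting: when few template
  molecules enter a replicate, final counts no longer reflect starting
  abundances and replicate correlations collapse;
* Input counts `~ Multinomial(depth_rna, rates)` after multiplying each
  rate by an i.i.d. Gamma(1/φ, φ) factor (negative-binomial
  over-dispersion, RNA only); TRAP rates additionally carry `2^{te_e}` and
  fresh dispersion noise, sharing the replicate's bottleneck draw.

Defaults are the regime the pipeline targets: 6 RNA replicates, 2 DNA
replicates, depth of 5388 counts per barcode (sample depth scales with
library size), `element_effect_sd = 0.55` log2 units — placing ~99% of
elements within a ~7-fold (≈ 2.9 log2-unit) expression range —
`barcode_effect_sd = 0.2`, `plasmid_abundance_sd = 1.0` (log-normal copy
spread broad enough that DNA dominates expression variance),
`nb_dispersion = 0.05`, and no bottleneck. Severe bottlenecks
(λ ≈ 0.1) drive replicate count correlations from > 0.9 to near 0,
matching the qualitative jackpotting signature; λ is a free knob with no
quantitative anchor, calibrated only by that contrast.

What the generator does **not** emulate: PCR duplicates and UMI
structure, sequence-dependent amplification bias, cloning dropout
correlated with GC (QC functions accept such data but the generator does
not produce it), read-level errors, and cross-contamination. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated stochastic model, not robustness to every artifact of real
libraries.

## Activity quantification

Counts are CPM-normalized per sample. A barcode/replicate cell enters the
activity table only if its raw count reaches `min_count` (default 10) in
the numerator sample and in every denominator sample; failing cells are
dropped, never imputed, so log2(0) cannot arise and no pseudocounts are
used. With multiple DNA replicates the default denominator is the pooled
mean DNA CPM per barcode (`dna_policy="mean"`), because DNA replicates
(e.g. two viral-prep libraries against many RNA replicates) generally do
not pair with RNA replicates; `per_replicate` pairing is available when
they do.

Raw read counting is exact anchored whitelist matching: the constant
linker is located exactly and the following 9 nt must equal a whitelist
barcode. Because barcodes are designed at pairwise Hamming ≥ 2, a
single-error read cannot be mis-assigned to another barcode; it is
discarded and tallied.

Element summaries fit `y = μ + b_BC + ε` by **maximum likelihood** (not
REML), so that likelihood-ratio tests between nested fixed-effect models
are valid. The variance ratio λ = σ_b²/σ_e² is profiled: for fixed λ the
GLS fixed effects and σ_e² are closed-form, and the scalar profile
likelihood is maximized over log λ ∈ [−15, 15] (bounded Brent, tolerance
1e-8) with an explicit λ = 0 boundary check. On balanced designs with
group-constant covariates — the usual barcode layout — the ML solution is
instead computed exactly from within/between sums of squares (the two
likelihood pieces separate), which also makes the 10,000-iteration power
simulations fast. Degenerate inputs fall back gracefully: one barcode or
λ̂ = 0 gives the OLS/sample-mean fit with σ_b = 0; all-identical values
give μ̂ = c and zero variances (log-likelihood computed with a 1e-12
variance floor). The implementation is cross-checked in the test suite
against an independent mixed-model ML fitter to ~1e-5 in log-likelihood.

## Differential testing

`Activity ~ Allele + (1|BC)` vs `Activity ~ (1|BC)`, both ML, p from χ²
with 1 df; no boundary correction is needed because the tested parameter
(the allele effect) is interior. Replicate is deliberately not modelled as
an additional effect, matching the model formulas above. Tests are
two-sided; q-values are Benjamini–Hochberg. Non-converged fits are
reported with p = 1 and a flag rather than dropped.

The Wilcoxon signed-rank comparison drops zero differences, mid-ranks
ties, enumerates the exact null for ≤ 25 tie-free differences and uses the
continuity-corrected normal approximation otherwise. Direction enrichment
builds the 2×2 table rows = (significant, non-significant) × columns =
(down, up) and reports the one-sided Fisher/hypergeometric p with the
sample odds ratio; this table convention is one of several defensible
readings and is documented so either convention can be reproduced.

The inclusion-threshold grid search retains a comparison at a grid point
(min_count, min_barcodes, min_replicates) when both sides have ≥
min_barcodes barcodes passing the count floor in ≥ min_replicates
replicates, tests the retained set, and returns the point maximizing the
number of BH-significant calls. Ties break toward stringency: largest
min_barcodes, then min_replicates, then min_count. Count thresholds below
10 are floored at 10. Typical settings — ≥ 3 barcodes / ≥ 10 counts / ≥ 4
replicates in vitro, ≥ 5 barcodes / ≥ 10 counts / 6 replicates in vivo —
are ordinary grid points.

## Barcode-effect power simulation

From a pool of ~100 barcodes tagging one null element, two disjoint sets
of k barcodes are repeatedly drawn as pseudo-alleles and passed through the
same LRT as the real analysis; the log2FC is the difference of
pseudo-allele barcode-mean activities (the mixed-model fixed effect under
balance). The curve over k ∈ [3, 50] reports |log2FC| quartiles,
P(|log2FC| > 0.25) and the fraction of p < α. With σ_b = 0 the curve is
flat at ≈ α; with σ_b > 0 the small-k rates are inflated and decline as
barcodes dilute the barcode effects — at σ_b = 0.3, σ_e = 0.1 the measured
false-positive rate at k = 6 is ≈ 8%, and `recommend_barcode_count`
returns the smallest k within a tolerated rate (≈ 20 in this regime).

The default pool (`make_null_pool`) draws activities directly as
μ + b_i + ε_ir with explicit σ_b and σ_e: the calibration claims above are
statements about known variance components, which a count-level pool
cannot pin exactly (its residual noise is heteroskedastic count noise).
`pool_from_counts` builds the pool through the full generative chain
instead and shows the same phenomenology; both are exercised in the
tests. Default iteration count is 10,000 per k (overridable), which
bounds the Monte-Carlo standard error of a 5% rate at ~0.2%.

## k-mer classifier

Sequences are encoded as 4^k-dimensional k-mer frequency vectors over
sliding windows (windows touching ambiguous bases are skipped). The
classifier is a soft-margin linear SVM (C = 1.0) on standardized features
under seeded stratified 5-fold cross-validation; with word-length features
the gapped-k-mer kernel reduces to this full-word spectrum kernel, so the
settings `l = k = 4, 5` correspond to plain 4-/5-mer spectra. AUROC/AUPRC
are reported per fold and on pooled held-out scores (both, since either
aggregation is defensible). Label permutation (once per run, before
folding) provides the chance-level control. Individual k-mers are scored
by passing their one-hot frequency vector through the fitted decision
function.

The planted-motif benchmark inserts a tandem 3× copy of an AU-rich
element analog (`TTTATT`) at a random position of otherwise-random
positives — the tandem-array construction used for synthetic
response-element controls. A single embedded copy in a 120-nt sequence is
not separable in 4-mer space (the ideal single-feature score tops out near
AUROC 0.93 at this length), whereas the tandem array is; the benchmark is
meant to verify the learning machinery, not the detection limit.

## QC

Replicate Pearson correlations are computed pairwise-complete (per-pair
overlap, mirroring scatter plots) at three levels — raw/CPM barcode
abundance, per-barcode activity, and barcode-averaged element values —
since different views of reproducibility live at different levels.
Dropout is reported against the design (barcodes with zero DNA, surviving
barcodes per element, fraction of elements with ≥ 3 barcodes). The
jackpot index is the share of counts held by the top decile of barcodes
(scale-invariant; 0.1 under uniformity), with the Gini coefficient as an
alternative; the underlying phenomenon has no canonical statistic, so the
metric is a package choice. GC recovery bins elements by GC content and
reports mean DNA CPM per bin, the diagnostic view for composition-biased
cloning loss.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is deterministic given
it, including across grid values. The reproduction script
(`scripts/acceptance.py`) uses: the full-scale design (649 variants, 1624
elements, 9744 oligos); 1000 null LRT comparisons at 6 barcodes × 6
replicates; planted-effect recovery over 10 variants at depth 10⁶ and
6 × 6; power curves at 10,000 iterations per k on k ∈ {3, 6, 50} from
110-barcode pools; and the 200 + 200 planted-motif set with 5 permuted-label
runs. These sizes keep the Monte-Carlo error of each reported rate well
below the effect sizes being demonstrated while the whole script completes
in well under a minute.

## Known limitations

* The LRT's χ²₁ reference is asymptotic; at 3 barcodes per side it is
  mildly conservative under the null (measured ≈ 0.04 at α = 0.05), and
  genuinely anticonservative once barcode effects exist — which is
  precisely the phenomenon the power module quantifies.
* Activities from counts are treated as homoskedastic within an element;
  depth-dependent precision differences between barcodes are not weighted.
* The simulator's bottleneck acts per barcode × replicate independently;
  real transduction correlates barcodes within a cell.
* Exact barcode matching discards single-error reads rather than
  rescuing them; with Hamming-2 whitelists rescue would be safe for
  isolated errors but is intentionally omitted for simplicity.
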