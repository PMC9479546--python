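# Methods

This note documents the statistical models, the simulator, the numerical
choices and the known limits of the package. Everything stated here is
computed by the test suite or the reproduction script; nothing is an
external empirical claim.

## Study design and data model

The pipeline targets a two-sex staged floral development design: stages
M1..M4 (male) and F1..F4 (female), each with r = 3 replicate RNA-seq
libraries (24 samples), plus a concentration panel of 12 phytohormones and
4 sugar assays on the same samples, and qRT-PCR Ct tables for a validation
panel of genes. Counts are gene-level fragment counts; a gene length (bp)
accompanies each gene for FPKM normalization. Library size N_i is defined
as the column total of the count matrix — the mapped-fragment total of the
upstream aligner is not available to a reusable pipeline, and for the
simulated data the two coincide.

## Differential expression

FPKM_gi = c_gi · 10⁹ / (N_i · L_g). Fold change per contrast is
log2((mean_A FPKM + ε) / (mean_B FPKM + ε)) with ε = 1.0 by default. The
pseudocount stabilizes ratios at n = 3 where a group mean near zero would
otherwise explode the fold change; it biases |log2FC| downward for genes
whose FPKM is of order ε, which is intentional shrinkage at the noisy low
end. ε is configurable.

Significance is a Welch t test on log2(FPKM + 1) with Satterthwaite
degrees of freedom and a per-group variance floor of 1e-8 (identical
groups then give t = 0, p = 1 rather than 0/0). This is a deliberate,
documented surrogate for a count-model test: it is fully specified,
dependency-free, symmetric in the groups, and behaves conservatively at
n = 3 (the measured null fraction with p < 0.05 is ≈ 0.035 at 5,000
simulated null genes). All downstream logic consumes only the per-gene
(log2FC, p, call) columns, so a different test can be swapped in without
touching anything else. DEG calls use strict thresholds |log2FC| > 1 and
p < 0.05; ties at either threshold are "ns". Raw p-values are used for DE
calling (no multiple-testing correction), matching common practice for
this threshold-style calling; correction is applied in the enrichment
stage, where it belongs.

The contrast scheme is fixed: four male stage transitions, four female
stage transitions, four stage-matched cross-sex comparisons. "Up" always
means higher in the first-named group. Exclusive up-regulated sets are
plain set differences: S_target minus the union of the other sets of the
named family; exclusive sets over any family are pairwise disjoint by
construction.

## Pathway enrichment

For a DEG set reduced to the annotated universe (N genes, n DEGs), a
pathway with K members and k DEG members gets the upper-tail
hypergeometric p = P(X ≥ k). Only over-representation is tested. The
universe is restricted to annotated genes because the unannotated fraction
is unidentifiable for KEGG-style tests. Across pathways with k ≥ 1,
Benjamini–Hochberg step-up correction yields q; significance is q < 0.05.
BH is the standard realization of "corrected p" in this literature; the
choice is a documented default, not an inference.

## Co-expression network and hub selection

Candidate features — curated genes plus hormone/sugar analytes — are
profiled over the shared 24-sample layout. Profiles enter as
log2(value + 1) by default (the usual scale for co-expression; the raw
scale is available via `log_scale=False`, in which case the whole hub call
is exactly invariant to per-feature affine rescaling) and are
z-standardized, which leaves Pearson r unchanged. Constant profiles are
excluded with a warning since r is undefined for them.

Edges: all unordered pairs are scored; an edge is kept iff |r| ≥ 0.8 and
p < 0.05, with p from the exact t transform t = r·√((n−2)/(1−r²)),
df = n − 2. |r| = 1 maps to p = 0 without numerical blow-up. The p
threshold is applied to edges (the natural place for a correlation
threshold); the selection thresholds r_min and alpha_edge are configurable
`NetParams`.

Hub rule: s_v = √((lfc²_{M3vsF3} + lfc²_{M4vsF4})/2), the RMS log2 fold
change over the two late cross-sex comparisons; compound features use
stage-mean concentration fold changes with a relative pseudocount of 1% of
the analyte's global mean (analyte units differ, so an absolute
pseudocount would be meaningless). A feature is a hub iff it passes BOTH
top-40% conditions: degree within the top 40% of the degrees of nodes
present in the network (degree ≥ 1), and s_v within the top 40% of all
scored candidates. Both cutoffs are top-k order statistics with
k = ceil(0.4·m) and ties at the cutoff included, making the call
deterministic and independent of input order. The degree condition is
ranked over network nodes because degree is a property of the drawn
network and an isolated candidate cannot meaningfully be a hub; the RMS
condition ranks all candidates because the fold change is defined for all
of them. Raising either quantile can only shrink the hub set.

## qPCR quantification

Technical replicates are averaged (arithmetic mean of Ct) before
normalization — standard practice. ΔCt = Ct_target − Ct_reference per
sample, ΔΔCt subtracts the calibrator sample's ΔCt, RQ = 2^(−ΔΔCt);
RQ ≡ 1 at the calibrator and adding a constant to all Ct values of a
sample cancels exactly. Amplification efficiency is fixed at 2 (the
method's defining assumption); dilution-series efficiency correction is
out of scope. Platform concordance is Pearson r (and R² = r²) between
aligned per-(gene, contrast) log2 fold changes, with the qPCR fold change
defined as the group difference of mean log2 RQ.

## Compound statistics

One-way ANOVA uses the standard between/within decomposition; the
degenerate all-identical case is guarded (reported F = 0, p = 1, MSE = 0,
flagged). Duncan's multiple range test sorts means descending and tests
spans of p adjacent means against R_p = q*(α_p, p, df_e)·√(MSE/r) at
protection level α_p = 1 − (1−α)^(p−1), never declaring a range
heterogeneous inside an already-homogeneous wider range. Letters are
assigned from the maximal homogeneous intervals of the sorted order, so
two groups share a letter iff the procedure does not separate them. The
studentized-range quantile q* is obtained by numerical inversion of the
studentized-range CDF (scipy's implementation of the double-integral
distribution function) and cached; no lookup tables are shipped, and the
computed quantiles reproduce published 5% table values to two decimals.
Unbalanced groups use the harmonic-mean replicate count with a warning;
MSE = 0 with unequal means yields all-distinct letters (R_p = 0). Letters
are invariant to shifting or positively scaling all observations.

Calibration curves regress concentration on peak area by ordinary least
squares and predict by evaluating the fitted line; at least two distinct
standards are required.

## The simulator

The generator's defaults are the study conditions used throughout the
tests; they are chosen once and stated here.

Counts: gene baselines b_g are log-normal (median 150 counts, log-sd 1.2);
gene lengths uniform 500–3,000 bp; per-sample target depth uniform in
4–6 M fragments; counts are negative binomial with variance μ + φμ² and
constant dispersion φ = 0.05 (typical for bulk RNA-seq biological
replicates; parameterized as shape 1/φ). Expected counts are
μ_gic = N_i · q_gc / Σ_g q_gc with q_gc = b_g · 2^E_gc, i.e. depth is
fixed and abundances are compositional, as in real sequencing — planted
effects therefore induce a small compositional shift in the fold changes
of null genes (≈ 0.04 log2 units at the default planting rate), which the
recovery tolerances absorb.

Planted differential effects: per contrast, a configured fraction of
eligible genes (2% per contrast by default, magnitude uniform 1–3 log2
units, sign ± with equal probability) receive a multiplicative effect on
the first-named stage. Because an effect attaches to a stage, it is
visible in every contrast involving that stage; the recorded truth is the
per-contrast planted set, and `GroundTruth.true_lfc` reconstructs the net
planted log2FC of any contrast from the full effect matrix.

Hub block: n_hub genes (default 10) share a stage-indexed latent profile
(high in M3/M4, low in F3/F4 — a male-biased module) with log2 amplitude
`gain` (default 2.0, i.e. planted cross-sex |lfc| = gain·loading·Δlatent =
3.6) and mixing weight `loading` (default 0.9) between the shared latent
and a gene-private stage wobble. The loading is a convex mixing weight on
the log2 scale, not a correlation coefficient: at 0.9 the hub block is
near-clique under the default edge threshold, while lower values decouple
the genes. A further n_background genes (default 90) are designated
candidates with no planted effect; DE planting skips all designated
candidates so background features have genuinely null fold changes.
Candidate baselines are drawn log-uniform 200–2,000 expected counts —
curated network candidates are well-expressed genes, and this keeps their
profiles from being dominated by shot noise.

Compounds: each analyte gets a base level (log-uniform 10–1,000, units
arbitrary per analyte), a stage profile (random smooth shifts, log-sd 0.5),
and mean-preserving log-normal replicate noise at CV 0.15 (replicate
variability of hormone assays is a stated default, not an inference).
Analytes named in the hub spec (default ZT, TZR, sucrose) follow the
latent profile with the hub gain, planting real transcript–compound
correlations. Explicit per-stage means can be configured per analyte.

Ct: Ct = a_ct − b_ct·log2(FPKM + 1) + N(0, σ_ct) with a_ct = 35,
b_ct = 1 (one cycle per doubling), σ_ct = 0.2 cycles per technical
replicate (3 replicates); the reference gene is generated at a
stage-constant expected Ct. With σ_ct = 0 the recovered qPCR fold change
equals the expression fold change on the log2(FPKM+1) scale exactly.

Annotation: ~60% of genes get 1–3 of 20 pathways uniformly; each
contrast's planted genes additionally join a designated pathway with
probability 0.5, so enrichment of a recovered DEG set is detectable while
null draws stay calibrated.

All randomness derives from one integer seed through deterministically
spawned sub-streams per component; identical configurations are
bit-identical.

What the simulator does **not** model: read-level artifacts, alignment and
counting uncertainty, GC/length bias within a gene, batch effects,
isoforms, gene–gene correlation outside the hub block, heavy-tailed
dispersion across genes, assay limits of detection. Passing recovery tests
therefore demonstrates the correctness and calibration of the analysis
chain under its own assumptions, not performance on any particular real
dataset.

## Problem sizes used by the checks

The recovery benchmarks run at 20 seeds × 5,000 genes (differential
expression) and 20 seeds × 100 candidate features (hub selection); the
Duncan letter property uses 100 seeds of an 8-stage panel; the
null-calibration and null-centering properties use 200 replicate draws.
These sizes give stable averages (the reported rates move by < 0.05
between unrelated seed sets) while keeping the default test run fast.

## Known limitations

* The Welch surrogate does not share information across genes; at n = 3 it
  is conservative, and genes with tiny within-group variance by chance can
  reach small p. The variance floor bounds but does not remove this.
* Duncan's procedure controls the per-comparison protected error rate, not
  the familywise rate; letters from heavily unbalanced designs use the
  harmonic-mean approximation.
* The composite hub rule depends on the empirical degree distribution: in
  a sparse network the top-40% degree cutoff can sit at degree 1, making
  hub membership sensitive to single edges near the r threshold.
* Compound fold changes use a relative pseudocount; analytes whose global
  mean is dominated by one extreme stage get proportionally larger
  shrinkage.
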