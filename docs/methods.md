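# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic data do and do not establish.

## T-RF semantics and digestion

A T-RFLP amplicon carries its fluorescent label on the 5′ end of the
forward strand, so only the fragment retaining that terminus is sized.
We define the T-RF length as the number of bases from the labeled
terminus through the last base before the cut on the labeled strand;
with a recognition site starting at 0-based position *s* and a cut
offset *c* (motif bases retained on the labeled fragment), the T-RF is
*s + c*. This matches fragment-analyzer size semantics. Enzyme
conventions are REBASE-standard and stored as data, not code: HhaI
recognizes GCGC and cuts GCG^C (*c* = 3); MspI recognizes CCGG and cuts
C^CGG (*c* = 1). Mono-digestion means separate aliquots per enzyme; the
two results never interact.

Sequences are restricted to uppercase A/C/G/T. IUPAC ambiguity codes are
rejected rather than expanded: a degenerate base makes the predicted
fragment size ill-defined, and all inputs this package generates are
unambiguous. Amplicons without a site return an explicit *uncut* flag,
never a pseudo-length; the ~600 bp full-length product falls outside
the scored window anyway.

## Peak processing

Scoring thresholds follow standard practice for ABI-style traces: sizes
in [50, 550] bp and heights ≥ 50 FU, both bounds inclusive. Relative
abundance is peak height over cumulative height per sample. Samples left
empty after filtering are kept as flagged empty rows so bookkeeping
survives.

Cross-sample alignment uses single-linkage clustering of observed sizes
with a 0.5 bp tolerance (configurable): consecutive sizes within the
tolerance chain into one bin, labeled by the rounded cluster mean. The
0.5 bp default is conservative for capillary size calls; the synthetic
generator caps size jitter below 0.5 bp so jittered peaks stay inside
their bin. If two clusters round to the same integer label they are
merged. A "major" T-RF is one carrying more than 5 % of total abundance
(reporting only). Replicate averaging is the arithmetic mean over a
replicate map (by default, sample ids ending in `.rep<k>` collapse onto
their stem).

## Diversity and similarity

Shannon diversity is computed in nats. "Shannon's evenness" names more
than one formula in the literature, and published index tables for this
system cannot be reconciled with any single standard form, so the
package defaults to Pielou's J = H / ln S and also offers Heip
((e^H − 1)/(S − 1)) and Sheldon (e^H / S); no published evenness value
is treated as ground truth. Berger-Parker is reported as dominance
d = max pᵢ (values below 1 that shrink as evenness grows, matching the
published ranges). Jaccard presence is abundance > 0 by default
(configurable threshold). Bray-Curtis dissimilarity is a semimetric —
no triangle inequality is asserted anywhere — which is one reason the
ordination is rank-based.

## NMDS

The ordination is Kruskal-style nonmetric MDS minimizing stress-1, with
pool-adjacent-violators isotonic regression over the full lower
triangle, written from scratch (established MDS implementations serve
only as independent oracles in the tests). The optimizer alternates
isotonic fits with SMACOF Guttman majorization steps; disparities are
rescaled to the configuration-distance scale before each step. Defaults:
2 dimensions, 20 restarts (restart 0 from classical Torgerson scaling,
the rest seeded uniform), 500 iterations, relative tolerance 1e-7. A
step that would increase stress-1 is rejected and terminates the
restart, so the recorded stress sequence is non-increasing by
construction. Ties follow Kruskal's primary approach: within a tie block
of dissimilarities, distances are pre-sorted ascending so the monotone
fit may break ties freely. Degenerate inputs (all-coincident
configurations, fewer than 3 samples, asymmetric matrices) raise. The
returned configuration is canonicalized — centered, rotated onto
principal axes, sign-fixed so the first sample's coordinates are
non-negative — making runs directly comparable; stress is invariant
under these transforms.

## Taxon affiliation

The bundled affiliation table carries 25 OTUs (distinct ordered
(HhaI, MspI) pairs) with taxon names, ranks and BLAST identity
percentages; two OTUs whose representative sequencing failed are flagged
`#` — their fragment lengths are real and count toward distinct-T-RF
totals, but they can never resolve an affiliation. Uncultured-clone hits
are stored at the rank actually printed (phylum or order) and do not
resolve at genus rank. A community T-RF resolves only when every OTU it
matches within the tolerance (default ± 1 bp, the conventional T-RFLP
drift allowance) agrees on one name at the requested rank; identity
thresholds (e.g. ≥ 97 %) are a filter parameter, not hard-coded. Genus
distributions are computed from HhaI profiles only (the discriminating
enzyme here); unresolved abundance is conserved under "unassigned".
Note the table's distinct MspI count is 14 by direct enumeration; only
the HhaI count (22) is used as a reference quantity.

## Chemistry and Duncan's test

One-way ANOVA is computed from sufficient statistics (mean, SD, n per
sample) because published tables carry only summaries; it is
algebraically identical to raw-data ANOVA whenever raw data realize the
summaries, which the tests verify. Duncan's multiple range test uses
critical ranges R_p = q(1−(1−α)^(p−1); p, df_w)·√(MSE/n), with the
studentized-range quantile computed numerically (no printed tables) and
a harmonic-mean n for unbalanced designs. Letters mark maximal
non-significant stretches of the mean-sorted samples (containment
protection included), so they are always contiguous; identical letter
sets define content groups, labeled High/Sub-high/Intermediate/Low by
descending mean when exactly four. Edge contracts: zero pooled error
with distinct means ⇒ every distinct mean its own class; all equal ⇒
one class; zero-variance ANOVA with equal means is flagged degenerate.

Two honest caveats, established analytically and by measurement:

- The published galangin letter display is **not** reproducible from the
  published summaries under Duncan's test: with pooled MSE 0.2841
  (se = 0.3077), the intermediate class spans 1.00 > R₅ = 0.993 and the
  sub-high class spans a 1.23 step > R₂ = 0.898, so both split. The
  printed letters are consistent with a single studentized-range
  critical value (≈ 1.57) instead; the original analysis presumably ran
  on raw replicate data. The volatile-oil column reproduces the printed
  four-class partition exactly. The corresponding acceptance test
  asserts the published behavior and is expected to fail on the galangin
  half; it is left failing deliberately.
- Exact recovery of planted groups by sample-level Duncan lettering is
  bounded by the protection levels themselves: within a true-null group
  of p samples a spurious split occurs with probability
  ≈ 1−(1−α)^(p−1), independent of the noise scale, so for groups sized
  (5, 3, 3, 1) exact recovery happens in ≈ 0.95⁸ ≈ 66 % of seeds. The
  tests therefore check planted-group recovery at the group level
  (where it is reliable) and check the sample-level rate against this
  closed-form expectation rather than against a wished-for bound.

Calibration curves are ordinary least squares on (amount, response)
standards; inversion is (response − intercept)/slope, with zero-slope
curves flagged non-invertible. Fold excess of a reference sample is
ref_mean/other_mean − 1, reported at 2-decimal rounding; it is
scale-invariant.

## Synthetic data: what it emulates, and what it does not

The generator is the package's test bed. Amplicon construction is
rejection-free: planted motif bases are forced at the positions implied
by the targets, and every free base is drawn only from characters that
do not complete a forbidden upstream motif occurrence in any
fully-determined window, so digestion reproduces the targets exactly and
construction always terminates (genuinely conflicting targets raise an
infeasibility error). Electropherograms place one peak per present taxon
at its target size (uncut taxa at full length, outside the window) with
Gaussian size jitter (default SD 0.1 bp), multiplicative height noise
(default CV 0.05) around an expected height of abundance × total signal
(default 10,000 FU — published traces do not constrain absolute
fluorescence, so this is an arbitrary documented scale), plus spurious
peaks drawn strictly below the 50 FU floor so filtering removes them
deterministically. Clone libraries are multinomial draws (study scale
226 clones). Chemistry replicates are Gaussian around group means; the
bundled design uses the published group-level analyte means with an SD
of 0.45, in line with the published per-sample SDs (≈ 0.46 on average).

The bundled 12-sample design plants four content groups with distinct
community profiles (the High group dominated by a 325-bp
*Pestalotiopsis* fragment, the Low group by a 389-bp *Marasmius*
fragment), each sample a seeded log-normal perturbation (σ = 0.15) of
its group profile. Passing tests on these data establish that the
pipeline's bookkeeping, statistics and optimization are correct and that
planted structure of realistic effect size is recovered; they do not
establish robustness to what the generator omits — PCR amplification
bias, chimeras, pseudo-T-RFs, size-calling nonlinearity, or taxa sharing
identical fragment lengths across both enzymes.

## Problem sizes

Default test and reproduction scales: 12-sample community matrices,
1,000-sequence digestion oracles, 50-seed Monte-Carlo runs for group
recovery, 10-seed end-to-end recovery runs, and 20-restart NMDS on
12 × 12 matrices. These sizes exercise every code path at the study's
own scale while keeping the full suite fast on a single CPU.
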