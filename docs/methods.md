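# Methods

## Problem and model

Hi-C measures genome-wide chromatin contact frequencies at a resolution
(typically 5–100 kb bins) far coarser than transcriptional regulator
(TR) binding events. `hicdci` connects the two scales in two stages:

1. **Differential chromatin interaction (DCI) profile.** For every bin,
   compare the bin's interactions with its flanking bins (within a
   genomic distance bound *D*) between two conditions, yielding a
   signed per-bin statistic.
2. **TR inference.** Project the binned profile onto a fixed catalog of
   candidate cis-regulatory elements (CREs), and rank TRs from a
   ChIP-seq binding compendium by how strongly each TR's bound CREs
   concentrate at high (or, after flipping the profile, low) scores.

### Distance normalization

Raw intra-chromosomal counts decay strongly with genomic distance. Per
chromosome and per replicate, each count c_ij is divided by the mean
count over all bin pairs at the same distance |i−j| (zero-count pairs
included in the denominator, because an unobserved pair in raw Hi-C is
a real observation of zero). After normalization every distance stratum
with any signal has mean exactly 1, and the transform is invariant to
scalar depth differences — so replicates of different sequencing depth
need no extra pre-scaling. Distance strata with zero total count map to
zero. This normalization removes distance decay only; it is not a
substitute for GC/mappability/enzyme-bias corrections, which are out of
scope.

### Contact score arrays and the DCI statistic

A bin's *contact score array* holds its normalized contacts at signed
flank distances −D_bins…−1, +1…+D_bins (D_bins = D / bin size; default
D = 200 kb, so 40 flanks per side at 5 kb bins). The self-interaction
diagonal (δ = 0) is excluded: it measures self-ligation and coverage,
not interaction with flanking regions. Arrays truncate at chromosome
ends rather than dropping edge bins; positions always match across
conditions because they are pure geometry.

For m control and n treatment replicates, all m×n (control, treatment)
pairs are tested with a two-sided paired t-test on the element-wise
array differences; the m×n p-values are combined with Fisher's method
(χ² = −2Σln p on 2mn df). The pairs share replicates when m, n > 1, so
the combined test is anticonservative in that regime — this dependence
is accepted as part of the design, and the null-calibration check is
run at m = n = 1 where the p-values are honestly uniform. The score is

    S = sign(Σ t) · (−log10 p_combined)

with sign 0 (and S = 0) on an exactly zero t-sum. Base-10 logs follow
genome-track conventions.

Numerical choices:

* p-values are floored at 1e-300 before logs so scores stay finite;
  a zero-variance nonzero shift in a paired test reports the floor
  directly with the shift's sign.
* The Fisher log-sum is computed over *sorted* p-values and the t-sum
  with exact (`fsum`) summation, making the profile invariant to the
  order replicate pairs are enumerated — swapping the two conditions
  then negates every S and preserves every p bit-for-bit.
* Bins with no contacts in any replicate of either condition are
  flagged no-data (S = 0, p = 1) and excluded from regression and
  rank-sum tests; absence of data must not imitate "no change". The
  same flag is applied in the degenerate geometry where a bin's
  truncated array has fewer than two flanks (chromosomes of < 3 bins).

### Coverage adjustment (optional)

Copy-number or accessibility changes alter per-bin read coverage and
can masquerade as interaction changes. The optional adjustment
computes, per bin, x = log2((mean treatment band coverage + 1) /
(mean control band coverage + 1)) — band coverage is the row sum of
raw counts within |i−j| ≤ D_bins, diagonal included, as the diagonal is
the strongest per-bin coverage proxy — and replaces S by the residual
of an ordinary least-squares fit of S on x over scored bins. A constant
covariate returns the profile unchanged with a warning. After
adjustment the score is a residual, no longer sign·(−log10 p); the
per-bin p and sign columns keep their unadjusted values.

### CRE mapping

Each CRE inherits the S of the bin containing its midpoint. Midpoint
assignment (rather than overlap-weighted averaging) is used because
CREs (~0.1–1 kb) are tiny relative to bins; it is unambiguous for
boundary-spanning CREs and order-independent. CREs on no-data bins or
chromosomes absent from the profile are masked out of the ranking, not
zero-filled. Flipping negates scores and leaves the mask; flip∘flip is
the identity.

### TR ranking

Scored CREs are ranked by descending score (ties broken by CRE ordinal
for determinism). Each binding dataset gets the Mann–Whitney AUROC of
its bound CREs under the ascending score ranks, with midranks for
score ties, over the full ranked list; datasets that bind all or none
of the scored CREs are skipped. Per TR, three statistics are computed
against the pool of all usable dataset AUROCs:

* one-sided Wilcoxon rank-sum of the TR's AUROCs vs all others'
  (exact enumeration for small tie-free samples, tie- and
  continuity-corrected normal approximation otherwise);
* z-score of the TR's mean AUROC against the mean and sample SD of all
  AUROCs;
* the TR's maximum AUROC.

Each statistic is converted to a rank quantile r = rank / N_TRs
(best → smallest; ties share the mean rank), and the rank sum
s = r_w + r_z + r_m is referred to the Irwin–Hall distribution with
k = 3 (lower tail) via the alternating-sum closed form. TRs are sorted
by ascending p with a name tie-break, so equal inputs give
byte-identical tables.

The three quantiles are computed from the same AUROC values and are
positively correlated, so the Irwin–Hall reference (which assumes
independence) is approximate: under a binding compendium independent
of the profile the p-values are only loosely uniform (empirical KS
distance ≈ 0.2 at 50 TRs), with a floor of (3/N)³/6 attained by the
chance-best TR. The p-value is therefore a ranking statistic more than
a calibrated error rate; the recommended control for false positives
is the replicate-background run (below).

## Synthetic data generator

The generator emulates the input contract at desk scale: per
chromosome, counts at bin distance d are Poisson with mean
λ₀·(d+1)^−α (defaults λ₀ = 100, α = 1, matching the roughly inverse
distance decay of real intra-chromosomal Hi-C), symmetric, with an
optional negative-binomial overdispersion knob. Differential "blocks"
multiply the expected count by a fold change when both partners fall
inside the block's bin range; keep block width ≤ D_bins so the signal
lies inside the tested band (the defaults use 40-bin = 200 kb blocks
at fold 3, one per chromosome). The CRE catalog scatters 2000 400-bp
intervals uniformly; the compendium has 50 TRs × 2 datasets binding 5%
of CREs, with the single causal TR's binding probability multiplied by
10 (capped at 1) inside blocks. Conditions and replicates draw from
independent, seeded substreams, so a no-block configuration makes the
two conditions exchangeable — the null-calibration setting.

What the generator does *not* emulate: TADs, compartments, loops,
GC/mappability bias, restriction-fragment structure, inter-chromosomal
contacts, or correlated binding across datasets of one TR. Passing
tests therefore demonstrate the statistical machinery on an idealized
contact model, not performance on real Hi-C libraries.

## Problem sizes used in the test battery

The bundled benchmark runs 20 independent genomes of 2 chromosomes ×
400 bins at 5 kb (D = 200 kb, fold 3, 50 TRs × 2 datasets, enrichment
10, 2 replicates per condition): the causal TR is required to rank
first in the increase direction in ≥ 19/20 runs, and — per the
technical-variation control, in which replicates of the *same*
condition are compared (rep 1 vs rep 2 of the control set, 1 vs 1) —
to stay outside the top decile in ≥ 18/20 runs. Null calibration uses
one 2000-bin chromosome with single replicates and no blocks and
requires the per-bin p-values to be uniform within KS distance 0.1.
Kernel exactness is checked against exhaustive pair counting (AUROC),
complete enumeration of rank-sum assignments (Wilcoxon, n ≤ 8), and a
10⁶-draw Monte-Carlo of the Irwin–Hall CDF.

## Known limitations

* The dependence between shared-replicate t-tests makes multi-replicate
  p-values anticonservative; interpret S as a ranking score.
* The Irwin–Hall p is approximate under correlated rank quantiles (see
  above).
* Locus-pair (loop-level) differential calls, TAD calling and
  inter-chromosomal interactions are out of scope by design.
* Genome rearrangements between conditions violate the model's
  assumption that differences reflect regulator activity in cis.
* Reading Juicer `.hic` files requires the optional `hicstraw`
  dependency; the HiC-Pro and cooler dialects are self-contained.
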