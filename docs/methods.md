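# Methods

`ciberseq` processes dual-barcoded CRISPRi expression-reporter screens:
pooled libraries in which every construct carries a tandem pair of sgRNAs
against one gene plus two random 25-nt barcodes, one embedded in a pathway
reporter transcript ("red", mCherry-linked) and one in a constitutive
control transcript ("ir", iRFP-linked). Sequenced barcode abundance is the
phenotype: a guide that blocks reporter induction depletes its red barcode
relative to its ir partner. This note records the models, the parameters
that matter, and the choices made where the design was genuinely open.

## Lookup construction from long reads

Long reads over the linearized plasmid library see both barcodes and the
guide cassette at once. Each anchor (a fixed vector flank, >= 12 nt) is
located by a Hamming-distance substring scan with at most
`max_anchor_mismatch` substitutions (default 2), leftmost-best, forward
strand first and then the reverse complement; indel alignment is not
attempted because substitutions dominate in the intended data and the
anchors are long enough to tolerate the budget. The bases between each
anchor pair must have exactly the expected length (25 nt per barcode,
2 x 20 nt for the cassette), otherwise the read is rejected with a reason
(`anchor_missing`, `length_mismatch`, `ambiguous_anchor` for anchors in a
conflicting arrangement, `ambiguous_base` for an N inside an extracted
element).

Reads are grouped by **exact** barcode-pair identity and each group is
assigned its majority cassette; `support` is the group size and `purity`
the majority fraction. Groups below `min_support` (default 3) or
`min_purity` (default 0.9) are discarded, and any barcode string that
survives in more than one entry (chimera/collision) removes every entry
containing it. Error-carrying reads are meant to *fail* these thresholds,
not to be corrected: in a 25-nt random barcode space, near-collisions
between genuine barcodes are vanishingly rare, so dropping is safe and
relinking impossible by construction.

Purity interacts with the long-read error rate: a read keeps its 40-nt
cassette error-free with probability (1-e)^40, which is ~0.96 at e = 0.1%
(HiFi-grade) but only ~0.67 at e = 1%. The 0.9 default is therefore
calibrated for HiFi-grade error; at 1% error a threshold of ~0.6 retains
majority-correct groups. Both knobs are exposed in the CLI and config.

## Tag extraction and error-aware counting

Amplicon reads carry the UMI in their first `umi_len` bases (default 10,
introduced by the RT primer) and the barcode adjacent to a fixed anchor
(default: anchor then barcode). Quality scores are ignored: molecule
counting is made robust downstream by UMI deduplication and barcode
collapse rather than by base-quality filtering. Reads that are too short,
lack the anchor within the mismatch budget, or contain an N inside the UMI
or barcode are rejected with a reason; record conservation (reads in =
tags out + rejects) is asserted at run time.

Both barcodes and UMIs are cleaned with the **directional** network rule:
a directed edge a -> b exists when Hamming(a, b) <= d (default d = 1 for
both) and reads(a) >= 2*reads(b) - 1; every sequence is absorbed into the
root of its highest-count reachable absorber, ties broken by higher count
then lexicographically smaller sequence. The count criterion separates
genuine neighbors of comparable abundance from error progeny, which carry
a small fraction of their parent's reads. Absorbed barcodes contribute
their UMI tables (read counts of identical UMIs summed) before UMIs are
deduplicated per canonical barcode; the molecule count is the number of
canonical UMIs. Neighbor candidates are found by exact-matching d+1
sequence segments, which is exhaustive for Hamming distance <= d and keeps
the implementation equal to an all-pairs oracle while scaling
near-linearly. Indels are not modeled (fixed-length extraction makes
substitutions the dominant error mode).

One intrinsic property worth knowing: with singleton counts the criterion
1 >= 2*1 - 1 holds, so two genuinely distinct molecules whose UMIs happen
to lie within Hamming distance 1 merge. At 10-nt UMIs this costs ~3e-5
per UMI pair and only matters at very high per-barcode molecule counts;
exact distinct-UMI counting is available via `umi_max_dist=0`.

## Matrix, filter, aggregation

The barcode x library matrix (one column per (sample, channel) amplicon
library) unions barcodes across libraries with zero fill. Barcodes with an
arithmetic mean count below 32 across **all** columns — both channels,
following the stage order trim -> collapse -> tabulate -> filter -> match
-> aggregate -> test — are discarded; the boundary is inclusive (mean
exactly 32 is kept). The filter is applied to deduplicated molecule
counts, i.e. the matrix the downstream test consumes. Because a barcode is
only measurable in its own channel's libraries, averaging over all
columns includes structural zeros and effectively doubles the abundance a
barcode needs in its measured libraries; analyses that plant strong
knockdown effects must budget sequencing depth for this (see "Synthetic
screens" below).

Matching annotates each barcode with its (construct, channel) from the
lookup; unmatched barcodes and channel conflicts (a barcode observed only
in the other channel's libraries) are reported, and per-construct sums
with `barcode_n` and `single_channel` flags follow. A conservation ledger
(raw column sums = construct + unmatched + filtered-out sums) is checked
on every run.

## Count model and testing

Counts are modeled as negative binomial with variance mu + alpha*mu^2.
The workflow is the standard RNA-seq recipe, re-implemented:

* **Size factors**: median-of-ratios over features with all-positive
  counts, rescaled to geometric mean 1; a positive-entry pseudo-reference
  is available for matrices without an everywhere-positive feature.
* **Dispersions**: per-feature method-of-moments estimates on normalized
  counts, pooling within-cell variances (cells = condition x channel
  replicate groups): alpha_hat = max(0, (s^2 - mean)/mean^2). A log-linear
  mean-dispersion trend is fitted to quantile-binned *untruncated* moment
  estimates — with ~4 residual degrees of freedom the per-feature moment
  estimator is roughly unbiased on the alpha scale but strongly skewed,
  so a per-feature log-scale fit would be biased low and inflate Wald
  tails; binning before taking logs avoids that. The final dispersion is
  the geometric mean (weight 0.5) of trend and raw values with the raw
  value floored at the trend, so no feature is ever assigned less
  dispersion than the trend predicts for its expression level. The floor
  is what keeps a null screen at its nominal false-positive rate; the
  symmetric two-sided shrink is available via `floor_at_trend=False`.
  Fewer than ~10 informative features triggers a global-median fallback
  (warned).
* **Wald tests**: per-feature NB log-link regressions with log size
  factors as fixed offsets, fitted by IRLS vectorized across features
  (shared design matrix, batched normal equations), Wald z on a single
  contrast coefficient, two-sided normal p, Benjamini-Hochberg adjustment
  (NA p-values excluded from the multiplicity count), and two-threshold
  hit calling: significant if padj < 0.01, hit if additionally |log2FC| >
  1.5. Features with all-zero counts get NA; an all-zero contrast group
  gets a 0.5-pseudo-count fold change for reporting only.

Three contrasts cover the screen designs: a condition effect within one
channel; the red:ir channel ratio within a condition (or across all
samples), with sample-level factors absorbing the pairing so count-level
uncertainty is retained (rather than collapsing to per-pair ratios); and
the interaction (change of the red:ir ratio between conditions).

Differences from DESeq2, which this workflow resembles: no Cox-Reid
adjustment, no apeglm/ashr shrinkage of fold changes, no independent
filtering, no outlier replacement. A construct-level TSV export is
DESeq2-ingestible for external cross-checks.

### Control-screen baseline normalization

A control screen whose two reporters share the same promoter measures
each barcode pair's sequence-intrinsic log2 red:ir baseline beta0 (a
minority of pairs differ several-fold). `estimate_baseline` runs the
channel-ratio contrast on the control screen and returns beta0 with its
SE; supplying the table to a later screen's channel-involving test adds
beta0*ln2 to the red-channel offsets, so departures are measured from the
measured baseline rather than from zero. The baseline is treated as
known: its SE is reported but not propagated into the test — a documented
limitation, acceptable because the control screen is typically much
deeper than any single comparison.

## Synthetic screens

The generator emulates the library statistics of a genome-scale screen at
desk scale: 2,000 constructs (standing in for ~21,554) of which 100 are
non-targeting controls (for ~989), mean 8 barcode pairs per construct
(1 + Poisson), 25-nt barcodes globally distinct by rejection sampling,
10-nt UMIs. Construct abundances are log-normal (sigma 0.5), barcode
shares within a construct symmetric Dirichlet, molecule counts NB with
dispersion 0.05 (defaults chosen as plausible for a deep bulk-RNA screen;
the source data report no empirical dispersion or duplication rate), PCR
duplication geometric with rate 0.5 (one extra copy per molecule on
average), substitution errors 0.5% per base on short reads and 1% on long
reads. Planted log2 effects act multiplicatively on the red channel in
chosen conditions; per-pair baseline biases (SD 0.35 in control-screen
scenarios) act on the red channel in every condition.

Simulation is molecule-first: each molecule receives its UMI before PCR
duplication and read errors, so deduplication truth is well-defined;
truth counts are recorded pre-error. Every output is a pure function of
the seed.

What the generator does **not** emulate: indel errors, quality-score
structure, index hopping, cell-level effects (integration copy number,
MOI, growth), guide efficacy variation, and correlated biological noise
across barcodes of one construct (counts are independent NB given the
construct abundance). Passing tests therefore demonstrate the pipeline's
arithmetic and statistical calibration under the stated noise model, not
robustness to every artifact of real libraries.

Problem sizes used by the acceptance checks: the null screen simulates
~21,000 barcode pairs (2,600 constructs) at 2e6 molecules per library
across 12 libraries and runs the full read-level pipeline (~48M reads);
planted-effect recovery uses 2,000 constructs at 4e6 molecules per
library at the count level. The planted-recovery depth is set so that a
4-fold-down construct's red barcodes clear the 32-mean filter (whose
average includes the other channel's structural zeros): an uninduced
per-barcode mean of ~250 leaves (3 + 3/4)*250/12 ~ 78 >= 32 with room for
the library's abundance spread.

## Numerical choices and degenerate inputs

* IRLS: initialization from least squares on log(counts + 0.5), linear
  predictor clipped to [-30, 30], weights floored at 1e-12, convergence at
  max |delta beta| < 1e-10 within 50 iterations; non-converged features
  are flagged and given NA p-values. Singular normal equations fall back
  to a ridge-stabilized solve / pseudo-inverse.
* Directional collapse ties: claim order is (higher count, then
  lexicographically smaller sequence); `max_dist=0` is the identity map.
* Majority vote ties in lookup construction resolve to the
  lexicographically smaller guide key (deterministic; such groups then
  fail any purity threshold > 0.5 anyway).
* Empty inputs: an empty parsed-read stream yields an empty lookup (not
  an error); an empty UMI table deduplicates to 0; an empty control
  screen is an error.
* BH adjustment is order-preserving and treats NA as excluded.

## Known limitations

* The Wald test with plug-in dispersions is approximate at 3 replicates;
  calibration was verified by simulation (null screens across seeds show
  no BH discoveries and near-uniform p-values), but extreme-tail behavior
  with very few replicates or very low counts is not exact.
* Baseline uncertainty is not propagated (above).
* Barcode collapse never merges at Hamming distance > `bc_max_dist`;
  two-error variants of a barcode survive as spurious low-count rows and
  are expected to die at the abundance filter, slightly inflating the raw
  (pre-filter) barcode count.
* The paired-channel model absorbs pairing through sample factors; it
  does not model overdispersion shared within a barcode pair beyond the
  planted baseline term.
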