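# Methods

This note documents the models, conventions and numerical choices behind
islandscan, what the synthetic-data generator does and does not emulate,
and the limitations a user should know before applying the pipeline to
real libraries.

## Coordinates and strands

All coordinates are 0-based, half-open, on the *analyzed* strand. The GFP
channel reads the top strand of a template; the RFP channel reads the
bottom strand, which the pipeline analyzes as the reverse complement in
its own frame. `motif_scan.map_to_top` converts bottom-frame starts back
to top-strand coordinates for display. Overlap of two hits is a nonempty
intersection of their half-open intervals.

## Position weight matrices

A PWM is a per-position log2-odds matrix against a uniform 25% background:
`log2(((count + c) / (n + 4c)) / 0.25)` with pseudocount `c ≥ 0`
(default 0). With `c = 0`, a base unobserved at a position scores −∞,
which can never pass a finite threshold — this is the intended semantics,
not an error. The total information content is
`Σ_positions (2 + Σ_b p_b log2 p_b)`; a matrix built from a single
instance therefore carries 2 bits per position.

The default call threshold is the matrix's total information content.
That convention yields 3.98 bits for the −10 box matrix and 3.39 bits for
the −35 box matrix built from the RegulonDB-derived instance sets used in
this field; "low-affinity" calls use exactly half of those thresholds
(1.99 / 1.70 bits). The UP element is only published as an IUPAC consensus
(NNAAAWWTWTTTTNNWAAASYM) with a fixed threshold of 19.2 bits (relaxed:
4.8 bits, a quarter); degenerate letters expand to equal frequencies over
their allowed bases. The H-NS matrix, when supplied as instances, defaults
to its own information content, by analogy with the boxes.

Overlapping hits of the same class at adjacent offsets are counted as
separate hits: every above-threshold start position is reported.

## Fluorescence scores and the promoter call

`F = Σ_f f·Reads_f / Σ_f Reads_f` over bins f = 1..4, per channel,
independent between channels; a channel with zero reads yields NaN and is
excluded from that channel's analyses without affecting the other. The
promoter call is `F ≥ 1.5` a.u.; the boundary is inclusive by default
(configurable), which is the reading consistent with a 1.49 a.u. sequence
being a non-promoter.

Filtering retains records with the wild-type length (150 bp), at least one
read in the unsorted library, at least 30 reads summed over all eight
sorted bins plus the unsorted library (whether the unsorted count
participates is a flag), and Hamming distance ≤ 10 to the closest parent;
parents with fewer than 2000 surviving unique daughters are then dropped
with all their daughters. Ties in parent assignment break by parent input
order and are flagged. The rejection log is a mandatory output, one reason
per dropped record, applied in the order above.

## Mutual information

For each position i, the plug-in mutual information between base identity
(4 levels) and fluorescence rounded half-up to the nearest bin (4 levels)
is corrected by the leading finite-sample bias term
`(n_b − 1)(n_f − 1) log2(e) / (2N) = 9 log2(e) / (2N)`; the O(N⁻²)
remainder of the expansion is unspecified in the source method and is
dropped. The corrected estimate can be slightly negative for
uninformative positions; that is expected and handled by the adjustment
step. Note the practical floor this imposes: signals of order
`9·log2(e)/(2N)` bits (≈0.016 bits at N ≈ 400 per pseudo-replicate) are
not resolvable, which is why libraries of ~2000 daughters per parent are
the intended operating point.

The library is split uniformly at random into three pseudo-replicates
(sizes within 1, seeded). Each replicate's profile is smoothed with a
Gaussian kernel (σ = 1 position, reflect boundary) *before* the
cross-replicate mean and standard deviation are taken (population std,
ddof = 0); the reverse order is available behind a flag since the source
method does not fully pin it down. The adjusted profile is mean − std with
values below 0.0005 bits truncated to 0.

Hotspots are positions whose adjusted value (a) reaches the 90th
percentile of the whole 150-position adjusted profile — linear
interpolation between order statistics, zeros included — and (b) strictly
exceeds both neighbours. Boundary positions cannot qualify. Downstream
proximity tests use peak ± 3 bp.

## Gain/loss association testing

For every window start (window width = PWM width), daughters are
partitioned by their own window score against the matrix threshold. A
two-sided Mann–Whitney U test (tie-corrected) runs when both groups hold
strictly more than 10 values; `delta_F` is median(F_with) −
median(F_without). Tests with p < 0.05 lying within ±3 bp of a hotspot
peak are recorded; Benjamini–Hochberg q-values are assigned over the
pooled family of recorded tests per motif class and channel (channels are
separate families; per-parent families are available). A significant
effect additionally requires |delta_F| > 0.5 a.u.

Direction is defined by the parent's own above-threshold status in the
window: "loss" where the parent has the box, "gain" otherwise. `delta_F`
always has the with-minus-without sign; the derived `effect` property
reports the change in the direction of the mutational event (negated for
losses), matching how loss effects are conventionally plotted as negative
when a promoter is destroyed.

The new-box census collects window starts above threshold in at least one
daughter but not in the parent; gains are classified homo (overlapping a
parent box of the same class), hetero (other class; when both overlap, the
homo event takes precedence and both are reported), or non-overlapping.
The spacing census counts new boxes with a cognate box — new or
preexisting — at a 15–20 bp spacer, and new −10 boxes whose creating
daughter carries TG at offsets −3..−2.

## Emergence statistics

P_new is the fraction of a parent's daughters at or above the promoter
threshold. The sigmoid is fitted in the canonical increasing form
`P_new = L / (1 + e^{−k(x − x0)})` by nonlinear least squares
(initialization L₀ = max(y), x₀ = 1.5 a.u., k₀ = 10; L bounded in (0, 1];
Wald p-values from the asymptotic covariance). The printed form of this
equation elsewhere uses the exponent −k(x0 − x), which is a decreasing
curve for k > 0; the increasing form is the one consistent with the fitted
behaviour, and a fit reported against the printed form simply carries k of
the opposite sign.

Feature regressions are ordinary least squares (scipy `linregress`), with
the Wald p for a zero slope and Pearson r². The k-mer analysis enumerates
all Σ_{k=1..6} 4^k = 5460 k-mers, counts overlapping occurrences on the
parent's analyzed strand only (top for GFP, reverse complement for RFP),
keeps k-mers with ≥3 occurrences in at least one parent, regresses counts
against P_new, applies BH at FDR 0.05, and reports a leave-one-out
sensitivity refit (dropping each parent in turn) — the instrument for
detecting single-parent-driven k-mer signals.

Scrambling nulls permute a whole parent (composition preserved) or a
motif-sized region only, the latter retrying until no *new*
above-threshold hit of any avoided matrix overlaps the region (bounded
retries; note the identity permutation is always acceptable, so failure is
only possible with small retry budgets). Hotspot/motif overlap is
tabulated over the four categories (−10 only, −35 only, both, neither) on
real and scrambled parents with hotspot coordinates held fixed, and
compared with a χ² goodness-of-fit test, `Σ (O−E)²/E` with df = 3, using
the comparison group's counts as expected values — the formulation that
reproduces all three published overlap statistics from the published count
vectors. A 2×4 contingency formulation was considered and rejected for
that reason. H-NS knockout candidates are Tukey outliers: values outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by linear interpolation, per
channel.

## The synthetic-data generator

The generator's defaults are the study conditions: 150 bp templates, a
planted consensus −35/−10 pair at spacer 17 (configurable 15–20), two
decoy boxes placed at non-overlapping positions constrained not to
complete a second legally spaced pair, 2000 daughters per parent with
zero-truncated Poisson mutation counts calibrated so the truncated mean is
2.5 (λ ≈ 2.344, capped at 10), substitutions uniform over the three
alternative bases, 50 reads per daughter per channel, and 5% symmetric
adjacent-bin spillover. Background composition defaults to 50% GC.
Non-promoter templates are resampled until no legal above-threshold pair
exists on the analyzed strand.

The activity model is a logistic of the best paired-box score: activity a
is the maximum over −35/−10 pairs (both above their matrix thresholds,
spacer 15–20) of the summed bit scores, 0 when no pair exists, minus a
configured repression strength while a planted H-NS site is intact;
`F = 1 + 3 / (1 + e^{−(a − a₀)/s})` with a₀ defaulting to the consensus
pair score − 10 and s = 1.5, so a consensus pair saturates near 4.0 a.u.
and a pairless sequence sits at the 1.0 a.u. floor. This is the simplest
deterministic model consistent with the pairing requirement and graded
fluorescence; it is not a biophysical claim about σ70.

The simulation matrices are built from small synthetic instance sets
written around the canonical consensus hexamers (the published
RegulonDB-derived instance files are external inputs, not shipped), with
pseudocount 0.5 so all scores are finite.

What the generator does **not** emulate: sequencing errors after sorting,
PCR duplicates/jackpots, FACS mis-sorting beyond nearest-neighbour
spillover, transition-biased mutation spectra (a weight matrix hook
exists), H-NS binding energetics, or any correlation structure between
channels beyond the shared sequence. Passing recovery tests therefore
demonstrate the estimators' correctness and power under idealized noise,
not robustness to real-library artifacts.

## Problem sizes and determinism

All randomness flows through seeded `numpy` generators; datasets are
byte-reproducible for a fixed configuration and seed. The end-to-end
recovery experiment runs 20 replicate simulations of 10 templates × 2000
daughters (depth 50, spillover 0.05) — the full stated study conditions —
and completes in well under a minute per ten replicates on one CPU thanks
to vectorized PWM scanning. Unit and property tests use smaller libraries
(300–1500 daughters) except where the MI correction floor requires the
full scale.

## Known limitations

* Fluorescence is quantized to four bins: a latent effect between bin
  centres is recovered with a quantization bias (the effect-size recovery
  tests plant effects at bin centres for this reason).
* The MWU normal approximation is used for tied or large samples; exact
  enumeration is only guaranteed for small untied groups.
* The hotspot caller's percentile threshold is global per parent; parents
  with a single dominant peak can have hotspots elsewhere suppressed.
* `filter_daughters` logs one (the first applicable) reason per record,
  so reason tallies are order-dependent.
* The χ² goodness-of-fit comparison treats the second condition's counts
  as expected values without renormalization; it requires all expected
  counts to be positive.
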