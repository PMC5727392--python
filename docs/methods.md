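# Methods

This note documents the models and procedures implemented in
`branchsense`, the parameter choices that matter, what the synthetic
data does and does not emulate, and the numerical conventions. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates

Intervals on disk are BED-style 0-based half-open. Inside an intron all
offsets are negative, with −1 the last intron nucleotide (the G of the
terminal AG). A BP heptamer starting at offset *o* occupies *o*…*o*+6
and its branch nucleotide (heptamer position 6) sits at *o*+5. Windows
such as "the 3′ 150 nt" or "positions −104 to −29" are suffix slices of
the sense-strand intron sequence; minus-strand introns are reverse
complemented once, at BED reading, so every downstream operation is
strand-agnostic.

## Branch-point scoring

**U2 pairing score** (0–6). The BP heptamer pairs with U2 snRNA's
GUAGUA with the branch adenosine bulged out; position 6 is therefore
unscored. Each of the six paired positions contributes 1.0 for the
Watson–Crick base (T,A,C,T,A,·,C), 0.5 for a G:U wobble (pre-mRNA G
where U2 presents U, positions 2 and 5; pre-mRNA U where U2 presents G,
positions 3 and 7), else 0. TACTAAC — the optimal BP from yeast to
mammals — uniquely attains 6.0 among heptamers with fixed flanks.
This deterministic pairing score, together with the SF1 PWM score below,
stands in for trained-SVM branch-point strength predictors whose weights
are external; it captures the same base-pairing-extent axis those tools
model.

**Functional vs decoy candidates.** A candidate without an adenosine at
position 6 can pair with U2 but cannot form the 2′–5′ lariat bond. Such
decoys are enumerated and flagged but never selected as the best
functional BP; selection maximizes pairing score among functional
candidates, breaking ties by PWM score and then toward the 3′-most
candidate (when several BPs are available the most 3′ one is used).
The branch must lie within the 3′ scan window (default 150 nt) and at
least 3 nt from the intron end, excluding the AG itself.

**SF1 PWM score.** The per-intron feature `bp_best_pwm` is the maximal
log2-odds PWM score within the 3′ window against a uniform background,
matching the "maximal binding score" convention for SF1. The default
matrix is built from the YNYYRAY consensus with equal weight to the
allowed bases and pseudocount 0.01 — a declared stand-in, since the
published SF1 matrix values are not redistributable here; any 4-column
TSV matrix can be supplied instead. N in a scanned sequence scores as
background (0 log-odds) and never matches a motif symbol.

## Py-tract scoring

No standard closed-form Py-tract statistic exists, so the package
defines one explicitly: the maximum-sum contiguous segment (Kadane's
algorithm) under per-base weights T +1.0, C +0.5, A −1.5, G −2.0
(N −2.0). The T>C ordering encodes that C-rich tracts bind U2AF65 more
weakly than T-rich tracts; purine penalties make tract boundaries
sharp. The empty segment is allowed (all-purine regions score 0, length
0) and ties break toward the 3′ end. The region scored runs from the
chosen branch nucleotide +1 to position −3, excluding the terminal AG.
Weights are sums of multiples of 0.5, so segment scores are exact in
floating point and tie comparison is reliable.

## PSI/PIR and classification

PSI(CE) = 100·(inc1+inc2)/(inc1+inc2+2·exc); PIR = 100·mean(ei1,ei2)/
(mean(ei1,ei2)+ee). These junction-ratio definitions are stand-ins for
full read-rescaling quantifiers and agree with them in expectation
under uniform junction coverage. Replicates are averaged per condition
before Δ = treated − control. Classification uses closed boundaries:
|Δ| ≥ 25 regulated (sign → up/down), |Δ| ≤ 5 non-regulated, otherwise
intermediate; an event whose smaller per-condition informative read
total is below 10 is `low_coverage` regardless of Δ. All thresholds are
arguments.

## Statistics

* Mann–Whitney U, two-sided, midranks for ties. Exact enumeration when
  min(n₁,n₂) ≤ 8 and no ties (the enumeration bound stays tractable);
  otherwise the normal approximation with tie and continuity
  corrections. Complete enumeration of the exact null at n₁=n₂=8 shows
  the corrected approximation is within 0.011 of exact in the worst
  case. Stars: * p<0.01, ** p<0.001, *** p<0.0001; raw p-values are
  always reported and no multiplicity correction is applied by default.
* χ² on 2×2 tables by the closed form n(ad−bc)²/∏margins, df 1, no
  Yates correction.
* Welch t for replicate PSI comparisons.
* Expression–splicing correlation: Pearson R between |Δ| and
  log10(FPKM+1); FPKM is heavy-tailed, hence the log default (a raw
  option exists).
* Boxplot summaries are Tukey (linear-interpolated quartiles, whiskers
  at the most extreme points within 1.5·IQR); outliers are listed for
  display only and never removed from tests.
* RNA maps: sequences right-aligned at the 3′ss; per position, the
  fraction of sequences in which a degenerate-motif match covers that
  position, among sequences long enough to be defined there; smoothing
  is a centered moving average (default 15 nt) whose window shrinks at
  boundaries, keeping values in [0,1].
* Heatmap ordering: agglomerative clustering, Euclidean distance,
  complete linkage; rows with missing values are dropped and reported.

## Synthetic data

The generator emulates the features the analysis assumes, with ground
truth retained:

* intron length: log-normal with mean 3.2, sd 0.55 in log10 nt,
  truncated to [70, 100 000] (resampled) — a realistic heavy-tailed
  human-like length distribution;
* GC: Beta(14, 16) (mean 0.47);
* one BP heptamer drawn from a pool spanning pairing scores 2.5–6.0,
  planted with its start in [−40, −18];
* a Py-tract of drawn strength ∈ [0,1] anchored at −3 (length 8–30 nt,
  pyrimidine and T fractions increasing with strength);
* with probability 0.5, one or two extra YNYYRAY realizations planted
  in [−100, −47] (the multi-BP/drug-resistance elements);
* terminal AG forced; background sequence i.i.d. at the target GC.

The response follows the logistic model in the README with default
coefficients (0, 1, 1, 1, 1, 1) and Δmax = 60 percent points; sign +
for IR, − for CE. Per-replicate PSI adds N(0, 3) noise (the visual
spread of triplicate minigene quantifications), clipped to [0, 100];
junction counts are Binomial at negative-binomial coverage (mean 100,
size 10) per replicate, two replicates per condition. FPKM is drawn
log-normally, independent of the response, building the
expression-splicing null into the default conditions (a dependent mode
is available for power checks). Control levels: inclusion
100·Beta(8,2) for CE, retention 100·Beta(2,12) for IR.

What it does **not** emulate: read-level alignment artifacts, junction
mapping bias, shared-gene correlation between events, quality-score
tiers of real quantifiers, transcript-assembly effects, or chance
sequence homology structure beyond i.i.d. background. Passing tests
therefore demonstrate that the analysis recovers effects *of the kind
and size planted*, not that real data are this clean. One consequence
is visible in the multi-BP analysis: background sequence produces
chance YNYYRAY matches (≈0.7 expected per 100 nt at GC 0.47), so the
measured single/multi partition is a noisy version of the planted
indicator — as in real introns — and the protection effect is
correspondingly diluted but clearly detectable.

Determinism: one `numpy.random.Generator` (PCG64) stream per run,
seeded from the single mandatory seed; no iteration-order or hash
dependence, so equal parameters give byte-identical FASTA/BED/TSV
output across platforms.

## Response-model fitting

`fit_response` recovers the logistic coefficients by ridge-penalized
IRLS (penalty 1e-4, intercept unpenalized, convergence when the max
coefficient step < 1e-8, cap 100 iterations) on a design signed like
the generative model, so estimates are directly comparable to planted
values. Two response codings:

* **fractional** (default): y = |Δ|/Δmax, a quasi-binomial fit that
  targets the latent logistic mean directly. This is the identified
  estimator; it recovers coefficient magnitudes.
* **binary**: y = 1[|Δ| ≥ 25]. Thresholding a near-deterministic
  logistic mean makes the coefficient vector identifiable only up to a
  common positive scale — the fitted slope steepens as residual noise
  shrinks — so this coding recovers signs and ratios, not magnitudes.
  It is retained because thresholded regulated/non-regulated labels are
  what real analyses usually have.

The default is the fractional coding for exactly this identifiability
reason; the acceptance recovery quantities use it.

## Problem sizes and defaults used in checks

The packaged checks simulate 2,000 events for the group-comparison and
null analyses and 5,000 for coefficient recovery — large enough that
every planted direction separates at p ≪ 0.01 while a full test run
stays interactive on a single CPU. The demo pipeline config uses 300
events and two to three drugs for the same reason.

## Known limitations

* The BP strength scores are sequence-only proxies; they ignore RNA
  structure, co-transcriptional timing and experimentally mapped lariat
  positions.
* PSI/PIR junction ratios ignore read-length/mappability rescaling, so
  absolute values can differ from full quantifiers on real data even
  though Δ contrasts are robust.
* The Py-tract weights are a defined convention, not fitted to binding
  data; only comparisons between groups scored with the same weights
  are meaningful.
* `three_prime_region` flags truncation for introns shorter than the
  window; features of such introns are computed on the whole intron.
* Cross-drug simulations share planted features across compounds and
  differ only in effect size (and optionally coefficients); they do not
  model drug-specific sequence preferences beyond that.
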