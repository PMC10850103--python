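# Methods

This note documents the models implemented in `splicescope`, the
parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinate model of the spliced sequence space

A peptide product of a substrate of length *L* is described by up to four
1-based inclusive indices: the first splice-reactant [i, j] and, for
spliced products, the second reactant [k, n], with each reactant at least
`l_ext` residues long (default 1) and only two-fragment ligation allowed.
The coordinate classes partition all admissible tuples:

* forward cis: `k ≥ j + 2` (at least one intervening residue);
* forward-adjacent (`k = j + 1`): **excluded** — the concatenation equals
  a contiguous substring and would double-count a non-spliced peptide;
* reverse cis: `i ≥ n + 1` (disjoint reactants, first product reactant
  downstream; a gap of zero is allowed);
* homologous trans: overlapping reactant intervals
  (`max(i, k) ≤ min(j, n)`), which a single substrate molecule cannot
  supply, hence the product requires two copies of the protein.

This partition is the unique one under which the closed-form counts agree
with exhaustive enumeration; `brute_force_counts` re-derives every count
by looping over all tuples and classifying them with the rules above, and
the test-suite sweeps L ≤ 30, N ≤ 15, l_ext ∈ {1, 2} asserting exact
equality. The trans-count polynomial is evaluated in exact rational
arithmetic and asserted to reduce to an integer.

Peptide-to-substrate mapping follows a staged procedure: exact substring
search of the full sequence first (under the I ≡ L mass equivalence,
applied only to mapping — the counting formulas are sequence-agnostic);
only if no contiguous occurrence exists is the sequence split at every
internal position and all valid fragment-pair locations collected. The
resolved product type uses the precedence non-spliced > cis > trans, a
sequence explainable by both forward and reverse cis splicing is flagged
as a cis multi-mapper, and the number of origins (used later for
intensity splitting) is the number of reported locations.

## Spectra, the mock predictor and iRT calibration

The spectral contrast angle on L2-normalized non-negative intensity
vectors, `1 − 2·arccos(cos θ)/π`, is the primary match-quality metric
(1 = proportional, 0 = orthogonal). Peak matching assigns each predicted
fragment the nearest observed peak within tolerance (default 0.02 Th,
matching common high-resolution fragment tolerances; a ppm mode is
available). The nearest-peak tie-break is our choice; nothing in the
pipeline is sensitive to it at realistic peak densities.

The spectrum predictor is a *contract*: any object with a deterministic
`predict(peptide, charge)` returning annotated fragments with
max-normalized intensities and a predicted iRT plugs in. The shipped
implementation computes exact singly-charged b/y fragment m/z from
monoisotopic residue masses (cysteine carried carbamidomethylated) and
draws intensities from a generator seeded by a hash of the peptide
string: deterministic, peptide-specific, and uncorrelated between
distinct peptides. Its iRT is a fixed hydrophobicity-like sum of
per-residue coefficients plus a length term. The mock reproduces the
*statistical* role of a learned predictor (correct assignments match
their spectra, incorrect ones do not); it does not model fragmentation
chemistry, and absolute spectral-angle values are therefore not
comparable to instrument data.

iRT calibration fits observed retention time against predicted iRT by
least squares on non-spliced PSMs with spectral angle > 0.9 (falling back
to all non-spliced PSMs, with a log message, when fewer than 20 qualify).
Ten-fold cross-validation selects nothing; it only reports out-of-fold
residuals as a diagnostic of the fit.

## Semi-supervised rescoring and stratified FDR

Each candidate PSM carries four features: spectral angle, Spearman
correlation between predicted and matched observed intensities, absolute
iRT error (minutes), and the binary origin flag (spliced = 1). A PSM
whose peptide maps both ways is kept only as non-spliced. Peptides
outside the predictor's 7–30 residue window are excluded as unscoreable.
A failed match (< 2 matched fragments) receives Spearman 0 — a bad match
is informative, not missing; the missing-value sentinel (stratum-median
imputation) is reserved for genuinely undefined correlations.

The trainer (`PsmRescorer`) iterates five times: compute target-decoy
q-values of the current score (initially the spectral angle), take
targets at q ≤ 1% as positives (top-k fallback when none qualify), fit an
L2-regularized logistic discriminant of positives versus decoys on
z-scored features, and rescore. q-values use the estimator
`(#decoys ≥ s + 1) / (#targets ≥ s)`, monotonized; peptide-level reports
keep the best-scoring PSM per I/L-collapsed sequence before computing
q-values. PEPs come from an isotonic regression (non-increasing in
score) of the local decoy fraction, converted to a decoy/target density
ratio and clamped to [0, 1]; the group FDR of a stratum is the mean PEP
of its accepted members.

**Regularization strength.** The penalty is deliberately strong
(λ = 100). With near-separable features, a lightly regularized fit lets
the handful of false targets that inevitably sit above the training
threshold (≈ 1% of positives by construction) dictate the coefficient of
a near-redundant feature such as the origin flag; heavy shrinkage makes
the coefficients track the stratum composition of positives versus
decoys — the behaviour that justifies origin-aware FDR adjustment — while
leaving the ranking, acceptance counts and empirical FDR unchanged
(verified over λ ∈ {1, 10, 100}).

Two arbitration filters follow acceptance: every accepted spliced peptide
is scored against all substrate substrings within 6 ppm of its
monoisotopic mass using the frozen model weights and removed if a
competitor scores strictly higher (ties keep the original assignment —
conservative toward the accepted hypothesis); and any PSM whose spectrum
is explained with strictly higher spectral angle by a contaminant
candidate is dropped. Decoy sequences are substrings of the reversed
substrate, with collisions against true substrings redrawn.

## Kinetic quantification

Kinetics tables hold MS1 intensities per (peptide, time, biological
replicate, technical replicate) with the grid including 0 h. The
background value of a peptide is its maximum 0 h intensity across
replicates; the median of those values is a global cut-off; measurements
below `max(peptide background, global cut-off)` are removed and the
threshold is subtracted from the survivors. The filter consumes raw
tables only (the output is tagged; a second pass raises). Technical
replicates are averaged per (peptide, time, biological replicate);
peptides with no positive intensity at the reference time (default 4 h)
in *any* biological replicate are dropped — the per-replicate reading of
the rule retains maximal data and every drop is logged. Spliced
substrate-contaminants are removed by splice-site identity (the (j, k)
junction pair, so longer control-sample precursors also match);
non-spliced ones only when their 0 h intensity exceeds every later time
point. Multi-mapper peptides split their intensity equally across
origins; the split conserves the total exactly.

## Sequence-preference analytics

SCS-P1 and PSP-P1 sum the origin-adjusted reference-time intensities of
all products whose P1 (C-terminus of the peptide, or of the first
splice-reactant) falls on each substrate residue, then express every
value as a percentage of the sum in a centred 29-residue window,
truncated at the termini (no padding, so percentages remain
well-defined).

Background databases: spliced — four positions sampled uniformly with
replacement from 1..L and accepted iff they form a valid spliced peptide
within the 7–30 identification window (accepted tuples are provably
uniform over the valid set; the test-suite verifies this by χ² against
the exhaustive list), sized at 50× the identified spliced set, and every
sampled sequence re-mapped to account for multi-mapping; non-spliced —
sampling with replacement from the full enumeration. Quantities are drawn
uniformly within the observed intensity range of the same product type; a
coarse spliced/non-spliced grouping is available for datasets where a
rare type (typically trans) was never detected, which would otherwise be
an error.

Position-weight matrices accumulate log10-transformed origin-adjusted
intensities per amino acid over the twelve positions P6…P1 / P1'…P6'
around the cleavage or splice junction (both windows read off the
substrate and are truncated at its ends) and are column-normalized. Logo
heights per position are the base-2 Jensen–Shannon divergence between the
two matrices; each letter receives the signed share
`(P − Q)/Σ|P − Q|` of that height, zero where the columns coincide. The
symmetric 12-column window is also used for the non-spliced C-terminus;
the column set is configurable.

Coverage profiles sum log10 origin-adjusted intensities of all peptides
covering each residue, min/max-scale, smooth with a cubic smoothing
spline whose penalty is chosen by generalized cross-validation (the
smoothing parameterization is ours and is recorded in the profile
object), and min/max-scale again; a constant profile maps to all zeros.
Detected P1 residues are split at the median of their coverages: the
upper half are hotspot residues, ties at the threshold all count as
hotspot and odd counts give the extra residue to the hotspot side; all
coverages equal is refused rather than guessed. The lowest hotspot
coverage is the cut-off defining the hotspot/non-hotspot sequence
stretches. Conditional motifs apply Bayes' rule
`P(R|H) = P(H|R)·P(R)/P(H)` with P(H) = 0.5 by construction, all matrices
column-normalized; randomized backgrounds permute coverage values over
the substrate 100 times (seeded) and average. P1 density divides the
distinct P1 residues inside a stretch by the stretch length, per reaction
class. Generation efficacy divides identified product counts by the
closed-form theoretical space summed over the identification window.

## Synthetic data: what it emulates and what it does not

The generator draws substrates i.i.d. from a configurable composition;
digestion products with residue-specific P1 propensities for hydrolysis
and splicing (spliced products a minority by default — fraction 0.15,
with rare overlapping-reactant trans products — matching the qualitative
structure of proteasomal digests); short first splice-reactants (2–6
residues); abundances following saturating accumulation
`A_max(1 − e^{−rt})` over the 0/1/2/4/24 h grid in 2 × 2 replicates with
multiplicative lognormal noise (CV 0.3) and a small 0 h background;
observed spectra as mock predictions with lognormal intensity noise
(σ = 0.15) and m/z jitter (σ = 0.003 Th); retention times on the line
RT = 2·iRT + 5 with 0.4 min jitter; false matches injected at rate 0.05
by swapping the source peptide, and decoys built the same way — making
false targets and decoys statistically exchangeable, which is exactly the
assumption target-decoy FDR estimation rests on, and what lets the tests
measure calibration against ground truth. All randomness flows from one
seed through labelled child seeds, so every fixture is bit-reproducible.

The generator does not emulate fragmentation chemistry, chromatographic
peak shapes, charge-state distributions, co-isolation or shared spectra
between near-isobaric species. Passing tests therefore demonstrate the
correctness and statistical calibration of the *pipeline*, not
instrument-level identification performance.

**Problem sizes used in the deep tests** (the package's own choice of
study scale): FDR calibration runs 5,000 targets + 5,000 decoys over 10
seeds; the spliced-free benchmark embeds 300 peptides per seed over 10
seeds; sampler uniformity uses 50,000 tuples per seed on an 8-residue
substrate; sequence-preference recovery simulates 250 products per seed
at spliced fraction 0.4 with 20-fold P1 propensity concentration —
enough spliced peptides (~100 after filtering) for a stable P1 column in
the divergence logo, which is underpowered below a few dozen sites.

## Known limitations

* Three-fragment splicing and heterologous trans-splicing are
  representable in the types but neither enumerated nor mapped.
* The benchmark's spliced embedding only certifies forward-cis
  recoverability.
* Group FDR is reported only for strata with accepted members.
* The hotspot analysis refuses degenerate (all-equal) coverage rather
  than choosing an arbitrary split.
* Logo rendering uses plain matplotlib glyph stacking; it is meant for
  inspection, not publication typography.
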