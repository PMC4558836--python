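# Methods

## Peptide space

Digestion follows trypsin's rule: cleavage after K or R except when the
next residue is P. *Full* fidelity requires both peptide termini at
cleavage sites or protein termini; *semi* fidelity additionally yields
every sub-peptide with exactly one conforming terminus. Missed cleavages
(internal uncut sites) are bounded by `missed_max` ∈ [0, 4]; the default
length filter of 5–50 residues is applied last and disabled in unit-test
fixtures. Peptides containing non-standard residue codes (B, Z, X, U, ...)
are dropped with a logged count, or rejected in strict mode.

Monoisotopic residue masses are carried to 10⁻¹¹ Da.
Carbamidomethyl-Cys (+57.021464 Da) is the only fixed modification;
N-terminal pyroglutamate from Gln (−NH₃, 17.026549 Da) or Glu (−H₂O,
18.010565 Da) is the only variable one. Decoys are whole-protein reversals
(`DECOY_` ids) searched concatenated with targets; peptides shared between
proteins are merged with the union of protein ids, and an entry is a decoy
only if every source was. Other enzymes, N-terminal Met clipping, further
PTMs and protein inference are out of scope.

## Search and scoring

The precursor acceptance region on the raw mass-error axis
Δ = M − M<sub>peptide</sub> is the union over isotope offsets
k = 0..isotope_max of [k·s − MME−, k·s + MME+], merged where overlapping or
touching; s defaults to the ¹³C−¹²C spacing 1.0033548 Da (the window-algebra
checks that idealize s = 1.0 Da pass it explicitly). Zero-width tolerances
accept nothing. The sign convention makes a measured mass heavier than
theory a positive error, so +1/+2 isotope misassignment is positive.

Spectra are square-root transformed, summed into bins of 1.0005 Da and
scaled to unit Euclidean norm; templates contain the singly charged b- and
y-ions with unit weight per occupied bin, unit-normalized. The score is
their dot product in [0, 1]. The template deliberately contains no
ammonia/water-loss series: the pyroglutamate resonance depends on the
scorer *not* crediting b* or b° ions, so an NH₃-loss spectrum of an
unmodified Gln-initial peptide is better explained by the pyroglutamate
candidate at ~+17 Da precursor error. An N-terminal modification shifts all
b-ions and the precursor, never the y-ions.

Per spectrum, candidates are index entries whose mass error lies in the
acceptance region; the best score wins, with ties broken by smaller
isotope-centered residual, target over decoy (avoiding anti-conservative
FDR on ties), then lexicographic sequence and modification name, making the
search fully deterministic and order-independent.

## Confidence

q-values come from the concatenated target-decoy competition: at each
score threshold, FDR = #decoys / max(1, #targets) (no +1 pseudocount by
default; a flag adds it), monotonized into q by a running minimum over
decreasing score; records tied on score share the more pessimistic value.
q-values are computed jointly over all charges for small-sample stability;
the charge restriction applies only to the fitness, which is the number of
accepted (q ≤ 0.01) doubly charged target PSMs divided by all spectra
searched. Simulator provenance enables `truth_eval`, which counts a PSM
correct when its sequence equals the planted one (the pyroglutamate flag is
ignored by default, since the loss events leave the peptide itself
unmodified).

## Genetic algorithm

Parameters map to genes (continuous, integer, boolean, categorical) with
optional dependencies: equality links copy from the source gene; `a ≤ b`
constraints clip the dependent gene. Defaults — population 20, tournament
size 2, single-point crossover at probability 0.7 with per-gene uniform-α
blending of continuous genes, per-gene mutation at 0.1 (Gaussian σ = 10% of
range for continuous, ±1 step for integer, flip for boolean, uniform reset
for categorical), elitism 1, stagnation stop after 5 flat generations —
are standard GA practice and all exposed in `GAConfig`. Objective failures
score 0 rather than aborting. Identical (spec, objective, config, seed)
yields identical logs; evaluations share no mutable state, so they are
order-independent (the only concession to parallelism).

## Retention-time suite

Three predictors of increasing flexibility:

| kind | features | free parameters |
| --- | --- | --- |
| linear_composition | 20 residue counts + intercept | 21 |
| coefficient_extended | + position-weighted (3/2/1) counts of residues in positions 1–3, length, length² | 43 |
| ann | standardized counts + length → 4 hidden units (lbfgs, seeded) | 93 |

A fit is *infeasible* — a typed outcome, not an exception — when the number
of training peptides does not exceed the free-parameter count, or when the
design rank falls below the family's generic maximal rank. For the extended
model that generic rank is 41, not 43: residue counts sum to the length and
the position weights sum to a constant, two structural collinearities the
minimum-norm least-squares solution handles; the rank test therefore only
flags genuinely degenerate training sets (e.g. a single repeated
composition). The feasibility thresholds order the models exactly by
complexity: 21 < 43 < 93 training peptides.

Model selection minimizes RMSD under the hold-out scheme: the validation
pool is the deduplicated set of peptides with confidence 1 − q ≥ 0.99,
partitioned into 10 seeded disjoint folds so each peptide is validated
exactly once; each fold trains on all peptides at the (optimizable)
training cutoff minus the held-out fold. Ties favor fewer parameters.
Accepted PSMs are then filtered by |Z| ≤ 2 of the retention residual, with
Z scaled by the training residual sd (a MAD-free choice; under Gaussian
residuals ~4.6% of true PSMs are sacrificed, which the tests verify).

## Simulator

The generator's defaults are the study conditions, chosen once: 50
proteins of mean length 300 (≈3,900 distinct target peptides after
digestion), 1,000 spectra, charge probabilities 0.10/0.65/0.25 over 1+/2+/3+,
Gaussian precursor error (bias 0, sd 0.05 Da), isotope misassignment
probabilities 0.15/0.05 for +1/+2, co-isolation probability 0.10 with the
recorded precursor uniform within ±2.5 m/z of the fragmenting peptide,
ammonia/water-loss probability 0.30 for Gln/Glu-initial peptides, and 20%
unmatchable pure-noise spectra. Fragments are the b/y ions, each detected
with probability 0.7, jittered by 0.1 Da, with log-normal intensities and
~Poisson(15) noise peaks; imperfect fragment evidence is what lets decoy
competition bite, so the fitness surface has an interior optimum rather
than growing monotonically with window width. Retention times follow a
planted 21-parameter linear composition model plus Gaussian(0, 0.5 min)
noise over a nominal 60-min gradient. Residue frequencies put K+R at 10%
so tryptic peptides average a realistic 8–20 residues.

What the simulator does **not** emulate: chimeric spectra with blended
intensities from two peptides (co-isolation is modeled as a precursor swap,
the simplest mechanism consistent with a mixed spectrum being identified
from the dominant fragments), chromatographic peak shapes, charge-reduced
species, real fragmentation propensities, and instrument-specific noise.
Passing tests therefore demonstrate the *mechanisms* — window algebra, FDR
calibration, the loss-event ridge, co-isolation gains, feasibility
ordering — not instrument-level effect sizes; optimal windows found on real
data will differ numerically.

## Problem sizes and numerical choices

The default acceptance-scale experiments use the 1,000-spectrum simulation
(GA population 12, 15 generations; one search of 1,000 spectra takes well
under a second), and exhaustive 26×26 grid cross-checks use a reduced
200-spectrum dataset — sizes chosen so the whole suite runs comfortably on
a laptop while keeping binomial noise small relative to the asserted
margins. Bisection resolves the window merge point to 10⁻¹² Da. Mass
comparisons in tests allow 10⁻⁶ Da (10⁻¹² for the analytic pyroglutamate
deltas, which are exact up to float round-off). All randomness flows from
one seed through named sub-streams (simulate / ga / folds).

## Known limitations

* The scorer is a plain normalized dot product; no hyperscore, fragment
  tolerance weighting or intensity modeling, so absolute score scales are
  not comparable to production search engines.
* Target-decoy q-values replace a mixture-model posterior; with few PSMs
  the q-value staircase is coarse.
* The ANN retention model is a fixed small architecture meant to occupy the
  "needs much more data" niche, not a competitive predictor.
* Decoy reversal preserves composition but not suffix statistics; shared
  target/decoy peptides are resolved in favor of the target.
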