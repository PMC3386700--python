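# Methods

## The assay model

A 96-well plate holds one detector-vesicle composition. Wells are of four
kinds: clinical serum samples in triplicate, five standardization sera
(identical aliquots present on every plate, also in triplicate), negative
color controls (unexposed blue-phase vesicles, background fluorescence
`Em_c`) and positive color controls (heat-converted red-phase vesicles,
maximal fluorescence `Em_r`). The chromatic response of a well with emission
`Em_i` is `%FCR = 100·(Em_i − Em_c)/(Em_r − Em_c)`, with `Em_c`/`Em_r`
estimated as the means of the plate's negative/positive control wells and
the per-serum value taken as the mean over its replicate wells. %FCR is
**not clipped** to [0, 100]: under noise the ratio legitimately exceeds
either bound, and clipping would bias every downstream statistic. A plate
whose mean positive control does not exceed its mean negative control is
rejected as degenerate.

Because %FCR is a ratio of differences of same-plate readings, it is an
exact algebraic invariant of any affine map `x → g·x + b` applied to all
wells of a plate. This is the property the pipeline's tests lean on: plate
distortions that are affine are removed *exactly*, and the test suite
asserts agreement to 1e-9 between distorted and undistorted synthetic
cohorts after the full chain.

## Cross-plate standardization

The assay design leaves the standardization algorithm open; this package
aligns plates by per-plate affine least squares. For each vesicle measured
on ≥2 plates, the cross-plate mean %FCR of each standardization serum
defines a five-point reference profile; each plate's %FCRs are mapped by
`x → a + b·x` with `(a, b)` the least-squares fit of that plate's five
standard responses onto the references. This is the minimal model that
removes exactly the gain/offset artifacts the %FCR ratio cannot see (e.g.
a mis-estimated control basis), and it is exactly invertible: a plate that
is an affine image of another is mapped onto it, which the tests assert.

Degenerate fallback: a plate whose standards have (near-)zero variance gets
an offset-only correction (`b = 1`) with a logged warning. Vesicles with a
single plate pass through unchanged.

Applying the operator twice equals applying it once (to float precision)
whenever plates are affine images of shared latent standard responses —
the regime the operator models, and the regime the idempotence test uses.
With replicate noise the five-point regression is itself a noisy estimator,
so a second application shifts values slightly; this is a property of any
finite-standard alignment scheme, not of the implementation.

Standardization runs **after** triplicate averaging (the order is not
dictated by the assay; averaging first is deterministic and cheaper, and
for affine maps the two orders commute).

## Per-plate normalization

"Plate controls" here means the **healthy-control clinical group's samples
on that plate**, not the five standardization sera (which are named
separately and serve the previous step). Per plate and vesicle, each
sample's (standardized) %FCR is z-scored against the mean and sample SD
(n−1 throughout the package) of that plate's control-group samples; controls
therefore have mean 0 and SD 1 per plate by construction. Plates need ≥2
control-group samples and nonzero control SD, else normalization aborts
with the plate named. Samples missing any vesicle measurement are dropped
from the feature matrix with a logged warning rather than imputed — any
imputation would inject assumptions the assay model does not state.

## Classification protocol

Binary comparisons only (control vs stomach, control vs pancreas, pancreas
vs stomach). Per repeat: a seeded random balanced partition (default 25
train + 25 test per group); exhaustive enumeration of all 2^k − 1 feature
subsets in canonical order (cardinality ascending, then lexicographic;
refused above 20 features); a linear-kernel SVM per subset, `C = 1`
(the LIBSVM default — no other hyperparameter is defensible when none is
specified) with features entering exactly as normalization produced them;
winner = best **resubstitution** (training-set) accuracy. Scoring selection
on the training set overfits the selection step by design — fidelity to the
protocol being modeled — which is precisely why the held-out test set and
the shuffle null exist. Ties break by training MCC, then fewer features,
then canonical order, making the whole experiment a pure function of
(features, seeds, C).

The per-repeat test metrics are Accuracy, Sensitivity, Specificity (as
percentages; the positive class is the cancer group against controls, and
stomach against pancreas) and MCC, with MCC = 0 by convention when a
confusion marginal is empty. `sizing="benchmark-26-25"` reproduces the
benchmark table's implied test composition (26 positives / 25 negatives
against controls; 26/26 for the two-cancer comparison) whose
sensitivity/specificity denominators differ from the stated 25/25 split;
both sizings are exposed and neither is silently preferred.

## Significance

*Exact binomial.* The chance model sets `p0` to the test set's
majority-class proportion — the success rate of the best label-blind
guesser (for a 26/25 test set, `p0 = 26/51`; this choice, and not 0.5,
reproduces the benchmark tail of 7×10⁻⁷ for 43/51 correct). The upper tail
P(X ≥ k) is inclusive and computed exactly (rational arithmetic for n ≤ 64,
log-space summation above; never a normal approximation). Two other
printed chance statements in the benchmark study (3×10⁻⁴ for 71% and 0.02
for 62.8%) are not reproduced by any chance model we tested and are treated
as unverified.

*Shuffle null.* Group labels of the whole cohort are permuted uniformly
(count-preserving; an identity draw is kept, not special-cased), and the
complete experiment — partitioning, exhaustive selection, test evaluation —
is re-run per shuffle. Mean best-model test MCC near 0 (the suite asserts
|mean| < 0.15 over 20 shuffles) confirms that performance on real labels is
label-driven, not pipeline leakage.

## Synthetic cohort generator

The generator is the package's stand-in for clinical sera and defines the
study conditions of every statistical test. Per serum and vesicle a latent
true response `f(s,v) ~ Normal(group_effect[g,v], serum_sd)`, truncated
(clipped) to [0, 100]; per well,
`emission = gain·(Em_c + f/100·(Em_r − Em_c) + ε) + offset` with
`ε ~ Normal(0, replicate_sd·(Em_r − Em_c)/100)`, per-plate
`gain ~ Normal(1, 0.05)`, `offset ~ Normal(0, 2)`, `Em_c ~ Normal(30, 2)`,
`Em_r ~ Normal(150, 5)` (arbitrary fluorescence units; the scale keeps all
emissions safely positive). Color-control wells receive the distorted
`Em_c`/`Em_r` plus the same replicate noise (real control wells are read by
the same detector). Standardization sera draw one latent per vesicle, held
fixed across plates.

Defaults, chosen once: `serum_sd = 10`, `replicate_sd = 4` (%FCR units;
yields ≈5–7% average RSD in a triplicate-mean 10-repeat assay, inside the
≤8% repeatability regime of such assays), group means control = 50 on all
vesicles, stomach = 45 on all vesicles (uniformly depressed reactivity),
pancreas = 62 on v3 and v5 and 42 elsewhere (a mixed response, elevated
only on the two compositions where pancreatic sera react more strongly).
These effect sizes put pancreas-vs-control test accuracy in the 80–95%
band — the same regime as the benchmark table, without claiming to
reproduce its clinical numbers, which would require the original sera.

150 sera in triplicate cannot share one 96-well plate, so each vesicle uses
six plates (3+3 color controls, 5 standards ×3, 25 samples ×3 = 96 wells).
Sera are assigned by a seeded within-group shuffle followed by interleaved
chunking, so every plate carries a near-balanced mix of the three groups;
fully uniform assignment could strand a plate without the ≥2 control-group
samples normalization requires. Confounded layouts (a group concentrated on
one plate) are deliberately not simulated.

What the generator does **not** emulate: reaction kinetics (the 60-min
equilibration), pH dependence, well-position (edge) effects, heavy-tailed
or skewed serum reactivity, correlated responses across vesicles, and any
real biochemistry of serum–vesicle interaction. Passing tests therefore
demonstrate the *statistical machinery* — plate-artifact removal,
selection, evaluation, significance — under a Gaussian additive model, not
clinical performance on real sera.

## Numerical conventions and problem sizes

- Sample SD (ddof = 1) everywhere; RSD = 100·SD/mean per serum, averaged
  over sera.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; experiments and the pipeline are pure functions of their seeds,
  and `run_all` re-runs are byte-identical.
- CSV emissions are serialized via Python's shortest-round-trip float
  representation, so write→read is bit-exact.
- The test suite and the acceptance script run the default cohort sizes
  (150 sera × 10 vesicles, five repeats, 20 shuffles); a full 5-repeat
  exhaustive experiment is ~5 s on one CPU and the complete acceptance run
  under a minute.

## Known limitations

- The exhaustive search is exponential; panels beyond 20 features are
  refused rather than silently falling back to a heuristic.
- Selection by resubstitution accuracy is the modeled protocol, not best
  practice; an internal cross-validated selector is a natural extension but
  is not what this package sets out to reproduce.
- The consensus-feature set is reported but deliberately not re-evaluated
  as a classifier: repeats share samples, so cross-repeat feature stability
  already "contaminates" any test set one might reuse.
- Multiclass classification, probability calibration and multiple-testing
  correction across repeats are out of scope.
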