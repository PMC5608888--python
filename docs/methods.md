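# Methods notes

This note records the models, conventions, and design decisions behind the
package, in the order data flows through the pipeline. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signals and the synthetic cohort

**What the generator emulates.** Each simulated subject is a 48-channel,
10 Hz, 1080 s recording (36 trials × 30 s) of slow hemodynamic fluctuations
plus a behavioral log of the guessing game. Channels are coupled through a
ground-truth graph `A`: `x = (I + c·A) z`, with `z` independent Gaussian noise
band-limited to 0.008–0.09 Hz and `c = 0.5` (the *coupling*), then each
channel standardized. Under this mixture, the population correlation of an
adjacent pair is `(2c + c²·m)/(1 + c²k)` (m = common neighbors, k = degree),
so adjacent channels correlate systematically above non-adjacent ones and
two-hop pairs inherit intermediate correlations — exactly the graded structure
a correlation-threshold estimator has to cope with. The default ground truth
is a Watts–Strogatz graph (48 nodes, mean degree 8, rewiring p = 0.1), chosen
because the analysis presumes small-world organization (σ > 1.1 over the
sparsity range).

**Stationarity.** A zero-phase Butterworth at a normalized low cutoff of
0.0016 (0.008 Hz at 10 Hz) has a startup transient that decays over hundreds
of samples and has a similar shape in every channel; filtering white noise
directly therefore produces spuriously correlated early samples. The generator
synthesizes `n + 2·burn` samples (burn = two slow periods = 250 s) and keeps
only the interior, so generated series are stationary from the first sample.
This matters: the honest state is always the *beginning* of a session.

**Behavior model.** Lies are only possible on incorrectly guessed trials
(p_incorrect = 0.5 per trial, a fair guess). The per-opportunity lie hazard is
logistic in age: base 0.076 at the reference age 9.5 with slope −0.85
log-odds/year. These two numbers were solved jointly in closed form (truncated
geometric first-lie distributions integrated over ages uniform on 7–12) so
that the expected liar fraction is 40/59 ≈ 0.678 and the expected mean
first-lie trial among liars is 11.45; the simulation-based check in the test
suite reproduces both. A limitation worth knowing: with any hazard that is
monotone in age and constant over trials, children with later first lies
necessarily lie less overall, so the model cannot make *both* the first-lie
trial and the lie frequency increase with age; the negative slope reproduces
the FLT–age direction (younger children lie earlier) at the cost of the
frequency–age direction.

**State change.** At a liar's first-lie trial onset the generating network
switches to a copy with `⌈0.3·E⌉` edges rewired to random vacant pairs (edge
count preserved). Note the direction this implies for the *estimated*
networks: random rewiring moves the graph toward an Erdős–Rényi topology, so
the dishonest-state estimates lose clustering — γ, σ and E_loc decrease —
while E_glob, if anything, *increases* toward the random-graph ceiling at
fixed density. "Disruption" here means disruption of the small-world
architecture, not a uniform drop of every efficiency measure; the recovery
tests assert detectability of the state change, and the directional test
asserts the directions the mechanism actually implies. The magnitude 0.3 is a
calibration knob of the generator, not an empirical claim.

**Trial-to-sample mapping.** Trials span a fixed 300 samples (30 s) with
onsets on that grid. No inter-trial timing is known for the real task; this
placeholder merely makes the first-lie split well defined. No hemodynamic
response convolution, motion artifacts, or systemic physiology are modeled —
passing tests say the *pipeline* behaves correctly, not that real fNIRS noise
is benign.

## Preprocessing

Filtering is a 4th-order Butterworth applied forward–backward (zero phase;
effective order 8), the standard choice for slow hemodynamic bands, run on the
full series *before* any split so that both segments are exact slices of one
filtered series. Series shorter than the filter's warm-up padding raise an
explicit error.

Liars are split at the first-lie trial onset, lie-free subjects at
`round(fraction · n_samples)` with fraction 11.5/36 (round-half-even,
documented and tested). Segments shorter than 60 s abort with a clear error
and the pipeline logs the subject as excluded — a liar whose first lie falls
on trial 1 or 2 has no usable honest state, and how the original design
handled such children is unknown; exclusion-with-reason is this package's
explicit policy.

**Equal-duration windows.** Correlation-estimation noise shrinks with window
length, and fixed-density thresholding converts a noise-level difference into
a systematic metric difference (noisier rankings admit more random pairs, so
the graph drifts toward Erdős–Rényi: lower Cp, higher E_glob). Since the
honest state is usually much shorter than the dishonest state (and the
non-liar split is fixed at 11.5/36 vs 24.5/36), comparing the raw segments
confounds state with estimation noise; in pilot simulations with no state
change built in, that confound alone produced 50–100% false-positive state
effects. The pipeline therefore estimates both matrices from equal-duration
windows adjacent to the split point (the long segment is truncated on the side
facing the split). This is a deliberate methodological correction, exposed as
`match_segment_lengths` (default on) for anyone who wants the uncorrected
comparison.

## Connectivity and thresholding

Plain Pearson correlation per unordered channel pair; no Fisher-z transform
before thresholding (thresholds operate on |r| directly, and the rank order is
z-invariant anyway). A zero-variance channel is an error naming the channel.

Binarization keeps exactly `round(S · N(N−1)/2)` pairs at sparsity S, ranked
by |r| (a `positive` ranking is available); exact ties at the cutoff are
broken by lexicographic pair order so results are bit-reproducible. Ranking by
magnitude is the dominant convention for channel-space hemodynamic
connectivity; the band-limited signals here produce predominantly positive
correlations, so the two rankings rarely differ in practice.

## Graph metrics

Definitions follow the standard unweighted conventions:

* **Cp** — Watts–Strogatz node-wise mean clustering; degree < 2 contributes 0.
* **Lp** — mean shortest-path length over *connected* ordered pairs.
  Excluding disconnected pairs keeps Lp finite at sparse thresholds;
  efficiency handles disconnection natively instead.
* **E_glob** — mean inverse shortest-path length over all ordered pairs,
  0 for disconnected pairs (Latora–Marchiori).
* **E_loc** — mean over nodes of E_glob on the neighbor-induced subgraph
  (node excluded); nodes with < 2 neighbors contribute 0.
* **γ, λ, σ** — Cp and Lp divided by their means over a degree-preserving
  random ensemble; σ = γ/λ.

The null model is Maslov–Sneppen double-edge swapping: 100 reference graphs,
10 attempted swaps per edge, rejected swaps (self-loop/multi-edge) skipped so
the degree sequence is preserved exactly; a swap-resistant graph (e.g. a star)
simply receives fewer effective swaps. Ensembles are seeded per sparsity level
from the study's master seed, so every curve is reproducible.

Implementation note: these kernels are hand-written in numba. On ≤ 60 nodes
each adjacency row packs into one 64-bit word, BFS becomes a handful of
OR/popcount operations, and the swap loop uses an inline xorshift64* generator
— one null-graph evaluation costs tens of microseconds, which is what makes
~10⁶ null evaluations per study practical. A dense any-size fallback
implements the same definitions, and the test suite pins both paths to
networkx and to brute-force Floyd–Warshall/triangle-enumeration oracles on all
996 connected graphs of ≤ 7 nodes (agreement to 1e-12).

The AUC uses the rectangular rule, `ΔS · Σ values` (the threshold-AUC
convention of the common connectome toolboxes); a trapezoidal alternative is
behind a flag. The default grid 0.25…0.48, step 0.01, has 24 levels.

**Data-driven range selection** reproduces the two published criteria: the
lower bound is the smallest grid level whose implied mean degree `S(N−1)`
exceeds `2 ln N` (natural log — for N = 48 that gives S = 0.17; a base-10
reading would make the criterion vacuous), and the upper bound is the largest
level at which the group-mean σ stays above 1.1. The group-mean convention
(one shared range per cohort) follows from the single range the design
reports; the grid is evaluated on group-mean curves.

## Statistics

With a two-level within factor, the RM-ANOVA is algebraically the pair of
regressions on centered age: difference scores give the State (intercept) and
State × Age (slope) tests, subject means give the between-subjects Age test,
all on (1, n−2) df. Effect sizes are partial η² = F/(F + df₂), labeled as
such. Degenerate inputs are handled explicitly: identical segments give
F = 0, p = 1; a constant nonzero difference (zero residual variance) is an
error rather than an infinite F.

The group comparison is a Group (±½ effect coding) × centered-age OLS with
interaction; each coefficient's t² is the marginal F on (1, n−4) df.

Cohen's d for the paired contrast is mean/SD of the differences — the
standard formula, reported as such.

Partial correlation removes the covariates from both variables by OLS and
correlates the residuals (p from the t-transform on n−2−k df). A variable
that is an exact linear function of the covariates has a null residual; its
partial correlation is defined as 0.

The hierarchical regression forces block 1 (age), then enters block-2
candidates stepwise by smallest p while p ≤ 0.05, removing any entered
variable whose p rises to ≥ 0.10 (the common package defaults, configurable).
Each step reports ΔR² and the F-change test; the final table reports
standardized β and part (semipartial) correlations, `sr = t·√((1−R²)/df)`
signed by t. Five ANOVAs per family are run without multiplicity correction,
mirroring the analysis design.

## Pipeline and reproducibility

`StudyConfig` holds every knob with the reference defaults (band
0.008–0.09 Hz; grid 0.25/0.48/0.01; non-liar fraction 11.5/36; n_random 100;
swaps/edge 10; 60 s minimum segment). One master seed drives cohort synthesis
(per-subject substreams via `SeedSequence.spawn`) and the per-subject,
per-segment, per-level null ensembles, so a rerun with the same config is
byte-identical. The manifest records the seed, a config hash, subject counts,
exclusions with reasons, and dependency versions. Analyses whose group has
fewer than 3 usable subjects (6 for the regression family) are skipped and
marked in the report; the run aborts only if both groups are unusable.

## Problem sizes used in validation

The recovery study in the test suite runs 20 replicate cohorts of 59 subjects
(40 liars/19 lie-free) per condition with the null-ensemble size reduced to
20 — ample for AUC stability in a paired contrast — and checks that the
built-in disruption is detected on the efficiency AUCs in ≥ 90% of cohorts,
that lie-free subjects show no period effect, and that cohorts generated
*without* disruption trigger state effects at no more than the nominal rate.
Behavior calibration is checked over 200 cohorts of 59. Type-I error of the
State test is measured on 1000 simulated null AUC tables.

## Known limitations

* The generator's linear mixture has no hemodynamic response function, no
  physiological nuisance structure, and a single network for all subjects in
  a cohort; effect sizes on synthetic cohorts say nothing about real-data
  effect sizes.
* The behavior model cannot reproduce both published age-correlation signs
  (see above); it is calibrated to the two cohort-level targets.
* Band-limited 1080 s segments contain only ~50–150 effective samples per
  correlation estimate, so single-subject binary graphs are noisy; all
  conclusions should rest on the paired, cohort-level contrasts the pipeline
  reports.
* Negative correlations are folded into |r| ranking by default; channel-space
  anticorrelation structure is not modeled separately.
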