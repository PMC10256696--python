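# Methods

## Task geometry

The apparatus is modelled as a 4-node, 5-edge undirected graph: two
reward suppliers `SL`/`SR` (degree 2), a base junction `A` where the
two return tracks meet the central stem, and a top junction `B` where
the stem meets the two choice arms.  This topology is the unique one
consistent with every structural count the task exhibits: 12
supplier-to-supplier elementary paths (6 per supplier) once immediate
edge reversals ("turn-backs") and mid-walk supplier visits are
excluded, a whole-path coding with 2 states × 6 actions, and a
turn-by-turn coding with 10 states × 2 actions.  Turn-backs are
structurally impossible in this representation, mirroring their
exclusion from the elementary-path vocabulary (they are vanishingly
rare on narrow elevated tracks).

Each elementary path is labelled `origin:shape` with shapes `good`
(return → stem → opposite arm; the rewarded alternation), `loop_low`
and `loop_top` (stem loops entered at A or B), `cross_low`, `cross_top`
(crossings below or above the stem) and `reverse` (the opposite good
path run backwards).

## Episodes and reward

An episode is the minimal path run that leaves a supplier, visits the
other supplier at least once, and returns to its origin; segmentation
is greedy left-to-right, so it is unique.  The reward is the number of
good paths in the episode (0, 1 or 2).  Paths left over at the end of a
session form a *trailing fragment*: their action choices enter the
likelihood (they were observed decisions) but no reward is ever
evaluated for them, so they trigger no credit update.  Episode duration
is the sum of the member paths' edge durations — locomotion only, no
dwell time at the suppliers — so the activities of an episode's actions
sum to exactly 1 and the total credit injected per episode is exactly
α·R.  (Per-path dwell could be added as an extra column and folded into
durations upstream; the dynamics only consume ratios.)

## Strategy codings

A model state carries (position, incoming edge, last visited supplier).
The last-supplier component is required because, on the stem, a loop
and a good path are indistinguishable without it; the incoming edge
encodes the no-turn-back constraint and makes the available-action sets
at the junctions well defined.  With it, the turn-by-turn model has
exactly 10 states (2 supplier states, A-from-return ×2, A-from-stem ×2,
B-from-arm ×2, B-from-stem ×2) and every hybrid has 6.  Credits are
never pooled between left/right mirror states: each (S, A) pair owns
its credit.

Cut rules per elementary path: `Paths` none; `Turns` at every junction
passed; `Hybrid1` at the second junction encountered (single-junction
paths stay whole); `Hybrid2` at the first junction encountered;
`Hybrid3`/`Hybrid4` at the physical junction A/B whenever the path
passes it, else the path stays whole.  In `Hybrid1` both segments are
softmax-chosen from their own credits (the first from the supplier
state, the second at the second-junction state): a likelihood must be
assigned to every observed decision, so "choose the last part by the
credit rule" is read as both chunks being credit-chosen.  Within a
state, actions are ordered lexicographically by edge chunk, fixing the
softmax support and all serialised output.

Every path decomposes into exactly one action sequence under every
model (verified by construction and by round-trip tests), so all six
models cover the same trajectory space and their likelihoods are
comparable on the same record.

## Credit dynamics and likelihood

Choice probabilities are softmax in the credits, computed with
max-subtraction (credits grow without bound over long runs; the shift
is exact).  Within an episode, probabilities are frozen at the table as
it stood when the episode began; the activity-weighted update applies
once at episode completion.  Session decay (×γ) applies at the start of
every session except the first — equivalently at the end of every
session except the last, where it could never affect a probability.

The log-likelihood of a record under a model runs these dynamics from
zero credits over the *entire* record and sums log-probabilities over
a selected window.  Hold-out windows are defined by the ordinal of the
containing elementary path (default cut: 800 paths); an episode
straddling the cut updates credits at its completion regardless, so the
dynamics are identical to an unsplit run and early + late likelihoods
sum exactly to the full-record likelihood.  By default credits keep
evolving through the test phase (the trained model keeps learning, as
the animal does); a `freeze_after_cut` flag stops updates and decay at
the cut for sensitivity analysis.  All computation is in log space; the
inner loop is compiled with numba and is checked to 1e-10 against a
hand-unrolled reference recursion in the tests.

## Fitting and selection

(α, γ) ∈ [0,1]² is estimated by maximising the early-phase
log-likelihood with bounded differential evolution (initial population
of `restarts` uniform points, default 20 and at least 20; tolerance
1e-8; L-BFGS-B polish), deterministic given the optimizer seed.  The
surface is smooth and two-dimensional, so this converges in a few
hundred evaluations; `restarts` can be raised towards 200 for a
heavier multi-start schedule with no other change.  Selection takes the
trained model with the maximal late-phase log-likelihood; an exact tie
falls to the model with fewer states (parsimony) and is flagged.
Pairwise test-LL differences and the exponential of the winner's
smallest margin (a likelihood ratio against the runner-up) are
reported.

## Synthetic behaviour generator

The simulator rolls a CoACA agent forward through a chosen model's
decision diagram: sample an action by softmax, traverse its edge chunk,
close elementary paths and episodes exactly as the segmentation module
defines them, update and decay credits identically to the likelihood
engine.  Edge traversal durations are drawn as 1 s × lognormal(σ=0.2);
only activity ratios enter the dynamics, so the duration scale is
immaterial (asserted by a rescaling-invariance test).  Sessions resume
at the supplier where the previous session ended (first session: `SR`).
The learning criterion — at least 80% good paths within one session,
inclusive comparison — gates the validation experiments; simulations
that never reach it are discarded and redrawn from child seed streams,
up to an attempt cap.

Default generating condition: **α = 0.15, γ = 0.8, 20 sessions × 75
paths**.  These values were chosen so that a Hybrid-3 agent reproduces
the qualitative features of real animals: it reaches the 80% criterion
in most runs, plateaus around 90–100% late-session success, shows
start-of-session dips attributable to forgetting, and — crucially for
hold-out selection — keeps making errors in the late phase, so the
test set retains information (late-phase log-likelihoods of magnitude
~10²–10³).  At substantially smaller α the agent never reaches the
criterion; at larger α (or γ → 1) behaviour saturates and every model
predicts the late phase almost perfectly, the regime in which no
selection method can discriminate.  What the generator does *not*
emulate: dwell times at suppliers, vicarious trial-and-error
micro-behaviour, unclassifiable track excursions, and day-to-day
variation in session length.  Passing validation therefore shows the
procedure recovers strategies from data generated by these dynamics,
not that real animals obey them.

## Validation experiments

*Model recovery*: simulate learning-criterion-filtered logs per
generating model, run the full six-model hold-out on each, and tabulate
the selected-model proportions (confusion matrix; rows over scored
replicates).  At the default condition the Hybrid-3 row concentrates
85–100% on the diagonal across seeds.

*Parameter recovery*: the MLE as a function of the number of training
paths.  α stabilises within a few hundred paths; γ converges much more
slowly since each session boundary contributes only one decay event,
and its per-log statistical error at the default condition is ~0.03–0.05
(profile-likelihood curvature), an intrinsic limit — once behaviour
saturates, further sessions add no information about γ.  Estimates from
windows spanning fewer than two sessions are flagged as unstable.

## Neural coding battery

The chi-square test compares a neuron's spike counts in one region
under two conditions against the occupancy-proportional multinomial
null, one degree of freedom, no continuity correction.  Exclusions:
zero occupancy under either condition, or minimum expected count
`n·min(p1, p2) < 5` — read as the standard minimum-expected-cell
validity rule (the low-firing-rate screen); the rule's exact cell
reference is an interpretation and is isolated in one function.
Benjamini–Hochberg runs over all candidate neurons of one
region/condition pair; coding means adjusted p < 0.05.  McNemar is
exact (two-sided binomial on the discordant counts) because coding
counts are small in practice; the asymptotic version with continuity
correction sits behind a flag.  Degenerate McNemar tables (no
discordant pairs) return p = 1 with a flag.  The synthetic generator
draws lognormal occupancies and Poisson counts, with a configurable
coding subpopulation whose condition-2 rate is scaled; at ratio 1 the
pipeline is calibrated (uniform eligible p-values, BH false-call rate
within Monte-Carlo error of 0.05), and these checks are part of the
test suite.

## Numerical and interface choices

Sessions, episodes, paths and actions are 1-based in all reports.
Behaviour logs serialise to CSV with durations at 6 decimals, making
writer output bit-stable; readers validate chainability and
classifiability with row-precise errors.  All randomness in a run
derives from one top-level seed split into named sub-streams
(simulation, optimizer, neural).  Problem sizes in the bundled
experiments (20 replicates, 20 sessions × 75 paths, 10-seed recovery
curves) are the package defaults for desk-scale validation; all are
configurable upwards.
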