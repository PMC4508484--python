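# Methods

`gazecoord` analyses dual eye-tracking recordings of collaborating dyads in
referential tasks: one participant (the *instructor*) verbally refers to an
object, the other (the *worker*) acts on it.  Each such *reference-action
sequence* is divided into five contiguous phases — pre-reference, reference,
post-reference, action, post-action — and the package asks how the two
participants' gaze streams coordinate across those phases.  This note
documents the models and the choices behind them.

## Data model and coding

The atomic record is a fixation: a half-open interval `[t_start, t_end)` in
integer milliseconds on a shared clock, labelled with a raw area of interest
(AOI): an ingredient identifier, the target bread, the partner, or
`unmapped` when gaze hit no AOI (about 20% of fixations in data of this
kind).  Within each sequence, raw AOIs are re-coded relative to that
sequence's referent into four categories per role — `Reference`, `Other`
(any other ingredient), `Target` (the bread), `Person` — so the same
physical ingredient is `Reference` in the sequence that refers to it and
`Other` elsewhere.  Unmapped gaze carries no code rather than an explicit
"elsewhere" category, which keeps the networks on the eight standard nodes
(`I.Gaze_*`, `W.Gaze_*`).

The coded timeline is discretised into 50-ms segments.  The grid is
anchored at each sequence's start (so phases tile cleanly), each segment
belongs to the phase containing its midpoint, and each segment carries the
code of the fixation covering its midpoint, per participant.  The midpoint
rule is deliberate: it guarantees at most one code per participant per
segment and resolves, unambiguously, what happens when a fixation is
shorter than a segment or straddles two.  Inter-sequence gaps are not
coded.  Domain objects are table schemas (validated pandas frames) rather
than per-record classes; the validators enforce non-overlap within a
participant, contiguous ordered phases, and non-overlapping sequences.

## The network model

For every *unit of analysis* (dyad-interaction × phase; additionally × the
repair flag for the breakdown contrast) the co-occurrences of codes within
segments are counted into a cumulative adjacency vector `U` over the 16
cross-person code pairs — edges connect only an instructor code with a
worker code, since one person cannot gaze at two targets at once.  Each `U`
is normalised to the unit hypersphere, `nU = U/‖U‖₂`, so units are compared
by the relative composition of their networks rather than by how much data
they contain.  The `nU` are centred on their grand mean and decomposed by
SVD; the top two components (orientation fixed by making each loading's
largest-magnitude entry positive) give each unit a point `Pᵢ` in the plane.

Mean-centring before the SVD is a choice the original method description
leaves open; we centre so that the origin is the data mean and the axes are
principal directions of variation.  Axis orientation may therefore mirror
other implementations.

Nodes (codes) are placed in the same plane by requiring each unit's network
centroid to sit near its projection.  We define the centroid `Cᵢ` as the
edge-weight-weighted mean of edge-endpoint midpoints, with each unit's
weights renormalised to sum to one.  `Cᵢ` is then *linear* in the node
coordinates, so minimising `Σᵢ‖Pᵢ − Cᵢ‖²` is a linear least-squares problem
with a closed-form solution — no iterative optimisation, a global optimum
by construction (the test suite verifies it beats 1,000 random layouts).
The design matrix has a row-sum-one structure, which makes the layout
translate exactly with the projections; a code that never co-occurs with
anything is unconstrained and is flagged and left at the origin (the
minimum-norm solution).

Group summaries average the normalised edge weights arithmetically (so a
size-weighted mean over a partition reproduces the group mean exactly) and
report t-based 95% confidence half-widths per dimension (standard errors
are exposed alongside).  Group comparisons are two-sample Student t-tests
with pooled variance on unit centroids along one dimension, with Cohen's d
from the pooled SD; Welch's correction is available behind a flag.  No
multiple-testing correction is applied across phases by default (a
Bonferroni flag exists).

One property of this construction worth knowing: because `nU` lives on the
sphere, units built from little data have noise-inflated norms, which
shrinks *every* structured mean-edge weight of that stratum.  When two
strata have unequal data per unit (e.g. rare repair sequences), this
shrinkage alone displaces the sparse stratum's centroid toward the origin.
The repair-contrast calibration tests therefore balance the strata; on
unbalanced data the contrast mixes genuine gaze differences with this
sampling artefact, as it would in any analysis of this family.

## Lag alignment

Alignment at lag τ is the fraction of a phase's segments in which the
worker gazes at the same *object* (raw AOI) the instructor gazed at τ
earlier (positive τ = instructor leads).  Matching by object rather than by
the four-way category is deliberate: both participants spend much of their
time scanning ingredients, so category matching would put chance-level
"alignment" near 40% in scanning-heavy phases and swamp the coordination
signal; the Same/Different recoding used for the shifted space is defined
as "gazing at the same object" for the same reason.  Category matching
remains available (`match="category"`) and is what the *descriptive*
shared-gaze percentage uses (below).

Denominators count comparable coded pairs only: pairs where either stream
is unmapped, or where the shifted partner falls outside the sequence, drop
out, and comparisons never straddle sequence boundaries.  Lags whose
denominator falls below 10% of the best-supported lag's are reported as
undefined — at extreme lags only the rare longest sequences contribute and
the fraction estimate degenerates.  Segments are pooled across dyads before
the fraction is taken (per-dyad averaging is a flag).  The optimal lag is
the argmax over the −2000…+2000 ms grid in 50-ms steps; exact ties break
toward the smallest |τ| and then toward the positive side, a rule that
matters because shallow peaks near zero live in near-flat territory.

For the lag-shifted space, each phase's worker segments are re-paired with
the instructor code at that phase's optimal lag (the worker stream anchors
the grid, consistent with the alignment scan), recoded Same/Different, and
run through the full network pipeline over the six-code set.

## Phase prediction

As a validation of the phase separation, the space is fitted with one dyad
held out; random 200-ms and 1000-ms windows of the held-out dyad's raw gaze
are accumulated into adjacency vectors, normalised, centred with the
*training* mean, projected, and labelled by the nearest per-phase centroid
of training units (Euclidean distance in the kept two dimensions; full-rank
distance behind a flag).  Windows must fit inside a single phase occurrence
— 1000-ms windows therefore undersample the short post-reference phase —
and windows with no co-occurrences at all are reported as uncodable rather
than forced into the confusion matrix.  Ties break deterministically by
phase order.  The number of windows per phase is a parameter (default 50).

## The synthetic generator

The study-style corpus this package would analyse is not publicly
deposited, so a generator produces corpora with the statistical structure
the analyses assume; it is first-class, tested code, and the packaged
default configuration (`defaults.yaml`) is calibrated so that the simulated
corpus reproduces the study-scale summary statistics.

Per sequence: the five phase durations are gamma draws (means
1.90/1.32/0.78/1.68/0.81 s, CV 0.4); each participant's gaze is a renewal
process of fixations with lognormal dwells (mean 300 ms, CV 0.4, 40-ms
floor) over `{Reference, Other, Target, Person, Unmapped}` with per-phase
categorical targets.  `Other` fixations pick a uniform non-referent
ingredient among the 23 on the table.  Coordination enters three ways:

* **Coupling.**  At each of its fixation onsets `t` the worker, with
  per-phase probability ρ, adopts the instructor's gaze target at
  `t − λ` (per-phase lead λ; negative λ = the worker runs ahead) and holds
  it for as long as the instructor holds it (so coupled dwells are the
  instructor's residual dwells, and chains of couplings track the
  instructor exactly at lag λ).  Copies of partner-directed gaze fall back
  to the marginal — one cannot follow a partner's gaze to oneself — which
  also keeps mutual gaze at the sub-1% scale seen in data of this kind.
  Coupling at the fixation level (not per segment) produces realistic dwell
  runs.
* **Referential timing.**  The instructor first fixates the referent a
  lognormal lead before the verbal onset (mean 1.45 s, CV 0.3; truncation
  at the phase start makes the *measured* anticipation average ≈1.31 s) and
  returns to it repeatedly (≈2.3 pre-onset referent fixations); the
  worker's first referent fixation is forced a lognormal latency after the
  onset (mean 1.65 s, CV 0.2).  Before those moments referent draws and
  referent copies are suppressed.
* **Repair.**  A sequence is flagged as containing a conversational repair
  with probability 0.35; repair sequences perturb the worker's marginals
  (pre-reference: +0.12 bread-gaze at the cost of other-gaze, emulating a
  worker still engaged with the previous action; reference and
  post-reference: +0.15/+0.12 gaze to non-referents at the cost of
  referent/bread gaze, emulating failed referent identification).

All randomness flows through one seeded generator; regeneration from a seed
is bit-identical.

### Calibration of the defaults

The per-phase target distributions were chosen by hand to reproduce the
qualitative mean-network pattern (pre-reference dominated by worker
other-gaze against instructor referent/other-gaze; a growing joint referent
edge through reference into post-reference, where referent–referent is
strongest; joint bread-gaze in action; instructor scanning against worker
bread-gaze in post-action), the ≈20% unmapped rates, and the ≈0.9% mutual
gaze level.  Given those, the per-phase coupling probabilities were fitted
by root-finding on the *simulated* peak alignment at the configured lead so
that the five peaks land on 22.5/27.6/36.1/34.6/27.0% at lags
0/700/−300/−50/300 ms, with the closed-form `expected_alignment` oracle
supplying starting points.  The calibration was run once and the resulting
numbers frozen; the acceptance tests re-measure them from scratch.

Two statistics deliberately use different matching conventions: the
alignment curves match objects, while the descriptive shared-gaze
percentage (≈31–34% under the defaults) matches the *codes* — the same
granularity the networks accumulate — because two participants scanning
different ingredients genuinely share an `Other–Other` code co-occurrence.
This is why the overall shared-gaze figure can exceed every object-level
peak alignment; with a single convention the two families of numbers would
be arithmetically incompatible.

### The closed-form alignment oracle

`expected_alignment(config, phase, lag)` computes the expected conditional
alignment deterministically (no Monte Carlo): the sequence timeline is
modelled with gamma-smeared phase boundaries (moment-matched partial sums),
the anticipation/latency mechanics are folded in by integrating the
lognormal lead/latency against the onset distribution, coupled time-share
accounts for residual dwells and fallback, and lags away from the
configured lead decay through the same-fixation probability of a stationary
lognormal renewal process toward the chance level `Σₖ p_I(k)p_W(k)/(q_I
q_W)`.  Its measured accuracy against simulation at the packaged defaults
is ±0.5–3 points of alignment for the pre-reference, post-reference and
post-action phases, and ±4–9 points for reference and action, where worker
fixations that straddle phase boundaries carry the previous phase's
coupling regime and coupling chains re-anchor in ways a first-order model
does not capture.  The tests assert the oracle at this measured accuracy;
calibration therefore trusts simulation, with the oracle as the initial
guess.

## What passing tests do and do not show

The generator emulates the *statistical* structure the analyses assume —
phase-conditioned categorical gaze, lag-coupled streams, referential
timing, repair perturbations — under one shared clock, with no eye-tracker
noise, no drift, no saccade gaps, no verbal content and no hand kinematics.
Passing tests therefore demonstrate that the machinery recovers known
structure at study scale (13 dyads × 2 interactions; 50-ms segments), not
that real gaze data has this structure.  In particular: per-phase marginals
are piecewise-stationary within phases, `Other` fixations land uniformly on
ingredients (real scanning is salience-biased, so chance object-alignment
is likely higher in real data), and the repair flag perturbs marginals
homogeneously across a sequence rather than marking a localised
clarification episode.

## Numerical and procedural choices

* Half-open `[start, end)` intervals, integer milliseconds throughout.
* Segment length 50 ms; lag grid −2000…+2000 ms in 50-ms steps; lags must
  lie on the segment grid.
* Normalisation rejects all-zero units ("empty unit"); spaces require at
  least two distinct units ("degenerate space").
* SVD sign convention: largest-magnitude loading entry positive; repeated
  fits agree to round-off (not bitwise — LAPACK is 1-ulp sensitive to
  memory layout).
* Node layout via `scipy.linalg.lstsq` (minimum-norm on rank deficiency).
* Lag ties: smallest |τ|, then positive; flat curves return 0 with a
  warning.  Classifier ties: phase order, with a warning.
* Confidence boxes are t-based 95% intervals (standard errors exposed).
* Type-I calibration of the repair contrast holds at the nominal 5% over
  500 null replicates; directional recovery of the configured perturbations
  holds in ≥95% of replicates with balanced strata (see the shrinkage note
  above for why balance matters).
* Test problem sizes were chosen to keep the full suite around three
  minutes while leaving every Monte-Carlo assertion several standard errors
  of headroom; the acceptance script scans a 780-sequence corpus for the
  lag statistics (study dyad structure, halved Monte-Carlo error) and a
  390-sequence corpus (the study's own size) for the descriptives.

## Known limitations

* The closed-form oracle is first-order; see its accuracy statement above.
* Real repair episodes are localised in time; the sequence-level flag and
  homogeneous perturbation are a simplification.
* The t-tests treat the two interactions of one dyad as independent units
  (n = 26), mirroring the analysis family this package implements; the
  dependence between a dyad's two interactions is a known caveat.
* Axis orientation of the spaces is only fixed up to the stated sign
  convention; figures may be mirrored relative to other implementations.
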