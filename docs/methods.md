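# Methods

`fetalvoc` analyzes the prenatal emergence of vocal-motor coordination in the
common marmoset: orofacial (mouth-opening) and head movements scored from
ultrasound imaging of fetuses between gestational days E93 and E146, and their
relation to the duration, syllable, and temporal-profile signatures of infant
calls recorded in the first postnatal week. This note documents the models,
parameters, and numerical choices; the README shows how to run everything.

## Timeline and movement units

All scoring lives on a 30 Hz frame timeline; frames convert to seconds as
`frame / 30` exactly, and files store seconds while memory stores integer
frames (scoring was frame-by-frame, and integer frames avoid float drift).
Individual movements of one kind separated by gaps of **at most 500 ms (15
frames)** merge into a single *movement unit*; the boundary case of exactly 15
frames merges. The 500 ms separator is the same criterion that separates
syllables within a marmoset call from the gap between calls, so the number of
constituent movements in a unit is its *syllable count*. Units truncated by
loss of the fetal face (partial units) count toward unit numbers, rates, and
state coding but are excluded from every duration or syllable statistic,
because their true extent is unknown.

## Behavioral states and information measures

Each movement occurrence is one of five states: isolated orofacial (S1),
isolated head (S2), orofacial-led overlap (S3: head onset at least one frame
after the orofacial onset and strictly before its offset), head-led overlap
(S4, the mirror case), and synchronous onset (S5: same frame). An overlapping
pair is a single occurrence; a unit that overlaps several opposite-kind units
pairs greedily with the earliest unpaired one (first-overlapper-wins), so every
unit contributes exactly once. Occurrences are ordered by the earlier onset of
the pair.

Per session, the state distribution P over S1..S5 gives

* Shannon entropy `H = -sum_i P_i log2 P_i` (0 log 0 := 0), ceiling
  `log2 5 ~ 2.32` bits — behavioral variability;
* divergence from the early-gestation baseline, where the baseline is the
  arithmetic mean of the per-session distributions of all sessions at E93-99
  (sessions weigh equally, then renormalized).

The two-argument operation `kl_divergence(P, Q) = sum_i P_i log2(P_i / Q_i)`
returns an explicit `+inf` marker when some `P_i > 0` meets `Q_i = 0`; no
silent smoothing is applied (an optional additive-smoothing parameter exists,
default off). For the developmental trajectory the package computes
`KL(session || baseline)`: the baseline, averaged over many early sessions,
has full support in practice, so this direction stays finite even for late
sessions that have lost whole states — which is precisely the phenomenon being
measured. The opposite direction would be infinite for every such session and
could not produce a finite trajectory. Entropy and KL are invariant under
relabeling of the states, so the S3/S4 naming convention does not affect them.

First-order transition matrices are row-normalized transition frequencies;
rows never observed as sources stay zero.

## Overlap and the permutation null

Percent overlap per session is `(#S3 + #S4 + #S5) / (#orofacial + #head
units)`, synchronous onsets included. Because overall movement declines with
age, a declining overlap could be a pure rate artifact; the permutation null
controls for this. Per replicate, each session's two streams are independently
rebuilt by resampling, with replacement, the observed unit durations and
inter-unit latencies (the gap preceding each unit; the initial offset from
time zero is pooled with the latencies) and laying alternating latency -
duration segments end to end from zero. Unit counts and both marginals are
preserved; timing relations between the streams are destroyed. Rebuilt units
crossing the session's visible span are dropped (truncation, not rescaling,
which would distort the marginals). Per replicate the per-session overlaps are
averaged per gestational day and a polynomial of the degree chosen on the
observed data (linear here) is fitted; over 1000 replicates the pointwise
2.5/97.5 percentiles form the envelope, the replicate slopes give a slope CI,
and the regression line through the replicate-mean curve provides the "flat
profile" check. Replicate r uses an independent substream `[seed, r]` of one
master generator.

## Trend fitting and hypothesis tests

Polynomial degrees are chosen by AIC in the Gaussian form
`AIC(d) = n ln(RSS_d / n) + 2 (d + 2)` (d + 1 coefficients plus a variance).
The search walks degrees upward and accepts a higher degree only when it
improves AIC by **more than 2** — the conventional "delta-AIC below 2 is no
substantial support" parsimony rule — stopping after two consecutive
non-accepted degrees (two, so that even-symmetric shapes such as an inverse-U,
where the linear term adds nothing, are still reached). A plain global argmin
is available (`patience=None, min_improvement=0`) but overfits nested models
with probability ~0.25-0.30 regardless of sample size, which would make exact
degree recovery unreliable. Fitting is done on standardized x (the raw
Vandermonde matrix of gestational days is numerically rank-deficient beyond
degree ~4); `PolyFit.raw_coefficients` converts back when raw-domain
coefficients are wanted. Percentile trend curves (25th/75th) reuse the degree
selected on the medians.

Significance of a gestational-day effect on any session-level quantity is
tested by OLS of the quantity on day plus reference-coded pregnancy
indicators, followed by the single-term ANOVA nullity test of the day effect;
with one numerator degree of freedom, F = t² exactly. With fewer than two
pregnancies the covariate is dropped with a warning. Its type-I error is
calibrated by simulation in the acceptance suite.

## Temporal profiles, DTW, and templates

A temporal profile is the frame-wise mouth-opening magnitude of one unit or
call. Conditioning: z-scoring removes amplitude (ultrasound amplitude is
posture-dependent and uninformative), then fetal traces are Savitzky-Golay
smoothed (degree 3, window 9) and infant exemplars smoothed with a cubic
smoothing spline, csaps-style parameter p = 0.999 (near-interpolating). The
csaps objective `p * sum (y-g)^2 + (1-p) * int g''^2` maps to the
penalized-spline weight `lam = (1-p)/p` on the unit-spaced sample grid; p = 1
interpolates and p -> 0 tends to the least-squares line.

DTW uses local cost `|a_i - b_j|`, the symmetric step set {(1,0), (0,1),
(1,1)}, and matched endpoints. The raw score is the unnormalized cumulative
cost, pinned by a brute-force path-enumeration oracle in the tests; an
optional uniform linear-interpolation refinement of both sequences
approximates continuous-time DTW (factor 1, i.e. off, by default). For
template *matching* and the session-median trajectory the score is divided by
`len(a) + len(b)`: the raw cumulative cost grows linearly with sequence
length, so with profile durations increasing through gestation it would
measure duration rather than shape; the per-step score is comparable across
ages and is the scale on which a developmental slope of order 10^-3 per day is
meaningful. DTW is non-negative, symmetric, zero on identical inputs, and
invariant to joint time reversal; it violates the triangle inequality and is
used only as a dissimilarity, never as a metric.

Contact-call templates: infant profiles of the same syllable count (1-7) are
averaged by DTW Barycenter Averaging — initialized at the medoid, each
iteration aligns every profile to the current average and replaces each sample
by the mean of its aligned samples, keeping the lowest-total-cost average and
stopping when the total cost stops decreasing (at most 10 iterations) — then
smoothed with the csaps-style spline at p = 0.1. Each fetal profile is
compared to all seven templates and the lowest cost retained, ties broken
toward the lower syllable count (arbitrary but fixed). Before matching, a
quality gate keeps only profiles that are at least one smoothing window long
and whose automated syllable count — prominent peaks (prominence 0.5 z-units,
minimum 4 frames apart) of the denoised trace — agrees with the manual count
on record, mirroring the study's exclusion of traces that contradicted manual
scoring. Per-session medians of retained costs feed the pregnancy-controlled
regression.

## Call-signature criteria

Signature boxes are closed intervals in (duration, syllable count):
contact 3.69-6.5 s x 5-9; twitter 0.96-1.5 s x 2-3; lick the union
{0.33-3.77 s x 1-6} and {6.67-14.29 s x 10-16}. Percent match of a session is
the share of its complete orofacial units falling in a box. `type_likelihood`
is the fraction of in-box infant calls that are of the target type;
`box_capture` the fraction of target calls a box catches (the lick criteria
are characterized by capture). `boxes_disjoint` checks exclusivity
exhaustively over the integer syllable grid and interval endpoints; note that
the contact box and the short-lick box genuinely share the sliver
[3.69, 3.77] s x {5, 6} syllables, so these two criteria are *not*
geometrically exclusive — any empirical 0% cross-capture is a statement about
a particular call sample, not about the boxes. A grid search
(`derive_criteria`) reconstructs boxes from labeled calls by maximizing
target likelihood subject to a minimum capture, with candidate bounds snapped
to 0.01 s. Audio-derived call durations are reconciled to the video timeline
by adding the median (video - audio) discrepancy of double-captured calls.

## Synthetic study conditions

The generator emulates the study design so that every stage runs without the
archived recordings: 4 pregnancies x 16 sessions evenly spaced over E93-146
(64 sessions), 1200 s of face-visible footage per session (within the 15-45
min imaging windows after visibility losses). Defaults, chosen once as the
package's study conditions:

* orofacial rate: inverse-U, `60 - 0.052 (day - 119)^2` per hour (~25 at E93,
  peak 60 near E119); head rate: linear 55 -> 12 per hour; both floored at a
  few movements/hour;
* orofacial-head coupling probability c(day): linear 0.8 -> 0.05. A coupled
  head unit is placed relative to a random orofacial unit with lead mode
  (orofacial-lead 0.45, head-lead 0.45, synchronous 0.10) so all five states
  occur; uncoupled units are placed uniformly. Same-kind units keep at least
  16 frames between them (one frame beyond the merge threshold) so written
  events re-merge to the same units;
* orofacial units: syllable count 1 + Poisson with mean rising 2 -> 5 across
  gestation, open-close cycle durations Normal(0.35 -> 0.55 s, sd 0.08),
  intra-unit gaps 2-14 frames; head durations Normal(1.0, 0.3) s; partial
  probability 0.05. These schedules make late units drift into the contact
  box, the trend the signature analysis must detect;
* profiles: raised-cosine open-close cycles with sub-500 ms gaps, additive
  Gaussian noise, a smooth monotone time warp, per-cycle amplitude jitter,
  and a slow baseline drift. Fetal profiles interpolate noise 0.35 -> 0.06,
  warp 0.6 -> 0.15, jitter 0.8 -> 0.05, drift 0.6 -> 0.03 across gestation:
  time warp is absorbed by DTW, but amplitude irregularity and drift are not,
  so early profiles are genuinely far from the stereotyped call templates in
  shape, not merely noisier;
* infant calls: contact durations Normal(3.69, 0.8) s clipped to [1, 6.5] and
  syllables round-Normal(5, 1.3) in 1-9 (medians near 3.69 s / 5); twitters
  Normal(1.2, 0.18) s with 2-3 syllables; licks a 70/30 mixture of short/few
  and long/many.

All randomness derives from one master seed through named integer substreams;
identical seeds give bit-identical cohorts, profiles, and call tables.

What the generator does **not** emulate: ultrasound imaging artifacts,
scorer disagreement, respiratory or autonomic rhythms, within-litter
differences between fetuses, non-stationarity within a session, or any
acoustic structure. Passing tests therefore demonstrate that the pipeline
recovers effects of the programmed kinds and magnitudes from data with the
study's design and sampling noise — not that the biological effect sizes are
as programmed.

## Degenerate inputs and edge rules

Sessions without occurrences yield flagged-empty distributions and are omitted
from entropy/KL/overlap points (NaN in tables); sessions whose streams lack
one kind pass through the shuffle unchanged; zero-RSS fits select the smallest
degree (the RSS is floored at 1e-300 inside the log); constant traces cannot
be z-scored and are rejected; empty criteria boxes give NaN likelihoods rather
than 0. Scaled-down cohorts are supported everywhere by capping the searched
polynomial degree at (points - 2).

## Known limitations

* The DTW step pattern and score scale of the study's original routine are
  not recoverable from its text; ours are pinned by oracles and documented
  above, so scores are comparable within this package but not directly to the
  study's units.
* The automated syllable counter is a stand-in for manual frame-by-frame
  scoring; its prominence threshold is tuned to the generator's clean cycle
  shapes.
* The criteria-derivation grid search reconstructs the *form* of the
  signature-box procedure; the study described its objective only informally.
* KL trajectories depend on the baseline having full support. When the
  pooled baseline does have an empty state cell (possible by chance when the
  early sessions are few or heavily coupled), the pipeline switches on the
  additive smoothing (`kl_smoothing`, default 1e-3) for that run and logs it;
  sessions that are still infinite are excluded from the trend fit, with the
  finite count recorded in the run's bookkeeping.
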