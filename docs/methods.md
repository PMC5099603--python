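# Methods

## The analysis problem

A Morris water maze study of Ts65Dn (trisomic) mice and euploid
littermates, with and without combined environmental-enrichment + EGCG
treatment, produces swim trajectories across five acquisition sessions
(four trials each), a removal (probe) trial, a cued control trial, and
three reversal sessions with the platform reflected through the pool
centre. This package reimplements the full analysis chain on top of
those trajectories. Because no raw trajectories are publicly deposited,
the package ships a generative swim model so that every stage is
exercised, and every statistical property verified, on data with known
ground truth.

## Coordinate and arena conventions

Pool-centred cm coordinates; pool radius 85 cm; platform radius 6 cm;
trials censored at 60 s; tracker rate 25 Hz. The acquisition platform
sits at (21.25, 29.75) cm — off the coordinate axes so that "the
quadrant containing the goal" (quadrants are the four half-plane
intersections of the axes) is unambiguous — and reversal reflects it to
(−21.25, −29.75). Four release points lie on the wall at the axis
crossings and are scheduled without replacement within each four-trial
session, the standard balancing used in MWM practice.

## The synthetic swim agent

Each trial is a discrete-time heading process. At each 40 ms step the
new heading direction mixes, with weight `w` ("goal weight"), the unit
vector toward the platform, and with weight `1 − w` a non-goal heading
that itself blends wall following (weight = thigmotaxis bias; a tangent
direction with a radial correction toward the middle of the outer
annulus) with persistence of the current heading. Gaussian angular
noise with standard deviation `heading_noise · sqrt(dt)` is added, the
position advances by `speed · dt` and reflects at the wall. A trial
ends at the first sample inside the platform disc, or at 60 s.

Learning is carried entirely by the goal weight: session `s` of a
learning phase uses `w(s) = min(1, w0 + rate · (s − 1))`, restarting
from `w0` in reversal (re-learning toward the reflected goal). Removal
trials steer toward the *former* platform with the session-5 weight and
cannot escape; cued trials use a high fixed weight (0.95) and no
thigmotaxis, standing in for the visible platform that all procedurally
competent mice find quickly.

The deterministic mixture turned out to be nearly bistable: mean
latency drops from 60 s to ~6 s over a goal-weight interval of ~0.1, so
group means would be all-ceiling or all-floor. Real cohorts are graded
because animals differ; the agent therefore adds a stable per-mouse
ability offset (sd 0.06) and per-trial goal-weight jitter (sd 0.09),
which produce smooth group learning curves and realistic within-group
spread of the supplementary points. The replica preset (group sizes 11,
8, 12, 8; w0/rate per group chosen once) yields mean latency curves of
roughly 35→12 s (WT), 57→56 s (TS, ~94% of trials censored), and
55→30 s (treated TS), echoing the qualitative study pattern: impaired
trisomics, partial rescue, unaffected wild types.

Reproducibility: every trial owns a child stream spawned from the design
seed (`numpy` `SeedSequence`), so cohorts are bit-identical under a
fixed seed and single trials can be replayed in isolation.

What the generator does *not* emulate: biomechanics (acceleration,
turning-rate limits), floating/immobility, inter-trial carry-over,
within-trial learning, or tracker noise. Tests passing on this model
therefore validate the *analysis machinery* — metric geometry,
likelihoods, permutation calibration — not any biological claim.

## Trial metrics

All metrics are computed on the sampled path. Latency is the time of
the first sample within the platform disc, censored at 60 s. Thigmotaxis
is the % of time samples in the outer annulus; the study's tracker
never documents the band width, so the default is the common convention
of 20% of the pool radius (configurable). The Gallagher proximity index
is the mean distance of all samples to the platform centre. The
accumulated Gallagher distance sums that distance after resampling the
path to 1 Hz (endpoints inclusive; a stationary 60 s trial at 40 cm
gives 61 · 40 = 2440 cm) so its magnitude is tracker-rate independent.
The Whishaw index is the % of *arc-length-uniform* samples (1 cm
spacing) inside the rectangle of width 12 cm (= platform diameter, the
most conservative reading of "optimal corridor") joining release point
and goal; using path-uniform rather than time-uniform samples keeps a
mouse pausing inside the corridor from inflating the index. The target
quadrant is the axis-quadrant containing the goal, boundaries counted
inward. The four trials of a session are averaged into one metric
vector per mouse-session; censored latencies enter descriptive averages
and the PCA at the 60 s bound (only the Tobit layer models censoring).

The cue inclusion rule retains only mice whose cued-trial latency is
strictly below 30 s; user-supplied exclusions (e.g. an over-performer)
are applied and logged alongside.

## Censored and mixed models

`fit_tobit` maximises the right-censored Gaussian likelihood by BFGS on
(β, log σ) from the censoring-ignorant OLS start, with analytic
gradients and a 1e-8 gradient tolerance; standard errors come from the
numerically differentiated observed information on the natural scale.
The latency analysis models session-averaged latencies on additive group
and session factors (a session average is censored only when all four
trials were), and tests the group factor by a likelihood-ratio χ² with
3 df for four groups — the df of the reported statistic form. The exact
design matrix behind the original analysis is not recoverable, so this
is the package's own choice.

`fit_random_intercept` wraps the REML random-intercept model (group
fixed, mouse random) and reports a Wald F for the group factor with
between-mouse denominator df (`n_mice − n_groups`). With one value per
mouse the random intercept is unidentifiable and the model collapses,
exactly, to one-way ANOVA (fitted by OLS) — used for the
novel-object discrimination index. Post-hoc contrasts are Wald z tests
with normal CIs; the family is adjusted by Benjamini–Hochberg (FDR, used
for the behavioural tables) or Holm (FWER, default for the morphometry
endpoints, where family-wise control is the stated goal). The max-T
("Tukey") joint adjustment is not implemented: the multiplicity control
actually applied downstream is the BH/Holm step.

Morphometry endpoints are analysed at image/dendrite level with mouse as
the clustering unit; VGLUT1/VGAT ratios are formed per image (a zero
VGAT denominator excludes that image, logged, never silently dropping
its pair), and post-hoc contrasts are gatekept behind the global F test
at α = 0.05.

## Supervised group-median PCA

The median matrix holds, per (group, session) cell, the median over mice
of the session-averaged variable — 20 rows for acquisition, 12 for
reversal. Each variable is standardised by the mean and population
standard deviation *over the matrix rows* (the only self-contained
reading of "scaled to unit variance"), so the eigenvalues of the row
covariance sum to 7 exactly. Components are oriented
deterministically: the Whishaw loading on PC1 and the speed loading on
PC2 are non-negative (efficient learning = large PC1); remaining
components sign their largest-magnitude loading positive. Variable
contributions are 100 · loading².

Individual mouse-sessions are standardised with the stored centre/scale
and multiplied onto the loadings, keeping all seven axes, so the
projection is an isometry: supplementary distances equal standardised
distances, group-session median rows project onto themselves, and the
within/between variance bookkeeping below closes exactly.

Within-group variance of a cell is the mean squared distance of its
supplementary points from their barycentre over all seven axes, divided
by 7. Between-group variance is reported in two variants: (a) the
variance of the median rows about the origin of the median-PCA space
(identically 1 under the ddof-0 scaling — reported as a consistency
anchor), and (b) the classical size-weighted variance of cell means
about the overall barycentre of the supplementary points, which
satisfies the law of total variance against the weighted within-cell
variance to numerical precision.

The permutation test reassigns mice to groups (sizes preserved; one
label per mouse across all sessions, preserving within-mouse
correlation), rebuilds the median matrix, refits the whole PCA and
reprojects at every shuffle, then compares Welch (unpooled) pseudo-*t*
statistics on the supplementary PC1 coordinates of the first and last
session of the phase; p = (1 + #{|t*| ≥ |t|}) / (1 + N) (add-one, so p
is never zero; minimum 1/(N+1)). The Welch form was chosen because the
within-group variances differ markedly between groups. Jackknife
stability deletes one mouse, rebuilds and refits, and reports
arccos|⟨v_new, v_old⟩| in degrees for PC1 and PC2; a deletion that
empties a cell (or removes a whole group) skips that mouse with a
logged warning.

## Numerical and testing choices

Problem sizes in the statistical test-bed were chosen to give stable
Monte-Carlo estimates at desk scale: permutation type-I error uses 300
exchangeable-null cohorts × 500 permutations on the Gaussian
metric-vector surrogate (`simulate_metric_table`, an affine map from a
latent learning level to the seven variables — exchangeability is all
the null requires, and it is ~100× cheaper than trajectory simulation);
the qualitative group-separation check runs 100 full trajectory-level
cohorts (4 × 10 mice, 5 × 4 trials) with 499-permutation tests; Tobit
recovery uses 50 replicates at n = 500 with ~30% censoring; mixed-model
calibration uses 500 null nested datasets. The trajectory-metric layer
is verified against brute-force point classification (and an independent
computational-geometry library for the corridor) on 1,000 random paths.

Known limitations: the Tobit design, the thigmotaxis band, the corridor
width, and the pseudo-*t* variance form are under-determined by the
study's text and are fixed here by the documented conventions above;
the swim agent is a statistical stand-in, not a behavioural model; and
the permutation machinery assumes complete mouse × session tables
(mice missing a session are rejected, not imputed).
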