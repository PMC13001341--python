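# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `sleepermeta` pipeline and of its synthetic-data
generator.

## Coordinate conventions

All behavioural time is in minutes of *experiment time*: minute 0 is
lights-on (ZT0) of the first recorded day; the ZT of minute *t* is
`t mod 1440`. Every interval is half-open `[start, end)`, so no boundary
minute is ever counted twice, and matched-baseline intervals are always
exactly 24 h earlier at the same clock time.

## Sleep calling and derived metrics

A minute is asleep iff it lies inside a maximal run of zero-activity
minutes of length ≥ 5 (`min_bout_minutes`, default 5 — the standard fly
criterion). The maximal run *is* the bout: a 9-minute quiet run is one
9-minute bout, never a 5+4 split.

Deprivation efficiency is `1 − sleep(SD)/sleep(matched baseline)`; the
inclusion filter is strictly `> 0.90` (exactly 0.90 fails). With zero
baseline sleep the efficiency is defined as 1 when SD sleep is also zero,
and 0 otherwise (the fly cannot demonstrate deprivation against an empty
baseline, so it conservatively fails the filter). Conditions that force
sleep use the mirrored filter (> 90 % of the interval asleep).

Cumulative sleep windows are nested totals: the *k*-hour value is total
sleep over the *k* hours immediately adjacent to the sampling minute, for
k = 1..12. Flies whose recording does not fully cover a window are excluded
from that window's mean rather than truncated or imputed; a recording
starting mid-window therefore drops the fly for that window. Dead flies
(no activity over a trailing ≥ 12 h while at least one other fly is active)
are removed before averaging. Rebound per window is the post-sampling
cumulative sleep minus the matched windows 24 h earlier.

## Directional calls and the cycling wild-card

Gates are strict: |log2FC| > 1 (FC1) or > 0.5 (FC0.5), q < 0.05. Polarity
semantics: up under a sleep-promoting manipulation, or down under a
wake-promoting one, is a *sleep* call; the converse is a *wake* call. A gene
present in a table but failing the gate is recorded as `none` (tested, not
regulated); a gene absent from a table receives no judgement there, and its
absence never blocks consistency elsewhere.

The baseline circadian experiment contributes only cycling wild-cards:
genes whose peak-trough amplitude of per-timepoint mean log2 expression
exceeds the same per-threshold fold-change cut at rhythmicity q < 0.05. The
amplitude gate deliberately re-uses the FC1/FC0.5 cut; whether the original
analyses tied the two cuts is not documented, so this is a package choice.

`de_lite` (mean log2(TPM+1) difference, Welch t-test, BH across genes) is a
deliberately simple two-sample stand-in used on synthetic data; real
analyses should ingest externally computed DE tables, for which the
pipeline has a reader. The pseudocount of 1 keeps zero TPMs finite.

## Consistency rule

A gene joins the consistent sleep set iff it has ≥ 1 directional sleep
call, zero wake calls anywhere, and total support ≥ `min_support`
(default 2), where a cycling wild-card contributes one unit of support
toward either direction and never a contradiction. "Supports both" cannot
mean simultaneous membership (the sets must be disjoint), so a gene with
only a wild-card joins neither set; requiring at least one directional call
keeps the direction well defined. Because it is genuinely unclear whether
one directional call plus the wild-card should suffice, a strict mode
(`wildcard_counts=False` / `--no-wildcard`) requires all support to be
directional. An experiment contributes at most one call per gene.

## Overlap enrichment

Detection backgrounds are per experiment: genes with TPM > 0 in strictly
more than half of that experiment's samples (a tie at exactly half fails,
reading ">50 %" literally). Each pair is tested on the intersection of the
two backgrounds, lists clipped to it (with a logged warning if anything
fell outside). The p-value is the upper hypergeometric tail — enrichment
only; depletion is never flagged. The odds ratio is the unconditional
sample ratio (ad)/(bc), displayed rounded with the overlap count in
parentheses; the conditional MLE is not computed. BH families are the
sleep-category pairs and the wake-category pairs, separately. In the
default pipeline the per-experiment lists are the directional call lists
(the alternative — consistency-filtered lists — is a switch), and the
baseline experiment enters with its wild-card genes in both categories.

## Correlation analyses

Genes with TPM < 1 in strictly more than half of the raw samples are
dropped; replicates are then averaged per condition and the mean is
log2(x+1)-transformed — averaging precedes the log, and the pseudocount
bounds the transform at 0. Pearson r is computed across condition columns
(n = number of conditions, not replicates or flies); p comes from the
t-transform with n−2 degrees of freedom. History correlations use all
conditions including each circadian timepoint as its own column; rebound
correlations exclude the circadian controls.

BH is applied across genes separately within each window (the twelve
windows are treated as separate analyses); a gene is significant if any
window passes q < 0.05, and its summary sign is the sign of r at the
minimum-q window (ties at the smallest window index). Because the family
choice is consequential and undocumented in the original description, a
pooled gene × window family is available behind `bh_family="pooled"`. If a
gene's significant windows disagree in sign, the summary still follows the
minimum-q window and the gene is flagged (`mixed_sign`). Zero-variance
genes or window metrics are skipped with a logged reason.

The history × rebound intersection partitions genes significant in *both*
analyses into four sign cells (pos/neg, neg/pos, pos/pos, neg/neg); the
cells are disjoint and cover exactly the doubly significant genes.

## Clustering views

Rows are z-scored with the sample standard deviation (ddof = 1);
zero-variance rows become all-zero with a warning. Both axes are clustered
by complete linkage on `1 − Pearson` distances (values clipped to [0, 2]
against floating-point excursions). Merge computation delegates to a
standard agglomerative implementation; on generic real-valued data
distances are tie-free, and where ties occur the library's deterministic
merge ordering is the package's tie-break rule.

## The synthetic generator

**What it emulates.** The default panel has 13 conditions × 3 replicates:
baseline collections every 4 h (ZT0–ZT20) at 25 °C, mechanical deprivation
for 3/6/12 h ending at lights-on, a thermogenetically wake-promoting line
(3 h activation ending at lights-on) and a sleep-promoting line (12 h
daytime activation) at 29 °C, with a driver-only 29 °C control and a 21 °C
control; 16 flies per condition recorded for three days. Five DE contrasts
(three mechanical, one wake, one sleep) plus the baseline cycling table
feed the consistency stage. The shared driver-only control is collected at
ZT0 while the sleep-promoting line samples at ZT12; the circadian confound
this builds into that one contrast is intentional — cycling genes acquire
directional calls there, as they do in real panels with imperfect
time-of-day matching.

**Behaviour model.** Two-state semi-Markov traces with geometric bout
lengths; mean bouts are 60 min wake / 12 min sleep by day and 12 min wake /
40 min sleep by night (night sleep fraction ≈ 0.75, day ≈ 0.2 — ordinary
laboratory values). Deprivation forces every minute of its interval active;
sleep promotion forces quiescence. The 12 h after a perturbation is
regenerated with sleep-bout lengths scaled by
`1 + 2.5 × (realised sleep lost)/720` (clipped to [0.3, 3.5]), so rebound
is proportional to each fly's own loss and sleep induction produces
antirebound. Awake minutes draw counts from 1 + Poisson; forced
deprivation uses a higher rate, so the > 90 % efficiency filter passes
essentially all deprived flies.

**Expression model.** log2 expression = per-gene baseline (uniform 3–8)
+ class effect + N(0, σ); TPM = 2^x − 1 clipped at 0. Defaults: 2,000
genes, 100 per planted class, effect 2.0 log2 units, σ = 0.25, coupling
β = 2.0 — sized so the full pipeline runs in seconds. Class effects:
wake/sleep-induced genes shift with the condition's sleep-wake state;
cycling genes are sinusoidal in sampling ZT (half-amplitude effect/2, i.e.
peak-trough = effect); temperature genes scale with (T − 25)/4;
activation-responsive genes follow thermogenetic activation regardless of
its polarity (and are therefore contradicted across the wake and sleep
contrasts — a planted method confound the consistency rule correctly
rejects). Coupled genes add β × standardised(condition metric at their
window); rebound couplings are standardised over the non-circadian
conditions the rebound analysis uses. Twenty history-coupled genes carry an
opposite-signed rebound coupling and vice versa, populating the discordant
intersection cells.

Two generative constraints matter: coupled genes' baselines are anchored in
[7, 10] so the ±2β linear swing survives the TPM ≥ 0 clip, and coupling
windows are drawn from 3–12 h because the 1–2 h windows carry almost no
between-condition variance — a coupling planted there is unrecoverable by
construction (|r| plateaus well below 1 even with zero expression noise),
which would make it a defect of the planted truth, not of the analysis.

**What it does not emulate.** RNA-seq count overdispersion and library-size
effects (noise is Gaussian on log2 TPM), arousal thresholds, video-level
behaviour, fly-to-fly expression variability within a replicate, and any
real gene-gene correlation structure. Passing tests therefore demonstrate
that the statistics recover planted linear/threshold structure under
realistic behavioural variation — not that real brains contain such genes.

## Determinism and problem sizes

All randomness flows through explicit seeds (behaviour, truth assignment
and expression noise use distinct streams derived from the study seed);
regeneration and full pipeline reruns are byte-identical, and no output
file contains a timestamp. The test suite validates each statistical
primitive against an independent oracle (run-length scan for sleep calling,
exact integer hypergeometric tail sums for every 2×2 table with background
≤ 60, the definitional BH step-up, a brute-force consistency predicate on
10,000 random profiles, a naive O(n³) agglomeration) and measures
planted-truth recovery over 20 replicate simulations of the default
scenario; `scripts/acceptance.py` reports the same recovery quantities
averaged over ten replicate simulations.

## Known limitations

* `de_lite`'s Welch test at n = 3 has very few degrees of freedom; it is a
  synthetic-data stand-in, not a substitute for a proper count-model fit.
* The per-window BH family is one of two defensible readings; switching to
  the pooled family changes which genes pass at the margin.
* The wild-card rule (one directional call + cycling support suffices) is a
  documented interpretation; strict mode is provided because the original
  criterion is ambiguous.
* Fisher odds ratios are unstable when any 2×2 cell is 0 (reported as 0 or
  infinity by the stated convention); the p-value, not the odds ratio,
  carries the inference.
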