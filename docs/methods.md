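# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `fmpy`. It describes what the code computes and why the
defaults are what they are; every number quoted here is produced by the test
suite or by `scripts/acceptance.py`, not asserted from elsewhere.

## From zone events to turns

A tracker log is an ordered list of (time, zone) events. Analysis needs
turns, and a turn is only defined on entering a *different* arm, so the
pipeline first drops non-arm zones (centre, outside — only arm identity
matters), then merges consecutive re-entries into the same arm into a single
visit keeping the first timestamp (`collapse_visits`, idempotent). With
three arms in a declared counter-clockwise cyclic order, every transition
between distinct arms moves either one position along the order or one
against it; a `chirality` flag maps these onto L and R
(`visits_to_turns`). n collapsed visits give exactly max(0, n − 1) turns,
each stamped with the destination entry time.

The handedness convention is deliberately explicit configuration rather
than a baked-in constant: trackers report arm labels, not turn direction,
and no convention can be recovered from labels alone. Swapping chirality is
provably equivalent to mirroring the output (tested as a property), so all
mirror-invariant statistics — alternation/repetition percentages,
uncertainty measures, ACF of the cumulative sum up to sign — are convention-free;
per-tetragram tables are reproduced up to the L↔R relabelling.

## Tetragram statistics

Overlapping width-4, stride-1 windows of a T-turn sequence give
max(0, T − 3) tetragrams over the 16 possible values. Each tetragram's
share is reported as a percentage of the *window count*, not of raw turns:
only window counts sum to 100%, and the memoryless chance level remains
6.25% per tetragram. At T ≈ 1000 the two denominators differ by 0.3%, far
below between-subject spread, so this choice does not affect interpretation
of hour-long sessions. Sequences with fewer than 4 turns yield an all-zero
table flagged undefined (percentages NaN) rather than a division error.

Time-resolved strategy splits the session into `n_bins` equal bins (default
6, i.e. 10-minute bins of an hour; configurable for 5-minute human
sessions). Turns are assigned to bins by timestamp using half-open
intervals [start, end) with the final bin closed, and tetragram windows are
recomputed *within* each bin, never straddling a boundary — bins are thereby
independent and the binned tables re-composable. The *immediate* strategy
is the table over the first 10 minutes (`immediate_window = 600 s`,
half-open to coincide with bin 1 when bin duration is 600 s); the *global*
strategy is the whole-session table. Sessions shorter than the immediate
window degrade gracefully: immediate = global, with a warning.

## Uncertainty measures

For an n-gram distribution p the uncertainty is the Shannon form
L = −Σ pᵢ log₂ pᵢ (bits), with p = 0 terms contributing zero by continuity.
L_max = log₂(#outcomes) = n bits at order n, and 1 − L/L_max ∈ [0, 1]
measures departure from randomness (0 = uniform usage, 1 = a single
motif). Per-subject reports carry L1 and L3 (order-1 and order-3
uncertainties), the relative complement at tetragram order (1 − L₄ᵍʳᵃᵐ/4),
and the order information L₄ = L(tetragram) − L(trigram), the conditional
uncertainty of one turn given the preceding three.

Two estimator details. First, all distributions are plug-in estimates from
overlapping windows; no small-sample bias correction (Miller–Madow or
similar) is applied, keeping the estimator simple and matching how the
measures are conventionally reported for ~1000-turn sessions, where the
plug-in bias ((K−1)/(2N ln 2)) is ≈ 10⁻⁴ bits. Second, L₄ estimates the
trigram distribution from the *prefixes of the tetragram windows* (trigrams
of the sequence minus its last turn) rather than from all trigram windows.
The difference is one window out of ~n, but it makes L₄ an exact empirical
conditional entropy, so the bounds 0 ≤ L₄ ≤ 1 hold for every finite
sequence — the naive difference of independently-estimated entropies can
leave that interval on short inputs (a four-turn sequence "LLLR" would give
−1). A long iid fair sequence gives L₄ → 1 bit; strict alternation or
constant turning gives 0.

## Step encoding and the missing-data rule

Each tetragram carries a signed step length: left-dominant motifs negative,
right-dominant positive, repetitions at the extremes (LLLL → −8,
RRRR → +8) and alternations at ±1; the map is a bijection onto
{−8…−1, +1…+8} and is mirror-antisymmetric (code(mirror(t)) = −code(t)).
Zero is reserved for missing-data fill and is never a tetragram code.

The series ω(k) is built from consecutive **non-overlapping** blocks of
four turns among the first `max_entries` (default 1000, so 250 steps;
use 100 for human-scale sessions). Non-overlapping blocks are the only
windowing under which 1000 entries produce 250 time points; stride-1
overlapping encoding remains available behind `overlapping=True` for
exploration. Subjects short of the `target_steps` length (default 250) by
more than `max_missing` steps (default 10) are flagged excluded — a data
state carried through all outputs, never a silent drop; deficits of up to
and including 10 steps are zero-filled at the series end. The fill position
is a choice: only the *count* of missing steps is knowable, not their
positions. Zero-filled points participate in downstream ACF computation,
and `n_missing_filled` is reported so sensitive analyses can exclude
heavily filled subjects.

## Autocorrelation and confidence bands

The ACF estimator is the standard biased form: numerator Σ over the n − k
available lagged products, denominator Σ over all n squared deviations,
both centred on the full-series mean (no per-window re-centering). It
agrees with the textbook estimator in statsmodels to 1e−12 (tested). Lags
are 1-indexed; r(0) ≡ 1 is implicit and never counted. Constant series and
max_lag > n − 2 are rejected.

Memory is read from the ACF of the **cumulative sum** of steps over the
first 20 lags. Three 95% bands, all centred on zero:

- `naive`: ±1.96/√n, the white-noise band (half-width 0.1240 at n = 250) —
  the correct null band for "is this series white?";
- `large_lag_bartlett` (default): ±1.96·√((1 + 2Σ_{j<k} r(j)²)/n),
  Bartlett's large-lag standard error. It equals the naive band at lag 1
  and widens as low-order correlation accumulates, asking the stricter
  question "is r(k) surprising *given* the correlation already seen?";
- `printed_bartlett` (diagnostic): partitions the series into consecutive
  windows (width n//10, at least 10), computes Bartlett's
  homogeneity-of-variances statistic
  T = ((n−k)·ln σ_p² − Σ(nᵢ−1)·ln σᵢ²) / (1 + (1/(3(k−1)))(Σ 1/(nᵢ−1) − 1/(n−k)))
  with pooled variance σ_p² = Σ(nᵢ−1)σᵢ²/(n−k), and scales the naive band
  by σ_p/σ_total. This is *one* construction of a per-lag band from a
  statistic that natively tests variance homogeneity, exposed for
  exploration; no claim is made that it reconstructs any particular
  published band. The statistic itself (`bartlett_statistic`) is exact and
  matches scipy's implementation to 1e−12 (tested).

The summary statistic is the count of lags 1–20 outside the band. Behaviour
under the study conditions, measured across seeds by the test suite: an
alternation-biased walker (markov1, p_alternate = 0.75, 1000 turns → 250
steps) has a count whose **median is 18 of 20** under the default large-lag
band, with substantial spread (single draws range from single digits to 20);
against the naive white-noise band the same agents exceed 18 in ≥ 95% of
seeds. An iid agent's *step series* stays inside the naive band at the
nominal rate — the per-lag false-positive rate averages ≈ 0.046 over a
1000-seed Monte Carlo — but note that the cumulative sum of *any*
non-degenerate step series is a random walk and therefore itself shows slow
ACF decay (lag-1 ACF > 0.9 at n = 250); the walk analysis characterises the
persistence structure, while step-level ACF against the naive band is the
sharp test of memorylessness.

## Simulator

Agents: `iid` (P(R) = p_right), `markov1` (next turn differs from the
previous with probability p_alternate; alternation events are iid Bernoulli
by construction, so the turn-level alternation frequency is an unbiased
estimator of p_alternate — recovered within 2 pooled binomial SEs over
20 × 1000 turns in tests), and `markovk` (explicit history→P(R) table,
uniform fallback for unlisted histories). The first turn (first k turns for
order k) is uniform. All draws come from `numpy.random.default_rng(seed)`;
identical specs give byte-identical output.

Sessions place entries as a Poisson process: exponential inter-entry gaps
(memoryless locomotion, the simplest rate model for free exploration),
truncated at the session duration, or exactly `n_entries_target` entries
when a fixed count is wanted. Defaults emulate the study conditions:
3600 s at a 3.6 s mean gap ≈ 1000 entries (hour-long animal sessions);
300 s at a 7 s gap gives the tens of turns of 5-minute human sessions.
Timing and choice use independent seeded streams, and arm labels are laid
out so that turn inference recovers the agent's sequence exactly (tested
round trip). "Impairment" fixtures are expressed as p_alternate shifts
toward or below 0.5 — the simulator tests detectability of strategy changes,
not pharmacology.

What the simulator does *not* emulate: within-arm trajectories, freezing
bouts and other non-stationary locomotion, turn-time/choice coupling,
individual turn biases drifting over a session, or tracker artefacts
(dropped frames, zone flicker beyond same-arm re-entries). Passing tests
therefore validate the *analysis chain* on processes with known memory
structure; they do not certify any biological claim about real subjects.

## Group-level scope

The package computes per-subject metrics and exports tidy long-format
tables (subject, group, window, metric, value) with total turns carried as
the locomotor covariate. Mixed-model fitting, ANOVA and post-hoc tests are
deliberately out of scope — they are standard procedures best run in
dedicated statistical software on the exported tables.

## Numerical and edge-case choices

- Percentages sum to 100 within 1e−9 whenever any window exists; undefined
  tables (T < 4) carry NaN percentages and a `defined = False` flag.
- Probability vectors must sum to 1 within 1e−9; zero-probability outcomes
  contribute zero entropy by continuity.
- Exactly `max_missing` missing steps are retained and filled ("more than
  ten" excludes; ten does not).
- Bin assignment uses half-open intervals; a timestamp equal to the session
  duration joins the last bin.
- `encode_steps` silently truncates to `max_entries`; `apply_missing_rule`
  truncates surpluses to `target_length`.
- Excluded subjects propagate as flagged rows with NaN ACF metrics.
- Test problem sizes: 100,000-turn sequences for chance-level convergence,
  1000-seed Monte Carlo for the false-positive calibration, 20–40 seeds for
  across-seed robustness checks, exhaustive enumeration of all L/R
  sequences up to length 12 against the brute-force window oracle.
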