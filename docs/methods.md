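# Methods notes

This note records the models behind the synthetic generators, the
numerical conventions of each analysis stage, and the design choices
made where the underlying definitions were genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and timing conventions

Arena coordinates are in cm with the origin at the arena centre; the
32-cm square arena holds a 9-cm square shelter in one corner (centre
(−11.5, −11.5)). Time is in seconds from session start and all intervals
are half-open `[start, end)`. A looming bout is five consecutive looms,
each 500 ms of expansion at 80 deg/s (to 40 deg) plus a 250-ms hold —
750 ms per loom, 3.75 s per bout. Loom windows for the looms-to-escape
label are half-open `[(i−1)·0.75, i·0.75)`; a reaction time exactly on a
boundary belongs to the later loom.

## Synthetic arena sessions

The locomotion model is a four-state semi-Markov agent
(shelter / explore / arrest / escape):

* **Shelter** — small positional jitter with a gentle drift to the
  shelter centre (no teleporting, so no spurious speed transients).
* **Explore** — out-and-back excursions to a random target; the speed is
  a mean-reverting (OU) process with mean 8 cm/s, relaxation 0.5 s and
  sd 2.5 cm/s, clipped to `[0, mean + 3 sd]` so exploration can never
  mimic an escape sprint. Excursion targets are drawn so some bouts stay
  short of the 10-cm threat zone and some cross it.
* **Trigger** — a stimulus is logged at the first outward crossing of
  the 10-cm radius with ≥ 30 s since the previous onset, the same rule
  the analysis stage applies, so the generator log and the re-derived
  log agree exactly.
* **Escape** — with per-loom probability `escape_prob_per_loom` over the
  five looms; if any draw succeeds, the latency (true time of peak
  speed) is drawn from a shifted log-normal whose *median is a direct
  generator input* (wild-type preset 0.3 s, mutant preset 1.5 s), and
  the loom index is derived from the latency. The escape run is a
  straight line to the shelter with a raised-cosine speed bump whose
  width is set by the distance and drawn peak speed, so the true time
  of maximum speed — the quantity the reaction-time measurement
  estimates — is known exactly. During the hazard delay the agent
  slows to near zero (risk-assessment-like), which also produces the
  S_im < S_at signature on late-escape trials.
* **Arrest** — near-zero speed with residual jitter for 2–5 s, then a
  walk back capped below the 20-cm/s escape criterion (a "no-response"
  trial by construction).

Ground truth records per-frame state labels, per-trial response type,
true latency and peak speed, and per-bout exit episodes with flags for
"crossed the dilated shelter boundary" and "returned to the shelter",
matching the analysis stage's hysteresis convention.

What this generator does **not** emulate: pose-level kinematics (snout
and back-paw points are placed geometrically on the heading axis), wall
following, grooming, rearing, or history-dependent sensitisation beyond
a per-day multiplier on the exit rate. Passing recovery tests therefore
demonstrates correctness of the measurement chain, not realism of mouse
behaviour.

## Behaviour stage conventions

* Speed = frame-to-frame displacement rate smoothed with a centred
  moving mean over 83 ms, rounded to an odd frame count (5 frames at
  60 Hz); edges use shrinking windows.
* Escape = shelter return within 7 s of onset **and** peak smoothed
  speed ≥ 20 cm/s in `(onset, entry]`; reaction time = time of that
  maximum; shelter entry = first frame inside the undilated shelter
  square after onset.
* "Full-body" shelter exits are approximated by the centroid crossing
  the shelter boundary dilated by +2 cm, with re-entry at the undilated
  boundary (hysteresis), since a centroid trace cannot observe the full
  body.
* S_at = mean speed over onset ± 50 ms; S_im = mean over onset
  + [300, 800) ms; the categorisation SD is computed over the pooled
  S_at values of all trials of the same genotype.
* Occupancy metrics use the first 10 min of a session, a 7-cm central
  disc and a 14-cm edge radius; shorter sessions are analysed in full
  with a warning.
* Cohort aggregation averages across escape trials within animal, then
  across animals within genotype; animals with zero escapes are excluded
  from reaction-time/vigour averages but retained in trial counts.

## In-vivo stage

* **CSD** — negative second spatial difference of the trial-averaged
  flash-locked LFP with one-channel Vaknin-style edge padding. The
  inflection depth is the midpoint of the strongest
  source-above/sink-below adjacent channel pair of the time-averaged CSD
  in the 0–100 ms post-flash window (configurable); edge channels are
  excluded from the search because padding biases them. A
  sink-above/source-below profile is reported but flagged
  polarity-inverted; no transition leaves the depth undefined. The
  synthetic LFP is built by discrete double integration of a template
  CSD aligned so the estimator recovers the template exactly in the
  noiseless case.
* **Responsiveness** — a ZETA-style statistic: the maximal absolute
  deviation of the ECDF of event-relative spike times from uniform over
  the response window, with a resampling null (surrogate event onsets
  drawn uniformly over the baseline span; a circular-shift permutation
  variant is provided). p = (1 + #{null ≥ obs})/(R + 1) with R = 100 by
  default. Note the circular-shift variant is only valid for aperiodic
  event schedules; the recording protocol's pseudorandom inter-bout
  gaps satisfy this.
* **Clustering** — k-means over k = 2..10; the Calinski–Harabasz
  "elbow" is operationalised as the smallest k whose CH index is within
  10% of the maximum. Identical rows give k = 1.
* **STA** — accumulated per frame lag over a 0–250 ms peri-spike window
  (configurable); centre = maximum-variance pixel across lags; crop
  160 × 160 clipped to the stimulus; SNR uses the squared centre value
  at the best lag over the variance of a 5-pixel border; polarity =
  sign of the centre-pixel mean; radius = half-peak half-width along
  the centre row. The synthetic checker stimulus is unshifted binary
  white noise, which makes STA recovery analytically clean; the
  physical stimulus's sub-checker grid shifts are not modelled.
* **Direction tuning** — per-direction trial-mean rates divided by the
  30-s pre-stimulus baseline rate; D_np is the direction 180° from the
  preferred; a zero denominator leaves the DSI undefined rather than 0.
* **Loom metrics** — per-loom PSTHs in 16.7-ms bins; mean/max/time-to-
  peak averaged over the five looms, ties broken to the earliest bin.
* **Pupil** — least-squares ellipse fit; "diameter" is the major-axis
  length. Motion is a two-class 1-D k-means on frame-difference energy;
  a repetition counts as running when > 50% of its frames are moving.

## Slice stage

* Spike detector: upward crossing of dV/dt ≥ 20 V/s confirmed by the
  voltage exceeding 0 mV within 2 ms, 1-ms refractory. The threshold
  point for kinetics is the dV/dt crossing.
* Passive properties: RMP from the pre-step baseline; R_in from the
  least-squares slope of steady-state (final 200 ms) ΔV vs I over the
  hyperpolarising steps and rest; τ from a single-exponential fit of the
  first 300 ms of the −10/−20 pA step onset excluding the first 2 ms;
  C_m = τ/R_in (GΩ·pF = ms, so the identity is unit-exact).
* DTX subtraction: protocol repeats averaged per condition, post-drug
  subtracted from baseline, each step summarised by the maximal signed
  deflection during the 1-s step in either direction, measured on the
  subtracted trace only, and divided by C_m for density.
* sEPSC detection: matched filter with a bi-exponential template
  (defaults rise 1.5 ms / decay 10 ms, config-exposed), threshold 3×
  the MAD-based noise sd; per-event amplitude against a local baseline,
  10–90% rise, single-exponential decay fit.
* Baseline-activity classification: exact 1-D two-means split of
  baseline rates; the high class is putative inhibitory; a guard treats
  cohorts whose centroids differ by < 10 Hz as a single low class.

### Synthetic membrane model

An exponential integrate-and-fire neuron with the regenerative term
capped (exponent argument ≤ 8) so the upstroke has a finite peak dV/dt
(~180 V/s), a fast fixed repolarising conductance that produces a full
waveform (overshoot ~+28 mV, downswing, AHP at the reset level), and one
non-inactivating K⁺ conductance g·n(t)^k with Boltzmann steady state
(default half −25 mV, slope 4 mV), first-order kinetics (τ = 20 ms) and
gate cooperativity k (default 2). Intrinsic current noise is diffusive
(sd per √ms), so spike-count variability is timestep-independent.
Integration uses forward Euler at 0.05 ms (a numba kernel); timesteps
above 0.1 ms are rejected.

The excitability genotype presets (`WT_CELL`, `MUTANT_CELL`) use k = 3
with a large maximal conductance: the gate charges only during spikes,
so the opposing current grows supralinearly with firing rate. This
yields the intended phenotype — unchanged rheobase and low-current
firing, suppressed firing at large current injections — which a single
linear gate cannot produce (its suppression is roughly proportional
across currents). Voltage-clamp sweeps return the closed-form ionic
current with the gate relaxing from its holding value, so subtracting a
zero-conductance set recovers the gated I–V curve exactly; steps below
the −60 mV hold peak at onset, and the ground-truth "deflection" curve
accounts for this.

Passive-property ground truth is computed from the model itself (the
subthreshold steady-state V–I relation and its slope), not from the
nominal leak parameters, because the K⁺ conductance contributes a small
subthreshold conductance; recovery tests compare against this honest
truth.

## Proteomics stage

* LM renormalisation: one additive offset per sample in log10 space,
  fitted with damped least squares (`scipy.optimize.least_squares`,
  `method="lm"`) against row medians (the row anchor; the choice of
  anchor is ours, the upstream definition being silent), offsets
  constrained to sum to zero. Samples > 90% missing are excluded with a
  warning; missing values stay missing throughout (no imputation).
* Batch correction follows the parametric ComBat algorithm: full-design
  standardisation (batch intercepts weighted by batch size plus
  reference-coded group covariates, so group means are preserved),
  normal/inverse-gamma empirical-Bayes shrinkage of per-batch location
  and scale, iterated to convergence. The test suite checks agreement
  with `sva::ComBat` (via Rscript) to < 0.01 on a fixture.
* Best-flyer quantification: member peptidoform profiles are mean-
  centred and averaged per sample (unique-only when ≥ 3 unique), then
  the profile is shifted so its mean equals the mean intensity of the
  group's most intense peptidoform. Phosphopeptidoforms (and their
  unmodified counterparts) are excluded.
* Moderated t: empirical-Bayes variance shrinkage with the prior
  (d₀, s₀²) estimated by method of moments on log s² (polygamma
  inversion); p from t on d + d₀ df, BH-adjusted. The implementation
  matches R limma's `eBayes` to machine precision on fixtures, which
  serves as the independent oracle. The "regulated" flag requires
  significance **and** |log2 FC| above the 95th percentile of
  |log2(control_i / mean(controls))| — our operationalisation of the
  control-to-average-control rule, exposed as configuration
  (`p_threshold`, `fc_threshold`, `fc_percentile`) because the verbal
  rule is ambiguous.

The synthetic peptidoform matrix is additive in log space (protein
level + peptidoform offset + loading + batch + noise) with missingness
at random. It does not emulate intensity-dependent missingness,
interference, or shared (razor) peptides across groups, so calibration
results speak to the statistical chain, not to raw-data pathologies.

## Statistics layer

Two-sample comparisons route on Shapiro–Wilk (each sample) and Levene
(across samples) at α = 0.05: normal → (paired) t test; otherwise
Wilcoxon signed-rank / rank-sum. Two-tailed throughout; fewer than 3
observations defaults to the rank family with a warning. The chi-square
test of independence is plain Pearson without Yates correction
(config-switchable), which reproduces the brute-force Σ(O−E)²/E formula
exactly. Repeated-measures/mixed ANOVA uses pingouin with
Greenhouse–Geisser correction when sphericity fails; pairwise follow-ups
use Bonferroni-corrected paired tests or Tukey's HSD.

## Problem sizes and test design

The test and acceptance suites use scaled study conditions chosen once:
20 sessions per genotype preset for behaviour recovery; 50 units / 6,000
checker frames for receptive-field recovery; 500 null units (100
resamples each) for responsiveness calibration; 20 random cells for
passive-property recovery; 8–10 cells per cohort for the F–I genotype
property (Bonferroni-corrected rank-sum across the 23 step currents,
mirroring a multiple-comparison analysis across injection levels); and
300–400 proteins at n = 6/group for proteomics calibration. The
null-calibration property for the routed tests runs 10,000 simulations.

## Known limitations

* The closed-loop emulation assumes the online tracker and the offline
  centroid agree; real sessions can disagree near the trigger radius.
* The ZETA-style test is a re-implementation of the published idea, not
  the reference code; its null is calibrated by construction and by the
  uniformity test, but numerical p-values will differ from other
  implementations.
* File support is plain CSV/TSV, the HDF5 sweep container and YAML
  config; proprietary acquisition formats are out of scope.
* The supplementary per-figure tables of the originating study are
  journal downloads without a public accession; the reproduction test
  for those cohort numbers can only run when the user places the tables
  under `data/supplementary/`.
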