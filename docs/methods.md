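# Methods

This note documents the models, conventions and numerical choices behind
`weanlab`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## 1. Lung–ventilator model

The simulator integrates a single-compartment equation of motion,

    Paw(t) + Pmus(t) = Ers·V(t) + Rphys·V̇(t) + PEEP_set + ΔP_ETT(V̇),

with volume V referenced to the relaxed end-expiratory volume at the set
PEEP. Airway pressure is defined machine-side of the endotracheal tube
(as measured at the proximal tube tip in practice), so the tube's
nonlinear drop ΔP_ETT separates Paw from tracheal pressure in both
directions of flow.

**Intrinsic PEEP by gas trapping.** Rather than adding a constant PEEPi
term to the ODE (which would contradict a zero-flow, open-airway rest
state), expiration is clamped once volume reaches the trapped volume
`V_trap = PEEPi/Ers`. End-expiratory alveolar pressure then sits at
`PEEP + PEEPi`, inspiratory flow cannot start until Pmus exceeds PEEPi,
and the Pes deflection between effort onset and first zero flow measures
PEEPi — the same signature the analysis chain relies on in real
recordings.

**Muscle pressure profile.** Within each neural cycle (period
60/RR s): parabolic rise `A·(1 − (1 − t/Ti)²)` to the amplitude A over
the neural inspiratory time Ti, then exponential relaxation with time
constant Ti/4. Continuous, non-negative, zero at onset. The residual at
cycle end (~0.1% of A for the defaults) is the only discontinuity.

**Ventilator state machine.**

* *Exhale*: Paw relaxes first-order to PEEP (τ = 50 ms); passive
  expiration against tube + airway resistance, trapping clamp active.
* *Trigger*: when patient flow demand exceeds `trigger_flow`
  (default 0.033 l/s ≈ 2 l/min) the demand phase starts: for
  `valve_delay` (default 100 ms) the inspiratory valve stays closed and
  the patient draws from the circuit, dipping Paw below PEEP by
  `trigger_resistance·Q` (default 10 cmH2O/(l/s), a free parameter set so
  simulated DPtrig ≈ −1 to −2 cmH2O). This produces the DPtrig/DTtrig
  phenomenology the trigger metrics measure.
* *Insufflation*: first-order pressurisation (τ = `rise_time_constant`,
  default 50 ms — "shortest rising time") toward `PEEP + PS` in PS mode
  or `PEEP + atc_fraction·ΔP_ETT(Q)` in ATC mode (inspiratory
  compensation only; expiratory compensation is never applied). Cycling
  off when flow falls to `cycle_off_fraction` (default 25%) of the
  running inspiratory peak, with a 0.15 s minimum and 3 s maximum.
* *Occlusion*: at scheduled neural-effort onsets the airway is closed
  for 0.3 s: flow ≡ 0 and `Paw(t) = Paw(t₀) − [Pmus(t) − Pmus(t₀)]`
  exactly. Occlusions are drawn uniformly over eligible cycles in the
  final two minutes, never adjacent.

**Flow solution and integration.** Each 2 kHz step solves the monotone
scalar equation `R·Q + ΔP_ETT(Q) = Paw + Pmus − Ers·V − PEEP` by
safeguarded Newton (the left side is strictly increasing in Q).
Explicit first-order stepping at 2 kHz is stable for the clinical
parameter range (mechanical time constants ≳ 0.2 s); all channels are
then decimated to the 200 Hz recording rate by a 10-sample boxcar
average. Ground-truth Pmus and volume go through the *identical*
decimation, so the linear identities (chest wall, occlusion contract)
hold sample-wise on the emitted 200 Hz grid.

**Esophageal pressure.** `Pes = Pes0 + Ecw·V − Pmus` (chest-wall
identity), plus optional white noise (default SD 0.2 cmH2O) and a
cardiac artifact (1.2 Hz sinusoid, default amplitude 0.5 cmH2O).

## 2. Tube model

Default turbulent (Blasius-type) law `ΔP = k·|Q|^1.75·sign(Q)` with
`k = C·L/d^4.75` (L cm, d mm). C is calibrated so a 7.5 mm × 29 cm tube
drops 6.5 cmH2O at 1 l/s, inside the published 5–8 cmH2O range for adult
tubes; the exact coefficients of any specific commercial tube are not
publicly tabulated, so this is a documented calibration, not a vendor
value. Rohrer coefficients per ID are least-squares fits of the Blasius
curve over 0–1.5 l/s. Default length 29 cm when unspecified.

The excess-support index normalises the summed delivered pressure above
PEEP by the summed ideal compensating pressure over inspiratory samples
(a ratio, reported in %). It is therefore invariant under sampling-rate
refinement on smooth signals.

## 3. Effort analysis conventions

* **Breath definition**: inspiration starts at the upward flow zero
  crossing preceding a sustained (≥ 80 ms) excursion above +0.05 l/s and
  ends at the downward zero crossing (hysteresis −0.05 l/s). The
  thresholds trade noise robustness against sensitivity at 200 Hz.
* **Effort onset**: the last sample at which smoothed Pes (75 ms boxcar)
  still sits within 0.05 cmH2O of its trailing 0.25 s baseline before
  the decline that reaches 0.5 cmH2O below baseline and leads into the
  flow onset. The short baseline matters: longer windows lag the passive
  expiratory Pes decay and fire early. Without a detectable decline the
  effort onset defaults to the flow onset.
* **Campbell window**: effort onset → end of inspiratory flow. The
  pre-flow (intrinsic-PEEP) segment sweeps no volume but raises Pmus at
  flow onset, so the PEEPi burden is counted in total WOB. The
  elastic/resistive split uses the chord between the two zero-flow
  points; elastic + resistive = total exactly by construction. Negative
  per-breath totals (possible under heavy noise) are floored at zero and
  flagged.
* **Summaries**: per-breath medians; powers are component medians ×
  respiratory rate, so total power = elastic + resistive power by
  construction. P0.1 is the mean over detected occlusions, reported
  positive; an absent maneuver yields an absent value, never zero.
* **Ecw**: reciprocal convention `Ecw = 1/(0.04·VC_pred)` with the
  spirometric reference equations `6.10·h − 0.028·a − 4.65` (men) and
  `4.66·h − 0.026·a − 3.28` (women), height in m, age in years. The
  literal alternative (per-breath ΔPes divided by 4% VC) is selectable.
* **Breaths overlapping occlusions** are discarded (0.1 s before the
  onset to 0.5 s after release — the occluded effort keeps running after
  the valve reopens and would otherwise count as a truncated breath).
  The opening breath of a record is skipped when it starts
  mid-inspiration; its effort onset cannot be located without Pes
  history.

## 4. EIT conventions

Row 0 of stored matrices is the most ventral row (enforced at
ingestion). Tidal image: mean end-inspiratory minus end-expiratory pixel
value over breaths, negatives clamped and counted. Lung ROI: pixels ≥
20% of the maximum tidal amplitude (configurable). Center of ventilation
is the ΔZ-weighted centroid of normalized row position, in % (50 =
mid-plane); the anterior-to-posterior ratio splits the *whole* image at
the row midline; the GI index normalises absolute deviations from the
ROI *median* by the ROI total; the coefficient of variation uses the
population (n) denominator over ROI pixels. All four are invariant to
global rescaling of ΔZ. These definitions follow common EIT literature
conventions; vendors differ in details, so absolute comparability with
any specific device toolchain is not claimed.

## 5. Crossover statistics

With period-ordered differences `d = y₁ − y₂` per patient and sequence
groups AB/BA: the treatment test is the Wilcoxon signed-rank on
within-patient (ATC − PS) differences; under a significant period effect
the period-adjusted variant compares d/2 between sequence groups
(rank-sum); the period test compares d with −d between groups; carryover
(treatment×period interaction) compares subject totals `y₁ + y₂`
between groups; under significant carryover the fallback compares first
periods only. The decision rule (adjust for period if significant; first
period only if interaction significant) is returned as an explicit
trace. Signed-rank p-values are exact by dynamic-programming enumeration
of the null for n ≤ 25 untied pairs, else a normal approximation with
tie and continuity corrections. Zero differences are dropped before
ranking. Quartiles use linear interpolation at positions 1 + (n−1)p, the
convention validated against the published patient table. No
multiple-comparison adjustment is applied anywhere.

Sample size for two means: `n = ceil(2σ²(z₁₋α/₂ + z_pow)²/δ²)`.

## 6. Cohort generator defaults (calibration)

Patients are drawn once per cohort: sex 3:1 male; age N(63, 12²) within
25–88; height N(1.75/1.62, 0.06²) by sex; ETT ID ∈ {7.0…8.5} mm;
Ers log-normal around 25 cmH2O/l (12–50); Rphys log-normal around
8 cmH2O/(l/s); PEEPi log-normal around 1 cmH2O (0.1–4); effort amplitude
U(8, 12) cmH2O; neural rate U(22, 30) /min; neural Ti N(0.9, 0.08²)
capped below 45% of the cycle. Chest-wall elastance is computed from the
drawn demographics through the predicted-VC equation — the same path the
measurement chain uses — and lung elastance is Ers − Ecw. These are
magnitude calibrations chosen so that simulated breathing-pattern and
effort metrics land in the clinically reported ranges; they are not
measured study values.

Arms: PS 7/PEEP 4 vs ATC 100%/PEEP 4, randomized sequence, both arms per
patient. The ATC arm's effort amplitude is multiplied by 1.35 by
default: an idealized proportional controller compensates only the tube,
so reproducing the observed higher patient effort under ATC requires a
drive increase; 1.35 matches the ratio of the reported median powers.
EIT series use one ventro-dorsal gradient per patient
(N(0.05, 0.1²), clipped), identical in both arms — ventilation
distribution is simulated as mode-independent.

Default record length is 150 s analysed over the final 120 s (the
last-two-minutes convention); the acceptance and property suites use
60–150 s records, which already contain 20–50 breaths per record.

## 7. What the synthetic data does not emulate

One homogeneous compartment (no regional mechanics, so EIT maps are
generated independently of the pressure–flow simulation); no leaks,
humidifier or circuit compliance; no expiratory muscle activity or
gastric pressure (none is corrected for in the analysis either); no
breath-to-breath variability of drive within a record beyond noise; an
idealized ATC control law (real devices deliver a few cmH2O of floor
assistance and have internal limits that are not modeled); no real
ventilator firmware quirks. Passing tests therefore demonstrate
correctness of the *measurement chain* under the stated model, not
fidelity of any specific ventilator's behavior, and real-data
performance of the detectors (effort onset, occlusion detection) beyond
the modeled noise levels is not established.

## 8. Numerical notes

* Energy conversion fixed at 0.0980665 J per cmH2O·l.
* Trapezoid integration for all areas; the Campbell areas equal a
  polygon (shoelace) evaluation of the sampled loop to machine
  precision, which the suite checks on >100 simulated breaths.
* Degenerate inputs: apneic records segment to an empty list (not an
  error); constant-input correlations and all-zero tidal images raise;
  zero-difference Wilcoxon returns p = 1 with a flag; missing Pes makes
  effort metrics unavailable but leaves flow/Paw analyses intact.
* All randomness flows from explicit integer seeds; identical
  inputs + seed give bit-identical records, cohorts and reports.
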