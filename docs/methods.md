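# Methods

This note documents the models, numerical schemes, calibrations and design
decisions behind `cardiolab`, and states what the desk-scale substitutions
can and cannot show.

## Myocyte electrophysiology

The cell model is the ten Tusscher–Panfilov (2006) human ventricular
formulation: twelve sarcolemmal currents, three-compartment calcium handling
(cytosol, subspace, SR with CICR release gating), and Hodgkin–Huxley gating.
All base parameters keep their published values except

* G<sub>Ks</sub> = 0.392 × 1.3 = 0.5096 mS/µF for endocardial and
  epicardial cells, 0.073 mS/µF for midmyocardial cells (the study's stated
  overrides; note the mid value is below the base model's 0.098), and
* I<sub>K1</sub>, replaced per mutation condition (below).

Transient-outward current keeps the base model's transmural pattern
(G<sub>to</sub> 0.073 endo, 0.294 mid/epi, with endo-specific s-gate
kinetics).

### The three I_K1 formulations

The mutation-condition current–voltage relations are rational/quadratic fits
in the driving force x = V − E_K:

* WT: I_K1 = 0.24731·x / (0.86426 + e^{0.0904·x}) − 0.06519
* WT/E299V: I_K1 = 0.11905·(x + 2.4) / (0.04092 + e^{0.01732·x}) − 0.36212
* E299V: I_K1 = 0.06634·(x + 6.5) − 2.44009×10⁻⁴·x² − 0.51383

**Grouping decision.** The source typography does not disambiguate whether
the trailing constant of each expression sits inside the exponent or is an
additive offset. We adopted the consistent reading above (additive offset,
matching the E299V quadratic's explicit trailing constant) after a grouping
calibration: under it the heterozygous formulation's simulated peak current
(2.23 pA/pF) and APDs (122.9/125.0/119.0 ms endo/mid/epi) and the
endocardial alternans behaviour match the reported phenotype closely,
whereas the in-exponent reading gives a heterozygous peak of 3.7 pA/pF and
~40-ms-shorter APDs. The in-exponent variants remain available
(`IK1_WT_FIT_A`, `IK1_HET_FIT_A`), as does the base model's native
rectifier (`IK1_NATIVE`).

Two consequences of using the printed coefficient sets verbatim are
documented rather than patched:

* the WT fit's maximum over the physiological driving-force range is
  ~0.72 pA/pF under any grouping — well below the 1.9 pA/pF the study
  reports for WT, a value that matches the *native* ten Tusscher rectifier
  (1.84 pA/pF simulated). We keep the printed WT fit because it, not the
  native rectifier, reproduces the reported WT APDs and alternans onsets;
* at V = E_K the WT expression carries its small offset (−0.065 pA/pF)
  rather than vanishing exactly.

With the printed mid-cell G<sub>Ks</sub> = 0.073 mS/µF the WT mid APD is
~435 ms (reported: 390 ms); a sensitivity scan shows ≈0.146 mS/µF would
reproduce 390 ms, but no such value appears in the source, so the printed
value stands. A corollary: the WT mid cell cannot hold 1:1 capture at
BCL ≤ ~420 ms (its APD exceeds the cycle length), so its restitution curve
truncates instead of showing an alternans onset.

### Numerics

Operator-split fixed-step integration at dt = 0.02 ms (configurable):
Rush–Larsen exponential updates for the twelve voltage gates (and the
calcium-dependent f<sub>Cass</sub> gate), forward Euler for V, the ionic
concentrations and the SR release gate. Voltage-dependent gate steady
states/time constants, the Rush–Larsen factors and the nonlinear current
prefactors are tabulated on a 0.05 mV grid with linear interpolation; the
I_K1 variants are tabulated in driving force. An untabulated right-hand
side (`ionic_cell.rhs`) backs reference integrations: the fixed-step
solution agrees with an LSODA dense solution (rtol 10⁻⁸) to < 1 ms in APD
at production dt (verified in the oracle suite), and the tables contribute
< 0.1 ms.

The stimulus is a 1-ms, −52 pA/pF square pulse. Single-cell steady state is
approximated by 50 paced beats at the protocol BCL (the slow Na⁺/K⁺
concentration drift changes APD by only a few ms between 20 and 200 beats;
the remaining drift is far smaller than the comparison tolerances).

### APD and protocols

APD is APD90: from the maximum-upstroke-velocity time to the interpolated
crossing of 90% repolarization toward the **pre-stimulus** diastolic
potential. Dynamic restitution paces each BCL for 30 equilibration + 8
measured beats, descending in 10-ms steps from 400 ms and carrying the
state across levels. Alternans is flagged when ≥ 4 consecutive APDs
alternate in sign with |ΔAPD| > 2 ms; the onset is the largest flagged BCL.
A loss of capture or of full repolarization truncates the curve (flagged,
not an error of the scan).

**Scan floor.** The scan stops at BCL 200 ms — the range over which the
wild-type comparison lives (WT blocks near 230 ms). The mutant cells hold
1:1 capture far below that, and like every model of this family they
eventually steepen and alternate near BCL ~110 ms; the study's mutant
cells are reported stable with restitution slope < 1, which pins its scan
range to the WT-relevant window. Slopes are central differences d(APD)/d(DI)
on the per-BCL mean curve (cross-checked against a cubic-spline derivative).

## Myofilament mechanics

A Rice-type approximate model: nonpermissive/permissive regulatory units
(N ↔ P) gate a three-state cross-bridge cycle (P → XB_PreR → XB_PostR, with
ATP-consuming detachment XB_PostR → P at rate g_xb). The N→P rate carries
the cooperative troponin factor (TCa)^{+7.5} and the reverse (TCa)^{−7.5},
implemented as the smooth saturating permissivity
√(1/(1+(perm50/TCa)^15)) with the inverse capped at 100. Rates (ms⁻¹):
f_app 0.5, g_app 0.07, h_f 2.0, h_b 0.4, g_xb 0.07, k_np 0.5, k_pn 0.05,
perm50 0.5.

Troponin calcium binding uses k_on = 50 mM⁻¹ms⁻¹ with an off-rate that
interpolates between 0.03 ms⁻¹ (no bound cross-bridges; apparent Kd
0.6 µM) and 0.0125 ms⁻¹ (full cross-bridge feedback; Kd 0.25 µM). These
off-rates are a deliberate adaptation: the ionic model's transients span
~0.2 µM (pure mutant) to ~1.1 µM (WT) systolic, and this window places the
cooperative switch in its graded range — WT near saturation, heterozygous
partially activated, pure mutant essentially silent — while keeping the
~0.1 µM diastolic level below the deactivation point so every twitch
relaxes (no latch-up).

Operation is isosarcometric at SL = 2.2 µm (the coupling is one-way), so
the mean-strain ODEs relax to their fixed point (0, x₀ = 0.007 µm) and
normalized force is F = SOVF_thick(SL)·(XB_PreR·x_PreR + XB_PostR·x_PostR)
/(x₀·XB_PostR^max), equal to 1 under optimal conditions (saturating
calcium, full single overlap at SL ≈ 2.3 µm, steady cycling). ATP turnover
is the beat-averaged detachment flux g_xb·XB_PostR, reported s⁻¹. Numerics:
exact two-state exponential update for N↔P (stiff at low calcium), Euler
for the cycle and strains, exact exponential for TCa; both substeps
conserve the fraction sum to round-off.

## Tissue

Monodomain reaction–diffusion with explicit second-order finite differences,
no-flux (mirror) boundaries, reaction–diffusion operator splitting at
dt = 0.02 ms and Δx = 0.025 cm (stability asserted before every run). With
D = 0 the scheme reduces *exactly* to independent single cells (the oracle
suite asserts < 10⁻⁶ mV deviation). The diffusion coefficient is calibrated
once so a WT planar wave on this grid conducts at 70 cm/s
(D ≈ 1.30×10⁻³ cm²/ms) and is then frozen across conditions; CV follows
√D scaling (ratio test 2.00 ± 5% on a refined grid) and converges under
grid refinement.

Geometries: a 1.5-cm transmural cable (2-mm endocardial and epicardial
shells, midmyocardium between) stimulated simultaneously along the whole
endocardial shell — emulating distributed Purkinje delivery, which is why
activation times barely differ between conditions; EAT is the −40 mV
upstroke crossing, EDT the 90% repolarization toward the pre-beat diastolic
potential; max EAT − min EAT and max EDT − min EAT serve as QRS and QT
surrogates. 2D sheets support cross-field S1–S2 spiral induction (failure
to induce is a recorded outcome, not an error).

**Reentry at desk scale.** Sustained functional reentry of a wild-type wave
(wavelength ≈ CV × APD ≈ 21 cm) cannot fit any desk-scale sheet, so
wavelength comparisons use the classic anatomical-reentry preparation: a
25-cm 1D ring on which a unidirectional wave (initiated by a transient
retrograde block) circulates indefinitely for all three conditions.
Wavelength is measured two independent ways — excited arc length
(V > −40 mV) and local CV × local APD at a probe — which agree within a few
percent; orderings across conditions (WT 14.8 > WT/E299V 6.3 >
E299V 3.3 cm at 2.5 s) mirror the wavelength shortening that stabilizes
reentry in the mutant. The 2D spiral machinery is exercised at reduced
scale in the test suite; a full mutant spiral study is feasible but slow on
one CPU.

## Circulation

Eight compartments (LV, LA, RV, RA, systemic artery/vein, pulmonary
artery/vein) with diode valves at the ventricular ports. Vascular and
atrial compartments are passive compliances (P = V/C); the ventricles are
varying elastances P = E(t)·(V − V₀). Default compliances (mL/mmHg):
SA 1.6, SV 60, PA 4, PV 12, LA = RA 15; resistances (mmHg·ms/mL): valves
5–8, systemic 1000, venous 30, pulmonary 100; E ranges 0.08–2.5 (LV) and
0.045–0.6 (RV) mmHg/mL before calibration. Explicit Euler at 0.25 ms;
every flow leaves one compartment and enters exactly one other, so total
blood volume is conserved to round-off.

**Tension → elastance.** E(t) = E_min + (E_max − E_min)·a(t), where a(t) is
the normalized force passed through an asymmetric first-order lag: rise
time constant 100 ms (isovolumic pressure development in the human LV takes
on the order of 0.1 s), fall 25 ms (rapid relaxation preserves diastolic
filling). The lag is the surrogate's stand-in for organ-level mechanics:
it makes brief mutant twitches disproportionately weak at the chamber
level, which is what the full finite-element ventricle shows. F_ref is
frozen at the wild-type calibration.

**Calibration.** A one-time two-knob fixed point adjusts total stressed
volume (through the venous reservoir) and E_max,LV so the WT sinus run at
100 bpm hits EDV = SV/EF = 109 mL and ESV = 50 mL (targets: SV 59 mL,
EF 54%); everything is then frozen and only the force waveform changes
between conditions. Achieved WT point: SV 54.2 mL, EF 51.7% (−8%/−4%).
Metrics come from the final settled beat (stroke-volume drift below 1%
with a 0.1 mL floor — near-zero-output runs redistribute volume on a
~minute timescale and never meet a purely relative criterion); stroke work
is the shoelace area of the PV loop, cross-checked against the
time-parametrized −∮P dV within 0.5%.

**Known limitation (documented, not patched).** With the circulation frozen,
SV, EF, SW, CO, peak LV pressure and the beat-averaged ATP rate all order
strictly WT > WT/E299V > E299V and the loops shift right — but the ratio
SW/ATP *rises* for the heterozygote instead of falling. A 0D elastance
chamber converts even a weak activation into stroke work efficiently, while
the heterozygous myofilament's ATP flux collapses faster than its force
(partial, brief activation), so stroke work falls more slowly than ATP.
Reproducing the organ-level efficiency loss would require a contraction
model with afterload-dependent internal losses, which is outside this
package's 0D scope.

## Synthetic inputs and what the tests show

`scenarios.SyntheticCaTransient` generates periodic double-exponential
calcium transients (baseline, amplitude, time-to-peak, decay constant;
time-to-peak must lie below the decay constant for the pulse family to peak
there). They emulate the amplitude and coarse time course of myocyte
transients but none of their rate dependence, SR-load memory or subspace
kinetics — so myofilament tests driven by them demonstrate the
force model's input–output behaviour (monotonicity in amplitude,
relaxation, conservation), not calcium-handling physiology. Conclusions
about the mutation itself always run the full ionic model.

The catalogue (`cardiolab list-scenarios`) covers every experiment of the
study — 9 condition × cell-type sinus runs, 3 restitution scans, 3 cable
runs, 3 reentry runs, 3 pump runs — each with a reduced-duration variant
(e.g. 2.5 s instead of 10 s reentry) used by the test suite; acceptance
computations use the full single-cell protocols. Problem sizes throughout
(50-beat steady states, 400→200 ms scans, 25-cm rings at Δx = 0.025 cm,
25-beat circulation runs) were chosen as the smallest at which the measured
quantities are protocol-converged (APD drift of a few ms, CV calibrated on
the production grid, settled stroke volume).

## Determinism

There is no randomness anywhere in the pipeline: identical configurations
reproduce identical traces and reports (asserted in the test suite). The
scenario `seed` field exists for forward compatibility of randomized
placements and is currently inert.
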