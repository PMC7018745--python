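# Methods

This note documents the models behind `spinalgaba`, the provenance and
meaning of every tunable constant, what the synthetic generators do and
do not emulate, and the numerical and design choices made where the
problem left them open.

## Receptor gating model

The GABA_A channel is reduced to three states,

    C0  <-k1[GABA]/k2->  C1  <-k3/k4->  O,

an unbound closed state, a bound closed state and an open state, with
mass-action kinetics and a deterministic (mean-field) interpretation:
the state variables are occupancy fractions summing to one. Desensitized
states are deliberately omitted — the scheme is the smallest one able to
reproduce event rise/decay times, peak open probability and steady-state
GABA sensitivity simultaneously; adding states would be unconstrained by
those observables.

The synaptic transmitter transient is a single exponential,
[GABA](t) = 0.63 mM · e^(−t/1 ms). Unit convention: k1 is second-order
(mM⁻¹·ms⁻¹) and always multiplies a concentration in mM; k2–k4 are
ms⁻¹. Rate-constant tables in this field often print all four in ms⁻¹;
the binding rate only makes dimensional sense per concentration, so the
second-order reading is asserted here and used consistently.

Presets (ms⁻¹, k1 per mM): control/sham 40, 0.8, 1, 0.15 and
nerve-injury/PNI 11.2, 0.8, 0.43, 0.06. The injury preset has ~3.4-fold
lower GABA affinity (steady-state EC50 8.75 µM vs 2.61 µM, closed form
k2·k4/(k1·(k3+k4))) and slower closing, reproducing the slower mIPSC
decay after injury.

Useful closed forms, each verified against the ODE in the tests:

- steady-state open fraction O(G) = k1·G·k3 / (k2·k4 + k1·G·(k3+k4));
  saturating limit k3/(k3+k4) (0.870 for control);
- post-transmitter decay: once [GABA] ≈ 0 the C1/O pair relaxes with the
  slow root of λ² + (k2+k3+k4)λ + k2·k4 = 0, i.e. 15.7 ms (control) and
  26.1 ms (injury).

### Event summaries

`summarize_event` reports the peak open fraction, 10–90% rise time from
threshold crossings, and a decay constant from a zero-offset
single-exponential fit between the peak and the last sample above 5% of
it. The fitted decay (16.18 ms for the control preset) sits slightly
above the slow eigenvalue (15.72 ms) because the early window still
contains the fast mode; both agree within 3%, and the fitted value is
the one comparable to experimental decay fitting (recorded control
events: 16.1 ± 1.3 ms).

### The seven-constraint fit

`fit_gating_constraints` refits all rate constants of both conditions
(with a shared unbinding rate k2 by default) to seven targets: rise and
decay times of both conditions, a ≥50% lower bound on the control peak
open fraction (hinge penalty), the relative injury-vs-control peak
reduction, and the control steady-state GABA EC50. Residuals are
normalized by their targets and weighted equally; optimization is
`scipy.optimize.least_squares` over log-rates (positivity for free).

Two structural facts are worth knowing. First, with the inequality
inactive there are six equalities for seven parameters, so an exact
solution forms a one-parameter family; the optimizer returns the family
member nearest its start, and the residual report says how well every
constraint is met. Second, the literal peak-reduction target of 37.2%
(the printed immunostaining increase in receptor number, imposed on the
open-fraction ratio) is *not* satisfied by the printed presets
themselves, which simulate to a 30.7% reduction; re-running the fit
satisfies it with near-zero residual while preserving the preset-derived
rise/decay/EC50 targets. The discrepancy between the "37.2% smaller"
wording and the 1 − 1/1.372 = 27.1% that equal maximal conductance would
imply is left visible in the residual report rather than resolved.

### Train depression

Evoked-train amplitudes are normalized to the mean of the first three
responses and fitted with c·(plateau + (1 − plateau)·e^(−n/τ)). The
free scale c is needed because the first three responses already
depress, so the normalized first pulse exceeds 1; fitting a fixed-scale
version of the same shape to data generated by this very procedure
biased τ by ~35% in simulation, while the free-scale fit is exact at
zero noise and recovers both parameters within 10% (median) at 5%
amplitude noise over 25 pulses. Constant trains return plateau 1 with a
degeneracy flag.

## Chloride homeostasis and the collapse

One compartment, ohmic currents. KCC2 extrusion is linear in the
E_Cl − E_K driving force with lumped strength g_KCC2 = F·U_KCC2; setting
synaptic Cl⁻ influx against extrusion gives the equilibrium

    E_Cl(g_inh, g_KCC2) = (g_inh·V_mean + g_KCC2·E_K) / (g_inh + g_KCC2),

and the net anionic current is x·g_inh·(V_eff − E_Cl) +
(1−x)·g_inh·(V_eff − E_HCO3) with x the Cl⁻ fraction of the inhibitory
conductance. A GHK-flux variant is not implemented; the ohmic form is
the primary model and the qualitative conclusions (collapse, synergy)
do not depend on the formalism.

Constants, units mV unless noted:

| constant | default | provenance |
|---|---|---|
| V_mean | −60 | printed (time-averaged membrane potential) |
| V_eff | −55 | printed (shunting-corrected zero-inhibition point) |
| g_inh baseline | 1 | normalization choice |
| g_KCC2 baseline | 0.81 | printed (sets baseline E_anion ≈ −65) |
| x | 0.8 | 4:1 Cl:HCO3 permeability |
| E_K | −95 | default, calibration output |
| E_HCO3 | −12.3 | Nernst 16/26 mM at 295 K, calibration output |
| offset | 6% MPA | printed no-drug analgesic offset |

Algebra used throughout: as a function of g = g_inh at fixed m = g_KCC2,
the current is I(g) = g(αg + β)/(g + m) with α = x(V_eff − V_mean) +
(1−x)(V_eff − E_HCO3) and β = m·(x(V_eff − E_K) + (1−x)(V_eff −
E_HCO3)). α < 0 is the collapse regime; the unique interior maximum sits
at g* = −m + √(m(m + β/|α|)). The public `optimal_conductance` uses
bounded scalar optimization and is cross-checked against this closed
form in the tests to 1e-6. A corollary: once a stationary point g* and
the baseline m are fixed, the maximal relative current gain
I(g*)/I(1) − 1 is fully determined — for g* = 2.9, m = 0.81 it is 23.8%,
independent of every other constant.

### Calibration and its honest residual

`calibrate_anion_constants` fits (x, E_K, E_HCO3) to the printed anchors
{E_anion ≈ −65 mV at baseline, Δg_inh* = 1.9, ΔI* ≈ 26%} by relative
least squares (closed-form stationary point inside the residuals, so the
objective is smooth). By the corollary above the anchor triple is
infeasible under the ohmic model: Δg* = 1.9 admits at most a 23.8% gain.
The calibration therefore reports a nonzero residual distributed across
the anchors (the fitted optimum lands near Δg* ≈ 1.98, ΔI* ≈ 24.6%) and
always includes the analytically attainable maximum in its report;
agreement is never forced. Dropping the ΔI* anchor leaves two equations
for three unknowns: the fit is then exact and flagged underdetermined
(the one-parameter solution family is real, not an error).

### Effect relation and effector maps

Effect(ΔI) = Max·ΔI/(Curhalf + ΔI), solved exactly from the two anchors
(ΔI, effect) = (26%, 25%) and (67%, 42%): Curhalf = 50.80, Max = 73.84.
The 6% no-drug offset is subtracted from behavioral effects before any
model use. Dose→effector maps compose the (offset-corrected) Hill curve
of each drug with Effect⁻¹ and the single-effector ΔI⁻¹; Δg = 1.9 means
the conductance is multiplied by 2.9. The g_inh branch is invertible
only up to the collapse optimum, and the KCC2 branch saturates (capped
at Δg_KCC2 = 50); map domains are restricted accordingly and
out-of-domain surface points are masked NaN, never extrapolated. All
inversions use bracketed root finding (`brentq`, tolerance 1e-9).

The behavioral Hill curves used by default are the printed in-vivo fits
(L838,417: EC50 0.43 mg·kg⁻¹, MPA 31.2%; CLP257: EC50 29.4 mg·kg⁻¹,
MPA 22.9%; Y0 = offset = 6%). The Hill slopes are not printed and are
taken as 1.

Combination surfaces: the common-effector surface converts the KCC2
dose to a current-equivalent potentiator dose and runs everything
through the g_inh branch; the distinct-effector surface applies each
drug to its own conductance and evaluates the joint current. For the
calibrated model the distinct surface strictly dominates the common one
at every interior grid point — the model's expression of synergy — and
a 40% KCC2 increase moves the collapse optimum beyond the baseline one
(both property-tested).

## Behavioral statistics

MPA is reported unclipped by default (negative values are meaningful
drug-worsening); a clipped view exists for display. Hill fits run on
per-animal MPA values (all timepoints pooled) rather than dose means —
the source protocol does not state which was fitted, and per-animal
fitting uses the replication structure; mean-aggregation is a one-line
`groupby` away for users who prefer it. Initialization: Y0 = min
response, Ymax = max, EC50 = geometric median dose, H = 1, with H
bounded in (0.1, 10]. The collapse product model Y(d)·C50^h/(d^h +
C50^h) fixes Ymax to an independently measured non-collapsing maximum;
when the data show no high-dose decline the collapse C50 escapes past
the dose range and the fit is flagged non-identifiable instead of
silently accepted.

Interaction classification compares observed vs Loewe-additive effects
against an uncertainty band supplied by the caller (defaulting in
practice to the SEM of the observed mean); formal hypothesis testing is
out of scope. The isobole solves a + a_eq(b) = EC50_a by root finding;
its A50 is the intersection with the fixed-ratio ray (1:55 for the
studied pair).

## Imaging operators

Punctum detection is a matched filter: a zero-mean disc kernel of
diameter equal to the PSF FWHM is convolved with the image and the
response thresholded at 4 robust SDs (median/1.4826·MAD) of the response
map. The zero-mean kernel cancels smooth background, so no raw-intensity
threshold exists to bias counts; a component must cover at least half
the disc support, which rejects single-pixel shot-noise excursions.
Components are 8-connected; border-touching objects are kept but
flagged. Per-object mean intensity is measured over a PSF-scale core
disc centered on the response-weighted centroid — the thresholded
support grows with object brightness and would dilute a support-mean by
20–30%, whereas the core mean recovers planted amplitudes within 10%
down to SNR ≈ 10. Areas and mask products use the full support.

Soma detection implements the stated adaptive rule: offset image =
original − 50-px local box average (bright-positive; the source text
words the subtraction the other way around, which would make somata
negative — implemented sign-corrected), threshold at mean + k·SD of the
offset image with k = 0.75 (midpoint of the stated 0.5–1 range), holes
filled, then area > 500 px and eccentricity ≤ 0.98 filters. On
noiseless fixtures the classification equals direct rule evaluation
exactly. Transcript dots are re-detected with the punctum detector at a
smaller PSF rather than marked manually; per-cell counts are raw (no
copy-index normalization is defined), dots outside every soma are
tallied as extracellular, and cells are typed inhibitory before
excitatory when both markers are present.

Membrane profiles are sampled along 3-pixel-thick crossing segments;
each membrane position is fitted with a Gaussian ridge plus an erf step
sharing its center, because the intracellular-vs-extracellular baseline
step otherwise biases an argmax inward by ~1 pixel. The membrane index
subtracts white-matter background from the whole image, then subtracts
the mean intracellular intensity from the mean over a large tissue ROI;
it is invariant to constant offsets by construction. Difference maps
smooth both mean images with a 20 µm Gaussian before the pixel-wise
(B − A)/A ratio, masking pixels whose reference falls below a noise
floor.

## Synthetic generators: what they emulate, and what they do not

Behavioral tables follow the Hill(×collapse) model with additive
Gaussian noise on the MPA scale, mapped back to WD50 through the exact
inverse of the MPA definition and clipped to [0, prePNI]; this keeps
zero-noise generation exactly invertible. Optional snapping to the 12
von Frey filament forces (0.04–60 g) is off by default. The default
design is 8 doses × 8 animals × 4 hourly timepoints with 5% MPA noise —
the protocol's scale; the per-animal WD50 variance is not published, so
the noise level is a stated free choice. Under these conditions the
regenerate-and-refit oracle recovers EC50 with 13.6% median relative
error over 200 seeds. Not emulated: the up-down filament testing
sequence, animal-level random effects, within-animal time correlation
(each timepoint draws independent noise), or tolerance/pharmacokinetic
time profiles.

Images are rendered as geometric objects (discs, rings, ellipses)
blurred by an isotropic Gaussian PSF (default FWHM 0.25 µm, 60×/1.4 NA
class), plus Poisson shot noise and Gaussian read noise, clipped to 12
bits. Puncta default to the measured cluster scale (radius ≈ 0.35 µm).
Not emulated: out-of-focus light and 3-D sectioning, chromatic shifts,
tissue autofluorescence texture, antibody-affinity variation, or
touching/overlapping cells. Passing recovery tests therefore
demonstrates correctness of the operators on data satisfying their
geometric assumptions, not robustness to every tissue artifact.

mIPSC traces place the gating-model unit waveform (normalized open
fraction) at Poisson event times with truncated-Gaussian amplitudes and
additive baseline noise, inward-negative. Event overlap is additive;
driving-force saturation and dendritic filtering are not modeled.

All generators take explicit integer seeds, use one `default_rng` per
call, and are bit-reproducible; every dataset ships with a truth bundle
recording its generating parameters.

## Numerical choices

ODE integration: LSODA with rtol 1e-8, output every 0.05 ms; event
simulations run 120 ms (≥ 10 transmitter time constants, and past 7
decay constants of the slowest preset). Acceptance computations reuse
these sizes. Nonlinear fits use `curve_fit`/`least_squares` with the
initializations stated above; fit failures raise with the starting
values, never return silently. Root finding is bracketed `brentq`
(xtol 1e-9 on dose/Δg scales). Degenerate inputs have defined behavior:
constant images yield zero detections, constant trains a flagged
plateau-1 fit, zero-width difference histograms a centered unit-width
bin range, and empty soma results are valid.

## Known limitations

- The chloride model is stationary: no Cl⁻ accumulation dynamics during
  trains, no bicarbonate regeneration, no spatial gradients. The
  eIPSC-train depression fit is descriptive, not mechanistic.
- The anion-anchor infeasibility (23.8% vs ≈26%) means downstream
  calibrated quantities carry a few-percent systematic tension; it is
  reported, not hidden, and the synergy conclusions are insensitive to
  it (property-tested across the calibration family).
- The gating fit's solution family means fitted rate constants are
  reproducible only given the documented starting point; observables
  (times, EC50, peak ratio) are the invariant outputs.
- Hill slopes of the in-vivo dose-response curves default to 1 because
  the printed fits do not report them.
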