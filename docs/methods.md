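# Methods

This note documents the models implemented in `pvretina`, their
assumptions, the defaults and why they were chosen, and what the synthetic
data can and cannot establish about real recordings.

## Volume-conduction model

The electrolyte (or retinal tissue) above the implant is treated as a
homogeneous resistive half-space `z >= 0` bounded below by the insulating
implant face.  A point current source on an insulating boundary produces
`phi = rho I / (2 pi r)`; every electrode field is an integral of this
kernel over the electrode footprint.

Active electrodes are disks with a **uniform current density (UCD)**
boundary condition, which is the correct idealization when the pulse is
much longer than the interface RC time: the capacitive interface forces
the current density toward uniformity.  With 4–10 ms pulses and an
active-electrode RC of a fraction of a millisecond this holds comfortably.
Closed forms used (and cross-checked against the finite-difference oracle):

* on-axis: `phi(0, z) = rho I (sqrt(a^2+z^2) - z) / (pi a^2)`;
* in-plane: complete elliptic integrals `E`, `K`;
* UCD access resistance (disk-averaged self potential): `8 rho / (3 pi^2 a)`;
* EP (equipotential) access resistance: `rho / (4 a)`.

Off-plane, off-axis potentials use adaptive radial quadrature of the
elliptic-integral kernel, cached as radial splines per (radius, height).

The common return is an annulus just outside the pixel field (default
760–790 um radius for the 1.5 mm device; the fabricated ring is not
dimensioned in the source, so the default is an idealization and is
configurable).  It is modeled as a uniformly collecting sink; its surface-
averaged self potential defines the return access resistance.

**Cross-resistance matrix.**  `R[i, j]` is the disk-averaged potential at
electrode i *relative to the return electrode surface* per unit current
injected at electrode j with its counter-current collected by the return.
This return-referenced form is exactly reciprocal (symmetric), is the
operator the circuit model needs, and for the 1.5 mm, 40 um-pixel array
puts nearest-neighbour couplings at 26–28 kOhm, within the 15–30 kOhm
range reported for the finite-element model of this device.  A
ground-referenced variant (`R_ground`) is provided for reporting; it is
not symmetric because the ring-to-pixel term depends on the receiving
pixel's position.

**Medium resistivity** defaults to 700 ohm-cm.  Dulbecco's PBS diluted to
10% by volume — the standard in-vitro surrogate for retinal resistivity —
is ten times the ~70 ohm-cm of full-strength DPBS.  The printed 0.24 ms
active-electrode RC corresponds to full-strength-saline conditions, not to
this retinal default; no constant is asserted from it.

**Finite-difference oracle.**  A vertex-centered finite-volume
discretization of the Poisson equation on a graded tensor grid, with
zero-flux conditions on the insulating plane, prescribed flux under
electrode footprints, and Dirichlet far-field boundaries (either grounded
or set to the analytic point-source field, which removes most truncation
error).  Jacobi-preconditioned conjugate gradients solve the system.  The
oracle exists purely to cross-check the quadrature kernels (2% on single
disks, 3% on 7-pixel clusters) and is not part of the production path.

## Pixel circuit model

Each pixel is a photocurrent source in parallel with a single Si diode.
The active (p+) terminal couples to the electrolyte through the SIROF
interface capacitance; all n+ terminals share the common return and its
much larger interface capacitance.  Sign conventions: anodic current
(active electrode into electrolyte) is positive; diode forward bias means
active terminal positive.  With interface voltages `u_i` (active) and
`u_r` (return), the diode voltage is

    V_D,i = u_i - u_r + sum_j R_ij I_j

and the instantaneous current balance

    I_i = I_ph,i - I_dark(V_D,i),     I_ph = responsivity x irradiance x area

is a monotone nonlinear system with a unique solution, solved by damped
Newton iteration to a residual below 1e-12 A.  Rows whose diode
conductance is negligible decouple in closed form, which shrinks the dense
linear solve to the conducting subset — the main cost saver on the
1285-pixel array.  State evolution is `C_a du_i/dt = I_i` and
`C_r du_r/dt = -sum_i I_i`; because the return carries the exact
counter-current, global charge conservation holds identically and is
verified as capacitor charge bookkeeping.

Parameters (all configurable):

| parameter | default | origin |
|---|---|---|
| responsivity | 0.51 A/W | printed device characterization |
| photosensitive area | 2 x electrode area | printed area ratio |
| SIROF specific capacitance | 6 mF/cm^2 | printed |
| electrode diameter | 18 um (40 um pixels) | printed; scales with pixel width |
| diode `I0`, `n`, `V_T` | 1.2e-12 A, 1.5, 25.852 mV | calibrated so turn-on ~0.5 V at ~0.5 uA and open-circuit photovoltage <= 0.6 V at 8 mW/mm^2 |
| return RC | 40 ms | printed; sets `C_r` given the computed ring access resistance |
| faradaic leakage | off | pure-capacitance interfaces; optional shunt conductance |

The integrator is an adaptive trapezoidal rule with step-doubling local
error control (default 1e-6 V per step; the desk-scale full-array
experiments use 1e-5 V, far below the mV-scale signals of interest) and
exact stepping at pulse edges.  The published solver was a customized
adaptive-step scheme; equivalence is defined behaviorally, by agreement
with an independent 1 us fixed-step implicit-Euler integration (measured:
~1e-4 relative RMS on both voltages and currents on a 13-pixel array,
against a 1% contract).

## Stimulation metrics

The activating function of bipolar-cell stimulation is approximated by the
trans-cellular potential step between z = 10 um (dendritic ends) and
z = 57 um (axonal terminals in mid-IPL).  Grating contrast over an
alternating-row pattern is

    contrast = 100 (Vb - Vd) / Vb   [%]

with `Vb`, `Vd` the mean steps over interior bright and dark pixel
centers (two row pitches in from the rim).  Under this definition 100%
contrast corresponds exactly to a non-positive dark-row step.  Contrast is
evaluated at the time of the peak bright-row step within the pulse; the
contrast experiment uses a single 10 ms pulse at 1 mW/mm^2 from the
preconditioned initial state (dark rows set to the requested interface
bias, bright rows at 0 V).

Computed on the full 1.5 mm array: pre-charging dark rows to 0.5 V drives
their step negative (contrast 122.8%), while a 0.2 V bias yields 70.4%.
The second number deserves a caveat: in this homogeneous half-space the
purely geometric contrast floor (zero dark conduction) is already 42% at
pixel centers, and the collective potential elevation of ~640
simultaneously driven pixels (several hundred mV — the same summation
that the transient-return mechanism exploits) partially forward-biases
even 0.2 V dark pixels.  A layered retina/vitreous conduction model, which
is out of scope here, suppresses long-range crosstalk and yields
substantially lower non-preconditioned contrast.  The *ordering* —
preconditioning strictly improves contrast, and only preconditioned dark
rows go negative — is robust to this approximation and is what the
package asserts.

The far-field (corneal-proxy) waveform is `c . I(t)` with fixed observer
coefficients from the same kernels at an on-axis point 5 mm above the
implant.  Only the waveform shape and the rate dependence normalized to
the lowest rate are meaningful; absolute corneal amplitudes would require
an anatomical eye/head conduction model.  The normalized peak-to-peak
amplitude declines monotonically from 1 Hz to 125 Hz (0.51 at 125 Hz on
the 19-pixel test array) because shorter inter-pulse intervals keep the
diodes nearer turn-on and shunt more photocurrent internally.

## Synthetic VEP generator

The generator emulates the *statistics* the acuity analysis assumes, not
cortical physiology: per trial,

    trace = A(s) template(t mod 500 ms) + artifact(t) + N(0, sigma)

sampled at 2 kHz, with `A(s) = max(0, beta0 + beta1 ln s)`, `s` the
inverse bar width.  The response template is a biphasic damped sine
confined to 0–100 ms after each reversal (dominant N1-like deflection near
30 ms — latency and shape are conventions, configurable).  The artifact is
a carrier-locked positive deflection confined to the 4 ms pulse windows at
64 Hz; a simulated far-field waveform can be substituted.  Defaults:
`beta0 = -31.9 uV`, `beta1 = -12 uV` per ln-unit (analytic acuity 29.9 um
at the 8.89 uV floor; magnitudes of tens of uV at coarse gratings, matching
the scale of reported group curves), per-trial noise SD 26 uV calibrated so
that 250-trial averaging leaves a static-grating peak-to-peak floor of
8.89 uV, per-animal intercept scatter 6 uV and noise-scale spread 28%
reproducing the reported 2.52 uV floor spread.

What passing tests do *not* show about real data: the generator's noise is
white and stationary, responses are deterministic within an animal, and
amplitude declines exactly log-linearly — real VEPs have colored noise,
latency jitter, and saturation, so estimator performance here bounds only
the statistical machinery, not biological variability.

## Acuity estimator

Pipeline: least-squares template subtraction of the stimulus artifact
(output orthogonal to the template); carrier-harmonic notching (zeroed FFT
bins within 1 Hz of k x 64 Hz, inverse transform; the 2 Hz reversal band
passes with <1% distortion); peak-to-peak amplitude in the 0–100 ms
post-reversal window, averaged over reversals; the same pipeline applied
to static gratings (120 and 30 um) defines the noise floor.

The fit selects bar widths whose amplitudes exceed the noise floor by a
one-sided Welch t-test (alpha = 0.05), walking from the coarsest grating
toward finer ones and stopping at the first non-significant width — the
sweep-protocol "falling limb" convention, which prevents chance
significances in the sub-acuity plateau from flattening the line.  All
per-recording replicates of the selected widths enter an ordinary
least-squares fit of amplitude on `ln s`; regressing replicates rather
than per-width means leaves `nK - 2` residual degrees of freedom, which
the normal-approximation interval below needs for calibration.  Acuity is
the bar width where the fit crosses the noise mean.  With
`g = ln(acuity) = -(N - beta0)/beta1`,

    Var(g) = J Cov(beta) J' + Var(N)/beta1^2,   J = [1/beta1, (N-beta0)/beta1^2]

assuming fit and noise estimates independent, `Var(N) = sd^2/n` for a
noise mean from n recordings, and the 95% CI is acuity +/- 1.92 SD — the
multiplier is implemented exactly as printed (1.92, not 1.96) and is
configurable.  Angular conversion uses 64.3 um per degree of visual angle
(rat), `cpd = 64.3 / (2 x bar width)`, with optional propagation of the
+/-2.9 um/deg factor uncertainty.

Calibration facts the test suite establishes: with zero noise the full
pipeline returns the analytic intersection to machine precision; on
amplitude-level generator-matched data the 1.92-sigma interval covers the
true acuity 93–94% of the time (10,000 replicates), inside the accepted
92–98% band.

**Known limitation — peak-to-peak bias.**  For noisy recordings the
measured amplitude is `E[p2p(signal + noise)] ~ p2p(signal) + ~0.6 x
floor` at every bar width, so the full-pipeline intersection sits finer
(smaller bar width) than the generator's analytic acuity — about 17 um
versus 29.9 um at default noise.  This is a property of the published
measurement procedure (peak-to-peak amplitudes intersected with a
peak-to-peak noise floor), not of this implementation; the bias vanishes
as noise goes to zero and cancels in comparisons between groups measured
with the same pipeline.  The demonstration experiment reports both the
estimate and the analytic reference so the effect is visible.

## Numerical choices and degenerate inputs

* Exponential overflow in the diode law is prevented by clipping the
  argument at 600; Newton steps are damped to at most ten thermal voltages
  of diode-bias change, then backtracked on the residual norm.
* Electrode overlap (center distance below one diameter), non-positive
  resistivity, evaluation below the electrode plane, pulse width at or
  above the period, empty bar-width lists, zero-norm templates, and
  estimation with fewer than two significant widths all raise typed errors.
* Adaptive steps that underflow 1e-7 ms raise a stiffness error with the
  failing time; steady-state iteration that does not repeat within 10 uV
  in 400 periods raises a non-stationarity error.
* Pattern masks use a 1e-9 band-index tolerance so that a grating with bar
  width exactly equal to the row pitch assigns rows deterministically.

## Problem sizes

Desk-scale defaults used throughout the shipped experiments and tests:
the full 1285-pixel array for cross-resistance and contrast; 7–19-pixel
clusters for oracle cross-validation and frequency sweeps; a 151-pixel
0.5 mm array for the field-stop transient; 4 s recordings (8 reversals)
per synthetic VEP; 500–10,000 Monte-Carlo replicates for estimator
calibration.
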