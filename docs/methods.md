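# Methods

This note records the models implemented, the defaults chosen where the
design was open, and what the synthetic-data round trips do and do not
demonstrate.

## Ionization model

Net charge is the standard multi-site Henderson–Hasselbalch sum: each group
class contributes its mean protonation fraction
`f = 1/(1 + 10^(pH − pKa))` (pKa of the conjugate acid), bases counting
`+f` and acids `−(1 − f)` per site.  Sites are independent — no microstate
coupling, no structure-based pKa prediction, no activity corrections
(ideal-dilute solution).  The default pKa table is
C-terminus 2.18, Glu 4.25, Lys 10.53, N-terminus 9.13 behind a leading Phe
and 8.95 behind a leading Lys; it is data (YAML), not code, and apparent-pKa
shifts are applied by overriding entries.  Sequences containing other
ionizable residues (D, C, Y, H, R) raise unless the supplied table covers
them.  Charges are in elementary-charge units; the isoelectric point is the
unique zero crossing of the strictly decreasing Z(pH), found by bisection
to 1e-6.

## Titration and calorimetric profiles

A titrated solution is modelled by the charge-balance residual

    f(pH) = [Na+] + C_p·Z+(pH) + [H+] − [Cl−] − C_p·Z−(pH) − [OH−],

with `[H+] = 10^−pH`, `[OH−] = 10^(pH−14)` (pKw fixed at 14, 25 °C) and
Z± the protonated-base / deprotonated-acid sums.  f is strictly decreasing,
so bisection on pH ∈ [0, 14] (tolerance 1e-8) is exact.  Peptides supplied
as HCl salts carry an unknown number of chloride counter-ions;
`infer_chloride_equivalents` fits that number so the zero-base equilibrium
reproduces the measured as-dissolved pH (2.6 for these sequences), rather
than guessing a salt stoichiometry.  Molarity is derived from mg/mL using
average residue masses plus one water; the counter-ion mass is excluded by
default.  Titrant-volume dilution is applied when an injection volume is
given, otherwise neglected.

Heat per injection is modelled as ΔH_class × (deprotonation events of that
class during the injection) + a constant dilution heat, with ΔH defaulting
to 1 kcal/mol in relative units — only the positions of transitions on the
NaOH:peptide ratio axis are interpreted, not calibrated enthalpies.  The
"transition ratio" is the argmax of |d heat/d ratio| (ties toward lower
ratio).  For a smooth single-class profile this lands on the completion
edge of the buffer region — the equivalence point, coinciding with the pH
jump — not on the half-deprotonation ratio; the tests assert that identity.
The default synthetic titration schedule spans 0–6 NaOH equivalents
because the inferred excess acid (~2.8 equivalents at 1 mg/mL and pH 2.6)
pushes the Glu transition to ratios near 4–5.

`fit_apparent_pka` refits a single class pKa by re-simulating the titration
and minimizing pH residuals (bounded scalar minimization, tolerance 1e-6).
The observed curve carries the theoretical system; the reported shift is
fitted-minus-theoretical.  Recovery is exact to <0.02 pH units on noiseless
curves across shifts of ±1.

## Cylinder form factors

The scattering amplitude of a tilted cylinder factorizes into an axial
sinc and a cross-section Bessel term; the elliptical cylinder uses the
azimuth-dependent radius `r(ψ) = R·sqrt(sin²ψ + ν²cos²ψ)`.  Intensities are
normalized so the orientational average is 1 at q → 0: `scale` absorbs
volume² × contrast², because beamline intensities here are on an arbitrary
scale and absolute calibration is unrecoverable.  No structure factor,
polydispersity or instrument smearing (dilute-regime model).

Numerics: for fibres hundreds of nm long the axial factor oscillates up to
~2500 times across the tilt range, far beyond any fixed low-order rule.
The tilt integral is therefore evaluated in u = cos α: the first 40 sinc²
lobes get a Gauss–Legendre rule with ≥6 nodes per lobe (spectrally
converged); beyond them the oscillatory part of sinc² averages out and only
the smooth envelope `B(s)/(2(qLu/2)²)` is integrated, in the variable
s = q·sin α where the cross-section term's own oscillations live, plus the
analytic endpoint term `−sin(qL)/(4(qL/2)³)` from one integration by parts.
The ψ-average B(s) is tabulated at ≥48 samples per oscillation (set by the
major axis, not by the quadrature-order knob) and interpolated by cubic
spline.  Agreement with 2×10⁶-point brute-force quadrature is ≤1e-5
relative over the fit window, and 76- vs 512-point settings agree to
~1e-10, so fits are insensitive to the quadrature order.  The ν = 1 limit
reproduces the circular cylinder to <1e-6 relative.

## SAXS interpretation chain

* Power-law fits are ordinary least squares of log I on log q inside a
  window; the exponent is scale-invariant.  The default low-q window is
  0.086–0.12 nm⁻¹ — the bottom of the experimental q range, below the
  cross-section features (q ≲ 2π/width) — where the wide-ellipse
  (twisted-fibre) geometry shows the flat-particle q⁻² law and the
  narrower ribbon geometry fits close to q^−5/3.  At larger q the model
  curves steepen through the width→thickness crossover, so windows like
  0.15–0.40 nm⁻¹ read −2.3 to −2.4 for the same geometry.
* Cross-section Guinier analysis regresses ln(qI) on q²;
  R_σ = sqrt(−2·slope).  A fit is flagged invalid when the slope is
  non-negative (R_σ reported as missing, never 0) or when q·R_σ > 1.3 at
  the window top (standard rod-Guinier validity).  On a circular cylinder
  the recovered R_σ matches R/√2 within 2%.
* The elliptical-cylinder refit minimizes Σ((I_obs − I_model)/σ)² with
  Levenberg–Marquardt (σ = 1 if absent), default q-range 0.1–7 nm⁻¹.
  Within that window q·L ≫ 1 for the published lengths, so the length is
  weakly identified: recovery protocols fix length and scale and fit the
  cross-section parameters plus background (default init min(I)/10 scale).
  Fits are deterministic given data and init; uncertainties come from the
  covariance, with a recorded warning when the Jacobian is degenerate.
* `regime_report` segments sliding-window log-log slopes at changes >0.25.
  It is descriptive; on curves with gradual crossovers the first segment
  averages over the crossover (≈ −2.3 for the twisted-fibre geometry)
  rather than isolating the asymptotic law — windowed fits are the
  quantitative tool.

A known inconsistency in the source data is documented rather than
resolved: the published Guinier radii (4.05/3.26 nm) are much smaller than
the cross-section Rg implied by the published ellipse parameters (~7 nm for
the ribbon row); the two analyses answer differently-posed questions and
the original data are not deposited, so no reconciliation is attempted.

## WAXS analysis

Bragg spacings use d = 2π/q with q as momentum transfer (the
crystallographic λ/(2 sin θ) form is equivalent).  Input dialects are
Å⁻¹ or nm⁻¹ and must be declared explicitly — never inferred.  Detection
subtracts a rolling-minimum baseline (window 5% of support, then smoothed)
for the broad water halo of hydrated gels, applies a light 5-point boxcar,
and takes local maxima above an absolute prominence; peak positions are
refined by a least-squares parabola over the apex half-width, giving
sub-grid accuracy (≤1 grid step at SNR ≥ 10 in seeded tests).  Harmonic
families are built greedily from descending d: a peak joins when its
spacing ratio to the fundamental is within 0.05 (absolute, on the ratio)
of an integer; each peak belongs to one family.  With the five observed
spacings this yields the 4.8/2.4/1.2 Å family (orders 1, 2, 4) and leaves
5.7 and 3.7 Å singletons; the β-sheet screen reports a peak in 4.4–5.0 Å
(inter-strand) and 3.5–3.9 Å (intra-chain residue spacing).

## Synthetic data

Generators are pure functions of (scenario, seed) using
`numpy.random.default_rng`; truth travels in metadata, never in the data
columns.  Defaults emulate the study conditions: SAXS on 200 log-spaced
points over the instrument window 0.086–7.76 nm⁻¹ with 1% multiplicative
Gaussian noise (beamline uncertainties are unreported; 1% is a typical
synchrotron statistics scale), parameter sets mirroring the published
5/10 mg/mL rows; WAXS on 2000 linear points over 1–6 Å⁻¹ with Gaussian
peaks at the five published spacings, the β-sheet peak tallest, a gently
sloping background and σ = 0.002 noise; titrations at 1 mg/mL, 0.025 M
NaOH, as-dissolved pH 2.6.

What passing round trips show — and what they do not: recovery tests prove
the analysis chain inverts its own forward model under the stated noise,
which validates the implementation, not the model's adequacy for real
gels.  Real data add inter-fibre structure factor, polydispersity,
smearing, background imperfections and assembly-coupled titration
behaviour, none of which the generators emulate.

## Pipeline

`RunConfig` (pydantic-validated YAML) drives charge → titration → SAXS →
WAXS stages into one output directory with per-stage subfolders and a
`report.json`; runs are deterministic per config + seed, and a failing
stage is marked in the report without discarding completed stages.  Logs
go to stderr with every stage's parameters.

## Problem sizes

Tests and the acceptance script run at the study's own scales: 200-point
scattering curves, 61–121-point titration grids, 2000-point WAXS patterns,
20 noisy refit replicates.  These sizes are the defaults of the emulated
protocols; the model evaluation (~10 ms per 200-point curve) makes larger
sweeps cheap if needed.
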