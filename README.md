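# peptide-nanoform

Charge, titration and X-ray scattering analysis for self-assembling
β-sheet-forming peptides.

Short amphipathic peptides such as FEFKFEFK (alternating phenylalanine with
glutamic acid / lysine) self-assemble into antiparallel β-sheet fibres and,
at sufficient concentration, hydrogels.  Characterizing variants of this
design — e.g. proline-substituted sequences that form flat nanoribbons or
twisted nanofibres instead of thin fibrils — relies on a small set of
standard desk analyses that this package implements as a tested library:

* **Net charge vs pH** — the multi-site Henderson–Hasselbalch sum

  $$Z(\mathrm{pH}) = \sum_i \frac{N_i}{1 + 10^{\,\mathrm{pH} - pK_{a,i}}}
    \;-\; \sum_j \frac{N_j}{1 + 10^{\,pK_{a,j} - \mathrm{pH}}}$$

  over the basic (N-terminus, Lys) and acidic (C-terminus, Glu) groups of a
  sequence, with a configurable pKa table.
* **Strong-base titration** — the solution pH as the root of the
  charge-balance equation for an HCl-salt peptide titrated with NaOH,
  calorimetric (ITC-style) heat-per-injection profiles versus the
  NaOH:peptide molar ratio, stoichiometric deprotonation counts, and
  least-squares recovery of apparent pKa shifts.
* **SAXS form factors and fits** — orientationally averaged circular and
  elliptical cylinder models $I(q) = s\,\langle F^2\rangle_{\alpha,\psi} + b$,
  low-q power-law regimes, cross-section Guinier analysis
  ($\ln qI$ vs $q^2$, slope $-R_\sigma^2/2$), and Levenberg–Marquardt
  refits of the elliptical-cylinder cross section.
* **WAXS peak assignment** — Bragg conversion $d = 2\pi/q$, baseline-aware
  peak detection, lamellar harmonic families ($d_1, d_1/2, d_1/3,\dots$) and
  the β-sheet inter-strand (~4.8 Å) / intra-chain residue (~3.7 Å) screen.
* **Synthetic data generators** — seeded SAXS/WAXS/titration emulators with
  embedded ground truth, for recovery tests and blind-analysis exercises.

## Worked example

`examples/` holds one short script per capability.  For instance, the
elliptical-cylinder refit round trip (`examples/saxs_fit_recovery.py`)
generates a synthetic dilute-fibre curve from a published nanoribbon
cross-section and refits it from a perturbed start:

```text
synthetic curve: 200 points, q 0.086-7.76 1/nm, 1% noise
refit (converged): R = 4.762 nm (truth 4.761), axis ratio = 2.783 (truth 2.783), chi2_red = 1.14e+00
low-q exponent -1.47 over (0.086, 0.12) 1/nm; Guinier R_sigma = 6.69 nm (valid=True); ellipse cross-section Rg = 7.04 nm
```

The fitted minor radius and axis ratio land on the generating values to
better than 1% under 1% multiplicative noise; the reduced χ² of ~1 says the
residuals match the injected noise level.  The titration example
(`examples/titration_itc.py`) prints

```text
1 mg/mL FEFKFEFK: 0.892 mM; 5.05 Cl-/peptide reproduce pH 2.6
Glu half-deprotonation at ratio 3.98; heat-profile transition (equivalence) at ratio 5.08
apparent Glu pKa fitted: 3.750 (theoretical 4.25, shift -0.500)
```

i.e. the as-dissolved acidity implies ~2.8 equivalents of free excess acid,
the Glu buffer region ends at the heat-profile transition, and a −0.5
apparent-pKa shift written into a synthetic measurement is recovered
exactly.

A thin CLI mirrors the library (`peptide-nanoform charge | titrate |
saxs-fit | waxs-peaks | simulate | run`); `peptide-nanoform run --config
examples/demo_run.yaml --out run/` executes all four stages for the four
study sequences and writes per-stage CSV/JSON plus a run report.

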