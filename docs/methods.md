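# Methods

## The 1:1 binding model

All analyses rest on a single complexation equilibrium
H + G ⇌ HG with association constant Ka = [HG]/([H][G]) (M⁻¹).
Mass balance at totals H₀, G₀ gives the quadratic

    Ka (H₀ − c)(G₀ − c) = c,

whose physical root is

    c = (S − √(S² − 4H₀G₀)) / 2,   S = H₀ + G₀ + 1/Ka.

When S² ≫ 4H₀G₀ (weak binding, strongly unequal totals) the subtraction
cancels catastrophically, so the implementation always evaluates the
algebraically identical conjugate form

    c = 2H₀G₀ / (S + √(S² − 4H₀G₀)),

which is stable everywhere in the domain (the denominator is a sum of
positive terms). Ka = 0 and Ka = ∞ are handled as explicit limits, c = 0
and c = min(H₀, G₀). A generalized single-complex equilibrium
mH + nG ⇌ HmGn (m, n ≤ 3) is solved by 200-step bisection on the extent
of reaction; it exists to show how the Job maximum discriminates
stoichiometry and is not part of any fitting path. Activity corrections,
ionic-strength effects and multi-equilibrium speciation are out of scope.

## Job (continuous-variation) analysis

Samples hold H₀ + G₀ = C constant and vary the host mole fraction x; the
complex concentration c(x) peaks at x = m/(m+n) for an m:n complex
(0.5 for 1:1, 1/3 for 1:2 host:guest). The default grid is 11 evenly
spaced mole fractions in [0, 1], a typical continuous-variation series.
For model-backed curves the maximum is refined by golden-section search
(tolerance 1e-9 on x) between the neighbours of the best grid point; a
1:1 curve returns 0.5 to better than 1e-6 regardless of Ka or C. Curves
carrying only experimental observables fall back to the parabola through
the best point and its neighbours. An identically flat curve has no
maximum and is an error.

## Spectroscopic titrations

Series are individually prepared at constant guest concentration, so no
in-series dilution correction is applied. Under fast exchange the
observed signal is the population average of free and bound guest, hence
linear in the bound fraction f_b = c/G₀:

    y(H₀) = y_free + (y_bound − y_free) · f_b(H₀; G₀, Ka).

Absorbance (molar absorptivities folded into y_free/y_bound) and
fast-exchange chemical shift obey the same three-parameter form, in either
direction of signal change. Slow-exchange NMR series show separate
free/bound resonances, violate the model, and are refused by the fitter
when flagged.

Fitting minimizes the sum of squared residuals over
(log₁₀Ka, y_free, y_bound); the log parameterization enforces positivity
and conditions the problem. Initialization is a grid over
log₁₀Ka ∈ {0,…,9} with y_free/y_bound pinned to the first/last point,
ties resolved toward the lowest Ka; refinement uses a trust-region
least-squares solver with cost tolerance 1e-10 and log₁₀Ka bounded to
[−6, 12]. Standard errors are asymptotic (Jacobian at the optimum, delta
method back to Ka). The reported ± is this asymptotic error by default;
a residual-bootstrap 2.5–97.5 % percentile interval (refitting from the
optimum, seeded, deterministic) is available as a companion, since
published ± values rarely state their method. A series with fewer than
4 points, non-increasing host totals, or constant observables is
rejected rather than fitted.

## ITC

The cell (volume V₀) holds guest at M₀; the syringe titrates host at
X_syr. Injection i of volume dVᵢ expels an equal volume of the current
mixture — the recursive overflow convention, one of several vendor
conventions, chosen here because it makes the mole bookkeeping exact and
testable:

    Mᵢ = Mᵢ₋₁ (1 − dVᵢ/V₀),
    Xᵢ = Xᵢ₋₁ (1 − dVᵢ/V₀) + X_syr dVᵢ/V₀.

With effective binding-site concentration n·Mᵢ, the complex cᵢ follows
from the 1:1 root, and the heat of injection i is

    qᵢ = ΔH · V₀ · (cᵢ − cᵢ₋₁(1 − dVᵢ/V₀)),

the last factor crediting complex expelled with the overflow. Heats are
stored in µcal and ΔH in kcal/mol (1 kcal = 10⁹ µcal; covered by a unit
test). Cumulative heat over a saturating schedule equals ΔH times the
total moles of complex ever formed (cell + expelled), which the tests
verify against an independent mole-tracking oracle.

Fitting estimates (n, log₁₀Ka, ΔH): n starts at 1, ΔH from the first
injection assuming complete binding, Ka from a coarse grid; ΔG = −RT ln Ka
and TΔS = ΔH − ΔG are filled by identity on every result. Identifiability
follows the usual c-value rule (c = Ka·M₀·n informative in roughly
1–1000); a schedule whose final molar ratio never reaches the fitted n is
flagged `identifiability_low`. Defaults — 200 µL cell, 20 × 2 µL
injections, 2 mM syringe, 298.15 K — mirror a standard single-cell
microcalorimeter protocol; the schedule is fully configurable. Blank
(dilution) heats are assumed subtracted upstream; inputs are integrated
heats, not power traces.

## Thermodynamic identities and audits

R = 1.987204 × 10⁻³ kcal mol⁻¹ K⁻¹; energies are reported at 2 dp with
round-half-even. The default temperature is 298.15 K (25 °C). The source
table for the packaged audit fixture prints T = 297.5 K next to the
ΔG = −RT ln K formula, but its printed ΔG values (−6.85, −5.21 kcal/mol)
reproduce only at 298.15 K, so 298.15 K is used and the discrepancy is
left visible in the audit residuals rather than hidden.

`audit_record` computes the residuals of ΔG + RT ln Ka and
ΔH − TΔS − ΔG and passes each iff |residual| < tolerance (strictly; a
residual exactly at the tolerance fails, so a table consistent at its own
rounding precision must have residual ≈ 0). On the packaged table of
published CB[7] encapsulation parameters this flags the cimetidine ITC
row (enthalpy identity residual 0.03 kcal/mol) and the famotidine
end-point-decomposition column (residual 0.01), while all other rows pass
at 0.01 — whether those two reflect unrounded inputs or transcription
slips cannot be decided from the printed values alone. The audit never
mutates records, and computing ΔE_TOT or TΔS_TOT themselves (end-point
free-energy methods) is out of scope.

## Mass spectrometry

Monoisotopic masses use an embedded most-abundant-isotope table
(¹²C 12 exactly, ¹H 1.0078250319, ¹⁴N 14.0030740052, ¹⁶O 15.9949146221,
³²S 31.97207069 Da) — monoisotopic, not average, masses are what
instrument software reports as "calculated" values. Protonation adds the
proton mass 1.00727646688 Da per charge (not the hydrogen atom mass; the
electron leaves with the charge):

    m/z = (n_H·M_host + n_G·M_guest + z·m_p) / z.

Internally full precision is kept; 2 dp rounding happens only at the
reporting boundary. Peak assignment enumerates compositions with
n_host, n_guest ≤ max_n and returns candidates within a ppm tolerance
sorted by |error|, ties to the smaller composition. The default 30 ppm
window is a convention covering typical external calibration, not an
instrument specification. Isotope-pattern simulation and non-protonated
adducts (Na⁺/K⁺) are not modelled. The molecular formulas of the bundled
species (CB[7] C42H42N28O14, cimetidine C10H16N6S, famotidine
C8H15N7O2S3, nizatidine C12H21N5O2S2) are standard chemical identities.

## Synthetic data

The generators emulate the study designs the analyses assume:
spectroscopic series of 12 evenly spaced host totals from 0 to the stated
equivalents (6 for the 0.05 mM design, 3 for the 0.04 mM and 1 mM
designs), 11-point Job grids at constant total concentration, and the ITC
schedule above with cell concentrations of 0.05–0.1 mM. Exact point
counts and replicate numbers are not published for such experiments; 12
points and single series are stand-in conventions.

Noise is additive homoscedastic Gaussian on the observable — no error
model is published, and homoscedastic noise is the simplest structure the
least-squares fits assume. Default magnitudes in the study bundles are
expressed as a fraction of each signal's dynamic range (1 % for
spectroscopic observables, 2 % of the largest heat for ITC). One seeded
`numpy` Generator drives each dataset; identical configs are
bit-identical. What passing round-trip tests show is therefore that the
estimation chain is correct and well-conditioned under the assumed model;
they do not probe heteroscedastic instrument noise, baseline drift,
slow-exchange lineshapes or concentration errors in real data (the
freely fitted ITC n absorbs the last of these in practice).

## Problem sizes and determinism

The test suite and acceptance script run everything at the study's own
scale: 12-point titrations, 11-point Job grids, 20-injection ITC runs,
200-replicate noise sweeps and 20 × 200 bootstrap refits — a few seconds
each on one core. All stochastic tests fix seeds; the acceptance script
threads its `--seed` through every random draw (the m/z and Job-maximum
quantities it reports are deterministic, and the seed only jitters the
Job grid to show grid independence).
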