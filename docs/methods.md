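# Methods

This note records the models implemented in `gapmech`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices that affect results.

## NMR observables

Chemical shift perturbations combine the ¹H and heteronucleus changes as
`CSP = sqrt(Δδ_H² + A·Δδ_X²)` with the conventional compression factors
A = 0.17 (¹⁵N) and A = 0.185 (¹³C), overridable per nucleus. Probes are
keyed by `(residue, atom)`, so prochiral methyl pairs (δ1/δ2, γ1/γ2) are
independent probes. Classification against σ uses half-open bands with ties
resolved upward: `csp ≥ 2σ` is *strong*, `σ ≤ csp < 2σ` *moderate*,
otherwise *weak*. When σ is not supplied it is estimated as
1.4826 × MAD of the observed CSP distribution; the median absolute
deviation is used because genuine interface perturbations are outliers that
would inflate a standard deviation.

Intensity ratios are `I/I₀` with the error propagated from spectral
signal-to-noise as `err = (I/I₀)·sqrt(SNR⁻² + SNR₀⁻²)` — the standard
relative-error combination for a quotient. Probes visible in the reference
state but lost in the other are kept with ratio 0 and the flag
`broadened-beyond-detection`; probes with non-positive reference intensity
are excluded with a warning record rather than silently dropped.

## Restraint generation

Relative solvent accessibility is Shrake–Rupley SASA (probe 1.4 Å, 960
sphere points) normalized by the tripeptide-based theoretical maxima of
Tien et al. (2013); only the 20% exposure cutoff depends marginally on the
normalization table. Active residues for ambiguous interaction restraints
are strongly perturbed *and* ≥ 20% exposed; passive residues are exposed
residues that are moderately perturbed and/or lie within 6.5 Å of an active
residue, measured between any heavy-atom pair (the most permissive reading;
a Cβ–Cβ mode is available). The "and/or" in the passive definition is
implemented as a union. An empty active set is a hard error, because
docking without actives is unconstrained.

Unambiguous restraints take every probe with `I/I₀` below the suppression
threshold (default 0.2) — including broadened-beyond-detection probes — and
assign the configured bounds, default 1.8–16 Å from the label site. In the
CNS serialization the bounds are encoded as `d −(d−lower) +0` with
d = upper, the common convention for upper-bound PRE restraints. The
restraint file writer is byte-stable; a parser is provided for round-trip
checks. The label-site atom is a placeholder at the mutated residue's Cβ:
the docking-time label position is not modeled here.

## PRE forward model

The transverse PRE rate for an electron–proton distance r is the
Solomon–Bloembergen expression
`Γ₂ = κ·[4τ_c + 3τ_c/(1 + ω_H²τ_c²)]·r⁻⁶` with κ = 1.23×10⁻³² cm⁶ s⁻²
(converted once to 1.23×10¹⁶ Å⁶ s⁻²; all distances are Å internally) and
`1/τ_c = 1/τ_R + 1/τ_S`, defaults τ_R = 70 ns (complex tumbling) and
τ_S = 100 ns (electron relaxation), giving τ_c ≈ 41.2 ns. The spectrometer
default is 850 MHz; at ω_H τ_c ≈ 220 the spectral-density term is
negligible, so this choice is non-critical. Conversion to intensity ratios
uses `I/I₀ = R₂·exp(−Γ₂t)/(R₂+Γ₂)` with t = 6.89 ms (total evolution time)
and R₂ either global or per-probe; `r2_from_linewidth` supplies
R₂ = π·FWHM from diamagnetic linewidths.

Ensemble averaging is done entirely in rate space (⟨r⁻⁶⟩ weighting): over
label-site samples within a frame, over the up-to-three methyl protons
(fast methyl rotation), then over frames. Explicit label rotamer libraries
are not used; instead label-site positions are supplied with the ensemble
or generated by a helper that places a pseudo-site 3.5 Å beyond Cβ along
Cα→Cβ with seeded isotropic jitter (sd 1.5 Å). This preserves the averaging
structure while removing the rotamer-library dependency; it will not
reproduce orientation-specific label packing.

Binding-pose populations are fitted by χ² between observed and
back-calculated ratios over a simplex grid (coarse step 0.05, one
refinement pass at 0.01 around the optimum), with rates mixed *before* the
nonlinear ratio map — mixing ratios instead is a different (wrong)
convention and a test asserts the two differ. Broadened probes contribute
one-sided residuals: they are penalized only if the calculated ratio
exceeds the detection floor (default 0.1), since their true ratio is only
bounded from above. Ties in the objective resolve toward the most uniform
weight vector. The reported slope is a regression through the origin of
calculated on observed ratios (the regression convention is not otherwise
standardized); Pearson r is computed on the same pairs. Grid search is used
instead of gradient descent because the objective can be flat or
multi-modal in the weights.

## Ensemble observables

Center-of-mass distances use all atoms of the selected residues
(mass-weighted; backbone-only optional) to a single named atom, per frame.
Per-residue distance shifts are differences of per-ensemble mean
Pγ→Cα distances with the error bar taken as the *sum* of the two SDs — a
deliberately conservative convention kept as the default (quadrature is
available). Hydrogen bonds use donor–acceptor heavy-atom distance ≤ 3.5 Å
and donor–H···acceptor angle ≥ 120°, both configurable; hydrogens are
located by covalent proximity (< 1.25 Å) to the donor, and a distance-only
mode must be enabled explicitly for hydrogen-free structures. Histograms
use a 0.1 Å default bin width and normalize to unit mass.

## Membrane kinetics

Two mass-action networks of 11 state variables describe a
membrane-anchored GTPase substrate (ArfT → ArfD), a weakly binding
catalytic module (ZA), and a lipid-binding PH module.

*In trans* (separate proteins): PH_s, PH_m, ZA, ArfT, ArfD, PH_s·ArfT,
PH_m·ArfT, ZA·ArfT, ZA·PH_s·ArfT, ZA·PH_m·ArfT, PH_m·ArfD. Reactions: PIP2-
dependent PH membrane partitioning; PH–substrate association in both PH
states; ZA association with free and PH-bound substrate; catalysis from
every ZA-engaged complex at k_cat, except the membrane ternary complex
(PH simultaneously PIP2- and substrate-bound) at α·k_cat; product release.

*In tandem* (PH–ZA fusion E): E_s, E_m, ArfT, ArfD, PH-docked complexes
(E_x·ArfT_P), fully engaged complexes (E_x·ArfT_PZ) reached through an
intramolecular step with forward rate `k_on_ZA·c_eff` (effective local
concentration of the tethered catalytic module), directly ZA-docked
complexes (E_x·ArfT_Z), and E_m·ArfD. α again applies only to the membrane
PZ complex. Both networks are data (species/reaction lists), so an
alternative network can be substituted without code changes; the builders
validate moiety conservation of every reaction at construction.

Membrane localization uses a reaction-shell approximation: membrane-bound
species are confined to `V_shell = (lipid count × 0.7 nm²) × h` with shell
height h = 10 nm, and bimolecular steps between two membrane-confined
species are accelerated by the bulk-to-shell volume ratio γ (≈ 474 at
0.5 mM accessible lipid). This standard dimensional-reduction treatment
keeps every species in bulk molar units.

Reference rate constants (`REFERENCE_PARAMETERS`) were chosen once to match
the published magnitudes of this system: ZA:substrate K_d = 1 mM (0.1–1 mM
range), PH:substrate K_d = 1.5 µM (≈ the 1–2 µM K_m), a catalytic
efficiency of order 10 M⁻¹s⁻¹ for the catalytic module alone, c_eff = 3 mM
for the tethered module, k_cat = 0.02 s⁻¹ and α = 10³. With these values
the scenario ladder reproduces the qualitative activity ordering
(module alone < recruitment only < binding only < recruitment+binding <
full model), recruitment and binding each contribute ~2.5–3 orders of
magnitude, their combination saturates as catalysis becomes rate-limiting,
the full span in efficiency is ~8 orders (compressed to ~6 orders in C50 at
the 1 µM substrate assay condition — both are reported, since "activity"
comparisons can mean either), and halving the PH:substrate affinity without
allostery changes C50 by < 0.5%.

Scenario presets (ZA alone; a lipid-anchoring-only surrogate PH; fusion
with/without PIP2; a localization-only hypothetical with α = 1; an
N-terminally truncated variant with doubled K_d and α = 1) are configuration
toggles, not separate code paths.

Integration uses LSODA (via `odeint`, numba-compiled right-hand side and
analytic Jacobian), rtol 1e-8 and an absolute tolerance scaled to
1e-10 × the smallest non-zero initial concentration — a fixed molar atol
would be coarser than the picomolar enzyme concentrations probed in the
titrations. Every simulated endpoint verifies conservation of all moieties
to a relative 1e-8 and rejects negative concentrations beyond tolerance.
C50 is obtained by log-linear interpolation between the bracketing
titration points and is flagged undefined when the curve does not cross
50%.

Global fitting minimizes fraction-scale residuals weighted by per-point
errors (default 5% of the signal) simultaneously across scenarios, with
shared free parameters (default α, k_cat, k_off for PH:substrate, c_eff)
in log10 space. Multi-start strategy: a short budgeted local search from
each of ≥ 20 seeded random starts inside the bounds, then full polishing of
the 3 best — a pragmatic trade against the cost of stiff ODE solves inside
the objective. Asymptotic standard errors come from the Jacobian at the
optimum; parameters with flat profiles are reported as unidentifiable
(e.g. α when no PIP2-containing scenario is in the data) rather than
silently fixed. The objective has a mild ridge between PH affinity and
c_eff, so those two individually carry more uncertainty than α.

Saturation-curve K_d estimation fits `rate(c) = r_free − Δr·c/(c+K_d)`
(dissociation-protection, where the concentration giving half the maximal
rate reduction equals K_d) or the same hyperbolic form read as competitive
inhibition; it warns when the titration does not reach ~2×K_d.

## Synthetic data

Generators are deterministic given a seed (identical arguments ⇒ identical
bytes) and always emit machine-readable ground truth. Peak lists draw
baseline shifts and intensities, give a configurable subset (default 10%)
true shifts large enough to exceed 2σ, add Gaussian shift noise and
log-normal intensity noise, and build the paramagnetic table by attenuating
intensities through the PRE forward model from a generated label–probe
geometry, dropping peaks whose true ratio falls below the detection floor.
The two-pose ensemble generator places the same probes at 8–18 Å (pose A)
and 18–35 Å (pose B) from the label with per-frame jitter, and the observed
profile is the rate-space mixture at the requested weights (default
0.9/0.1) plus Gaussian noise (default σ = 0.02) on every probe; an optional
detection floor reproduces lost-peak behavior. Dose–response data are
simulated from the reference parameter set at 10 log-spaced concentrations
per scenario with 5% multiplicative log-normal noise, matching the
precision class of the endpoint assay.

What the generators do *not* emulate: spectral overlap and peak-picking
errors, label rotamer anisotropy, internal-dynamics order-parameter
corrections to the PRE, scenario-correlated assay systematics, and any
membrane structural realism. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise models, not robustness
to those real-data pathologies.

Problem sizes used in the shipped tests and the reproduction script —
30 probes × 20 frames per pose for population fitting, 4 scenarios × 10
concentrations with 20 fit starts for the kinetics — keep a full run at
about a minute on one CPU while leaving all estimators in their intended
operating regime. At these conditions the population-weight estimate has a
seed-to-seed spread of ≈ 0.04 (sd), so recovery within one coarse grid step
is typical but not guaranteed for every noise realization.

## Known limitations

- The kinetic networks are a mechanistic reconstruction; absolute fitted
  constants are meaningful only relative to the stated reference magnitudes.
- The PRE model omits label-linker dynamics beyond isotropic jitter and
  uses a single effective τ_c for all probes.
- AIR generation assumes a single-chain partner per call; multi-chain
  partners must be processed per chain.
- The hydrogen-bond detector is O(donors × acceptors) per frame and is
  intended for selection-scale analyses, not whole-protein scans of long
  trajectories.
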