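# gapmech

Analysis toolkit for dissecting how a pleckstrin-homology (PH) domain turns a
weak GTPase-activating protein (GAP) into an efficient, membrane-dependent
enzyme, built around the Arf1:ASAP1 system. It is aimed at structural-NMR and
enzymology groups studying peripheral membrane enzymes who need to go from
raw per-residue spectral observables to docking restraints, ensemble
validation, and a quantitative mechanistic decomposition.

The package covers five connected analyses:

1. **NMR observables** (`gapmech.peaks`) — combined chemical shift
   perturbations `CSP = sqrt(Δδ_H² + A·Δδ_X²)` (A = 0.17 for ¹⁵N, 0.185 for
   ¹³C), σ-based interface classification, and intensity ratios `I/I₀` with
   SNR-propagated errors.
2. **Docking restraints** (`gapmech.restraints`) — ambiguous interaction
   restraints (active = strong CSP ∧ relative SASA ≥ 20%; passive = exposed
   neighbors within 6.5 Å and/or moderate CSP) and unambiguous distance
   restraints (every probe with `I/I₀ < 0.2`, including resonances broadened
   beyond detection, restrained to 1.8–16 Å from the spin-label site),
   serialized as CNS-style `assign` statements.
3. **PRE forward model** (`gapmech.pre`) — Solomon–Bloembergen transverse
   rates `Γ₂ = κ·[4τ_c + 3τ_c/(1+ω_H²τ_c²)]·r⁻⁶` with `1/τ_c = 1/τ_R + 1/τ_S`,
   ⟨r⁻⁶⟩ rate-averaging over label-site samples, methyl protons and frames,
   conversion `I/I₀ = R₂·e^(−Γ₂t)/(R₂+Γ₂)`, and grid-search fitting of
   binding-pose populations mixed in rate space.
4. **Ensemble observables** (`gapmech.ensembles`) — switch-region
   center-of-mass distances to the GTP γ-phosphate, per-residue Cα distance
   shifts between ensembles, and hydrogen-bond occupancies.
5. **Membrane kinetics** (`gapmech.kinetics`) — two 11-state mass-action
   networks ("in trans" PH + ZA, "in tandem" PH–ZA fusion) with a
   reaction-shell membrane compartment, an allosteric factor α applied to
   catalysis only from the ternary complex in which the PH module is
   simultaneously lipid- and substrate-bound, endpoint dose–response
   simulation with C50 extraction, global multi-start fitting, and a
   scenario-ladder decomposition of catalytic enhancement into recruitment,
   binding and allosteric contributions.

`gapmech.synthetic` generates every input class (peak lists, two-pose
conformer ensembles, dose–response titrations, toy PDB fixtures) with known
ground truth, so the whole pipeline is testable without external data.

## Worked example

Decompose the catalytic enhancement predicted by the reference kinetic model
(substrate 1 µM, 3-minute endpoint):

```python
import gapmech.kinetics as kin

ladder = kin.decompose_enhancement()
print(ladder.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

```
                    scenario    c50_m  fold_c50_vs_za  efficiency_per_m_s  fold_efficiency_vs_za
                    za_alone 0.000234               1                  20                      1
                  phdza_pip2 6.32e-07             370            6.39e+03                    320
                  pza_nopip2 3.23e-07             725            1.07e+04                    538
           localization_only 1.63e-07        1.43e+03             1.5e+04                    750
                    pza_pip2 2.05e-10        1.14e+06             1.2e+07               6.01e+05
halved_affinity_no_allostery 1.64e-07        1.43e+03             1.5e+04                    749
```

Reading the table: the catalytic module alone (`za_alone`) needs ~0.2 mM to
hydrolyze half the substrate in 3 min. Membrane recruitment alone
(`phdza_pip2`) and substrate binding alone (`pza_nopip2`) each buy roughly
2.5–3 orders of magnitude; combining them (`localization_only`) saturates
because catalysis becomes rate-limiting; only the allosteric 1000-fold
increase in k_cat (`pza_pip2`) reaches the full ~6 orders in C50 (~6 orders
in apparent efficiency at assay conditions). Halving the PH:substrate
affinity in the no-allostery model shifts C50 by 1.003× — recruitment keeps
the enzyme substrate-saturated, so affinity barely matters there.

Fit binding-pose populations from a synthetic two-state PRE mixture:

```python
from gapmech import synthetic
from gapmech.pre import RelaxationParameters, ensemble_gamma2, fit_populations

params = RelaxationParameters()          # κ=1.23e-32 cm⁶s⁻², τ_R=70 ns, τ_S=100 ns
mix = synthetic.gen_two_state_ensemble(seed=7)   # 9:1 mixture, σ=0.02 noise
states = {"dominant": ensemble_gamma2(mix["ensemble_a"], params),
          "minor":    ensemble_gamma2(mix["ensemble_b"], params)}
fit = fit_populations(mix["observed"], states, params)
print(fit.weights, round(fit.dominant_ratio, 2), round(fit.pearson_r, 2))
# [0.9 0.1] 9.0 0.95
```

A thin CLI wraps the same library calls:

```sh
gapmech --seed 1 --outdir out generate peaklists
gapmech --outdir out observables --reference out/reference.tsv --perturbed out/perturbed.tsv
gapmech kinetics decompose
```

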