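# peroxifit

A pairwise-additive, all-atom force-field model of hydrogen peroxide
(H2O2), together with the full analysis stack used to parametrize and
evaluate such a model: trajectory-derived property estimators, liquid–vapor
coexistence analysis, and an artificial-neural-network (ANN) surrogate
optimizer. The package is aimed at molecular-simulation practitioners who
build and vet small-molecule force fields.

## The model

H2O2 is a four-site H1–O1–O2–H2 chain. Bonded terms are harmonic bonds and
angles plus a Ryckaert–Bellemans (RB) torsion

V(ψ) = Σₙ cₙ cosⁿψ,  ψ = a_d − 180°,

whose six coefficients derive from one scale c₂ through the constraints
c₀ = 0.312 c₂, c₁ = −c₂, c₃ = 0.300 c₂, c₄ = c₅ = 0. Nonbonded terms are a
Lennard-Jones potential on the oxygens only plus Coulomb interactions from
partial charges +q_H on each hydrogen and −q_H on each oxygen; all
intramolecular LJ is excluded, and intramolecular Coulomb is either fully
excluded (default) or the single 1–4 H–H pair kept at half strength (OPLS
convention). Seven physical parameters define the model; the shipped
defaults are the optimized set

d_OO = 0.1463 nm, d_OH = 0.0979 nm, a_HOO = 95.79°, q_H = 0.4323 e,
σ_OO = 0.29989 nm, ε_OO = 0.8912 kJ/mol, c₂ = 26.91 kJ/mol.

## What the package computes

- **forcefield**: geometry construction/measurement, RB torsion profile and
  its analytic stationary points, intramolecular and two-molecule energies,
  molecular dipole (site sum and closed form), gas-phase reference energy
  U_g(T) = U_g^min + 3RT.
- **estimators**: NPT fluctuation formulas (κ_T, α_P, C_P), derived caloric
  quantities (C_V = C_P − TVα_P²/κ_T, κ_S = κ_T·C_V/C_P), Kirkwood
  dielectric constant from box-dipole fluctuations, Einstein-relation
  diffusion from multi-origin MSDs, geometric hydrogen-bond counting
  (0.35 nm / 30° criterion), cosine-flow shear viscosity, enthalpy of
  vaporization ΔH_vap = U_g − U_l + RT, and the self-polarization energy
  correction E_pol = k_e(Δμ)²/(2α′).
- **coexistence**: slab density profiles, two-interface tanh phase
  partitioning, virial surface tension λ = (L_z/2)[P_N − P_T], ideal-gas
  vapor pressure, quadratic boiling-point crossing at 1.013 bar, critical
  point by rectilinear diameters + scaling law with β = 0.32, and
  Clausius–Clapeyron ΔH_vap.
- **surrogate**: [0,1]⁷-normalized small feed-forward regressors over a
  24-architecture grid (1–3 layers × {2,4,8,16} neurons × {ReLu, Sigm}),
  the weighted squared-relative-deviation target function F, a 10⁵–10⁶
  sample random search, and stochastic local refinement
  p_try = p_start + ξ ⊙ Δp with out-of-range rejection.
- **synthetic**: seeded generators that invert every estimator
  (trajectory-like series, slab profiles, coexistence curves) and a smooth
  parameter→property oracle with a constructed known optimum, emulating the
  shape of the MD training tables (7 inputs, 22 property targets).
- **gmxio / cli**: deterministic itp/gro/xvg readers and writers and a
  `peroxifit` command-line tool (`topology`, `scan`, `estimate`, `coexist`,
  `optimize`, `synth`).

## Worked example

```python
import numpy as np
from peroxifit.forcefield import (ModelParameters, build_conformation,
                                  gas_minimum, molecular_dipole)
from peroxifit.estimators import self_polarization_correction

p = ModelParameters()                     # the optimized parameter set
ref = gas_minimum(p)
print(round(ref.a_d_min, 1), round(ref.u_g_min, 2))
# 114.9 2.44      -> torsional minimum at +-114.9 deg, RB energy 2.44 kJ/mol

conf = build_conformation(p, a_d=104.0)   # most-probable liquid dihedral
print(round(float(np.linalg.norm(conf.H2 - conf.H1)), 2))
# 0.23            -> intramolecular H-H distance, the first H-H g(r) peak (nm)

_, mu = molecular_dipole(build_conformation(p, 115.0), p.q_H)
print(round(mu, 2))
# 2.17            -> molecular dipole in debye at a_d = 115 deg

print(round(self_polarization_correction(2.69, 2.05), 1),
      round(self_polarization_correction(2.69, 2.26), 1))
# 6.6 3.0         -> self-polarization correction window (kJ/mol) spanned by
#                    the experimental gas-phase dipole range 2.05-2.26 D
```

And the surrogate pipeline on synthetic training tables:

```python
from peroxifit.synthetic import OracleSpec, make_training_tables, oracle_properties
from peroxifit.surrogate import (train_surrogate, random_search, local_refine,
                                 target_function, normalize)

spec = OracleSpec(seed=0)                      # known optimum spec.u_star
train, val = make_training_tables(spec, 1000, 300, seed=0)
model = train_surrogate(train, "ReLu/1/8", seed=0)
hit = random_search(model, spec.weights, n=100_000, seed=0)
best = local_refine(hit["p_best"], 0.1 * (spec.ranges.upper() - spec.ranges.lower()),
                    lambda q: target_function(oracle_properties(q, spec), spec.weights),
                    n_iter=200, seed=1, ranges=spec.ranges)
print(np.abs(normalize(best["p_best"], spec.ranges) - spec.u_star).max().round(3))
# 0.032           -> recovered optimum within ~3% of each parameter's range
```

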