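# Methods

## Model definition and conventions

The H2O2 molecule is a four-site H1–O1–O2–H2 chain with harmonic bonds and
angles and a Ryckaert–Bellemans (RB) torsion V(ψ) = Σₙ cₙ cosⁿψ evaluated at
ψ = a_d − 180°, where a_d is the IUPAC dihedral (cis = 0°, trans = ±180°).
The six RB coefficients all derive from one scale c₂ via c₀ = 0.312 c₂,
c₁ = −c₂, c₂, c₃ = 0.300 c₂, c₄ = c₅ = 0, so the torsion is a cubic in
cos ψ. Its interior stationary point follows analytically from the quadratic
0.9x² + 2x − 1 = 0 (x = cos ψ), giving minima at a_d = ±114.87° and barrier
heights of 0.521 c₂ (trans) and 1.921 c₂ (cis) above the minimum
(0.0906 c₂). A 0.01° brute-force grid serves as the independent oracle for
these numbers in the tests.

Nonbonded interactions: Lennard-Jones on the oxygen sites only; Coulomb on
all sites with charges (+q_H, −q_H, −q_H, +q_H). Intramolecular LJ is always
excluded. Two intramolecular Coulomb policies are provided:
`exclude_all_intra` (default; all intramolecular nonbonded terms zero) and
`opls_14_half` (the single 1–4 H–H pair at half strength). Units are
engine-style throughout: nm, ps, K, kJ/mol, e, bar; dipoles are carried in
e·nm and reported in debye (1 e·nm = 48.032047 D).

The isolated-molecule (gas) reference uses equipartition over the
3N_sites − 6 internal degrees of freedom with no constraints:
U_g(T) = U_g^min + 3RT. The default torsional minimum evaluated from the
main-text energy terms is +0.0906 c₂ = +2.44 kJ/mol; because published
topologies may carry constant offsets in their torsion definitions,
`GasReference.u_g_min` is directly settable from configuration, and the
run-configuration default is −1.53 kJ/mol, the reference value commonly
used with this model for the enthalpy-of-vaporization route. The dihedral
location of the RB minimum under the stated constraints is ±114.9°, not the
±130° sometimes quoted for torsions of this shape; the package reports what
the cubic gives.

## Estimators

All trajectory energies are molar (kJ/mol for the whole system), so k_B
appears as R. Fluctuation formulas in the NPT ensemble:
κ_T = ⟨δV²⟩/(⟨V⟩RT), α_P = ⟨δVδH⟩/(⟨V⟩RT²), C_P = ⟨δH²⟩/(RT²) (reported per
mole of molecules). Derived caloric quantities:
C_V = C_P − TVα_P²/κ_T and κ_S = κ_T C_V/C_P; a non-positive C_V is rejected
as a second-law violation. Block averaging uses 10 equal blocks by default;
blocks more than three standard deviations from the all-block mean are
discarded before the final average — the same outlier rule for every
fluctuation property, which keeps the estimator uniform and testable.

The dielectric constant assumes conducting (tin-foil) Ewald boundaries:
ε = 1 + 4π k_e(⟨M²⟩ − ⟨M⟩²)/(3⟨V⟩RT), with the mean subtracted per Cartesian
component (identical to |⟨M⟩|² for equilibrated samples).

Diffusion uses the Einstein relation on an MSD averaged over all time
origins (FFT algorithm, chunked over particles). The fit window defaults to
[10%, 50%] of the series; the least-squares slope is inverse-variance
weighted with var(MSD) ∝ lag³, the scaling of an origin-averaged random
walk, because unweighted fitting lets the noisiest long lags dominate. A
negative fitted slope is clamped to zero and flagged.

Hydrogen bonds use the geometric criterion: donor-O⋯acceptor-O minimum-image
distance ≤ 0.35 nm and hydrogen–donor–acceptor angle ≤ 30° (the written
convention; acceptor–donor–hydrogen is selectable). Counts are normalized
per peroxide oxygen, per water molecule, or per total oxygen depending on
the pair class.

Viscosity uses the periodic-perturbation route: a single cosine acceleration
mode of amplitude A = 0.05 nm/ps² and wavevector k = 2π/L_z gives
η = Aρ/(⟨v_max⟩k²). The enthalpy of vaporization is
ΔH_vap = U_g(T) − U_l(T) + RT (rigid-molecule flag holds U_g constant), and
the self-polarization correction is E_pol = k_e(Δμ)²/(2α′) with
α′ = 1.3 × 1.444e−3 nm³ by default (30% above SPC/E water's polarizability
volume).

## Coexistence analysis

Slab profiles are per-species mass histograms along the long (z) axis,
normalized so the bin sum times bin volume equals the total mass exactly.
Bulk densities come from a two-interface hyperbolic-tangent fit — the
standard functional form for liquid–vapor interfaces; a profile without
density contrast signals single-phase input. Vapor pressure follows the
virial route (⟨P_zz⟩) above 2 bar and the ideal-gas route
P = Σ_s (ρ_s/M_s)RT below it, where the virial estimate loses precision.
Surface tension is virial-route, λ = (L_z/2)[⟨P_zz⟩ − (⟨P_xx⟩+⟨P_yy⟩)/2],
the ½ accounting for the two interfaces. The boiling temperature is the
crossing of a quadratic fit of P_v(T) (smallest pressures bracketing
1.013 bar) with 1.013 bar. The critical point is a simultaneous least
squares of the rectilinear-diameter law (ρ_l+ρ_v)/2 = ρ_c + A(T_c−T) and
the scaling law ρ_l−ρ_v = B(T_c−T)^β with β = 0.32 held fixed;
initialization linearizes the scaling law via (ρ_l−ρ_v)^{1/β}. P_c comes
from a linear fit of ln P_v vs 1/T extrapolated to T_c. Clausius–Clapeyron
ΔH_vap is −R times the slope of ln P_v vs 1/T (closed form for two points).

## Surrogate optimization

Inputs (7 parameters) are normalized to [0,1] by the sweep ranges
(c₂ 25.5–36 kJ/mol, q_H 0.43–0.47 e, σ_OO 0.296–0.300 nm, ε_OO 0.7–0.9
kJ/mol, d_OO 0.145–0.148 nm, d_OH 0.094–0.099 nm, a_HOO 94–102°); outputs
(22 property slots) by the training-table extrema. The 22 slots cover ρ, ε,
μ, P_v and λ for pure H2O2 and a 70 wt % peroxide–water mixture at the
simulated temperatures, plus the vapor composition for the mixture; the
layout and the handbook-typical experimental references are a documented
configuration default. The target function is
F = Σᵢ wcᵢ wpᵢ ((xᵢ − x_eᵢ)/x_eᵢ)², with wc = 1 (pure) / 0.25 (mixture) and
wp = 1 except 0.5 for viscosity. The squared form was chosen for the
aggregate (the common least-squares choice) and is isolated in one function
so an alternative aggregate is a one-line change.

Surrogates are small feed-forward regressors over the grid 1–3 layers ×
{2,4,8,16} neurons × {ReLu, Sigmoid}, trained by mini-batch (64) adaptive-
moment backpropagation with MSE loss, learning rate 3e−3, at most 1500
epochs with a plateau stopping rule, and 3 seeded restarts keeping the
lowest final loss. Mini-batching replaced a full-batch variant that stalled
above the noise floor on some seeds; everything is deterministic given the
seed. Optimization is a uniform random search over the unit cube (10⁵
samples by default in the tests; the CLI accepts 10⁶) through one or more
surrogates, keeping the per-model minimizer and a candidate pool within a
relative band of the minimum, followed by stochastic local refinement
p_try = p_start + ξ ⊙ Δp, ξ uniform in [−0.5, 0.5]⁷, with proposals outside
the ranges rejected rather than clamped. In the end-to-end pipeline the
refinement evaluates the data source itself (for synthetic studies, the
noise-free oracle — the analogue of vetting final candidates with longer,
converged simulations); refining on single noisy draws biases best-so-far
acceptance toward lucky noise.

## Synthetic data

The generators are formal inverses of their consumer estimators: correlated
Gaussian (V,H) pairs with covariance inverted from the fluctuation
formulas, isotropic Gaussian box dipoles inverted from the dielectric
formula, Gaussian random walks with per-axis step variance 2DΔt, noisy
stationary cosine-flow amplitudes, tanh slab profiles, rectilinear+scaling
density curves and Clausius–Clapeyron pressure curves. At zero noise each
round trip closes to ≤1e−6 relative. Default conditions: 2×10⁵ NPT frames,
512 walkers × 10⁴ steps, 5×10³ velocity amplitudes, 8 coexistence
temperatures with 1% density noise — sizes at which the estimators' stated
recovery tolerances (3% for κ_T/α_P/C_P/D, 5% for ε, 2% for η, 1% for ρ_l
and T_c) hold across seeds.

The parameter→property oracle emulates the *shape* of MD-produced training
tables: each property responds as x_e(1 + l·du + duᵀQdu), du = u − u*, with
a random class-scaled linear response (density weak at 0.15, viscosity
strong at 0.8 — mirroring how strongly short-run MD properties move over
these parameter ranges), a positive-semidefinite quadratic (curvature 0.3 of
the class scale), and multiplicative Gaussian noise per class (0.2% for
density up to 5% for ε, μ, P_v — the relative uncertainties typical of
short runs). Every property equals its reference exactly at the constructed
optimum u*, so F has its exact global zero there. Earlier purely-quadratic
maps produced one-signed deviations (unrealistic) and were materially harder
for 8-neuron nets without changing what the pipeline tests. The oracle makes
no attempt to mimic real H2O2 property surfaces quantitatively: passing
recovery tests demonstrates the statistical machinery, not force-field
accuracy on real trajectories; likewise the uncorrelated-noise thermo series
mean the block-error bars, not the estimates, are optimistic relative to
autocorrelated MD output.

## Numerical choices and degenerate inputs

- Torsional stationary points: 0.5° scan + bounded scalar minimization
  (ties toward smaller |a_d|); analytic cubic roots cross-checked in tests.
- Cubic ρ(T) fits and quadratic boiling fits are centered on the mean
  temperature for conditioning; α_P is invariant under temperature shifts.
- Zero-variance series return zero response functions with a warning;
  empty selections, collinear H–O–O geometries, coincident sites,
  non-bracketing boiling data and supercritical grids raise immediately.
- Degenerate (constant) training-table columns keep zero output span, so
  surrogate predictions reproduce the constant exactly.
- Force-constant numerics are configuration inputs with documented
  placeholder defaults of realistic magnitude; no headline quantity depends
  on them (bonds and angles sit at equilibrium in every closed-form result).

## Known limitations

- No MD/MC propagation, Ewald sums or periodic energy evaluation: single-
  and two-molecule energies only.
- No Green–Kubo viscosity, finite-size diffusion corrections, or quantum
  corrections to ΔH_vap.
- Block length/count for error analysis is a convention (10 blocks), not a
  fitted choice; error bars inherit the uncorrelated-noise caveat above.
- The surrogate stack trains on CPU only and covers exactly the
  24-architecture grid; no uncertainty quantification of surrogates.
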