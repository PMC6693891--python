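# Methods

## Model and assumptions

The ferritin core is treated as N classical iron spins partitioned into n
equal, magnetically independent, exchange-coupled clusters of N/n spins.
Each cluster is a rigid classical moment m_cluster = (N/n)·m_Fe; its
orientation distribution in a field B at temperature T is Boltzmann,
p(cos θ) ∝ exp(x·cos θ) with x = m_cluster·B/(k_B·T), so the mean
alignment is the Langevin function L(x) = coth x − 1/x and the particle
moment along the field is m_TOT = n·m_cluster·L(x). The treatment is
deliberately classical (no Brillouin quantization), carries no anisotropy
energy barriers, and ignores intra-particle dipolar coupling between
clusters — the clusters are independent by assumption. n = 1 and n = N
recover the superparamagnetic and paramagnetic limits.

All mechanism estimates are *upper bounds by construction*: the spatially
varying dipole field of the particle is collapsed to its surface maximum,
torques assume perpendicular geometry (sin θ = 1), the external and
particle fields add as scalars (maximal alignment), and the Einstein–de
Haas calculation uses the full saturation moment reversal. Forces and
torques are reported as magnitudes with orientation (repulsive/attractive)
carried as a flag; no vector field geometry is resolved.

The magneto-caloric transfer ΔE = T·|ΔS| assumes a complete, lossless
adiabatic hand-off from the spin ensemble to the particle lattice; no
efficiency factor or heat-diffusion model is included. Moment-fluctuation
dynamics (GHz-scale Néel/Brown processes) are out of scope: no validated
equations of motion exist for this construct, so the package stops at
energy-scale plausibility.

## Parameters

| Parameter | Symbol | Default | Why |
|---|---|---|---|
| Iron atoms per core | N | 4500 | maximum loading of the ferritin cavity |
| Atomic moment | m_Fe | 5 μ_B | highest value reported for iron in oxide form |
| Core diameter | — | 8 nm | ferritin cavity size |
| Mineral density | — | 5.24×10³ kg/m³ | magnetite |
| Temperature | T | 310 K | physiological |
| Field range | B | 0–2 T (0.01 T grid) | attainable DC laboratory magnets |
| Cluster grid | n | {1, 5, 15, 45, 450, 4500} | spans the three spin regimes; a dense integer scan is available behind `--dense-scan` |
| External gradient | ∇B | 50 T/m | optimistic bore-edge value for a superconducting magnet |
| Membrane modulus | E | 100 Pa | softest reported neural-membrane stiffness |
| Poisson ratio | ν | 0.5 | incompressible membrane |
| Susceptibility | χ | −1×10⁻⁵ | water-like; ordered lipid domains may be ~10× larger, exposed as a parameter |
| Patch radius | r | 4 nm | particle radius sets the loaded footprint |
| Loaded thickness | t | 1 nm | field and gradient decay within ~1 nm of the surface |
| Reversal time | Δt | 1 ns | plausible moment-reversal timescale; exposed as a parameter |
| Gyromagnetic ratio | γ | e/m_e | spin angular momentum convention; the g-factor correction (~0.1%) is below every tolerance used |

Constants are CODATA via scipy. Everything internal is SI; the CLI accepts
nanometres, Bohr magnetons, Tesla and Kelvin and converts at the boundary.
Non-integer cluster sizes N/n are allowed (the model is continuous in
cluster size; cluster-number scans treat n as free) with a warning when
N mod n ≠ 0.

## Numerical choices

- **Langevin stability.** For |x| < 10⁻⁴ the direct form coth x − 1/x
  cancels catastrophically; the series x/3 − x³/45 is used there (its
  truncation error at the cutoff is ~10⁻²⁰).
- **Entropy bracket.** 1 − x·coth x + ln(sinh x / x) is evaluated as a
  series −x²/6 + x⁴/60 for x < 10⁻³ (cancellation), directly for
  intermediate x, and via ln(sinh x / x) = x − ln 2x + ln(1 − e^{−2x}) for
  x > 30 (sinh overflow). Branch joins are continuity-tested.
- **Quadrature oracle.** Orientation averages are recomputed by adaptive
  quadrature (tolerance 10⁻¹²) with the integrand rescaled by e^{−x}
  (every value is exp(x(u−1)) ≤ 1), which is overflow-free for arbitrary x.
  This was preferred over switching to asymptotic closed forms at large x,
  which would have made the oracle partially dependent on the expressions
  it exists to check.
- **Monte-Carlo oracle.** cos θ is drawn by the exact inverse CDF,
  u = 1 + ln(U + (1−U)e^{−2x})/x — no rejection step, fully deterministic
  given a seed. Seeds are mandatory arguments; there is no global random
  state.
- **Ties and determinism.** The magneto-caloric argmax breaks ties toward
  smaller n; report rows are sorted (mechanism, then scenario; n then B)
  and floats are written with six significant digits, so identical inputs
  produce byte-identical CSV/JSON.
- **Degenerate inputs.** B = 0 returns exactly zero moment, energy and
  entropy change; T ≤ 0, E ≤ 0, r ≤ 0 and paramagnetic-positive χ raise.

## The scenario generator

`oracles.canonical_scenarios()` builds the study grid: the canonical
particle crossed with n ∈ {1, 5, 15, 45, 450, 4500} and
B ∈ {0.1, 0.5, 1, 2} T at 310 K, each carrying the default membrane and
Einstein–de Haas blocks and the 50 T/m external gradient. These are
parameter scenarios, not data: they emulate the *assumed* physical
conditions, so passing tests demonstrate internal consistency of the
energy-scale analysis under those assumptions — they say nothing about the
actual (unmeasured) spin configuration, iron loading, membrane
susceptibility or nanomechanics of any real magnetogenetics construct.
Scenario sets serialize to JSON and round-trip losslessly.

## Design choices where the ground was open

- The membrane indentation uses the flat-punch contact form
  d = 2(1−ν²)·r·(F/A)/E — the standard uniform-pressure result for a
  circular region on an elastic half-space — with the body force applied
  across a 1 nm shell so F/A = (F/V)·t.
- The inter-particle force uses the contact geometry of two touching
  saturated spheres: the second particle's moment times the first's
  surface gradient, not a full dipole–dipole tensor. With the canonical
  particle this bounds the force at ~10⁻¹⁰ N.
- The dense integer scan of the magneto-caloric optimum at 1 T is flat to
  <1% across n ≈ 13–15; the package reports the on-grid argmax n = 15 for
  the canonical candidate set and exposes the dense scan behind a flag.
- The paramagnetic-limit moment at 1 T computed from this model is
  ≈7.5×10⁻²² A·m². Paramagnetic figures of ≈2.4×10⁻²² A·m² circulating in
  the literature correspond to different loading assumptions (fewer iron
  atoms, smaller per-atom moments) and are *not* reproduced by the
  N = 4500, 5 μ_B parameter set; the suite pins the model value against
  the independent quadrature oracle instead.

## Comparator constants

Three literature thresholds are carried as labelled constants, never
computed: k_B·T at the scenario temperature (4.28×10⁻²¹ J at 310 K), the
~1 pN minimum mechanosensitive-gating force, and the ~1 J/kg maximum
specific loss per cycle reported for magnetic-particle hyperthermia.

## Problem sizes

Everything here is desk-scale closed-form arithmetic: the full test suite
evaluates quadrature oracles on ~40-point log grids, Monte-Carlo batteries
of 10⁴–10⁵ draws, and dense cluster scans to n = 100; the whole suite runs
in a few seconds.

## Known limitations

Upper-bound conventions mean every reported force/energy is optimistic;
real geometry, partial saturation, anisotropy and lossy energy transfer
only reduce them. The model cannot say which spin partition nature chose —
it maps the consequences of each choice. Heat transport from particle to
channel, lipid-phase effects, ion-diffusion and membrane-potential
mechanisms are out of scope.
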