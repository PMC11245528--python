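# Methods

## Model

The knock-on cycle of the KcsA selectivity filter is reduced to a two-level
system: |0⟩ is the configuration with K⁺ at sites 1,3 (waters at 2,4), |1⟩
the 2,4 configuration, with the convention σ_z|0⟩ = +|0⟩.  The opposite
sign choice only conjugates off-diagonal elements; all comparisons are
invariant under it.  The self-Hamiltonian is H_s = ½ω₀σ_z − ½Δ₀σ_x, with the
tunneling element Δ₀ identified with the ion conduction (hopping) rate and
the asymmetry ω₀ between the two near-degenerate configurations defaulting
to 0.  Units: ħ = 1, all energies are angular rates in s⁻¹, and temperature
enters only as the thermal rate k_BT/ħ (a CODATA-based Kelvin converter is
provided).

Multi-site/vacancy extensions, Coulomb repulsion between the ions, and any
claim about the biological selectivity mechanism are out of scope; the
two-configuration reduction is the model.

## Quantum route: Spin–Boson Born–Markov equation

The filter couples through σ_z to an Ohmic bath with Lorentz–Drude cutoff
J(ω) = (2Mγ₀/π)·ω·ω_c²/(ω_c²+ω²), odd in ω.  Only the lumped prefactor
Mγ₀ matters; in practice the coupling is *calibrated*:
Mγ₀ = γ_target·(Δ₀²+ω_c²)/(Δ₀ω_c²), so that the decay coefficient
γ = (π/2)J(Δ₀) equals a requested value — the presets use
γ = 0.5×10⁷ s⁻¹.  Coefficients:

* closed form (odd-J collapse plus high-temperature limit, valid for
  βω_c ≪ 1; a warning is issued above 0.1 and the mode refuses βω_c ≥ 1):
  γ = (π/2)J(Δ₀), D = γ coth(Δ₀/2k_BT),
  f = 2Mγ₀k_BT·ω_cΔ₀/(Δ₀²+ω_c²), which under calibration simplifies to
  f = 2γk_BT/ω_c (verified algebraically and in tests);
* numeric: brute-force τ-integration of the noise kernel
  ν(τ) = ∫J coth(ω/2k_BT)cos(ωτ)dω and dissipation kernel
  η(τ) = ∫J sin(ωτ)dω.  Frequency integrals are truncated at
  50·max(ω_c, k_BT) with scipy's oscillatory QAWO rule plus an analytic
  Si/Ci tail for the Lorentzian remainder (η has the closed form
  Mγ₀ω_c²e^(−ω_cτ), which the numeric kernel matches to 1e−6 relative);
  τ-integrals run over [0, 50/ω_c] on a composite Gauss–Legendre panel
  whose subdivision tracks max(Δ₀, ω_c) (8 nodes per oscillation quarter,
  at least 20 panels).  ν(0) is log-divergent in the cutoff; the truncation
  is therefore part of the kernel's definition, and the τ-quadrature nodes
  never touch τ = 0.

Two equation forms are integrated, and every output records which:

* `operator_derived` (default): dρ/dt = −i[H′_s,ρ] − D[σ_z,[σ_z,ρ]] +
  ζσ_zρσ_y + ζ*σ_yρσ_z with ζ = f − iγ and
  H′_s = ½ω₀σ_z − (½Δ₀ + ζ*)σ_x, expanded by matrix algebra.  The double
  commutator decays off-diagonals at 4D.
* `printed_component`: the published component system verbatim.  Its ρ₀₁ line
  carries the opposite sign on the 4D term (growth instead of decay), so
  integrating it at realistic D inflates the coherence exponentially.  It is
  kept for literal reproduction and for documenting the discrepancy —
  the package never silently "fixes" a printed equation.

Neither form is Lindblad.  Both share the trace derivative
2γ(ρ₀₁+ρ₁₀) from the ζ terms, so the trace drifts at rate ~2γ⟨σ_x⟩; the
drift is measured and reported per run, and an off-by-default post-hoc
renormalization ρ → ρ/Tr ρ is available.  The derived form also carries an
anti-Hermitian generator −γ[σ_x,·] from the complex Lamb term; on the
standard trajectory (ω₀ = 0 from the equal superposition) the y/z Bloch
sector never activates and Hermiticity is preserved to solver tolerance,
which the tests assert for that sector rather than claiming it in general.

Integration uses LSODA on the 8 real components (D can exceed the coherent
rates by orders of magnitude, so stiffness-capable stepping is required) at
rtol 1e−10 / atol 1e−12, recording trace drift, purity, Hermiticity defect
and the minimum eigenvalue (positivity is monitored, never enforced).

## Classical route: stochastic Hamiltonian

H(t) = H₀ + z(t)σ_z with z a real zero-mean process.

* White Gaussian noise, C(t) = αδ(t): the averaged equation is exact,
  dρ/dt = −i[H₀,ρ] − (α/2)[σ_z,[σ_z,ρ]] (off-diagonal decay 2α; trace and
  Hermiticity conserved identically).  The published component form writes
  this decay as 2γ, silently identifying α with the Spin–Boson γ; the
  package keeps α independent with default α = γ for cross-model
  comparisons and records the identification in run metadata.
* Ornstein–Uhlenbeck noise, C(t) = (α′/2τ)e^(−|t|/τ): the normative
  equation is the second-order memory-kernel master equation
  dρ/dt = −i[H₀,ρ] − [σ_z, K(t)],
  K(t) = ∫₀ᵗ ds C(t−s)U₀(t−s)[σ_z,ρ(s)]U₀†(t−s).  The published OU
  component system is asymmetric (one line keeps an unevaluated time
  integral) and cannot be made Hermiticity-consistent as printed, so it is
  treated as a non-normative symbolic instance of this operator equation.
  Two discretizations with identical contracts serve as mutual oracles:
  (a) fixed-step Heun with trapezoid quadrature over the stored ρ history
  (evaluated incrementally in the interaction picture — algebraically the
  same trapezoid sum, O(history)-free per step), and (b) an
  auxiliary-operator ODE dK/dt = C(0)[σ_z,ρ] − K/τ − i[H₀,K], exact for the
  single-exponential kernel, solved adaptively.  They agree to better than
  1e−6 on the test grids; route (b) is the default.

The OU strength and correlation time have no canonical values for the
filter; the defaults are α′ = α and τ = 10/ω_c, echoed in every output.

## Trajectory synthesis (the synthetic-data generator)

Each noise realization evolves unitarily with the exact per-step SU(2)
exponential of the traceless generator H₀Δt + φ_kσ_z — never a generic
matrix exponential — so purity is conserved to ~1e−14 over 10⁶ steps.

* White noise has no pointwise samples: paths store Wiener increments
  ΔW_k ~ N(0, Δt) and the phase kick is φ_k = √α·ΔW_k.  The normalization
  is pinned by the Δ₀ = 0 closed form: E[e^(−2i√αW_t)] = e^(−2αt), exactly
  the averaged equation's decay with the *same* α.  This is the single most
  error-prone convention in the build and is fixed by that analytic oracle.
* OU paths use the exact stationary AR(1) discretization
  z_{k+1} = z_k e^(−Δt/τ) + √((α′/2τ)(1−e^(−2Δt/τ)))·ξ_k,
  z₀ ~ N(0, α′/2τ); the phase kick is z_kΔt (left node).

Seeding: trajectory r of an ensemble draws from
`SeedSequence(base_seed).spawn(n)[r]`; ensembles are therefore deterministic
given (n, base_seed, grid), and the vectorized block propagation reproduces
individual `run_trajectory` calls to ~1e−14 (asserted in tests).  Ensemble
means carry per-time standard errors of Re/Im ρ₀₁ and the mean *per
trajectory* |ρ₀₁|, which exhibits the defining contrast: individual
coherences do not decay; only the ensemble mean does.

What the generator emulates: stationary Gaussian white/OU dephasing noise
entering through σ_z, with piecewise-constant z per step.  What it does not:
non-Gaussian or non-stationary processes, noise in the tunneling term,
continuous-time path features below the step size (the left-node OU phase
has an O(Δt/τ) bias, which the tests keep subdominant by choosing
Δt ≤ τ/100).  Passing tests therefore validate the mimicry question inside
this Gaussian dephasing class, not for arbitrary channel noise.

## Comparison layer

ΔR(t) = Re ρ₀₁^SB − Re ρ₀₁^N on a shared grid (grid mismatch is an error;
resampling is refused), with max|ΔR|, time-averaged |ΔR|, an imaginary-part
twin, and a first-crossing divergence time at a configurable threshold
(default 0.05 coherence units — "divergence at longer times" has no
canonical criterion, so the threshold is exposed, not asserted).

## Choice of the comparison bath

The bath-kernel module's default is physiological: T = 310 K
(k_BT/ħ ≈ 4.06×10¹³ s⁻¹) and ω_c = 10¹² s⁻¹ (βω_c ≈ 0.025).  In that regime
D/γ = coth(Δ₀/2k_BT) ≈ 10⁶–10⁷ across the hopping window: the Born–Markov
coherence dies within ~10⁻¹³ s while the classical-noise models decay at
2γ = 10⁷ s⁻¹, so the two pictures are maximally discrepant at every hopping
rate and the comparison is degenerate (the max|ΔR| sweep collapses to ties
at machine precision).  This is a real feature of the model, documented and
still reachable through configuration.

The *figure presets* therefore use a comparison bath chosen so the
quantum-to-classical crossover lies inside the experimental window: thermal
rate k_BT/ħ = 10⁸ s⁻¹ — the upper end of the stated conduction window — and
ω_c = 2×10⁶ s⁻¹ (βω_c = 0.02, keeping the high-temperature closed forms
valid).  Then coth(Δ₀/2k_BT) falls from ~20 at Δ₀ = 10⁷ s⁻¹ to ~2.2 at
10⁸ s⁻¹, and the white-noise agreement improves monotonically with hopping
rate, which is the phenomenology the model comparison is about.  The window
top (rather than a lower rate) matters because the ζ-term trace drift gives
max|ΔR| an asymptotic floor of 1/e as Δ₀ → ∞: with a lower thermal rate the
sweep's high end undershoots that floor and rises back, breaking
monotonicity.  At ω₀ = 0 the x/trace Bloch sector closes
(ẋ = −4Dx − 2γn, ṅ = 2γx, independent of Δ₀ and f), which is how these
statements were derived before being checked numerically.

## Numerical and test design choices

* Default comparison window: t_end = 10/min(Δ₀, 2γ) with 2001 saved points
  (several coherence oscillations and decay times for every preset).
* The Monte-Carlo check of the white-noise equation (2000 trajectories,
  Δ₀ = 10⁷, α = 0.5×10⁷ s⁻¹) uses the pointwise tolerance
  3·SE + αΔ₀Δt·t_end, the second term being a worst-case operator-splitting
  bound; the measured bias is ~25× smaller, while a wrong noise
  normalization would exceed the tolerance by a factor of ~5.
* The second-order accuracy of the memory-kernel equation is measured in
  the commuting Δ₀ = 0 sector (per-step trajectory unitaries are then exact,
  isolating the kernel truncation) as the log-coherence error at the end of
  a fixed window, which scales as α′² — the sup-norm gap over a long window
  does not, because its arg-max moves with the decay time.  Common random
  numbers across the α′ and α′/2 runs stabilize the measured ratio (~3.8–4.1
  across seeds; the test accepts 2.8–5.4).
* Noise-process statistics use a single stationary path of 10⁵ points with
  AR(1)-corrected effective sample sizes for the standard errors.
* Degenerate inputs: Δ₀ = 0 is allowed everywhere (pure-dephasing limits
  anchor the closed-form oracles); α = 0 or α′ = 0 recover unitary dynamics;
  a zero time step or empty grids are rejected.

## Known limitations

* Born–Markov only: no NIBA/TCL4/HEOM route, no strong coupling, no
  sub-/super-Ohmic spectral densities, no zero-temperature kernels.
* The trace drift of the Spin–Boson forms means long-window populations are
  not quantitatively trustworthy; the comparison statistic deliberately
  reads the coherence, and the drift is reported with every run.
* The OU memory equation is second order in the noise Hamiltonian and is
  quantitatively wrong for 2α′τ ≳ 0.5 (shown directly by the trajectory
  ensembles); conclusions drawn from it at strong noise are qualitative.
* The decoherence-time calculator is an order-of-magnitude clock; ΔX has no
  canonical value for the filter, so results are reported with all inputs
  echoed rather than asserted against a range.
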