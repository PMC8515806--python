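# Methods

This note records the model, the conventions that fix every sign and
factor, the numerical choices, and what the synthetic fixtures do and do
not emulate.

## Model

The electronic wavefunction is expanded over the field-free eigenstates of
a closed-shell molecule: the ground state |0> plus `N_states - 1` excited
states written in the configuration-interaction-singles (CIS) ansatz,
|M> = sum_{i,a} d_{i,M}^a |Phi_i^a>, where |Phi_i^a> is the spin-adapted
singlet single excitation from occupied MO i to virtual MO a. The
coefficient tensors may come from a Tamm–Dancoff-style calculation (where
they are CIS-like by construction) or from a full linear-response
calculation; in the latter case the de-excitation content makes the tensor
only approximately CIS-like, and the loader renormalizes it to unit norm
(within 1e-6, beyond which it is a schema error, not noise). Complex
orbitals, open shells, double excitations and spin–orbit coupling are out
of scope.

The wavepacket obeys i dC/dt = H(t) C with
H_LM(t) = E_M delta_LM − sum_gamma <L|mu_gamma|M> F_gamma(t), i.e. the
semiclassical dipole coupling to a classical field; ionization, nuclear
motion and dissipation are excluded. The field is a sum of Gaussian-envelope
pulses F_max exp(−(t−t0)²/2σ²) cos(ω(t−t0)+φ); the carrier is cosine so the
field peaks at the envelope center, the phase is configurable, and the
two-pulse delay is center-to-center. Intensity converts as I = |F_max|²/2
(1 a.u. of intensity = 3.50944758e16 W/cm²).

## Spin and sign conventions

All one-electron matrix elements between configurations follow from
Slater–Condon rules applied to singlet-adapted determinants,
|Phi_i^a> = (|i_alpha→a_alpha> + |i_beta→a_beta>)/sqrt(2) with *in-place*
replacement (the new spin orbital occupies the hole's slot). This
convention fixes:

- <0|O|Phi_i^a> = sqrt(2) O_ia  (the singlet factor),
- <Phi_i^a|O|Phi_j^b> = delta_ij O_ab − delta_ab O_ji
  + delta_ij delta_ab <0|O|0>  (note the **minus** on the hole term),
- occupied-MO occupation in a pure single excitation = 2 − 1 = 1, and
  <I|n_i|0> = 0 identically (the number operator cannot de-excite).

These are not taken on faith: the test suite contains a brute-force oracle
(`tests/determinant_oracle.py`) that expands every configuration into spin-
orbital determinants, counts permutation parities explicitly, and agrees
with the fast formulas to 1e-12 on every index combination of a 3×3 toy
space. The factor 2 of the spin-summed density of states is absorbed into
the ground occupations n_i0 = 2, which makes the pure-state dPDOS peak
masses exactly ±p.

## Propagation

"Second-order Euler" is implemented as the explicit leapfrog
C(t+dt) = C(t−dt) − 2i dt H(t) C(t), bootstrapped by a single exact
exponential exp(−i H(0) dt). The scheme is second-order accurate (the test
suite measures error ratios of 3.5–4.5 per dt halving) and does **not**
conserve the norm exactly; the norm is tracked at every step and the run
aborts beyond a configurable drift (default 1e-3). No renormalization is
ever applied — drift is a diagnostic of integrator error and silently
fixing it would mask the problem. At the 0.121-as production step the
drift stays below 1e-6 over 100 fs of weak-field driving.

The correctness anchor is `propagate_reference`: adaptive DOP853 at
rtol 1e-10 / atol 1e-12, which conserves the norm to 1e-10 and reproduces
field-free analytic phases. The leapfrog is validated against it, never
the other way round.

## Descriptors

- **Populations** |C_M(t)|²; their sum equals the recorded norm.
- **Induced density.** Linear mode Gamma_1 = sum_M 2 Re[C_M] Gamma_M
  assumes C_0 ≈ 1 and warns if |C_0|² < 0.9; explicit mode uses
  2 Re[C_0* C_M]. The linear form is *not* invariant under a global phase
  of the coefficients — it lives in the gauge fixed by C_0 ≈ 1 real —
  whereas populations, dPDOS, TCM and the explicit mode are phase
  invariant (and tested to be).
- **dPDOS.** Unit-area Lorentzians (HWHM eta, default 0.027 eV) on the MO
  energies, weighted by Mulliken fragment weights
  w_i^K = sum_{alpha in K, beta} d_alpha^i S_alphabeta d_beta^i and by the
  occupation changes d<n_i>(t). Because the Lorentzians have unit area,
  the energy integral collapses analytically to sum_i w_i^K d<n_i>(t) —
  the fragment charge trace carries no quadrature error, and its zero sum
  (Mulliken completeness × particle conservation) is exact to rounding.
  Curve-level integrals on a finite grid carry Lorentzian tail truncation
  ~ eta/(pi X) at distance X from a peak; conservation statements are
  therefore asserted on the analytic integrals, and the numerical
  quadrature is cross-checked at the 1e-4 level on a wide grid.
- **TCM.** TCM(e_o, e_v, t) = sum_{j,b} g(e_o−eps_j) g(e_v−eps_b)
  |sum_M C_M d_{j,M}^b|²; the squared-modulus form follows from the
  projector identity summed over both state indices, and makes the map
  non-negative. The ground state carries no singles amplitude and cannot
  contribute (asserted, not assumed). Convolution Gaussians are
  area-normalized so the map mass equals the excited population exactly
  for orthonormal states; a peak-normalized switch reproduces the
  unit-peak plotting convention. Fragment projection multiplies each
  (j, b) term by w_j^K w_b^P; the four quadrants sum to the unprojected
  map by Mulliken completeness.
- Snapshot times are matched to the nearest stored grid point (no
  interpolation); the matched time is recorded in the result object.

## Synthetic fixtures

The generators produce the study conditions, not tuned inputs:

- `make_two_level(E1, mu01)`: one excited state; the sqrt(2) singlet factor
  is folded into the MO dipole element so the *state-level* coupling is
  exactly mu01.
- `make_ladder(energies, chain)`: one occupied MO, one virtual per state;
  the state dipole matrix is exactly tridiagonal — the pump–probe test bed.
  Default demo energies reuse a typical visible chromophore setting
  (3.679 eV pump, 1.112 eV probe gap) with 15/25 fs FWHM pulses at
  5e8 W/cm², where final populations are O(1e-2) — the linear regime.
- `make_donor_acceptor`: occupied MOs Mulliken-localized (target weight
  0.95, contract ≥ 0.9) on fragment A, lowest virtual on B; state 1 is the
  pure HOMO→LUMO charge-transfer configuration at 5.4 eV. Tails of
  different size on occupied and virtual MOs prevent the Löwdin
  orthogonalization from symmetrically cancelling the delocalization.
- `make_random_system`: SPD overlap = identity + bounded symmetric jitter
  (regenerated on SPD failure), MOs orthonormalized against it, state
  vectors orthonormalized in the singles space. Used for property tests
  (Mulliken completeness over ≥100 draws, particle-number conservation).
- Volumetric synthesis uses one isotropic s-Gaussian AO per basis function
  (exponent alpha, default 0.8 bohr^-2) — enough to exercise every grid
  path without angular-momentum machinery. `make_gaussian_ao_system`
  orthonormalizes the MOs against the *analytic* Gaussian overlap so grid
  integrals of transition densities vanish as the grid refines.

All generators are bit-reproducible under a fixed seed.

What the fixtures do **not** emulate: exchange/correlation-consistent
energies and dipoles, de-excitation structure of full linear response,
degenerate-orbital complications, and realistic AO shells. Passing tests
therefore demonstrate the correctness of the algebra, the integrator and
the descriptors — not the accuracy of any electronic-structure method.

A physical caveat worth recording: for a charge-transfer state whose
occupied and virtual orbitals do not overlap spatially, the transition
density (an orbital *product*) is exponentially small while the diagonal
pair-density difference is O(phi²). The usual weak-field power counting
max|Gamma_2| ≲ |C_1| max|Gamma_1| presumes comparable field magnitudes and
holds for delocalized systems; on the donor–acceptor toy Gamma_2 can
dominate pointwise even at low intensity. The Gamma_2-vs-Gamma_1 check
accordingly runs on the delocalized Gaussian-AO fixture.

## Numerical choices and problem sizes

- Internal units: hartree / bohr / atomic time throughout; boundaries
  accept fs, eV, W/cm², Debye with explicit tags. Conversion constants are
  fixed in `excidyn.units`.
- Tolerances: MO orthonormality 1e-6 (error), excited-state orthogonality
  1e-4 (warning; error under --strict), state norm 1e-6 (renormalize below,
  error above).
- Energy grids default to 400 points per axis, spanning MO ranges padded
  by 10 eta (dPDOS) / 5 sigma (TCM).
- Test and acceptance runs use two- and three-state systems with 60–100 fs
  propagations: at 0.121 as that is ~8e5 leapfrog steps, a few seconds —
  long enough for drift and order measurements, small enough to run
  everywhere. The descriptor pipelines use a 0.25-au step, two orders
  below the leapfrog stability limit of these Hamiltonians.
- Indexing is 0-based in memory and in JSON, 1-based in user-facing text;
  every interchange file header says so.

## Known limitations

- Real orbitals/coefficients only; no complex CIS vectors.
- Whether an upstream code exports X, X+Y or X−Y normalized eigenvectors
  cannot be detected from the file; renormalization covers the norm but
  not the convention.
- Mulliken weights are basis-dependent and unbounded; degenerate MOs get
  no symmetrization.
- The MO-cube dialect (negative atom count) is read-only and restricted to
  a single data set per file.
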