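"""Time-resolved descriptors: populations, induced density, delta-PDOS,
charge traces and transition contribution maps."""

import numpy as np
import pytest

import excidyn as xd
from excidyn import units
from excidyn.model_io import SchemaError


ETA = 0.027          # eV, Lorentzian HWHM
SIG = 0.027          # eV, TCM Gaussian widths


@pytest.fixture(scope="module")
def da_run(request):
    """Donor-acceptor toy driven resonantly at weak field, plus its algebra."""
    system, states, scheme = xd.make_donor_acceptor()
    dip = xd.state_dipole_matrix(states, system)
    nb = xd.number_operator_blocks(states, system)
    w = xd.mulliken_weights(system, scheme)
    energies = np.concatenate([[0.0], states.energies])
    sigma = units.fs_to_au(units.fwhm_to_sigma(15.0))
    f = xd.intensity_to_amplitude(5e8)
    pulse = xd.Pulse(f_max=[0, 0, f], t0=units.fs_to_au(30.0), sigma=sigma,
                     omega=states.energies[0])
    traj = xd.propagate_euler2(energies, dip, [pulse], dt=0.25,
                               t_end=units.fs_to_au(60.0), store_every=50)
    return system, states, scheme, nb, w, traj


@pytest.fixture(scope="module")
def da_fields(da_run):
    system, states, _, _, _, _ = da_run
    grid = xd.GridSpec.cube_around(system.atom_coords, margin=3.0, spacing=0.5)
    tds = xd.make_transition_density(system, states, grid)
    pairs = xd.make_pair_densities(system, states, grid)
    return tds, pairs


def _ground_only_traj(n_states, n_t=5):
    times = np.linspace(0.0, 10.0, n_t)
    coeffs = np.zeros((n_t, n_states), dtype=complex)
    coeffs[:, 0] = 1.0
    return xd.Trajectory(times=times, coeffs=coeffs,
                         norm_series=np.ones(n_t),
                         field_series=np.zeros((n_t, 3)))


def _with_global_phase(traj, phi):
    return xd.Trajectory(times=traj.times, coeffs=traj.coeffs * np.exp(1j * phi),
                         norm_series=traj.norm_series,
                         field_series=traj.field_series,
                         max_norm_drift=traj.max_norm_drift)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

class TestPopulations:
    def test_field_free_ground_state(self):
        traj = _ground_only_traj(3)
        pops = xd.populations(traj)
        np.testing.assert_array_equal(pops[:, 0], 1.0)
        np.testing.assert_array_equal(pops[:, 1:], 0.0)

    def test_sum_equals_recorded_norm(self, da_run):
        *_, traj = da_run
        np.testing.assert_allclose(xd.populations(traj).sum(axis=1),
                                   traj.norm_series, rtol=1e-13)


# ---------------------------------------------------------------------------
# Induced density
# ---------------------------------------------------------------------------

class TestInducedDensity:
    def test_zero_excited_coefficients_give_zero_field(self, da_fields):
        tds, _ = da_fields
        traj = _ground_only_traj(len(tds) + 1)
        g1 = xd.induced_density(traj, tds, traj.times[-1])
        assert np.max(np.abs(g1.values)) == 0.0

    def test_linearity_in_transition_densities(self, da_run, da_fields):
        """Gamma_1 is the 2 Re[C_M]-weighted sum of the Gamma_M fields."""
        *_, traj = da_run
        tds, _ = da_fields
        k = traj.index_at(traj.times[-1])
        g1 = xd.induced_density(traj, tds, traj.times[-1])
        manual = sum(2.0 * np.real(traj.coeffs[k, 1 + m]) * tds[m].values
                     for m in range(len(tds)))
        np.testing.assert_allclose(g1.values, manual, atol=1e-15)

    def test_field_doubling_in_linear_regime(self, donor_acceptor, da_fields):
        """Doubling |F_max| doubles Gamma_1 pointwise within 2%."""
        system, states, _ = donor_acceptor
        tds, _ = da_fields
        dip = xd.state_dipole_matrix(states, system)
        energies = np.concatenate([[0.0], states.energies])
        sigma = units.fs_to_au(units.fwhm_to_sigma(10.0))
        snapshots = []
        for f0 in (5e-5, 1e-4):
            pulse = xd.Pulse(f_max=[0, 0, f0], t0=4 * sigma, sigma=sigma,
                             omega=states.energies[0])
            traj = xd.propagate_reference(energies, dip, [pulse], dt=5.0,
                                          t_end=8 * sigma)
            k = int(np.argmax(np.abs(np.real(traj.coeffs[:, 1]))))
            snapshots.append(xd.induced_density(traj, tds, traj.times[k]).values)
        ratio = (np.max(np.abs(snapshots[1])) / np.max(np.abs(snapshots[0])))
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_explicit_mode_is_phase_invariant(self, da_run, da_fields):
        *_, traj = da_run
        tds, _ = da_fields
        t = traj.times[-1]
        a = xd.induced_density(traj, tds, t, mode="explicit")
        b = xd.induced_density(_with_global_phase(traj, 1.234), tds, t,
                               mode="explicit")
        np.testing.assert_allclose(a.values, b.values, atol=1e-15)

    def test_linear_mode_warns_when_ground_state_depleted(self, da_fields):
        tds, _ = da_fields
        n = len(tds) + 1
        traj = _ground_only_traj(n)
        traj.coeffs[:, 0] = np.sqrt(0.5)
        traj.coeffs[:, 1] = np.sqrt(0.5)
        with pytest.warns(UserWarning, match="linear-regime"):
            xd.induced_density(traj, tds, traj.times[-1])

    def test_grid_mismatch_rejected(self, da_run, da_fields):
        system, *_ , traj = da_run
        tds, _ = da_fields
        bad = [tds[0],
               xd.VolumetricField(origin=tds[1].origin + 1.0, axes=tds[1].axes,
                                  values=tds[1].values)]
        with pytest.raises(SchemaError, match="congruent"):
            xd.induced_density(traj, bad, traj.times[-1])


class TestGamma2:
    def test_single_state_population_weight(self, da_fields):
        _, pairs = da_fields
        n_exc = max(k[1] for k in pairs)
        traj = _ground_only_traj(n_exc + 1)
        p = 0.04
        traj.coeffs[:, 0] = np.sqrt(1 - p)
        traj.coeffs[:, 1] = np.sqrt(p)
        g2 = xd.induced_density_gamma2(traj, pairs, traj.times[-1])
        np.testing.assert_allclose(g2.values, p * pairs[(1, 1)].values,
                                   atol=1e-15)

    def test_zero_excited_coefficients_give_zero(self, da_fields):
        _, pairs = da_fields
        n_exc = max(k[1] for k in pairs)
        traj = _ground_only_traj(n_exc + 1)
        g2 = xd.induced_density_gamma2(traj, pairs, traj.times[-1])
        assert np.max(np.abs(g2.values)) == 0.0

    def test_gamma2_is_subleading_at_weak_field(self):
        """In the linear regime Gamma_2 is at least one order of |C_1| below
        Gamma_1, evaluated where Re[C_1] peaks.  Uses a delocalized system:
        for spatially overlapping orbitals the transition and pair densities
        have comparable magnitude, so the |C|-power counting applies."""
        spec = xd.SyntheticSpec(n_ao=4, n_occ=2, n_vir=2, n_states=2, seed=21)
        system, states, alpha = xd.make_gaussian_ao_system(spec, spread=1.2)
        dip = xd.state_dipole_matrix(states, system)
        mu01 = dip.values[:, 0, 1]
        pol = mu01 / np.linalg.norm(mu01)
        sigma = units.fs_to_au(units.fwhm_to_sigma(15.0))
        f0 = 0.16 / (np.linalg.norm(mu01) * sigma * np.sqrt(2 * np.pi))
        pulse = xd.Pulse(f_max=f0 * pol, t0=4 * sigma, sigma=sigma,
                         omega=states.energies[0])
        energies = np.concatenate([[0.0], states.energies])
        traj = xd.propagate_reference(energies, dip, [pulse], dt=5.0,
                                      t_end=8 * sigma)
        grid = xd.GridSpec.cube_around(system.atom_coords, margin=4.0,
                                       spacing=0.5)
        tds = xd.make_transition_density(system, states, grid, alpha=alpha)
        pairs = xd.make_pair_densities(system, states, grid, alpha=alpha)
        k = int(np.argmax(np.abs(np.real(traj.coeffs[:, 1]))))
        t = traj.times[k]
        g1 = xd.induced_density(traj, tds, t)
        g2 = xd.induced_density_gamma2(traj, pairs, t)
        c1 = np.abs(traj.coeffs[k, 1])
        assert 0.01 < c1 < 0.3       # genuinely weak-field run
        assert np.max(np.abs(g2.values)) < c1 * np.max(np.abs(g1.values))


# ---------------------------------------------------------------------------
# Delta-PDOS
# ---------------------------------------------------------------------------

class TestDeltaPDOS:
    def test_zero_before_the_pulse(self, da_run):
        system, states, _, nb, w, traj = da_run
        curve = xd.delta_pdos(traj, nb, w, system.mo_energies, ETA, 0.0)
        assert np.max(np.abs(curve.values)) < 1e-12

    def test_pure_state_peak_masses(self, da_run):
        """Pure HOMO->LUMO wavepacket of population p: integrated HOMO peak
        is -p, LUMO peak +p (summed over fragments), by the analytic
        Lorentzian integral."""
        system, states, _, nb, w, _ = da_run
        p = 0.25
        traj = _ground_only_traj(states.n_states + 1)
        traj.coeffs[:, 0] = np.sqrt(1 - p)
        traj.coeffs[:, 1] = np.sqrt(p)
        curve = xd.delta_pdos(traj, nb, w, system.mo_energies, ETA,
                              traj.times[-1])
        n_occ = states.n_occ
        dn = curve.occupation_changes
        assert dn[n_occ - 1] == pytest.approx(-p, abs=1e-12)   # HOMO
        assert dn[n_occ] == pytest.approx(+p, abs=1e-12)       # LUMO
        assert np.sum(np.abs(dn)) == pytest.approx(2 * p, abs=1e-12)

    def test_fragment_sum_integrates_to_zero(self, da_run):
        system, states, _, nb, w, traj = da_run
        curve = xd.delta_pdos(traj, nb, w, system.mo_energies, ETA,
                              traj.times[-1])
        p_exc = np.sum(np.abs(traj.coeffs[-1, 1:]) ** 2)
        assert abs(np.sum(curve.integral())) <= 1e-6 * p_exc

    def test_phase_invariance(self, da_run):
        system, states, _, nb, w, traj = da_run
        t = traj.times[-1]
        a = xd.delta_pdos(traj, nb, w, system.mo_energies, ETA, t)
        b = xd.delta_pdos(_with_global_phase(traj, 0.77), nb, w,
                          system.mo_energies, ETA, t)
        np.testing.assert_allclose(a.values, b.values, atol=1e-14)

    def test_narrow_grid_warns(self, da_run):
        system, states, _, nb, w, traj = da_run
        grid = np.linspace(-0.1, 0.1, 50)     # misses every MO peak
        with pytest.warns(UserWarning, match="grid"):
            xd.delta_pdos(traj, nb, w, system.mo_energies, ETA,
                          traj.times[-1], grid_ev=grid)


class TestChargeTrace:
    def test_ground_state_gives_all_zeros(self, da_run):
        system, states, _, nb, w, _ = da_run
        traj = _ground_only_traj(states.n_states + 1)
        trace = xd.integrated_delta_pdos(traj, nb, w)
        assert np.max(np.abs(trace.delta_q)) == 0.0

    def test_donor_acceptor_charge_transfer_is_symmetric(self, da_run):
        """Resonant pulse moves electrons from A to B; the two fragment
        traces mirror each other at every step."""
        system, states, _, nb, w, traj = da_run
        trace = xd.integrated_delta_pdos(traj, nb, w)
        i_a = trace.labels.index("A")
        i_b = trace.labels.index("B")
        assert trace.delta_q[-1, i_b] > 1e-4          # electrons arrive on B
        assert trace.delta_q[-1, i_a] < 0.0
        np.testing.assert_allclose(trace.delta_q[:, i_a],
                                   -trace.delta_q[:, i_b], atol=1e-12)
        np.testing.assert_allclose(trace.delta_q.sum(axis=1), 0.0, atol=1e-12)

    def test_matches_numerical_quadrature_on_wide_grid(self, da_run):
        system, states, _, nb, w, traj = da_run
        t = traj.times[-1]
        grid = np.linspace(units.hartree_to_ev(system.mo_energies.min()) - 3e3 * ETA,
                           units.hartree_to_ev(system.mo_energies.max()) + 3e3 * ETA,
                           400000)
        curve = xd.delta_pdos(traj, nb, w, system.mo_energies, ETA, t,
                              grid_ev=grid)
        trace = xd.integrated_delta_pdos(traj, nb, w)
        np.testing.assert_allclose(curve.integral(analytic=False),
                                   trace.delta_q[-1], atol=1e-4)


# ---------------------------------------------------------------------------
# Transition contribution maps
# ---------------------------------------------------------------------------

class TestTCM:
    def test_ground_state_gives_zero_map(self, da_run):
        system, states, *_ = da_run
        traj = _ground_only_traj(states.n_states + 1)
        m = xd.tcm(traj, states, system.mo_energies, SIG, SIG, traj.times[-1])
        assert np.max(np.abs(m.values)) == 0.0

    def test_pure_state_single_spot(self, da_run):
        """Pure HOMO->LUMO population p: one spot at (eps_HOMO, eps_LUMO)
        with peak p g(0)^2."""
        system, states, *_ = da_run
        p = 0.2
        traj = _ground_only_traj(states.n_states + 1)
        traj.coeffs[:, 0] = np.sqrt(1 - p)
        traj.coeffs[:, 1] = np.sqrt(p)
        n_occ = states.n_occ
        eps_h = units.hartree_to_ev(system.mo_energies[n_occ - 1])
        eps_l = units.hartree_to_ev(system.mo_energies[n_occ])
        eo = np.linspace(eps_h - 5 * SIG, eps_h + 5 * SIG, 201)
        ev = np.linspace(eps_l - 5 * SIG, eps_l + 5 * SIG, 201)
        m = xd.tcm(traj, states, system.mo_energies, SIG, SIG, traj.times[-1],
                   eps_occ_grid=eo, eps_vir_grid=ev)
        g0 = 1.0 / (SIG * np.sqrt(2 * np.pi))
        assert np.max(m.values) == pytest.approx(p * g0 ** 2, rel=1e-3)
        io, iv = np.unravel_index(np.argmax(m.values), m.values.shape)
        assert eo[io] == pytest.approx(eps_h, abs=2 * (eo[1] - eo[0]))
        assert ev[iv] == pytest.approx(eps_l, abs=2 * (ev[1] - ev[0]))

    def test_mass_equals_excited_population(self, da_run):
        system, states, _, nb, w, traj = da_run
        m = xd.tcm(traj, states, system.mo_energies, SIG, SIG, traj.times[-1])
        p_exc = np.sum(np.abs(traj.coeffs[-1, 1:]) ** 2)
        assert m.mass() == pytest.approx(p_exc, abs=1e-8)

    def test_fragment_quadrants_sum_to_unprojected_map(self, da_run):
        system, states, _, nb, w, traj = da_run
        t = traj.times[-1]
        full = xd.tcm(traj, states, system.mo_energies, SIG, SIG, t)
        total = np.zeros_like(full.values)
        for pair in (("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")):
            part = xd.tcm(traj, states, system.mo_energies, SIG, SIG, t,
                          weights=w, fragment_pair=pair,
                          eps_occ_grid=full.eps_occ_grid,
                          eps_vir_grid=full.eps_vir_grid)
            total += part.values
        np.testing.assert_allclose(total, full.values, atol=1e-10)

    def test_donor_to_acceptor_quadrant_dominates(self, da_run):
        system, states, _, nb, w, traj = da_run
        k = int(np.argmax(np.abs(traj.coeffs[:, 1])))
        t = traj.times[k]
        ab = xd.tcm(traj, states, system.mo_energies, SIG, SIG, t,
                    weights=w, fragment_pair=("A", "B"))
        ba = xd.tcm(traj, states, system.mo_energies, SIG, SIG, t,
                    weights=w, fragment_pair=("B", "A"),
                    eps_occ_grid=ab.eps_occ_grid, eps_vir_grid=ab.eps_vir_grid)
        assert np.max(np.abs(ab.values)) > 100.0 * np.max(np.abs(ba.values))

    def test_phase_invariance(self, da_run):
        system, states, _, nb, w, traj = da_run
        t = traj.times[-1]
        a = xd.tcm(traj, states, system.mo_energies, SIG, SIG, t)
        b = xd.tcm(_with_global_phase(traj, 2.1), states, system.mo_energies,
                   SIG, SIG, t, eps_occ_grid=a.eps_occ_grid,
                   eps_vir_grid=a.eps_vir_grid)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_disjoint_superposition_has_no_cross_terms(self):
        """Two states sharing no configurations: the map of the coherent
        superposition is the population-weighted sum of the pure maps."""
        n_occ, n_vir = 2, 2
        coeffs = np.zeros((2, n_occ, n_vir))
        coeffs[0, 1, 0] = 1.0
        coeffs[1, 0, 1] = 1.0
        states = xd.ExcitedStateSet(energies=np.array([0.1, 0.2]), coeffs=coeffs)
        mo_energies = np.array([-0.6, -0.4, 0.3, 0.5])
        mix = _ground_only_traj(3)
        a1, a2 = 0.3 * np.exp(0.4j), 0.2 * np.exp(-1.1j)
        mix.coeffs[:, 0] = np.sqrt(1 - abs(a1) ** 2 - abs(a2) ** 2)
        mix.coeffs[:, 1] = a1
        mix.coeffs[:, 2] = a2
        t = mix.times[-1]
        m_mix = xd.tcm(mix, states, mo_energies, SIG, SIG, t)
        maps = []
        for idx, amp in ((1, a1), (2, a2)):
            pure = _ground_only_traj(3)
            pure.coeffs[:, idx] = abs(amp)
            pure.coeffs[:, 0] = np.sqrt(1 - abs(amp) ** 2)
            maps.append(xd.tcm(pure, states, mo_energies, SIG, SIG, t,
                               eps_occ_grid=m_mix.eps_occ_grid,
                               eps_vir_grid=m_mix.eps_vir_grid).values)
        np.testing.assert_allclose(m_mix.values, maps[0] + maps[1], atol=1e-10)

    def test_unknown_fragment_label_rejected(self, da_run):
        system, states, _, nb, w, traj = da_run
        with pytest.raises(SchemaError, match="fragment"):
            xd.tcm(traj, states, system.mo_energies, SIG, SIG, traj.times[-1],
                   weights=w, fragment_pair=("A", "nope"))


class TestExtremaTrace:
    def test_minmax_trace_tracks_charge_buildup(self, da_run):
        system, states, _, nb, w, traj = da_run
        t_fs, mins, maxs = xd.pdos_extrema_trace(traj, nb, w,
                                                 system.mo_energies, ETA,
                                                 grid_points=200)
        i_b = w.labels.index("B")
        assert maxs[0, i_b] == pytest.approx(0.0, abs=1e-10)
        assert maxs[-1, i_b] > 0.0
        assert mins[-1, w.labels.index("A")] < 0.0
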