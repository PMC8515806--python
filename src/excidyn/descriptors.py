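"""Time-resolved observables of the propagated wavepacket.

All descriptors consume a :class:`~excidyn.propagation.Trajectory` whose
coefficient vector is (C_0, C_1, ..., C_{N-1}) with the ground state at
index 0, together with the precomputed state algebra (number-operator
blocks, Mulliken weights, CIS coefficients).

Energy axes handed to and returned from the broadened descriptors
(delta-PDOS, TCM) are in eV, matching how these maps are read; all other
quantities stay in atomic units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import units
from .model_io import ExcitedStateSet, VolumetricField, SchemaError
from .excited_states import MullikenWeights, NumberOperatorBlocks


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class PDOSCurve:
    """Fragment-projected change of the density of states at one time."""

    energy_grid: np.ndarray        # (n_grid,) eV
    values: np.ndarray             # (n_fragments, n_grid), states / eV
    labels: list[str]
    eta: float                     # Lorentzian HWHM, eV
    time_fs: float
    occupation_changes: np.ndarray  # (n_mo,) Delta<n_i>(t), electrons
    weights: np.ndarray            # (n_mo, n_fragments) Mulliken weights

    def integral(self, analytic: bool = True) -> np.ndarray:
        """Energy integral per fragment (net electron-count change).

        Unit-area Lorentzians integrate to 1 over the full line, so the
        analytic integral is exactly sum_i w_i^K Delta<n_i>; the numerical
        variant trapezoid-integrates the stored grid and carries tail
        truncation error.
        """
        if analytic:
            return self.weights.T @ self.occupation_changes
        return np.trapezoid(self.values, self.energy_grid, axis=1)


@dataclass
class TCMMap:
    """Transition contribution map at one time, optionally fragment-projected."""

    eps_occ_grid: np.ndarray       # (n_occ_grid,) eV
    eps_vir_grid: np.ndarray       # (n_vir_grid,) eV
    values: np.ndarray             # (n_occ_grid, n_vir_grid)
    sigma_occ: float               # eV
    sigma_vir: float               # eV
    time_fs: float
    fragment_pair: tuple[str, str] | None
    pair_intensity: np.ndarray     # (n_occ, n_vir) raw orbital-pair weights

    def mass(self, analytic: bool = True) -> float:
        """Double integral of the map.

        With area-normalized Gaussians this equals the summed orbital-pair
        intensity, i.e. the total excited population for the unprojected
        map of an orthonormal state set.
        """
        if analytic:
            return float(np.sum(self.pair_intensity))
        inner = np.trapezoid(self.values, self.eps_vir_grid, axis=1)
        return float(np.trapezoid(inner, self.eps_occ_grid))


@dataclass
class ChargeTrace:
    """Net change of fragment electron counts along the trajectory."""

    times_fs: np.ndarray
    delta_q: np.ndarray            # (n_t, n_fragments), electrons
    labels: list[str]


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def populations(traj) -> np.ndarray:
    """|C_M(t)|^2 per state; rows sum to the recorded norm."""
    return np.abs(traj.coeffs) ** 2


# ---------------------------------------------------------------------------
# Induced density
# ---------------------------------------------------------------------------

def induced_density(traj, transition_densities: list[VolumetricField], t_au: float,
                    mode: str = "linear") -> VolumetricField:
    """Wavepacket-induced density Gamma_1(r, t).

    In the weak-field (linear) regime C_0(t) ~ 1 and

        Gamma_1(r, t) = sum_{M>0} 2 Re[C_M(t)] Gamma_M(r);

    ``mode="explicit"`` keeps the ground-state coefficient:
    2 Re[C_0*(t) C_M(t)].  ``transition_densities`` holds one Gamma_M field
    per excited state, on congruent grids.
    """
    if mode not in ("linear", "explicit"):
        raise ValueError("mode must be 'linear' or 'explicit'")
    n_exc = traj.n_states - 1
    if len(transition_densities) != n_exc:
        raise SchemaError(
            f"need one transition density per excited state "
            f"({n_exc}), got {len(transition_densities)}")
    ref = transition_densities[0]
    for fld in transition_densities[1:]:
        if not ref.congruent(fld):
            raise SchemaError("transition-density grids are not congruent")
    k = traj.index_at(t_au)
    c = traj.coeffs[k]
    if mode == "linear":
        p0 = abs(c[0]) ** 2
        if p0 < 0.9:
            warnings.warn(
                f"linear-regime induced density requested with |C_0|^2 = {p0:.3f} "
                f"< 0.9; the neglected ground-coefficient and excited-excited "
                f"terms are not small here -- use explicit mode", stacklevel=2)
        factors = 2.0 * np.real(c[1:])
    else:
        factors = 2.0 * np.real(np.conj(c[0]) * c[1:])
    values = np.zeros_like(ref.values)
    for f, fld in zip(factors, transition_densities):
        values += f * fld.values
    return VolumetricField(origin=ref.origin.copy(), axes=ref.axes.copy(),
                           values=values, atom_numbers=ref.atom_numbers,
                           atom_coords=ref.atom_coords)


def induced_density_gamma2(traj, pair_densities: dict, t_au: float) -> VolumetricField:
    """Second-order induced density Gamma_2(r, t) from excited-excited densities.

    Gamma_2 = sum_{L,M>0} C_L*(t) C_M(t) <L| rho(r) |M>, with the pair
    densities supplied as ``{(L, M): VolumetricField}`` using 1-based excited
    labels and (L, M) with L <= M (Hermitian completion is implied).  Kept
    separate from Gamma_1 so the weak-field neglect can be quantified.
    """
    if not pair_densities:
        raise SchemaError("pair densities are required for Gamma_2")
    k = traj.index_at(t_au)
    c = traj.coeffs[k]
    ref = next(iter(pair_densities.values()))
    values = np.zeros_like(ref.values)
    n_exc = traj.n_states - 1
    for L in range(1, n_exc + 1):
        for M in range(L, n_exc + 1):
            key = (L, M)
            if key not in pair_densities:
                raise SchemaError(f"missing pair density for states {key}")
            fld = pair_densities[key]
            if not ref.congruent(fld):
                raise SchemaError("pair-density grids are not congruent")
            w = np.conj(c[L]) * c[M]
            factor = float(np.real(w)) if L == M else 2.0 * float(np.real(w))
            values += factor * fld.values
    return VolumetricField(origin=ref.origin.copy(), axes=ref.axes.copy(),
                           values=values, atom_numbers=ref.atom_numbers,
                           atom_coords=ref.atom_coords)


# ---------------------------------------------------------------------------
# Delta-PDOS and its energy integral
# ---------------------------------------------------------------------------

def lorentzian(x: np.ndarray, eta: float) -> np.ndarray:
    """Unit-area Lorentzian of half-width-at-half-maximum eta."""
    return (eta / np.pi) / (x ** 2 + eta ** 2)


def occupation_changes(traj, nblocks: NumberOperatorBlocks, k: int) -> np.ndarray:
    """Delta<n_i>(t_k) for every MO (occupied first, then virtual).

    Delta<n_i> = sum_{I,J>0} C_I* C_J <I|n_i|J> - n_i^0 sum_{J>0} |C_J|^2;
    the ground-state PDOS is subtracted by construction and ground-excited
    cross terms are identically zero for CIS states.
    """
    c_exc = traj.coeffs[k, 1:]
    p_exc = float(np.sum(np.abs(c_exc) ** 2))
    # hole part: <I|n_i|J> = 2 delta - M_i  ->  Delta = -c+ M_i c
    d_occ = np.real(np.einsum("I,iIJ,J->i", np.conj(c_exc),
                              nblocks.occ_blocks, c_exc)) - nblocks.n0_occ * p_exc
    d_vir = np.real(np.einsum("I,bIJ,J->b", np.conj(c_exc),
                              nblocks.vir_blocks, c_exc))
    return np.concatenate([d_occ, d_vir])


def delta_pdos(traj, nblocks: NumberOperatorBlocks, weights: MullikenWeights,
               mo_energies: np.ndarray, eta_ev: float, t_au: float,
               grid_ev: np.ndarray | None = None,
               grid_points: int = 400) -> PDOSCurve:
    """Fragment-projected change of the density of states at time t.

    DeltaPDOS_K(t, eps) = sum_i w_i^K L_eta(eps - eps_i) Delta<n_i>(t),
    with unit-area Lorentzians on the MO energies (converted to eV).  The
    default grid spans the MO energy range padded by 10 eta.
    """
    eps_ev = units.hartree_to_ev(np.asarray(mo_energies, dtype=float))
    n_mo = eps_ev.shape[0]
    if weights.w.shape[0] != n_mo:
        raise SchemaError("Mulliken weights and MO energies are inconsistent")
    if nblocks.n_occ + nblocks.n_vir != n_mo:
        raise SchemaError("number-operator blocks and MO energies are inconsistent")
    if grid_ev is None:
        grid_ev = np.linspace(eps_ev.min() - 10 * eta_ev,
                              eps_ev.max() + 10 * eta_ev, grid_points)
    else:
        grid_ev = np.asarray(grid_ev, dtype=float)
        if grid_ev.min() > eps_ev.min() - eta_ev or grid_ev.max() < eps_ev.max() + eta_ev:
            warnings.warn("energy grid does not cover all MO peaks; "
                          "a substantial part of the broadened mass is truncated",
                          stacklevel=2)
    k = traj.index_at(t_au)
    dn = occupation_changes(traj, nblocks, k)
    # (n_mo, n_grid) Lorentzian profiles
    prof = lorentzian(grid_ev[None, :] - eps_ev[:, None], eta_ev)
    values = weights.w.T @ (dn[:, None] * prof)
    return PDOSCurve(energy_grid=grid_ev, values=values, labels=weights.labels,
                     eta=eta_ev, time_fs=float(traj.times[k] * units.AU_TIME_FS),
                     occupation_changes=dn, weights=weights.w)


def integrated_delta_pdos(traj, nblocks: NumberOperatorBlocks,
                          weights: MullikenWeights) -> ChargeTrace:
    """Time evolution of the net fragment charges, Delta Q_K(t).

    The Lorentzians have unit area, so the energy integral of DeltaPDOS_K
    collapses analytically to sum_i w_i^K Delta<n_i>(t): no quadrature
    error, and sum_K Delta Q_K(t) = 0 exactly (Mulliken completeness plus
    particle-number conservation).  Values are electron-count changes;
    positive means electrons arriving on the fragment.
    """
    n_t = traj.coeffs.shape[0]
    dq = np.empty((n_t, weights.w.shape[1]))
    for k in range(n_t):
        dn = occupation_changes(traj, nblocks, k)
        dq[k] = weights.w.T @ dn
    return ChargeTrace(times_fs=traj.times_fs, delta_q=dq, labels=weights.labels)


# ---------------------------------------------------------------------------
# Transition contribution map
# ---------------------------------------------------------------------------

def gaussian(x: np.ndarray, sigma: float, peak_normalized: bool = False) -> np.ndarray:
    g = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    if peak_normalized:
        return g
    return g / (sigma * np.sqrt(2.0 * np.pi))


def tcm(traj, states: ExcitedStateSet, mo_energies: np.ndarray,
        sigma_occ_ev: float, sigma_vir_ev: float, t_au: float,
        weights: MullikenWeights | None = None,
        fragment_pair: tuple[str, str] | None = None,
        eps_occ_grid: np.ndarray | None = None,
        eps_vir_grid: np.ndarray | None = None,
        grid_points: int = 400,
        peak_normalized: bool = False) -> TCMMap:
    """Time-resolved transition contribution map, optionally fragment-projected.

    TCM(eps_occ, eps_vir, t) = sum_{j,b} g_occ(eps_occ - eps_j)
    g_vir(eps_vir - eps_b) |sum_{M>0} C_M(t) d_{j,M}^b|^2, where the
    squared-modulus form follows from the projector identity
    <L|P_j^b|M> = (d_{j,L}^b)* d_{j,M}^b summed over both state indices;
    the ground state carries no singles amplitude, so it cannot contribute.
    With a fragment pair (K, P) each (j, b) term is weighted by
    w_j^K w_b^P (occupied MO on K, virtual on P).
    """
    eps_ev = units.hartree_to_ev(np.asarray(mo_energies, dtype=float))
    n_occ, n_vir = states.n_occ, states.n_vir
    if eps_ev.shape[0] != n_occ + n_vir:
        raise SchemaError("MO energies inconsistent with state coefficients")
    eps_occ = eps_ev[:n_occ]
    eps_vir = eps_ev[n_occ:]
    k = traj.index_at(t_au)
    c_exc = traj.coeffs[k, 1:]
    if c_exc.shape[0] != states.n_states:
        raise SchemaError("trajectory and state set have different state counts")
    amp = np.tensordot(c_exc, states.coeffs, axes=(0, 0))  # (n_occ, n_vir) complex
    pair = np.abs(amp) ** 2
    if fragment_pair is not None:
        if weights is None:
            raise SchemaError("fragment projection requires Mulliken weights")
        try:
            k_idx = weights.labels.index(fragment_pair[0])
            p_idx = weights.labels.index(fragment_pair[1])
        except ValueError as exc:
            raise SchemaError(f"unknown fragment label in {fragment_pair}") from exc
        w_occ = weights.w[:n_occ, k_idx]
        w_vir = weights.w[n_occ:, p_idx]
        pair = pair * np.outer(w_occ, w_vir)
    if eps_occ_grid is None:
        pad = 5 * sigma_occ_ev
        eps_occ_grid = np.linspace(eps_occ.min() - pad, eps_occ.max() + pad,
                                   grid_points)
    if eps_vir_grid is None:
        pad = 5 * sigma_vir_ev
        eps_vir_grid = np.linspace(eps_vir.min() - pad, eps_vir.max() + pad,
                                   grid_points)
    g_occ = gaussian(np.asarray(eps_occ_grid)[:, None] - eps_occ[None, :],
                     sigma_occ_ev, peak_normalized)      # (grid, n_occ)
    g_vir = gaussian(np.asarray(eps_vir_grid)[:, None] - eps_vir[None, :],
                     sigma_vir_ev, peak_normalized)      # (grid, n_vir)
    values = g_occ @ pair @ g_vir.T
    return TCMMap(eps_occ_grid=np.asarray(eps_occ_grid),
                  eps_vir_grid=np.asarray(eps_vir_grid), values=values,
                  sigma_occ=sigma_occ_ev, sigma_vir=sigma_vir_ev,
                  time_fs=float(traj.times[k] * units.AU_TIME_FS),
                  fragment_pair=fragment_pair, pair_intensity=pair)


def pdos_extrema_trace(traj, nblocks: NumberOperatorBlocks,
                       weights: MullikenWeights, mo_energies: np.ndarray,
                       eta_ev: float, grid_points: int = 400):
    """Minimum and maximum of each fragment's DeltaPDOS curve along time.

    Returns (times_fs, minima, maxima) with shapes (n_t,), (n_t, n_frag),
    (n_t, n_frag).  Simple postprocessing of the curve at every stored step.
    """
    n_t = traj.coeffs.shape[0]
    n_frag = weights.w.shape[1]
    minima = np.empty((n_t, n_frag))
    maxima = np.empty((n_t, n_frag))
    for k in range(n_t):
        curve = delta_pdos(traj, nblocks, weights, mo_energies, eta_ev,
                           traj.times[k], grid_points=grid_points)
        minima[k] = curve.values.min(axis=1)
        maxima[k] = curve.values.max(axis=1)
    return traj.times_fs, minima, maxima
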