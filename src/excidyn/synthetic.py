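"""Self-consistent synthetic model systems for the full pipeline.

Real inputs to this package come from quantum-chemistry exports (excitation
energies, CIS-like eigenvectors, MO data).  This module builds algebraically
consistent stand-ins -- minimal two-level and ladder systems for pulse
physics, random systems for property tests, a donor-acceptor toy for
charge-transfer descriptors, and analytic s-Gaussian volumetric transition
densities -- so every operation can be exercised without any electronic-
structure code.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .model_io import (ElectronicSystem, ExcitedStateSet, FragmentScheme,
                       VolumetricField, SchemaError)


@dataclass
class SyntheticSpec:
    """Dimensions and style of a randomly generated model system."""

    n_ao: int = 8
    n_occ: int = 3
    n_vir: int = 5
    n_states: int = 4
    n_fragments: int = 2
    seed: int = 0
    overlap_style: str = "jittered"    # "identity" | "jittered" | "gaussian"
    locality: float = 0.95             # donor-acceptor Mulliken localization target

    def validate(self) -> None:
        if self.n_occ + self.n_vir > self.n_ao:
            raise SchemaError("n_occ + n_vir must not exceed n_ao")
        if self.n_states > self.n_occ * self.n_vir:
            raise SchemaError("more states than singles space dimensions")
        if not 0.5 < self.locality <= 1.0:
            raise SchemaError("locality must lie in (0.5, 1]")


def _minimal_system(n_occ, n_vir, mo_energies, mo_dipoles, atom_of_mo=None,
                    atom_coords=None, ground_dipole=(0.0, 0.0, 0.0)):
    """One AO per MO, identity overlap: the smallest valid ElectronicSystem."""
    n_mo = n_occ + n_vir
    if atom_of_mo is None:
        atom_of_mo = np.zeros(n_mo, dtype=int)
        atom_coords = np.zeros((1, 3))
    occ = np.zeros(n_mo, dtype=int)
    occ[:n_occ] = 2
    return ElectronicSystem(
        mo_energies=np.asarray(mo_energies, dtype=float),
        mo_coeffs=np.eye(n_mo),
        ao_overlap=np.eye(n_mo),
        occupations=occ,
        mo_dipoles=np.asarray(mo_dipoles, dtype=float),
        ao_to_atom=np.asarray(atom_of_mo, dtype=int),
        atom_coords=np.asarray(atom_coords, dtype=float),
        ground_dipole=np.asarray(ground_dipole, dtype=float),
    )


def make_two_level(e1_ev: float, mu01_au: float):
    """Two-level (ground + one excited state) system, Rabi test bed.

    The single excited state sits at ``e1_ev`` above the ground state and
    couples to it with a transition dipole of exactly ``mu01_au`` along z
    (the sqrt(2) singlet factor is absorbed into the MO dipole element so
    the *state-level* dipole is what the caller asked for).
    """
    if e1_ev <= 0:
        raise SchemaError("excitation energy must be positive")
    e1 = units.ev_to_hartree(e1_ev)
    mo_energies = np.array([-e1 / 2.0, e1 / 2.0])
    mu = np.zeros((3, 2, 2))
    mu[2, 0, 1] = mu[2, 1, 0] = mu01_au / np.sqrt(2.0)
    system = _minimal_system(1, 1, mo_energies, mu)
    coeffs = np.ones((1, 1, 1))
    states = ExcitedStateSet(energies=np.array([e1]), coeffs=coeffs, tda_flag=True)
    return system, states


def make_ladder(energies_ev, dipole_chain_au):
    """N-level ladder: state dipoles couple only adjacent states.

    ``energies_ev`` are the excited-state energies (ascending);
    ``dipole_chain_au`` the couplings (mu_01, mu_12, ...) with
    len = n_states.  Realized with one occupied MO and one virtual MO per
    state (state M = pure HOMO -> virtual_M configuration), which makes the
    state-level dipole matrix exactly tridiagonal.
    """
    energies_ev = np.asarray(energies_ev, dtype=float)
    chain = np.asarray(dipole_chain_au, dtype=float)
    n = energies_ev.shape[0]
    if chain.shape[0] != n:
        raise SchemaError("need one chain coupling per state (incl. ground->1)")
    if np.any(np.diff(energies_ev) <= 0) or np.any(energies_ev <= 0):
        raise SchemaError("ladder energies must be positive ascending")
    e_au = units.ev_to_hartree(1.0) * energies_ev
    n_mo = 1 + n
    homo = -e_au[0] / 2.0
    mo_energies = np.concatenate([[homo], e_au + homo])
    mu = np.zeros((3, n_mo, n_mo))
    mu[2, 0, 1] = mu[2, 1, 0] = chain[0] / np.sqrt(2.0)   # ground <-> state 1
    for m in range(1, n):
        # virtual MO of state m sits at column m, of state m+1 at m+1
        mu[2, m, m + 1] = mu[2, m + 1, m] = chain[m]      # state m <-> m+1
    system = _minimal_system(1, n, mo_energies, mu)
    coeffs = np.zeros((n, 1, n))
    for m in range(n):
        coeffs[m, 0, m] = 1.0
    states = ExcitedStateSet(energies=e_au, coeffs=coeffs, tda_flag=True)
    return system, states


def _spd_overlap(rng: np.random.Generator, n_ao: int, jitter: float = 0.15,
                 max_tries: int = 50) -> np.ndarray:
    """Identity plus bounded symmetric jitter, regenerated until SPD."""
    for _ in range(max_tries):
        j = rng.uniform(-jitter, jitter, size=(n_ao, n_ao))
        s = np.eye(n_ao) + 0.5 * (j + j.T)
        np.fill_diagonal(s, 1.0)
        if np.linalg.eigvalsh(s).min() > 0.05:
            return s
    raise RuntimeError("failed to draw an SPD overlap")


def _orthonormal_mos(rng: np.random.Generator, s: np.ndarray, n_mo: int) -> np.ndarray:
    """MO coefficients with C^T S C = I: S^{-1/2} times a random orthogonal block."""
    vals, vecs = np.linalg.eigh(s)
    s_inv_half = vecs @ np.diag(vals ** -0.5) @ vecs.T
    q, _ = np.linalg.qr(rng.normal(size=(s.shape[0], n_mo)))
    return s_inv_half @ q


def _orthonormal_states(rng: np.random.Generator, n_states: int, n_occ: int,
                        n_vir: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(n_occ * n_vir, n_states)))
    return q.T.reshape(n_states, n_occ, n_vir)


def make_random_system(spec: SyntheticSpec):
    """Random valid (ElectronicSystem, ExcitedStateSet, FragmentScheme) triple."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_mo = spec.n_occ + spec.n_vir
    if spec.overlap_style == "identity":
        s = np.eye(spec.n_ao)
    elif spec.overlap_style == "jittered":
        s = _spd_overlap(rng, spec.n_ao)
    else:
        raise SchemaError(f"unknown overlap_style {spec.overlap_style!r} "
                          "(use gaussian_ao_system for analytic overlaps)")
    c = _orthonormal_mos(rng, s, n_mo)
    mo_energies = np.sort(rng.uniform(-1.0, 1.0, size=n_mo))
    mu = rng.normal(scale=0.5, size=(3, n_mo, n_mo))
    mu = 0.5 * (mu + np.swapaxes(mu, 1, 2))
    n_atoms = max(spec.n_fragments, spec.n_ao // 2)
    ao_to_atom = np.sort(rng.integers(0, n_atoms, size=spec.n_ao))
    ao_to_atom[:n_atoms] = np.arange(n_atoms)   # every atom carries >= 1 AO
    ao_to_atom = np.sort(ao_to_atom)
    atom_coords = rng.normal(scale=2.0, size=(n_atoms, 3))
    occ = np.zeros(n_mo, dtype=int)
    occ[:spec.n_occ] = 2
    system = ElectronicSystem(
        mo_energies=mo_energies, mo_coeffs=c, ao_overlap=s, occupations=occ,
        mo_dipoles=mu, ao_to_atom=ao_to_atom, atom_coords=atom_coords,
        ground_dipole=rng.normal(scale=0.5, size=3))
    system.validate()
    energies = np.sort(rng.uniform(0.05, 0.5, size=spec.n_states))
    states = ExcitedStateSet(
        energies=energies,
        coeffs=_orthonormal_states(rng, spec.n_states, spec.n_occ, spec.n_vir),
        tda_flag=True)
    states.validate()
    bounds = np.linspace(0, n_atoms, spec.n_fragments + 1).astype(int)
    frags = [list(range(bounds[i], bounds[i + 1])) for i in range(spec.n_fragments)]
    scheme = FragmentScheme(fragments=frags,
                            labels=[f"F{i + 1}" for i in range(spec.n_fragments)])
    scheme.validate(n_atoms=n_atoms)
    return system, states, scheme


def make_donor_acceptor(spec: SyntheticSpec | None = None, e1_ev: float = 5.4,
                        mu01_au: float = 1.5):
    """Two-fragment charge-transfer toy: occupied MOs on A, lowest virtual on B.

    The first excited state is the pure HOMO(A) -> LUMO(B) configuration, so
    a resonant pulse moves electron density from fragment A to fragment B
    -- the synthetic analogue of an intramolecular charge-transfer
    excitation.  ``spec.locality`` sets the Mulliken weight of each MO on
    its home fragment (default 0.95, >= 0.9 required).
    """
    spec = spec or SyntheticSpec(n_ao=4, n_occ=2, n_vir=2, n_states=2,
                                 n_fragments=2)
    spec.validate()
    if spec.n_fragments != 2:
        raise SchemaError("donor-acceptor toy requires exactly 2 fragments")
    if spec.locality < 0.9:
        raise SchemaError("donor-acceptor localization below the w >= 0.9 contract")
    n_occ, n_vir = spec.n_occ, spec.n_vir
    n_mo = n_occ + n_vir
    n_ao = n_mo                       # one AO per MO, identity overlap
    # AOs 0..n_occ-1 on fragment A atoms, the rest on fragment B atoms
    delta = np.sqrt(1.0 / spec.locality - 1.0)
    c = np.zeros((n_ao, n_mo))
    home = list(range(n_occ)) + list(range(n_occ, n_mo))
    away = list(range(n_occ, n_mo)) + list(range(n_occ))
    # tails of different size on occupied vs virtual MOs keep the Lowdin
    # orthogonalization from cancelling the delocalization symmetrically
    for m in range(n_mo):
        c[home[m], m] = 1.0
        c[away[m], m] = delta if m < n_occ else 0.4 * delta
    # Lowdin-orthonormalize while keeping the localization (delta is small)
    g = c.T @ c
    vals, vecs = np.linalg.eigh(g)
    c = c @ (vecs @ np.diag(vals ** -0.5) @ vecs.T)
    e1 = units.ev_to_hartree(e1_ev)
    gap = e1
    mo_energies = np.concatenate([
        np.linspace(-gap, -gap / 2.0, n_occ),
        np.linspace(gap / 2.0, gap, n_vir)])
    mo_energies[n_occ - 1] = -e1 / 2.0
    mo_energies[n_occ] = e1 / 2.0
    mo_energies = np.sort(mo_energies)
    mu = np.zeros((3, n_mo, n_mo))
    mu[2, n_occ - 1, n_occ] = mu[2, n_occ, n_occ - 1] = mu01_au / np.sqrt(2.0)
    atom_coords = np.array([[-2.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    ao_to_atom = np.array([0] * n_occ + [1] * n_vir)
    occ = np.zeros(n_mo, dtype=int)
    occ[:n_occ] = 2
    system = ElectronicSystem(
        mo_energies=mo_energies, mo_coeffs=c, ao_overlap=np.eye(n_ao),
        occupations=occ, mo_dipoles=mu, ao_to_atom=ao_to_atom,
        atom_coords=atom_coords, ground_dipole=np.zeros(3))
    system.validate()
    scheme = FragmentScheme(fragments=[[0], [1]], labels=["A", "B"])
    # state 1: HOMO -> LUMO (A -> B); state 2: HOMO-1 -> LUMO+1 if available
    n_states = min(spec.n_states, 2 if (n_occ > 1 and n_vir > 1) else 1)
    coeffs = np.zeros((n_states, n_occ, n_vir))
    coeffs[0, n_occ - 1, 0] = 1.0
    energies = [e1]
    if n_states > 1:
        coeffs[1, n_occ - 2, 1] = 1.0
        energies.append(e1 * 1.6)
    states = ExcitedStateSet(energies=np.array(energies), coeffs=coeffs,
                             tda_flag=True)
    states.validate()
    # verify the localization contract
    from .excited_states import mulliken_weights
    w = mulliken_weights(system, scheme).w
    if w[n_occ - 1, 0] < 0.9 or w[n_occ, 1] < 0.9:
        raise RuntimeError("requested localization not achieved")
    return system, states, scheme


# ---------------------------------------------------------------------------
# Analytic s-Gaussian AO model and volumetric transition densities
# ---------------------------------------------------------------------------

def make_gaussian_ao_system(spec: SyntheticSpec, alpha: float = 0.8,
                            spread: float = 2.5):
    """Random system whose AO overlap is the analytic s-Gaussian overlap.

    One normalized Gaussian ``(2 alpha / pi)^(3/4) exp(-alpha |r - R|^2)``
    per atom site; MOs are orthonormalized against the *analytic* overlap,
    so grid integrals of MO products converge to Kronecker deltas.  Use
    this fixture whenever volumetric output is being tested.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_mo = spec.n_occ + spec.n_vir
    centers = rng.uniform(-spread, spread, size=(spec.n_ao, 3))
    s = _analytic_overlap(centers, alpha)
    c = _orthonormal_mos(rng, s, n_mo)
    mo_energies = np.sort(rng.uniform(-1.0, 1.0, size=n_mo))
    mu = rng.normal(scale=0.5, size=(3, n_mo, n_mo))
    mu = 0.5 * (mu + np.swapaxes(mu, 1, 2))
    occ = np.zeros(n_mo, dtype=int)
    occ[:spec.n_occ] = 2
    system = ElectronicSystem(
        mo_energies=mo_energies, mo_coeffs=c, ao_overlap=s, occupations=occ,
        mo_dipoles=mu, ao_to_atom=np.arange(spec.n_ao),
        atom_coords=centers, ground_dipole=np.zeros(3))
    system.validate()
    energies = np.sort(rng.uniform(0.05, 0.5, size=spec.n_states))
    states = ExcitedStateSet(
        energies=energies,
        coeffs=_orthonormal_states(rng, spec.n_states, spec.n_occ, spec.n_vir),
        tda_flag=True)
    return system, states, alpha


def _analytic_overlap(centers: np.ndarray, alpha: float) -> np.ndarray:
    """<g_A|g_B> = exp(-alpha |R_A - R_B|^2 / 2) for equal exponents alpha."""
    diff = centers[:, None, :] - centers[None, :, :]
    return np.exp(-0.5 * alpha * np.sum(diff ** 2, axis=-1))


def _ao_values_on_grid(centers: np.ndarray, alpha: float, grid_xyz: np.ndarray
                       ) -> np.ndarray:
    """Normalized s-Gaussian values, shape (n_ao, n_points)."""
    norm = (2.0 * alpha / np.pi) ** 0.75
    d2 = np.sum((grid_xyz[None, :, :] - centers[:, None, :]) ** 2, axis=-1)
    return norm * np.exp(-alpha * d2)


@dataclass
class GridSpec:
    """Regular orthogonal voxel grid for volumetric synthesis."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]

    @classmethod
    def cube_around(cls, coords: np.ndarray, margin: float = 4.0,
                    spacing: float = 0.4) -> "GridSpec":
        lo = coords.min(axis=0) - margin
        hi = coords.max(axis=0) + margin
        shape = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
        return cls(origin=lo, spacing=spacing, shape=shape)

    def points(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        pts = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3) * self.spacing
        return pts + self.origin

    def axes(self) -> np.ndarray:
        return np.eye(3) * self.spacing


def make_transition_density(system: ElectronicSystem, states: ExcitedStateSet,
                            grid: GridSpec, alpha: float = 0.8
                            ) -> list[VolumetricField]:
    """Volumetric Gamma_M(r) = sqrt(2) sum_{i,a} d_{i,M}^a phi_i(r) phi_a(r).

    The AO model is one isotropic s-Gaussian of exponent ``alpha`` per
    basis function at its atom's site (the singlet sqrt(2) follows the
    package-wide spin convention).  Warns when the grid spacing is too
    coarse to resolve the AO width.
    """
    import warnings
    width = 1.0 / np.sqrt(2.0 * alpha)
    if grid.spacing > width:
        warnings.warn(
            f"grid spacing {grid.spacing:.2f} bohr exceeds the AO width "
            f"{width:.2f} bohr; volumetric output will be poorly resolved",
            stacklevel=2)
    centers = system.atom_coords[np.asarray(system.ao_to_atom)]
    pts = grid.points()
    ao_vals = _ao_values_on_grid(centers, alpha, pts)          # (n_ao, n_pts)
    mo_vals = system.mo_coeffs.T @ ao_vals                     # (n_mo, n_pts)
    occ = system.occupied
    vir = system.virtual
    fields = []
    for m in range(states.n_states):
        d = states.coeffs[m]                                   # (n_occ, n_vir)
        occ_amp = d @ mo_vals[vir]                             # (n_occ, n_pts)
        gamma = np.sqrt(2.0) * np.sum(mo_vals[occ] * occ_amp, axis=0)
        fields.append(VolumetricField(
            origin=np.asarray(grid.origin, dtype=float),
            axes=grid.axes(),
            values=gamma.reshape(grid.shape),
            atom_numbers=np.ones(system.n_atoms, dtype=int),
            atom_coords=system.atom_coords))
    return fields


def make_pair_densities(system: ElectronicSystem, states: ExcitedStateSet,
                        grid: GridSpec, alpha: float = 0.8) -> dict:
    """Excited-excited density fluctuations <L| rho(r) |M> - delta_LM rho_0(r).

    Built from the same Slater-Condon algebra as the dipole matrix, with
    the operator replaced by the point density phi_s(r) phi_t(r).  Keys are
    1-based (L, M) with L <= M.  Subtracting the ground density from the
    diagonal makes Gamma_2 the genuine second-order induced term, O(|C|^2).
    """
    centers = system.atom_coords[np.asarray(system.ao_to_atom)]
    pts = grid.points()
    ao_vals = _ao_values_on_grid(centers, alpha, pts)
    mo_vals = system.mo_coeffs.T @ ao_vals
    occ = system.occupied
    vir = system.virtual
    out = {}
    for li in range(states.n_states):
        for mi in range(li, states.n_states):
            dl = states.coeffs[li]
            dm = states.coeffs[mi]
            # particle term: sum_i (d_L^T)_{a i} (d_M)_{i b} phi_a phi_b
            pv = np.einsum("ia,ib->ab", dl, dm)
            # hole term: sum_a d_{i,L}^a d_{j,M}^a phi_i phi_j
            ho = np.einsum("ia,ja->ij", dl, dm)
            vals = (np.einsum("ab,ap,bp->p", pv, mo_vals[vir], mo_vals[vir],
                              optimize=True)
                    - np.einsum("ij,ip,jp->p", ho, mo_vals[occ], mo_vals[occ],
                                optimize=True))
            out[(li + 1, mi + 1)] = VolumetricField(
                origin=np.asarray(grid.origin, dtype=float),
                axes=grid.axes(),
                values=vals.reshape(grid.shape),
                atom_numbers=np.ones(system.n_atoms, dtype=int),
                atom_coords=system.atom_coords)
    return out
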