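"""Algebra on the CIS ansatz for closed-shell singlet excited states.

An excited state |M> = sum_{i,a} d_{i,M}^a |Phi_i^a>, where |Phi_i^a> is the
spin-adapted singlet single excitation i -> a.  For a spin-free one-electron
operator O with MO matrix O_st the Slater-Condon rules give

    <Phi_i^a| O |Phi_j^b> = delta_ij O_ab - delta_ab O_ji
                            + delta_ij delta_ab <0|O|0>
    <0| O |Phi_i^a>       = sqrt(2) O_ia

(the sqrt(2) is the singlet spin-adaptation factor).  These formulas are
checked sign-by-sign against an explicit determinant-expansion oracle in the
test suite.  All coefficients are real; complex orbitals are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import ElectronicSystem, ExcitedStateSet, FragmentScheme, SchemaError


@dataclass
class DipoleMatrix:
    """State-state dipole matrix, ground state at index 0.

    ``values`` has shape (3, n_states + 1, n_states + 1); each Cartesian
    component is real-symmetric.  Diagonal entries are permanent state
    dipoles, off-diagonal entries transition dipoles (a.u.).
    """

    values: np.ndarray

    @property
    def n_states(self) -> int:
        return self.values.shape[1] - 1

    def component(self, gamma: int) -> np.ndarray:
        return self.values[gamma]


@dataclass
class MullikenWeights:
    """Per-MO fragment weights w_i^K; rows sum to 1 for normalized MOs."""

    w: np.ndarray          # (n_mo, n_fragments)
    labels: list[str]

    @property
    def totals(self) -> np.ndarray:
        return self.w.sum(axis=1)


@dataclass
class NumberOperatorBlocks:
    """Excited-block matrix elements of the MO number operators.

    ``occ_blocks[i]`` is the (n_states x n_states) matrix <I| n_i |J> for
    occupied MO i; ``vir_blocks[b]`` likewise for virtual MO b.  Ground-state
    occupations are 2 (occupied) and 0 (virtual); ground-excited cross
    elements <I| n_i |0> vanish identically for CIS states and are not
    stored.
    """

    occ_blocks: np.ndarray     # (n_occ, n_states, n_states)
    vir_blocks: np.ndarray     # (n_vir, n_states, n_states)
    n0_occ: float = 2.0

    @property
    def n_occ(self) -> int:
        return self.occ_blocks.shape[0]

    @property
    def n_vir(self) -> int:
        return self.vir_blocks.shape[0]

    @property
    def n_states(self) -> int:
        return self.occ_blocks.shape[1]


def config_dipole_element(i: int, a: int, j: int, b: int,
                          mo_dipoles: np.ndarray,
                          ground_dipole: np.ndarray,
                          n_occ: int) -> np.ndarray:
    """<Phi_i^a| mu |Phi_j^b> for singlet configurations, per component.

    ``i, j`` are occupied MO indices (< n_occ) and ``a, b`` virtual MO
    indices (>= n_occ), all 0-based global MO indices.  ``ground_dipole``
    enters the fully diagonal element <Phi_i^a| mu |Phi_i^a> =
    ground_dipole - mu_ii + mu_aa.
    """
    mo_dipoles = np.asarray(mo_dipoles)
    n_mo = mo_dipoles.shape[1]
    if not (0 <= i < n_occ and 0 <= j < n_occ):
        raise IndexError("i and j must be occupied MO indices")
    if not (n_occ <= a < n_mo and n_occ <= b < n_mo):
        raise IndexError("a and b must be virtual MO indices")
    out = np.zeros(3)
    if i == j:
        out += mo_dipoles[:, a, b]
    if a == b:
        out -= mo_dipoles[:, j, i]
    if i == j and a == b:
        out += np.asarray(ground_dipole, dtype=float)
    return out


def ground_config_dipole_element(i: int, a: int, mo_dipoles: np.ndarray) -> np.ndarray:
    """<0| mu |Phi_i^a> = sqrt(2) mu_ia (singlet spin adaptation)."""
    return np.sqrt(2.0) * np.asarray(mo_dipoles)[:, i, a]


def state_dipole_matrix(states: ExcitedStateSet,
                        system: ElectronicSystem) -> DipoleMatrix:
    """Full (ground + excited) state-state dipole matrix from Eq-1-style states.

    Contraction of the configuration-level Slater-Condon elements with the
    CIS coefficient tensors:

        mu_0M = sqrt(2) sum_{ia} d_{i,M}^a mu_ia
        mu_LM = sum_i (d_L^T mu_vv d_M)_ii - sum_a (d_L mu_oo^T d_M^T)_aa
                + <d_L|d_M> mu_00

    Requires ``system.ground_dipole`` for the diagonal (and the <d_L|d_M>
    term, which only touches the diagonal for orthonormal states).
    """
    if system.ground_dipole is None:
        raise SchemaError("ground_dipole is required to build the state dipole matrix")
    occ = system.occupied
    vir = system.virtual
    if states.n_occ != len(occ) or states.n_vir != len(vir):
        raise SchemaError("state coefficient dimensions inconsistent with system")
    d = states.coeffs                                  # (S, o, v)
    S = states.n_states
    mu = np.asarray(system.mo_dipoles)
    mu_ov = mu[:, occ[:, None], vir[None, :]]          # (3, o, v)
    mu_oo = mu[:, occ[:, None], occ[None, :]]          # (3, o, o)
    mu_vv = mu[:, vir[:, None], vir[None, :]]          # (3, v, v)

    out = np.zeros((3, S + 1, S + 1))
    g0 = np.asarray(system.ground_dipole, dtype=float)
    out[:, 0, 0] = g0
    # ground <-> excited block
    out[:, 0, 1:] = np.sqrt(2.0) * np.einsum("Mia,gia->gM", d, mu_ov)
    out[:, 1:, 0] = out[:, 0, 1:]
    # excited block
    ovl = d.reshape(S, -1) @ d.reshape(S, -1).T        # <d_L|d_M>
    term_v = np.einsum("Lia,gab,Mib->gLM", d, mu_vv, d, optimize=True)
    term_o = np.einsum("Lia,gji,Mja->gLM", d, mu_oo, d, optimize=True)
    out[:, 1:, 1:] = term_v - term_o + ovl[None] * g0[:, None, None]
    # enforce exact symmetry against einsum round-off asymmetry
    out = 0.5 * (out + np.swapaxes(out, 1, 2))
    return DipoleMatrix(values=out)


def mulliken_weights(system: ElectronicSystem,
                     fragments: FragmentScheme) -> MullikenWeights:
    """Collective Mulliken weight of each MO on each atom fragment.

    w_i^K = sum_{alpha in K} sum_beta d_alpha^i S_alphabeta d_beta^i;
    over all fragments the weights sum to 1 for S-normalized MOs (individual
    weights can be negative -- Mulliken partitioning is not bounded).
    """
    fragments.validate(n_atoms=system.n_atoms)
    C = np.asarray(system.mo_coeffs, dtype=float)
    S = np.asarray(system.ao_overlap, dtype=float)
    SC = S @ C                                         # (ao, mo)
    per_ao = C * SC                                    # rho_alpha,i = d_a^i (S d)_a^i
    ao_atom = np.asarray(system.ao_to_atom)
    w = np.zeros((system.n_mo, fragments.n_fragments))
    for k, atoms in enumerate(fragments.fragments):
        mask = np.isin(ao_atom, list(atoms))
        w[:, k] = per_ao[mask, :].sum(axis=0)
    return MullikenWeights(w=w, labels=list(fragments.labels))


def number_operator_blocks(states: ExcitedStateSet,
                           system: ElectronicSystem) -> NumberOperatorBlocks:
    """Matrix elements <I| n_i |J> of MO number operators between CIS states.

    For occupied i:  <I| n_i |J> = 2 delta_IJ - sum_a d_{i,I}^a d_{i,J}^a
    For virtual  b:  <I| n_b |J> = sum_j d_{j,I}^b d_{j,J}^b

    The hole in a pure singlet single excitation removes exactly one
    electron from the occupied MO (2 -> 1); ground-excited cross elements
    vanish because n_i cannot de-excite a singly excited determinant back to
    the reference.
    """
    occ = system.occupied
    vir = system.virtual
    if states.n_occ != len(occ) or states.n_vir != len(vir):
        raise SchemaError("state coefficient dimensions inconsistent with system")
    d = states.coeffs                                  # (S, o, v)
    S = states.n_states
    hole = np.einsum("Iia,Jia->iIJ", d, d)             # (o, S, S)
    part = np.einsum("Ijb,Jjb->bIJ", d, d)             # (v, S, S)
    eye = np.eye(S)
    occ_blocks = 2.0 * eye[None, :, :] - hole
    return NumberOperatorBlocks(occ_blocks=occ_blocks, vir_blocks=part, n0_occ=2.0)
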