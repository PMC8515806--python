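"""Brute-force Slater-determinant oracle for one-electron matrix elements.

This module is the independent reference for every sign and spin factor used
by the fast CIS algebra: determinants are explicit ordered lists of spin
orbitals, matrix elements follow from antisymmetry alone (permutation
parity counted explicitly), and singlet configurations are the symmetric
spin combination of in-place single replacements.  Nothing here imports the
implementation it checks.

Spin orbitals are pairs ``(p, s)`` of a spatial index ``p`` and spin
``s in {0, 1}`` (alpha/beta).  A determinant is a tuple of spin orbitals in
the order the creation operators are applied; reordering flips the sign by
the permutation parity.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

Alpha, Beta = 0, 1


def ground_determinant(n_occ: int) -> tuple:
    """|0> = occupied spatial orbitals 0..n_occ-1, both spins, canonical order."""
    return tuple((p, s) for p in range(n_occ) for s in (Alpha, Beta))


def replace(det: tuple, old, new) -> tuple:
    """Single replacement *in place*: new spin orbital sits where old one was.

    Keeping the slot fixes the relative phase between determinants, which is
    what makes the singlet combination below a genuine spin eigenfunction.
    """
    if old not in det or new in det:
        raise ValueError("invalid replacement")
    return tuple(new if so == old else so for so in det)


def _parity_sort(det: tuple) -> tuple[tuple, int]:
    """Sort spin orbitals canonically; return (sorted_det, permutation sign)."""
    det = list(det)
    sign = 1
    # insertion sort, counting transpositions
    for i in range(1, len(det)):
        j = i
        while j > 0 and det[j - 1] > det[j]:
            det[j - 1], det[j] = det[j], det[j - 1]
            sign = -sign
            j -= 1
    return tuple(det), sign


def one_electron_element(bra: tuple, ket: tuple, O: np.ndarray) -> float:
    """<bra| sum_pq O_pq a+_p a_q |ket> for a spin-free one-electron operator.

    ``O`` is the operator matrix in the *spatial* orbital basis.
    """
    if len(bra) != len(ket):
        return 0.0
    b, sb = _parity_sort(bra)
    k, sk = _parity_sort(ket)
    pref = sb * sk
    bset, kset = set(b), set(k)
    only_b = sorted(bset - kset)
    only_k = sorted(kset - bset)
    if len(only_b) == 0:
        return pref * sum(O[p, p] for (p, s) in b)
    if len(only_b) == 1:
        (p, sp), (q, sq) = only_b[0], only_k[0]
        if sp != sq:
            return 0.0
        sign = (-1) ** (b.index(only_b[0]) + k.index(only_k[0]))
        return pref * sign * O[p, q]
    return 0.0


class SingletConfiguration:
    """Spin-adapted singlet single excitation i -> a of a closed-shell reference.

    |Phi_i^a> = (|i_alpha -> a_alpha> + |i_beta -> a_beta>) / sqrt(2),
    with each determinant an in-place replacement of the ground determinant.
    The ground state itself is SingletConfiguration(None, None, n_occ).
    """

    def __init__(self, i: int | None, a: int | None, n_occ: int):
        g = ground_determinant(n_occ)
        if i is None:
            self.dets = [(g, 1.0)]
        else:
            da = replace(g, (i, Alpha), (a, Alpha))
            db = replace(g, (i, Beta), (a, Beta))
            w = 1.0 / math.sqrt(2.0)
            self.dets = [(da, w), (db, w)]

    def matrix_element(self, other: "SingletConfiguration", O: np.ndarray) -> float:
        return sum(wb * wk * one_electron_element(db, dk, O)
                   for db, wb in self.dets for dk, wk in other.dets)


def config_dipole_oracle(i, a, j, b, mo_dipoles, n_occ):
    """<Phi_i^a| mu |Phi_j^b> per Cartesian component, by explicit expansion."""
    bra = SingletConfiguration(i, a, n_occ)
    ket = SingletConfiguration(j, b, n_occ)
    return np.array([bra.matrix_element(ket, mo_dipoles[g]) for g in range(3)])


def ground_excited_dipole_oracle(i, a, mo_dipoles, n_occ):
    """<0| mu |Phi_i^a> by explicit expansion."""
    bra = SingletConfiguration(None, None, n_occ)
    ket = SingletConfiguration(i, a, n_occ)
    return np.array([bra.matrix_element(ket, mo_dipoles[g]) for g in range(3)])


def number_operator_oracle(state_coeffs_bra, state_coeffs_ket, mo: int, n_occ: int,
                           n_vir: int) -> float:
    """<I| n_mo |J> for CIS states given by (n_occ, n_vir) coefficient arrays.

    ``n_mo`` counts both spins of spatial orbital ``mo`` (MO-level index:
    occupied MOs 0..n_occ-1, virtuals n_occ..n_occ+n_vir-1).
    """
    dim = n_occ + n_vir
    O = np.zeros((dim, dim))
    O[mo, mo] = 1.0
    confs = [(i, n_occ + a) for i in range(n_occ) for a in range(n_vir)]
    total = 0.0
    for (i, a), cb in zip(confs, np.asarray(state_coeffs_bra).ravel()):
        if cb == 0.0:
            continue
        bra = SingletConfiguration(i, a, n_occ)
        for (j, b), ck in zip(confs, np.asarray(state_coeffs_ket).ravel()):
            if ck == 0.0:
                continue
            ket = SingletConfiguration(j, b, n_occ)
            total += cb * ck * bra.matrix_element(ket, O)
    return total


def state_dipole_oracle(coeffs_bra, coeffs_ket, mo_dipoles, n_occ, n_vir,
                        include_ground_bra=False, include_ground_ket=False):
    """Dipole between CIS wavefunctions by full determinant expansion."""
    confs = [(i, n_occ + a) for i in range(n_occ) for a in range(n_vir)]

    def expand(coeffs, include_ground):
        if include_ground:
            return [(SingletConfiguration(None, None, n_occ), 1.0)]
        return [(SingletConfiguration(i, a, n_occ), c)
                for (i, a), c in zip(confs, np.asarray(coeffs).ravel()) if c != 0.0]

    bras = expand(coeffs_bra, include_ground_bra)
    kets = expand(coeffs_ket, include_ground_ket)
    out = np.zeros(3)
    for g in range(3):
        O = mo_dipoles[g]
        out[g] = sum(wb * wk * cb.matrix_element(ck, O)
                     for cb, wb in bras for ck, wk in kets)
    return out


def all_index_combinations(n_occ: int, n_vir: int):
    """Every (i, a, j, b) quadruple of a toy occupied x virtual space."""
    occ = range(n_occ)
    vir = range(n_occ, n_occ + n_vir)
    return list(itertools.product(occ, vir, occ, vir))
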