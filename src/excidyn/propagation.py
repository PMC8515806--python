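"""Wavepacket propagation in the eigenstate basis under Gaussian pulses.

The time-dependent Schrodinger equation i dC/dt = H(t) C is integrated on
the (ground + excited) eigenstate basis with

    H_LM(t) = E_M delta_LM - sum_gamma <L| mu_gamma |M> F_gamma(t)

and a Gaussian-envelope field

    F(t) = sum_pulses F_max exp(-(t - t0)^2 / (2 sigma^2)) cos(omega (t - t0) + phi).

Two integrators are provided: the production second-order Euler (leapfrog)
scheme, C(t+dt) = C(t-dt) - 2i dt H(t) C(t), bootstrapped by one exact
exponential of H(0); and a high-accuracy adaptive reference propagator used
as ground truth.  The leapfrog does *not* renormalize: norm drift is a
diagnostic of integrator error and aborts past a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from . import units
from .model_io import PulseConfig
from .excited_states import DipoleMatrix


@dataclass
class Pulse:
    """Gaussian-envelope pulse; all fields in atomic units."""

    f_max: np.ndarray        # (3,) field amplitude vector
    t0: float                # envelope center
    sigma: float             # envelope width
    omega: float             # carrier angular frequency
    phase: float = 0.0

    def __post_init__(self):
        self.f_max = np.asarray(self.f_max, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def from_config(cls, cfg: PulseConfig) -> "Pulse":
        return cls(f_max=cfg.amplitude * cfg.polarization, t0=cfg.t0,
                   sigma=cfg.sigma, omega=cfg.omega, phase=cfg.phase)

    @property
    def fwhm(self) -> float:
        return units.sigma_to_fwhm(self.sigma)

    def envelope(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-((t - self.t0) ** 2) / (2.0 * self.sigma ** 2))

    def __call__(self, t):
        """Field vector(s) at time(s) t; shape (..., 3)."""
        t = np.asarray(t, dtype=float)
        scal = self.envelope(t) * np.cos(self.omega * (t - self.t0) + self.phase)
        return np.multiply.outer(scal, self.f_max)


def field_at(pulses, t):
    """Superposed field of a pulse train at time(s) t, shape (..., 3)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape + (3,))
    for p in pulses:
        out += p(t)
    return out


def intensity_to_amplitude(intensity_wcm2: float) -> float:
    """Peak field amplitude |F_max| (a.u.) from intensity I = 1/2 |F_max|^2."""
    if intensity_wcm2 < 0:
        raise ValueError("intensity must be non-negative")
    return float(np.sqrt(2.0 * intensity_wcm2 / units.AU_INTENSITY_WCM2))


def amplitude_to_intensity(amplitude_au: float) -> float:
    return 0.5 * amplitude_au ** 2 * units.AU_INTENSITY_WCM2


def build_hamiltonian(energies: np.ndarray, dipoles: DipoleMatrix | np.ndarray,
                      field: np.ndarray) -> np.ndarray:
    """H(t) = diag(E) - sum_gamma mu_gamma F_gamma(t); Hermitian by construction."""
    mu = dipoles.values if isinstance(dipoles, DipoleMatrix) else np.asarray(dipoles)
    energies = np.asarray(energies, dtype=float)
    n = energies.shape[0]
    if mu.shape != (3, n, n):
        raise ValueError(f"dipole matrix shape {mu.shape} does not match {n} states")
    return np.diag(energies) - np.einsum("g,gij->ij", np.asarray(field, dtype=float), mu)


@dataclass
class Trajectory:
    """Stored propagation result on a (possibly decimated) time grid."""

    times: np.ndarray            # (n_t,) a.u.
    coeffs: np.ndarray           # (n_t, n_states) complex C_M(t)
    norm_series: np.ndarray      # (n_t,) sum_M |C_M|^2
    field_series: np.ndarray     # (n_t, 3)
    max_norm_drift: float = 0.0  # max |norm - 1| over *all* integration steps

    @property
    def n_states(self) -> int:
        return self.coeffs.shape[1]

    @property
    def times_fs(self) -> np.ndarray:
        return self.times * units.AU_TIME_FS

    def index_at(self, t_au: float) -> int:
        """Nearest stored grid point to a requested snapshot time."""
        return int(np.argmin(np.abs(self.times - t_au)))

    def populations(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2


def _prepare(energies, dipoles, c_init, n_states_used):
    energies = np.asarray(energies, dtype=float)
    mu = dipoles.values if isinstance(dipoles, DipoleMatrix) else np.asarray(dipoles)
    n = energies.shape[0]
    if n_states_used is not None:
        if n_states_used > n:
            raise ValueError("n_states_used exceeds available states")
        energies = energies[:n_states_used]
        mu = mu[:, :n_states_used, :n_states_used]
        n = n_states_used
    if c_init is None:
        c0 = np.zeros(n, dtype=complex)
        c0[0] = 1.0
    else:
        c0 = np.asarray(c_init, dtype=complex).copy()
        if c0.shape != (n,):
            raise ValueError("C_init has wrong length")
        if abs(np.vdot(c0, c0).real - 1.0) > 1e-8:
            raise ValueError("C_init must be normalized")
    return energies, mu, c0, n


def propagate_euler2(energies, dipoles, pulses, dt: float, t_end: float,
                     c_init=None, n_states_used: int | None = None,
                     store_every: int = 1,
                     drift_abort: float = 1e-3) -> Trajectory:
    """Leapfrog (second-order Euler) propagation of the TDSE.

    C(t + dt) = C(t - dt) - 2i dt H(t) C(t), with the first step taken as
    one exact exponential of H(0).  Deterministic; no renormalization.
    ``store_every`` decimates storage, the norm-drift maximum is tracked at
    every step regardless.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    energies, mu, c0, n = _prepare(energies, dipoles, c_init, n_states_used)
    n_steps = int(round(t_end / dt))
    times = dt * np.arange(n_steps + 1)
    fields = field_at(pulses, times)                        # (n_t, 3)

    # Precompute the Hamiltonian stack when it fits comfortably in memory.
    ediag = np.diag(energies)
    bulk = (n_steps + 1) * n * n
    h_stack = None
    if bulk <= 5e7:
        h_stack = ediag[None, :, :] - np.einsum("kg,gij->kij", fields, mu)

    def hmat(k):
        if h_stack is not None:
            return h_stack[k]
        return ediag - np.einsum("g,gij->ij", fields[k], mu)

    stored_idx = list(range(0, n_steps + 1, store_every))
    if stored_idx[-1] != n_steps:
        stored_idx.append(n_steps)
    store_pos = {k: p for p, k in enumerate(stored_idx)}
    coeffs = np.empty((len(stored_idx), n), dtype=complex)
    norms = np.empty(len(stored_idx))

    c_prev = c0
    max_drift = 0.0
    if 0 in store_pos:
        coeffs[0] = c0
        norms[0] = np.vdot(c0, c0).real
    if n_steps == 0:
        return Trajectory(times, coeffs, norms, fields, max_drift)

    c_cur = expm(-1j * dt * hmat(0)) @ c0
    nrm = np.vdot(c_cur, c_cur).real
    max_drift = max(max_drift, abs(nrm - 1.0))
    if 1 in store_pos:
        p = store_pos[1]
        coeffs[p] = c_cur
        norms[p] = nrm

    two_i_dt = 2j * dt
    for k in range(1, n_steps):
        c_next = c_prev - two_i_dt * (hmat(k) @ c_cur)
        nrm = np.vdot(c_next, c_next).real
        drift = abs(nrm - 1.0)
        if drift > max_drift:
            max_drift = drift
        if drift > drift_abort:
            raise RuntimeError(
                f"norm drift {drift:.3e} exceeded abort threshold {drift_abort:g} "
                f"at t = {times[k + 1] * units.AU_TIME_FS:.4f} fs "
                f"(step {k + 1}); reduce dt")
        c_prev, c_cur = c_cur, c_next
        if (k + 1) in store_pos:
            p = store_pos[k + 1]
            coeffs[p] = c_cur
            norms[p] = nrm

    return Trajectory(times=times[stored_idx], coeffs=coeffs, norm_series=norms,
                      field_series=fields[stored_idx], max_norm_drift=max_drift)


def propagate_reference(energies, dipoles, pulses, dt: float, t_end: float,
                        c_init=None, n_states_used: int | None = None,
                        store_every: int = 1, rtol: float = 1e-10,
                        atol: float = 1e-12) -> Trajectory:
    """High-accuracy adaptive propagator (DOP853), the verification oracle.

    Output is sampled on the same grid the leapfrog would use, so the two
    trajectories are directly comparable.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    energies, mu, c0, n = _prepare(energies, dipoles, c_init, n_states_used)
    n_steps = int(round(t_end / dt))
    times = dt * np.arange(n_steps + 1)
    stored_idx = list(range(0, n_steps + 1, store_every))
    if stored_idx[-1] != n_steps:
        stored_idx.append(n_steps)
    t_eval = times[stored_idx]
    ediag = np.diag(energies).astype(complex)

    def rhs(t, c):
        f = field_at(pulses, t)
        h = ediag - np.einsum("g,gij->ij", f, mu)
        return -1j * (h @ c)

    sol = solve_ivp(rhs, (0.0, times[-1]), c0, method="DOP853", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"reference propagator failed: {sol.message}")
    coeffs = sol.y.T
    norms = np.sum(np.abs(coeffs) ** 2, axis=1)
    return Trajectory(times=t_eval, coeffs=coeffs, norm_series=norms,
                      field_series=field_at(pulses, t_eval),
                      max_norm_drift=float(np.max(np.abs(norms - 1.0))))
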