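"""On-disk artifacts: interchange schema, Gaussian cube files, run
configuration and tabular outputs.

The interchange format is deliberately plain: one JSON document per object,
with mandatory ``format`` and ``version`` fields and numeric arrays stored
as (nested) lists.  Python's shortest-repr float serialization makes the
round trip bit-exact, and the files stay human-readable and diffable.
Orbital indices are 0-based in memory and in the JSON arrays; user-facing
text (CSV headers, CLI messages) is 1-based and says so.

Internal units are atomic units everywhere.  ``parse_config`` is the one
place where lab units (fs, eV, W/cm^2) enter and are converted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import units

SCHEMA_VERSION = 1

ORTHONORMALITY_TOL = 1e-6   # Ct S C deviation -> hard error
STATE_ORTHO_TOL = 1e-4      # excited-state vector overlap -> warning (error if strict)


class SchemaError(ValueError):
    """Raised when an on-disk artifact violates the documented schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ElectronicSystem:
    """One-electron structure of a closed-shell molecule.

    Attributes
    ----------
    mo_energies : (n_mo,) MO energies eps_i in hartree, ascending.
    mo_coeffs : (n_ao, n_mo) expansion coefficients d_beta^i of MOs in AOs.
    ao_overlap : (n_ao, n_ao) AO overlap matrix S, symmetric positive definite.
    occupations : (n_mo,) electrons per MO, 0 or 2 (closed shell).
    mo_dipoles : (3, n_mo, n_mo) dipole matrix elements mu_st in the MO
        basis, one symmetric matrix per Cartesian component, a.u.
    ao_to_atom : (n_ao,) atom index of each basis function.
    atom_coords : (n_atoms, 3) Cartesian positions in bohr.
    ground_dipole : optional (3,) permanent ground-state dipole, a.u.
    """

    mo_energies: np.ndarray
    mo_coeffs: np.ndarray
    ao_overlap: np.ndarray
    occupations: np.ndarray
    mo_dipoles: np.ndarray
    ao_to_atom: np.ndarray
    atom_coords: np.ndarray
    ground_dipole: np.ndarray | None = None

    @property
    def n_ao(self) -> int:
        return self.mo_coeffs.shape[0]

    @property
    def n_mo(self) -> int:
        return self.mo_coeffs.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.atom_coords.shape[0]

    @property
    def n_electrons(self) -> int:
        return int(round(float(np.sum(self.occupations))))

    @property
    def occupied(self) -> np.ndarray:
        """Indices of occupied MOs."""
        return np.flatnonzero(np.asarray(self.occupations) > 0)

    @property
    def virtual(self) -> np.ndarray:
        """Indices of virtual MOs."""
        return np.flatnonzero(np.asarray(self.occupations) == 0)

    def validate(self) -> None:
        S = np.asarray(self.ao_overlap, dtype=float)
        C = np.asarray(self.mo_coeffs, dtype=float)
        if S.shape != (self.n_ao, self.n_ao):
            raise SchemaError("ao_overlap shape does not match n_ao")
        if not np.allclose(S, S.T, atol=1e-12):
            raise SchemaError("ao_overlap is not symmetric")
        eigvals = np.linalg.eigvalsh(S)
        if eigvals.min() <= 0:
            raise SchemaError(
                f"ao_overlap is not positive definite (min eigenvalue {eigvals.min():.3e})"
            )
        gram = C.T @ S @ C
        dev = np.max(np.abs(gram - np.eye(self.n_mo)))
        if dev > ORTHONORMALITY_TOL:
            raise SchemaError(
                f"MOs are not S-orthonormal: max |CtSC - I| = {dev:.3e} "
                f"(tolerance {ORTHONORMALITY_TOL:g})"
            )
        occ = np.asarray(self.occupations)
        if not np.all(np.isin(occ, (0, 2))):
            raise SchemaError("occupations must be 0 or 2 (closed shell)")
        if self.n_electrons % 2 != 0:
            raise SchemaError("odd electron count in a closed-shell system")
        mu = np.asarray(self.mo_dipoles, dtype=float)
        if mu.shape != (3, self.n_mo, self.n_mo):
            raise SchemaError("mo_dipoles must have shape (3, n_mo, n_mo)")
        if not np.allclose(mu, np.swapaxes(mu, 1, 2), atol=1e-10):
            raise SchemaError("mo_dipoles components must be symmetric")
        if len(self.ao_to_atom) != self.n_ao:
            raise SchemaError("ao_to_atom length must equal n_ao")
        if np.max(self.ao_to_atom) >= self.n_atoms:
            raise SchemaError("ao_to_atom references an unknown atom")


@dataclass
class FragmentScheme:
    """Disjoint atom groups covering the whole molecule."""

    fragments: list[list[int]]
    labels: list[str]

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def validate(self, n_atoms: int | None = None) -> None:
        if len(self.labels) != len(self.fragments):
            raise SchemaError("one label per fragment required")
        seen: set[int] = set()
        for frag in self.fragments:
            fs = set(int(a) for a in frag)
            if fs & seen:
                raise SchemaError("fragments must be disjoint")
            seen |= fs
        if n_atoms is not None:
            if seen != set(range(n_atoms)):
                raise SchemaError("fragments must cover every atom exactly once")


@dataclass
class ExcitedStateSet:
    """Excitation energies and CIS-like coefficient tensors d_{i,M}^a.

    ``coeffs`` has shape (n_states, n_occ, n_vir); occupied index i counts
    occupied MOs from the bottom, virtual index a counts virtuals from the
    LUMO.  Each state's coefficient matrix has unit Frobenius norm.
    """

    energies: np.ndarray           # (n_states,) hartree, ground state at 0
    coeffs: np.ndarray             # (n_states, n_occ, n_vir)
    tda_flag: bool = True

    @property
    def n_states(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_occ(self) -> int:
        return self.coeffs.shape[1]

    @property
    def n_vir(self) -> int:
        return self.coeffs.shape[2]

    def flat(self) -> np.ndarray:
        """States as row vectors in the singles space, (n_states, n_occ*n_vir)."""
        return self.coeffs.reshape(self.n_states, -1)

    def validate(self, strict: bool = False) -> None:
        E = np.asarray(self.energies, dtype=float)
        if E.shape != (self.n_states,):
            raise SchemaError("energies length must equal number of states")
        if np.any(E <= 0):
            raise SchemaError("excitation energies must be positive")
        if np.any(np.diff(E) < 0):
            raise SchemaError("excitation energies must be ascending")
        flat = self.flat()
        norms = np.linalg.norm(flat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise SchemaError(
                f"state coefficient matrices must have unit norm (max dev "
                f"{np.max(np.abs(norms - 1.0)):.3e})"
            )
        if self.n_states > 1:
            overlap = flat @ flat.T
            off = np.max(np.abs(overlap - np.diag(np.diag(overlap))))
            if off > STATE_ORTHO_TOL:
                msg = (f"excited-state coefficient vectors are not mutually "
                       f"orthogonal (max overlap {off:.3e})")
                if strict:
                    raise SchemaError(msg)
                warnings.warn(msg, stacklevel=2)

    def renormalized(self) -> "ExcitedStateSet":
        """Return a copy with each state scaled to exact unit norm.

        Scaling is only allowed within 1e-6 of unity (the loader contract);
        a larger deviation is a schema violation, not noise.
        """
        flat = self.flat()
        norms = np.linalg.norm(flat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise SchemaError("state norms deviate from 1 beyond 1e-6; refusing to rescale")
        coeffs = self.coeffs / norms[:, None, None]
        return ExcitedStateSet(np.array(self.energies, dtype=float), coeffs, self.tda_flag)


@dataclass
class VolumetricField:
    """Scalar field on a regular (possibly non-orthogonal) voxel grid."""

    origin: np.ndarray             # (3,) bohr
    axes: np.ndarray               # (3, 3) step vectors, bohr
    values: np.ndarray             # (nx, ny, nz)
    atom_numbers: np.ndarray | None = None    # (n_atoms,) nuclear charges
    atom_coords: np.ndarray | None = None     # (n_atoms, 3) bohr

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise SchemaError("values must be a 3-d array")
        if abs(np.linalg.det(self.axes)) < 1e-14:
            raise SchemaError("grid axes are linearly dependent")

    def integral(self) -> float:
        """Riemann-sum integral of the field over the grid."""
        return float(np.sum(self.values) * self.voxel_volume)

    def congruent(self, other: "VolumetricField", tol: float = 1e-10) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.axes, other.axes, atol=tol))


@dataclass
class PulseConfig:
    """One Gaussian-envelope pulse, all quantities in atomic units."""

    amplitude: float               # |F_max| a.u.
    sigma: float                   # envelope width, a.u. time
    t0: float                      # envelope center, a.u. time
    omega: float                   # carrier angular frequency, hartree
    polarization: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    phase: float = 0.0


@dataclass
class RunConfig:
    """Propagation + descriptor settings, converted to atomic units."""

    pulses: list[PulseConfig]
    dt: float                      # a.u. time
    t_end: float                   # a.u. time
    n_states_used: int | None = None
    output_every: int = 1
    linear_regime: bool = True
    eta_ev: float = 0.027          # Lorentzian HWHM for PDOS, eV
    sigma_occ_ev: float = 0.027    # TCM Gaussian widths, eV
    sigma_vir_ev: float = 0.027
    snapshot_times_fs: list[float] = field(default_factory=list)
    fragment_file: str | None = None
    grid_points: int = 400

    def validate(self) -> None:
        if self.dt <= 0:
            raise SchemaError("dt must be positive")
        if self.t_end <= 0:
            raise SchemaError("t_end must be positive")
        for p in self.pulses:
            if p.sigma <= 0:
                raise SchemaError("pulse FWHM/sigma must be positive")
            if p.amplitude < 0:
                raise SchemaError("pulse amplitude must be non-negative")


# ---------------------------------------------------------------------------
# Interchange JSON readers/writers
# ---------------------------------------------------------------------------

def _check_header(doc: dict, expected: str) -> None:
    if not isinstance(doc, dict) or "format" not in doc or "version" not in doc:
        raise SchemaError("missing format/version header")
    if doc["format"] != expected:
        raise SchemaError(f"expected format {expected!r}, found {doc['format']!r}")
    if doc["version"] != SCHEMA_VERSION:
        raise SchemaError(f"unrecognized schema version {doc['version']!r}")


def _require(doc: dict, *keys: str) -> None:
    for k in keys:
        if k not in doc:
            raise SchemaError(f"missing required field {k!r}")


def save_system(system: ElectronicSystem, path: str | Path) -> None:
    doc = {
        "format": "excidyn-system",
        "version": SCHEMA_VERSION,
        "indexing": "orbital and atom indices in this file are 0-based",
        "units": "hartree / bohr / a.u. dipole",
        "mo_energies": system.mo_energies.tolist(),
        "mo_coeffs": system.mo_coeffs.tolist(),
        "ao_overlap": system.ao_overlap.tolist(),
        "occupations": np.asarray(system.occupations).tolist(),
        "mo_dipoles": system.mo_dipoles.tolist(),
        "ao_to_atom": np.asarray(system.ao_to_atom).tolist(),
        "atom_coords": system.atom_coords.tolist(),
    }
    if system.ground_dipole is not None:
        doc["ground_dipole"] = np.asarray(system.ground_dipole).tolist()
    Path(path).write_text(json.dumps(doc))


def load_system(path: str | Path) -> ElectronicSystem:
    doc = json.loads(Path(path).read_text())
    _check_header(doc, "excidyn-system")
    _require(doc, "mo_energies", "mo_coeffs", "ao_overlap", "occupations",
             "mo_dipoles", "ao_to_atom", "atom_coords")
    system = ElectronicSystem(
        mo_energies=np.array(doc["mo_energies"], dtype=float),
        mo_coeffs=np.array(doc["mo_coeffs"], dtype=float),
        ao_overlap=np.array(doc["ao_overlap"], dtype=float),
        occupations=np.array(doc["occupations"], dtype=int),
        mo_dipoles=np.array(doc["mo_dipoles"], dtype=float),
        ao_to_atom=np.array(doc["ao_to_atom"], dtype=int),
        atom_coords=np.array(doc["atom_coords"], dtype=float),
        ground_dipole=(np.array(doc["ground_dipole"], dtype=float)
                       if "ground_dipole" in doc else None),
    )
    system.validate()
    return system


def save_excited_states(states: ExcitedStateSet, path: str | Path) -> None:
    doc = {
        "format": "excidyn-states",
        "version": SCHEMA_VERSION,
        "indexing": "occupied index counts occupied MOs from the bottom (0-based); "
                    "virtual index counts from the LUMO (0-based)",
        "units": "hartree",
        "energies": np.asarray(states.energies).tolist(),
        "coeffs": np.asarray(states.coeffs).tolist(),
        "tda": bool(states.tda_flag),
    }
    Path(path).write_text(json.dumps(doc))


def load_excited_states(path: str | Path, strict: bool = False,
                        system: ElectronicSystem | None = None) -> ExcitedStateSet:
    doc = json.loads(Path(path).read_text())
    _check_header(doc, "excidyn-states")
    _require(doc, "energies", "coeffs")
    coeffs = np.array(doc["coeffs"], dtype=float)
    if coeffs.ndim != 3:
        raise SchemaError("coeffs must be (n_states, n_occ, n_vir)")
    states = ExcitedStateSet(
        energies=np.array(doc["energies"], dtype=float),
        coeffs=coeffs,
        tda_flag=bool(doc.get("tda", True)),
    )
    if system is not None:
        if states.n_occ != len(system.occupied) or states.n_vir != len(system.virtual):
            raise SchemaError("excited-state dimensions inconsistent with system")
    states.validate(strict=strict)
    return states.renormalized()


def save_fragments(scheme: FragmentScheme, path: str | Path) -> None:
    doc = {
        "format": "excidyn-fragments",
        "version": SCHEMA_VERSION,
        "indexing": "atom indices are 0-based",
        "fragments": [[int(a) for a in frag] for frag in scheme.fragments],
        "labels": list(scheme.labels),
    }
    Path(path).write_text(json.dumps(doc))


def load_fragments(path: str | Path, n_atoms: int | None = None) -> FragmentScheme:
    doc = json.loads(Path(path).read_text())
    _check_header(doc, "excidyn-fragments")
    _require(doc, "fragments", "labels")
    scheme = FragmentScheme(fragments=[list(map(int, f)) for f in doc["fragments"]],
                            labels=[str(x) for x in doc["labels"]])
    scheme.validate(n_atoms=n_atoms)
    return scheme


# ---------------------------------------------------------------------------
# Gaussian cube files
# ---------------------------------------------------------------------------

def write_cube(fld: VolumetricField, path: str | Path,
               comment: str = "excidyn volumetric field") -> None:
    """Write the standard cube dialect (positive atom count, bohr)."""
    fld.validate()
    nx, ny, nz = fld.shape
    if fld.atom_coords is not None:
        numbers = (fld.atom_numbers if fld.atom_numbers is not None
                   else np.ones(len(fld.atom_coords), dtype=int))
        atoms = list(zip(numbers, fld.atom_coords))
    else:
        atoms = []
    lines = [comment, "scalar field, z-fastest value order"]
    ox, oy, oz = fld.origin
    lines.append(f"{max(len(atoms), 1):5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}")
    for n, ax in zip((nx, ny, nz), fld.axes):
        lines.append(f"{n:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}")
    if atoms:
        for z, xyz in atoms:
            lines.append(f"{int(z):5d} {float(z):12.6f} "
                         f"{xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}")
    else:
        # cube demands at least one atom record; a ghost at the origin
        lines.append(f"{0:5d} {0.0:12.6f} {ox:12.6f} {oy:12.6f} {oz:12.6f}")
    vals = fld.values.reshape(nx * ny, nz)
    for row in vals:
        for k in range(0, nz, 6):
            lines.append(" ".join(f"{v: .5E}" for v in row[k:k + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> VolumetricField:
    """Read a Gaussian cube file.

    Handles the MO-cube dialect (negative atom count followed by an extra
    integer record) read-only, for a single data set.
    """
    tokens_lines = Path(path).read_text().splitlines()
    if len(tokens_lines) < 6:
        raise SchemaError("cube file too short")
    body = tokens_lines[2:]
    hdr = body[0].split()
    natoms_signed = int(hdr[0])
    natoms = abs(natoms_signed)
    origin = np.array([float(x) for x in hdr[1:4]])
    shape = []
    axes = []
    for line in body[1:4]:
        parts = line.split()
        shape.append(int(parts[0]))
        axes.append([float(x) for x in parts[1:4]])
    nx, ny, nz = shape
    atom_lines = body[4:4 + natoms]
    numbers = []
    coords = []
    for line in atom_lines:
        parts = line.split()
        numbers.append(int(parts[0]))
        coords.append([float(x) for x in parts[2:5]])
    rest = body[4 + natoms:]
    if natoms_signed < 0:
        # MO dialect: one record "m id1 id2 ..." precedes the values
        mo_record = rest[0].split()
        n_sets = int(mo_record[0])
        if n_sets != 1:
            raise SchemaError("multi-MO cube files are not supported")
        rest = rest[1:]
    values = np.array(" ".join(rest).split(), dtype=float)
    expected = nx * ny * nz
    if values.size != expected:
        raise SchemaError(
            f"cube value block has {values.size} entries, expected {expected}")
    fld = VolumetricField(
        origin=origin,
        axes=np.array(axes),
        values=values.reshape(nx, ny, nz),   # z-fastest on disk
        atom_numbers=np.array(numbers, dtype=int) if numbers else None,
        atom_coords=np.array(coords) if coords else None,
    )
    fld.validate()
    return fld


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def _pulse_from_block(block: dict, prev_t0: float | None) -> PulseConfig:
    if "fwhm_fs" in block:
        sigma = units.fs_to_au(units.fwhm_to_sigma(float(block["fwhm_fs"])))
    elif "sigma_fs" in block:
        sigma = units.fs_to_au(float(block["sigma_fs"]))
    elif "sigma_au" in block:
        sigma = float(block["sigma_au"])
    else:
        raise SchemaError("pulse block needs fwhm_fs, sigma_fs or sigma_au")
    if sigma <= 0:
        raise SchemaError("pulse width must be positive")

    if "amplitude_au" in block:
        amp = float(block["amplitude_au"])
        if amp < 0:
            raise SchemaError("amplitude must be non-negative")
    elif "intensity_wcm2" in block:
        intensity = float(block["intensity_wcm2"])
        if intensity < 0:
            raise SchemaError("intensity must be non-negative")
        # I = 1/2 |F_max|^2 in atomic units
        amp = float(np.sqrt(2.0 * intensity / units.AU_INTENSITY_WCM2))
    else:
        raise SchemaError("pulse block needs amplitude_au or intensity_wcm2")

    if "omega_ev" in block:
        omega = units.ev_to_hartree(float(block["omega_ev"]))
    elif "omega_au" in block:
        omega = float(block["omega_au"])
    else:
        raise SchemaError("pulse block needs omega_ev or omega_au")

    if "t0_fs" in block:
        t0 = units.fs_to_au(float(block["t0_fs"]))
    elif "delay_fs" in block:
        if prev_t0 is None:
            raise SchemaError("delay_fs requires a preceding pulse")
        t0 = prev_t0 + units.fs_to_au(float(block["delay_fs"]))
    else:
        raise SchemaError("pulse block needs t0_fs or delay_fs")

    pol = np.array(block.get("polarization", [0.0, 0.0, 1.0]), dtype=float)
    nrm = np.linalg.norm(pol)
    if nrm == 0:
        raise SchemaError("polarization vector must be non-zero")
    return PulseConfig(amplitude=amp, sigma=sigma, t0=t0, omega=omega,
                       polarization=pol / nrm,
                       phase=float(block.get("phase", 0.0)))


def parse_config(path: str | Path) -> RunConfig:
    """Parse a YAML/JSON run configuration into atomic units.

    Pulse blocks accept ``fwhm_fs`` (converted as sigma = FWHM / (2 sqrt(2 ln 2))),
    ``intensity_wcm2`` or ``amplitude_au``, ``omega_ev``/``omega_au`` and
    ``t0_fs`` or ``delay_fs`` relative to the previous pulse's center.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError("configuration root must be a mapping")
    _require(raw, "pulses", "dt_fs" if "dt_fs" in raw else "dt_au", "t_end_fs"
             if "t_end_fs" in raw else "t_end_au")
    dt = (units.fs_to_au(float(raw["dt_fs"])) if "dt_fs" in raw
          else float(raw["dt_au"]))
    t_end = (units.fs_to_au(float(raw["t_end_fs"])) if "t_end_fs" in raw
             else float(raw["t_end_au"]))
    if dt <= 0:
        raise SchemaError("dt must be positive")
    pulses: list[PulseConfig] = []
    prev_t0: float | None = None
    for block in raw["pulses"]:
        p = _pulse_from_block(block, prev_t0)
        pulses.append(p)
        prev_t0 = p.t0
    cfg = RunConfig(
        pulses=pulses,
        dt=dt,
        t_end=t_end,
        n_states_used=(int(raw["n_states_used"]) if "n_states_used" in raw else None),
        output_every=int(raw.get("output_every", 1)),
        linear_regime=bool(raw.get("linear_regime", True)),
        eta_ev=float(raw.get("eta_ev", 0.027)),
        sigma_occ_ev=float(raw.get("sigma_occ_ev", 0.027)),
        sigma_vir_ev=float(raw.get("sigma_vir_ev", 0.027)),
        snapshot_times_fs=[float(t) for t in raw.get("snapshot_times_fs", [])],
        fragment_file=raw.get("fragment_file"),
        grid_points=int(raw.get("grid_points", 400)),
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

def write_timeseries(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with full float precision (lossless re-read at 1e-12)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_map(eps_occ: np.ndarray, eps_vir: np.ndarray, values: np.ndarray,
              path: str | Path, value_name: str = "tcm") -> None:
    """Long-format CSV of a 2-d map over (eps_occ, eps_vir) axes."""
    eo, ev = np.meshgrid(eps_occ, eps_vir, indexing="ij")
    df = pd.DataFrame({
        "eps_occ_ev": eo.ravel(),
        "eps_vir_ev": ev.ravel(),
        value_name: np.asarray(values).ravel(),
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Trajectory container (runtime artifact, numpy archive)
# ---------------------------------------------------------------------------

def save_trajectory(traj, path: str | Path) -> None:
    np.savez(path,
             times=traj.times,
             coeffs=traj.coeffs,
             norm_series=traj.norm_series,
             field_series=traj.field_series,
             max_norm_drift=np.array([traj.max_norm_drift]))


def load_trajectory(path: str | Path):
    from .propagation import Trajectory
    with np.load(path) as data:
        return Trajectory(
            times=data["times"],
            coeffs=data["coeffs"],
            norm_series=data["norm_series"],
            field_series=data["field_series"],
            max_norm_drift=float(data["max_norm_drift"][0]),
        )
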