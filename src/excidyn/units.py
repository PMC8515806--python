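"""Unit conversions between atomic units and laboratory units.

Everything inside the package is in Hartree atomic units (hbar = m_e = e =
a0 = 1).  User-facing boundaries (configuration files, CSV output, CLI
options) speak eV, fs, Debye and W/cm^2; the constants below are the single
source of truth for those conversions.
"""

import math

# 1 atomic unit of time in femtoseconds
AU_TIME_FS = 2.4188843265857e-2
# 1 hartree in electronvolts
HARTREE_EV = 27.211386245988
# 1 atomic unit of field intensity in W/cm^2
AU_INTENSITY_WCM2 = 3.50944758e16
# 1 atomic unit of electric dipole in Debye
AU_DIPOLE_DEBYE = 2.541746473

# FWHM of a Gaussian envelope exp(-t^2/(2 sigma^2)) divided by sigma
FWHM_OVER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fs_to_au(t_fs: float) -> float:
    return t_fs / AU_TIME_FS


def au_to_fs(t_au: float) -> float:
    return t_au * AU_TIME_FS


def ev_to_hartree(e_ev: float) -> float:
    return e_ev / HARTREE_EV


def hartree_to_ev(e_au: float) -> float:
    return e_au * HARTREE_EV


def debye_to_au(mu_d: float) -> float:
    return mu_d / AU_DIPOLE_DEBYE


def au_to_debye(mu_au: float) -> float:
    return mu_au * AU_DIPOLE_DEBYE


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian envelope width sigma from its full width at half maximum."""
    return fwhm / FWHM_OVER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return sigma * FWHM_OVER_SIGMA
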