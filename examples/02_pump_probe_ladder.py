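"""Pump-probe population transfer on a three-level ladder.

The pump is resonant with the ground -> |1> transition (3.679 eV) and the
probe with |1> -> |2> (1.112 eV); both have 15 fs FWHM and an intensity of
5e8 W/cm^2 -- a weak-field, linear-response setting.  The probe alone can
barely reach |2>; after the pump has populated |1>, it can.
"""

import numpy as np

import excidyn as xd
from excidyn import units

system, states = xd.make_ladder([3.679, 4.791], [2.0, 1.5])
dipoles = xd.state_dipole_matrix(states, system)
energies = np.concatenate([[0.0], states.energies])

f = xd.intensity_to_amplitude(5e8)
sigma = units.fs_to_au(units.fwhm_to_sigma(15.0))
t01 = units.fs_to_au(40.0)
t02 = t01 + units.fs_to_au(70.0)                 # 70 fs center-to-center delay
pump = xd.Pulse(f_max=[0, 0, f], t0=t01, sigma=sigma, omega=states.energies[0])
probe = xd.Pulse(f_max=[0, 0, f], t0=t02, sigma=sigma,
                 omega=states.energies[1] - states.energies[0])
t_end = t02 + units.fs_to_au(50.0)

both = xd.propagate_euler2(energies, dipoles, [pump, probe], dt=0.25,
                           t_end=t_end, store_every=400)
alone = xd.propagate_euler2(energies, dipoles, [probe], dt=0.25,
                            t_end=t_end, store_every=400)

p = both.populations()
print(f"final populations (pump + probe): P1 = {p[-1, 1]:.4e}, "
      f"P2 = {p[-1, 2]:.4e}")
print(f"final P2 with probe alone       : {alone.populations()[-1, 2]:.4e}")
print(f"enhancement P2(both)/P2(alone)  : "
      f"{p[-1, 2] / max(alone.populations()[-1, 2], 1e-300):.2e}")
print("The probe only drives the excited-excited transition when the pump")
print("has first populated |1>: sequential two-pulse excitation climbs the")
print("ladder, the hallmark of a pump-probe experiment.")
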