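# excidyn

Excited-state electron wavepacket dynamics under shaped laser pulses, with
time-resolved orbital descriptors.

## What it does, and for whom

`excidyn` is aimed at theoretical/computational chemists who have
excited-state data from a linear-response calculation (TDDFT or GW/BSE
excitation energies `E_M` and CIS-like eigenvectors `d_{i,M}^a`) and want to
simulate and dissect the real-time electron dynamics that an ultrafast pulse
sequence drives through those states. The package covers the whole chain:

1. **State algebra.** Excited states are taken in the
   configuration-interaction-singles ansatz
   `|M> = sum_{i,a} d_{i,M}^a |Phi_i^a>` over spin-adapted singlet single
   excitations. Slater–Condon rules give every one-electron matrix element;
   in particular the full (ground + excited) state–state dipole matrix

       <Phi_i^a| mu |Phi_j^b> = delta_ij mu_ab - delta_ab mu_ji
                                + delta_ij delta_ab <0|mu|0>,
       <0| mu |Phi_i^a> = sqrt(2) mu_ia,

   which is what makes excited–excited (pump–probe) transitions available.
2. **Propagation.** The time-dependent Schrödinger equation
   `i dC/dt = H(t) C` on the eigenstate basis, with
   `H_LM(t) = E_M delta_LM - sum_gamma <L|mu_gamma|M> F_gamma(t)` and a
   Gaussian-envelope field
   `F(t) = F_max exp(-(t-t0)^2 / 2 sigma^2) cos(omega (t-t0) + phi)`
   (intensity `I = |F_max|^2 / 2`). The production integrator is the
   explicit second-order (leapfrog) scheme
   `C(t+dt) = C(t-dt) - 2i dt H(t) C(t)`; a high-order adaptive reference
   propagator serves as ground truth.
3. **Descriptors.** State populations `|C_M(t)|^2`; the wavepacket-induced
   density `Gamma_1(r,t) = sum_M 2 Re[C_M(t)] Gamma_M(r)` (with the
   second-order term `Gamma_2` available to quantify its neglect); the
   fragment-projected change of the density of states
   `dPDOS_K(t,eps) = sum_i w_i^K L_eta(eps - eps_i) d<n_i>(t)` built from
   Mulliken weights `w_i^K` and number-operator matrix elements between
   excited states; its analytic energy integral (net fragment charges);
   and time-resolved transition contribution maps
   `TCM(eps_occ, eps_vir, t)`, optionally projected on a fragment pair to
   resolve the direction of charge flow.

Everything runs on synthetic model systems built by the package itself
(two-level, ladder, donor–acceptor, random, and analytic-Gaussian volumetric
fixtures), so the full pipeline works and is tested without any
electronic-structure code; real data enters through a documented JSON
interchange format.

## Worked example

Rabi inversion by a resonant pi pulse (`examples/01_two_level_rabi.py`):

```text
pulse peak field      : 7.5791e-03 a.u. (1.008e+12 W/cm^2)
final P1 (reference)  : 0.999883
final P1 (leapfrog)   : 0.999883
leapfrog norm drift   : 2.70e-07
```

A Gaussian pulse whose envelope area `mu |F_max| sigma sqrt(2 pi)` equals pi
moves the full population to the excited state; the 1.2e-4 deficit is the
counter-rotating correction, and the leapfrog at a 0.121-as step reproduces
the adaptive reference to 2e-7 while conserving the norm to 3e-7.

Charge transfer through the fragment dPDOS
(`examples/03_charge_transfer_pdos.py`):

```text
net charge change     : dQ_A = -0.00692 e, dQ_B = +0.00692 e
zero-sum residual     : 1.0e-17
```

The donor fragment loses exactly the electrons the acceptor gains, step by
step — Mulliken completeness plus particle-number conservation make the sum
exactly zero. The other examples cover pump–probe ladder climbing, plain and
fragment-projected TCM maps, and cube-file output of the induced density.

## Command line

A thin CLI wraps the same calls:

```bash
excidyn synth --preset donor-acceptor --out fixture --cubes
excidyn propagate --config run.yaml --system fixture/system.json \
    --states fixture/states.json --out-dir out
excidyn pdos --trajectory out/trajectory.npz --system fixture/system.json \
    --states fixture/states.json --fragments fixture/fragments.json \
    --out-dir pdos --minmax-trace
excidyn tcm  ... --pair A B
excidyn density ... --cubes fixture/gamma_state1.cube,fixture/gamma_state2.cube
```

Configuration is YAML with explicit unit tags (`fwhm_fs`, `omega_ev`,
`intensity_wcm2`, `t0_fs`/`delay_fs`); internally everything is atomic
units.

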