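"""Calibrate the default vibronic parameter set.

Fixed by physics:
  * mode quantum  hbar*omega = 177 cm^-1 (the Cu–Met stretch)
  * reduced mass  m = Cu–S reduced mass = 21.21 amu
  * S = 1/2, g = 2 (Cu(II) d9), B_ext = 0.35 T, I1/I0 = 1

Calibrated here:
  * a       from hbar*omega, D and m
  * D       chosen (500 meV) so that B_vib(290)/B_vib(50) >= 100
  * kappa   so that P(290 K) = 20.0% exactly

Run from the repository root:  python scripts/calibrate_vibronic.py
Paste the printed numbers into spinpath.vibronic.VibronicParams defaults.
"""

import math

import numpy as np

from spinpath.constants import CM1_TO_MEV, HBAR2_OVER_2M, K_B, MU_B
from spinpath.vibronic import VibronicParams, b_vib, thermal_displacement

HW_TARGET = 177.0 * CM1_TO_MEV          # meV
M_CU = 62.9296                          # 63Cu
M_S = 31.9721                           # 32S
M_RED = M_CU * M_S / (M_CU + M_S)
D = 500.0                               # meV
P_TARGET = 20.0                         # percent at 290 K
T_ROOM, T_COLD = 290.0, 50.0
B_EXT = 0.35


def main() -> None:
    a = HW_TARGET / (2.0 * math.sqrt(D * HBAR2_OVER_2M / M_RED))
    print(f"hbar*omega target = {HW_TARGET:.4f} meV")
    print(f"reduced mass      = {M_RED:.4f} amu")
    print(f"a                 = {a:.6f} 1/Angstrom")

    p = VibronicParams(D=D, a=a, m=M_RED, kappa=1.0, B_ext=B_EXT)
    print(f"hbar*omega check  = {p.hbar_omega:.4f} meV, bound states {p.n_bound}")

    dx_room = thermal_displacement(p, T_ROOM)
    dx_cold = thermal_displacement(p, T_COLD)
    print(f"dx(290 K) = {dx_room:.6e} A,  dx(50 K) = {dx_cold:.6e} A")
    print(f"fold growth 50->290 K = {dx_room / dx_cold:.2f}  (contract: >= 100)")

    # P = 100 |S * B_S(x)| with I1/I0 = 1; for S=1/2, B_S = tanh
    sz_target = P_TARGET / 100.0          # = |<S_z>| * I1/I0
    x = math.atanh(sz_target / 0.5)
    b_total = x * K_B * T_ROOM / (2.0 * MU_B * 0.5)
    kappa = (b_total - B_EXT) / dx_room
    print(f"B_total(290 K)    = {b_total:.4f} T  -> kappa = {kappa:.6g} T/A")

    p2 = VibronicParams(D=D, a=a, m=M_RED, kappa=kappa, B_ext=B_EXT)
    bv = b_vib(p2, T_ROOM)
    sz = 0.5 * math.tanh(2 * MU_B * 0.5 * (bv + B_EXT) / (K_B * T_ROOM))
    print(f"check: B_vib(290) = {bv:.3f} T, P(290) = {100 * abs(sz):.4f} %")
    print(f"check: B_vib(290)/B_vib(50) = {b_vib(p2, T_ROOM) / b_vib(p2, T_COLD):.2f}")


if __name__ == "__main__":
    main()
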