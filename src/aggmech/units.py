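"""Unit conventions and conversions used throughout the package.

Working units (chosen to match how aggregate-mechanics quantities are
reported in practice):

========================  =========  ===========
quantity                  unit       SI factor
========================  =========  ===========
length                    µm         1e-6 m
time (force traces)       s          1 s
time (fusion)             min        60 s
force                     µN         1e-6 N
surface/cortical tension  mN/m       1e-3 N/m
viscosity                 Pa·s       1 Pa·s
visco-capillary velocity  µm/min     1e-6/60 m/s
fluidity                  (Pa·s)⁻¹   1 (Pa·s)⁻¹
========================  =========  ===========

All conversions live here so that no other module hard-codes a factor.
"""

from __future__ import annotations

UM = 1e-6          # µm -> m
UN = 1e-6          # µN -> N
MN_PER_M = 1e-3    # mN/m -> N/m
MIN = 60.0         # min -> s

UM_PER_MIN = UM / MIN  # µm/min -> m/s


def tension_si(sigma_mN_per_m: float) -> float:
    """mN/m -> N/m."""
    return sigma_mN_per_m * MN_PER_M


def velocity_si(v_um_per_min: float) -> float:
    """µm/min -> m/s."""
    return v_um_per_min * UM_PER_MIN


def velocity_um_per_min(v_m_per_s: float) -> float:
    """m/s -> µm/min."""
    return v_m_per_s / UM_PER_MIN


def visco_capillary_velocity(sigma_mN_per_m: float, eta_Pa_s: float) -> float:
    """v = sigma/eta, returned in µm/min."""
    return velocity_um_per_min(tension_si(sigma_mN_per_m) / eta_Pa_s)


def viscosity_Pa_s(sigma_mN_per_m: float, v_um_per_min: float) -> float:
    """eta = sigma/v, returned in Pa·s."""
    return tension_si(sigma_mN_per_m) / velocity_si(v_um_per_min)


def laplace_force_uN(sigma_mN_per_m: float, r2_um: float, r3_um: float) -> float:
    """Plate force F = sigma * pi * R3^2 * (1/R2 + 1/R3), in µN.

    Tension in mN/m and radii in µm: the SI factors collapse to 1e-3.
    """
    import math

    f_si = (
        tension_si(sigma_mN_per_m)
        * math.pi
        * (r3_um * UM) ** 2
        * (1.0 / (r2_um * UM) + 1.0 / (r3_um * UM))
    )
    return f_si / UN


def sigma_from_laplace_uN(force_uN: float, r2_um: float, r3_um: float) -> float:
    """Invert :func:`laplace_force_uN` for the tension in mN/m."""
    import math

    denom = math.pi * (r3_um * UM) ** 2 * (1.0 / (r2_um * UM) + 1.0 / (r3_um * UM))
    return (force_uN * UN / denom) / MN_PER_M
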