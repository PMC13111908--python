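"""Unit conventions and conversion constants.

The toolkit works in a fixed unit system: millimetres for geometry, L/min for
cardiac output, Pa for pressures and stresses, SI (m, m/s, Pa·s) inside the
flow solver. mmHg appears only in right-heart-catheterization records.
Resistances are reported in dyn·s·cm⁻⁵, the clinical convention
(1 Wood unit = 1 mmHg·min/L = 80 dyn·s·cm⁻⁵).
"""

MM_PER_M = 1000.0
M_PER_MM = 1.0e-3

PA_PER_MMHG = 133.322387415

#: 1 Wood unit (mmHg·min/L) in dyn·s·cm⁻⁵
DYN_S_CM5_PER_WOOD = 80.0

#: 1 Pa·s/m³ in dyn·s·cm⁻⁵  (1 Pa = 10 dyn/cm², 1 m³ = 10⁶ cm³)
DYN_S_CM5_PER_PA_S_M3 = 1.0e-5

SECONDS_PER_MINUTE = 60.0
M3_PER_LITRE = 1.0e-3


def lpm_to_m3s(q_lpm: float) -> float:
    """Convert a flow rate from L/min to m³/s."""
    return q_lpm * M3_PER_LITRE / SECONDS_PER_MINUTE


def m3s_to_lpm(q_m3s: float) -> float:
    """Convert a flow rate from m³/s to L/min."""
    return q_m3s * SECONDS_PER_MINUTE / M3_PER_LITRE


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / PA_PER_MMHG
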