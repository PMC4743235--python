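"""Unit conversion helpers.

All internal computation is in SI (m, Pa, Pa·s, m³/s).  Millimetres,
micrometres, mmHg and cm/s appear only at I/O boundaries.
"""

MMHG_TO_PA = 133.322  # 1 mmHg in Pa (fixed convention)


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def mm_to_m(x_mm: float) -> float:
    return x_mm * 1e-3


def m_to_mm(x_m: float) -> float:
    return x_m * 1e3


def um_to_m(x_um: float) -> float:
    return x_um * 1e-6


def m_to_um(x_m: float) -> float:
    return x_m * 1e6


def cms_to_ms(v_cms: float) -> float:
    return v_cms * 1e-2


def ms_to_cms(v_ms: float) -> float:
    return v_ms * 1e2
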