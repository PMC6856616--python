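"""Physical constants for Nernstian dye partitioning."""

from scipy.constants import R as GAS_CONSTANT  # J mol^-1 K^-1
from scipy.constants import physical_constants

FARADAY = physical_constants["Faraday constant"][0]  # C mol^-1

#: Default temperature (37 degC) for live-cell imaging.
DEFAULT_TEMPERATURE_K = 310.15

#: Charge of the monovalent cationic probes (TMRE/TMRM/Rho123).
DYE_VALENCE = 1


def nernst_kappa_mv(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT/zF in millivolts.

    At 310.15 K this is ~26.73 mV: a compartment 26.73 mV more polarized
    than its reference accumulates e-fold more monovalent cationic dye.
    """
    if temperature_K <= 0:
        raise ValueError(f"temperature_K must be positive, got {temperature_K}")
    return 1000.0 * GAS_CONSTANT * temperature_K / (DYE_VALENCE * FARADAY)
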