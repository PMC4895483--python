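"""The committed calibrated default parameter set.

Body-text constants (dilution rate from the 70-min cell cycle, C = 0.0003,
delta_peripl = 6, K_M_nrf = 0.03 mM, K_M_NirC,in = K_M_NirC,out = 1 mM,
baseline kt_nrf_cp = 0.01 1/s, 2 h cytoplasmic half-life with a ten-fold
more stable periplasmic fraction, NirC translation at least five-fold NirB)
are fixed; the remaining values were calibrated so the steady-state scan
reproduces the documented behaviour of the system (intracellular nitrite
capped at 14 uM and within 6-15 uM for s in [4, 7] mM, the low/high regime
boundaries near 1.25 and 3.5 mM, import-NirB coupling, negligible baseline
export).  See ``data/default_params.toml``.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .io import params_from_dict
from .kinetics import ModelParameters

__all__ = ["default_params"]


@lru_cache(maxsize=1)
def _cached() -> ModelParameters:
    import tomllib

    ref = resources.files("nitrite_chemostat").joinpath("data/default_params.toml")
    with ref.open("rb") as fh:
        return params_from_dict(tomllib.load(fh))


def default_params() -> ModelParameters:
    """Return the calibrated default :class:`ModelParameters`."""
    return _cached()
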