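"""Published deformed-Arrhenius parameters for PFK-1 channel water diffusion.

Reported fits of ln D = ln D0 + B/(RT) + C/(RT)^2 for water self-diffusion
in the three channel classes of the phosphofructokinase-1 (PFK-1) tetramer
(interface, porous and transient), over 260-340 K, with R = 8.314
J K^-1 mol^-1.  B is J/mol and C is J^2/mol^2; all three rows have C < 0
(super-Arrhenius: activation energy decreasing with temperature).  These
serve as realistic inputs for worked examples and generator settings; the
derived Ea(T) values are computed, never stored.
"""

from __future__ import annotations

import numpy as np

from .kinetics import SuperArrheniusFit

__all__ = ["CHANNEL_FITS", "channel_fit"]

#: (ln D0, B [J/mol], C [J^2/mol^2], R^2) per channel class.
CHANNEL_FITS: dict[str, tuple[float, float, float, float]] = {
    "transient": (-33.77, 9.98e4, -1.58e8, 0.9998),
    "interface": (-19.90, 2.49e4, -6.40e7, 0.9997),
    "porous": (-17.61, 8.31e3, -3.86e7, 0.9999),
}


def channel_fit(name: str) -> SuperArrheniusFit:
    """Published channel fit as a SuperArrheniusFit (zero covariance)."""
    ln_pre, B, C, r2 = CHANNEL_FITS[name]
    return SuperArrheniusFit(
        ln_pre=ln_pre, B=B, C=C, r_squared=r2,
        covariance=np.zeros((3, 3)), value_kind="diffusion", n_points=0,
    )
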