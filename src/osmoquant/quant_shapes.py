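"""Geometric cell-volume models used to convert per-cell amounts to mM.

Cell volumes are computed from microscopy dimensions using the standard
solid for each morphology (the usual practice for phytoplankton biovolume
estimates).  1 um^3 = 1 fL = 1e-3 pL.
"""

from __future__ import annotations

import math

__all__ = ["cell_volume_from_shape", "SUPPORTED_SHAPES"]

SUPPORTED_SHAPES = ("sphere", "cylinder", "prolate_spheroid")


def cell_volume_from_shape(shape: str, **dimensions_um: float) -> float:
    """Cell volume in pL from a geometric shape and its dimensions in um.

    Supported shapes and their keyword dimensions:

    * ``sphere``: ``diameter``
    * ``cylinder``: ``diameter``, ``height``
    * ``prolate_spheroid``: ``diameter`` (equatorial), ``length`` (polar)
    """
    for name, value in dimensions_um.items():
        if value <= 0:
            raise ValueError(f"dimension {name} must be > 0, got {value}")

    def need(*names: str) -> list[float]:
        missing = [n for n in names if n not in dimensions_um]
        if missing:
            raise ValueError(f"shape {shape!r} requires dimensions {missing}")
        return [dimensions_um[n] for n in names]

    if shape == "sphere":
        (d,) = need("diameter")
        volume_um3 = math.pi * d ** 3 / 6.0
    elif shape == "cylinder":
        d, h = need("diameter", "height")
        volume_um3 = math.pi * (d / 2.0) ** 2 * h
    elif shape == "prolate_spheroid":
        d, length = need("diameter", "length")
        volume_um3 = math.pi * d ** 2 * length / 6.0
    else:
        raise ValueError(
            f"unsupported shape {shape!r}; supported: {SUPPORTED_SHAPES}"
        )
    return volume_um3 * 1e-3  # um^3 -> pL
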