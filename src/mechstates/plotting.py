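"""Rendering of state maps as raster images.

Full mode maps each of the twelve states to a fixed accessible colour
(warm colours for active contractions, blues/cyans for relaxations, greens
for quiescence); simplified mode shows active contraction in red, active
relaxation in blue and all passive states in white.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluation import simplify_codes
from .maps import StateMap
from .states import STATES

__all__ = ["FULL_PALETTE", "SIMPLIFIED_PALETTE", "render_state_map"]

# Canonical-order palette: oimc, oimr, dipi, dipd, itc, itr, atc, atr, ps, pd, oq, dq
FULL_PALETTE: tuple[str, ...] = (
    "#d7191c",  # oimc  red           (active contraction)
    "#08306b",  # oimr  dark blue
    "#bf812d",  # dipi  tan
    "#8c510a",  # dipd  brown
    "#f46d43",  # itc   orange        (active contraction)
    "#74add1",  # itr   light blue    (active relaxation)
    "#ffd92f",  # atc   yellow        (active contraction)
    "#00ced1",  # atr   cyan          (active relaxation)
    "#f1b6da",  # ps    pink
    "#9970ab",  # pd    purple
    "#006837",  # oq    dark green
    "#a6d96a",  # dq    light green
)

# pas, ac, ar
SIMPLIFIED_PALETTE: tuple[str, ...] = ("#ffffff", "#d7191c", "#2c7bb6")


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    h = h.lstrip("#")
    return tuple(int(h[i:i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def palette_legend(mode: str = "full") -> list[tuple[int, str, str]]:
    """(code, name, colour) rows of the palette legend."""
    if mode == "full":
        return [(s.value, s.label, FULL_PALETTE[s.value]) for s in STATES]
    if mode == "simplified":
        return [(0, "pas", SIMPLIFIED_PALETTE[0]), (1, "ac", SIMPLIFIED_PALETTE[1]),
                (2, "ar", SIMPLIFIED_PALETTE[2])]
    raise ValueError(f"mode must be 'full' or 'simplified', got {mode!r}")


def render_state_map(states: StateMap | np.ndarray, mode: str = "full",
                     path: str | Path | None = None, scale: int = 4) -> np.ndarray:
    """Rasterise a state map, one ``scale`` x ``scale`` pixel block per cell.

    Returns the RGB uint8 image array; if *path* is given the image is also
    written there (format from the extension, e.g. ``.png``).
    """
    codes = np.asarray(getattr(states, "codes", states), dtype=np.intp)
    if codes.ndim == 1:
        codes = codes[None, :]
    if codes.size == 0:
        raise ValueError("state map is empty")
    if mode == "full":
        lut = np.array([_hex_to_rgb(c) for c in FULL_PALETTE], dtype=np.uint8)
        idx = codes
    elif mode == "simplified":
        lut = np.array([_hex_to_rgb(c) for c in SIMPLIFIED_PALETTE], dtype=np.uint8)
        idx = simplify_codes(codes)
    else:
        raise ValueError(f"mode must be 'full' or 'simplified', got {mode!r}")
    img = lut[idx]
    img = np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)
    if path is not None:
        import matplotlib.image

        matplotlib.image.imsave(str(path), img)
    return img
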