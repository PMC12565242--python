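"""Representative-slice (RS) geometry anchored on the position markers.

With marker slices r_u < r_m < r_l (apical onset, tracheal bifurcation,
upper diaphragm), a case is summarised by 3, 5 or 9 slices at fixed
fractional positions of the two inter-marker intervals:

* 3-RS: one slice a third of the way down the upper interval, the
  bifurcation itself, and one slice a third of the way down the lower
  interval.
* 5-RS: slices at 1/3 and 2/3 of each interval plus the bifurcation.
* 9-RS: the 3-RS slices together with their immediate superior and
  inferior neighbours.

Anchoring on markers removes inter-patient variation in lung size; the
geometry is translation-equivariant in the marker indices.  Fractional
positions are measured from the superior end of each interval and rounded
half away from zero; 9-RS neighbours are clamped to the volume, and any
post-clamp duplicate is an error (markers too close) rather than silently
repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import CTVolume, ScannerMask, apply_scanner_mask, rgb_windowing
from .pm import PMAnnotation, PMSelection

__all__ = ["RSSet", "extract_rs", "stack_rs_volume", "random_slice_baseline"]

_STRATEGY_SIZES = {"RS3": 3, "RS5": 5, "RS9": 9}


@dataclass
class RSSet:
    strategy: str                      # RS3 | RS5 | RS9
    indices: tuple[int, ...]           # strictly increasing slice indices
    source: PMSelection | PMAnnotation | None = None

    def __post_init__(self):
        if self.strategy not in _STRATEGY_SIZES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if len(self.indices) != _STRATEGY_SIZES[self.strategy]:
            raise ValueError(f"{self.strategy} needs {_STRATEGY_SIZES[self.strategy]} "
                             f"indices, got {self.indices}")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError(f"indices must be strictly increasing, got {self.indices}")

    def __len__(self) -> int:
        return len(self.indices)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _marker_tuple(pm) -> tuple[int, int, int]:
    if isinstance(pm, (PMSelection,)):
        return pm.indices
    if isinstance(pm, PMAnnotation):
        return pm.as_tuple()
    ru, rm, rl = pm
    return int(ru), int(rm), int(rl)


def extract_rs(pm, strategy: str | int, n_slices: int,
               lower_anchor: str = "bifurcation") -> RSSet:
    """Select representative slices from marker indices.

    ``strategy`` is 3/5/9 or 'RS3'/'RS5'/'RS9'.  ``lower_anchor`` resolves an
    ambiguity in the 3-RS lower slice: 'bifurcation' (default) measures one
    third downward from the bifurcation; 'diaphragm' measures one third
    upward from the diaphragm marker.
    """
    if isinstance(strategy, int):
        strategy = f"RS{strategy}"
    if strategy not in _STRATEGY_SIZES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if lower_anchor not in ("bifurcation", "diaphragm"):
        raise ValueError(f"unknown lower_anchor {lower_anchor!r}")
    ru, rm, rl = _marker_tuple(pm)
    if not 0 <= ru < rm < rl <= n_slices - 1:
        raise ValueError(f"marker ordering violated or out of range: "
                         f"({ru}, {rm}, {rl}) with {n_slices} slices")

    up, lo = rm - ru, rl - rm
    if lower_anchor == "bifurcation":
        rs3_lower = rm + _round_half_away(lo / 3)
    else:
        rs3_lower = rl - _round_half_away(lo / 3)
    rs3 = (ru + _round_half_away(up / 3), rm, rs3_lower)

    if strategy == "RS3":
        indices = rs3
    elif strategy == "RS5":
        indices = (ru + _round_half_away(up / 3), ru + _round_half_away(2 * up / 3),
                   rm,
                   rm + _round_half_away(lo / 3), rm + _round_half_away(2 * lo / 3))
    else:
        indices = tuple(sorted(
            min(max(i + d, 0), n_slices - 1) for i in rs3 for d in (-1, 0, 1)))

    if len(set(indices)) < _STRATEGY_SIZES[strategy]:
        raise ValueError(f"markers too close for {strategy}: duplicate slice "
                         f"indices in {indices}")
    source = pm if isinstance(pm, (PMSelection, PMAnnotation)) else None
    return RSSet(strategy=strategy, indices=tuple(int(i) for i in indices),
                 source=source)


def stack_rs_volume(volume: CTVolume, rs: RSSet, out_size: int = 518,
                    mask: ScannerMask | None = None,
                    order: str = "window_first") -> np.ndarray:
    """Assemble the per-case model input: a (T, S, S, 3) uint8 stack of the
    RGB-windowed representative slices, ordered superior to inferior."""
    if max(rs.indices) > volume.n_slices - 1:
        raise ValueError(f"slice index {max(rs.indices)} outside volume of "
                         f"{volume.n_slices} slices")
    frames = []
    for m in rs.indices:
        hu = volume.slices[m]
        if mask is not None:
            hu = apply_scanner_mask(hu, mask)
        frames.append(rgb_windowing(hu, out_size=out_size, order=order))
    return np.stack(frames)


def random_slice_baseline(n_slices: int, n_select: int, seed: int = 0) -> tuple[int, ...]:
    """Uniformly sampled sorted slice indices (the random-selection control)."""
    rng = np.random.default_rng(seed)
    if n_select > n_slices:
        raise ValueError("cannot select more slices than the volume holds")
    return tuple(sorted(rng.choice(n_slices, size=n_select, replace=False).tolist()))
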