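"""Retention-time correction anchored on pseudo-internal standards.

Instead of an exogenous n-alkane ladder, a handful (at most eight) of stable
endogenous metabolite peaks observed in the current batch serve as anchors.
Each anchor contributes a pair (rt_old, rt_new): the retention time recorded
in the reference library and the retention time at which the compound
actually eluted in this batch.  Library retention times are updated through a
strictly monotone piecewise-linear map through the anchor pairs; outside the
anchor range the boundary segment's affine law is extended, and a single
anchor degenerates to a pure time offset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

MAX_ANCHORS = 8

__all__ = [
    "MAX_ANCHORS",
    "Anchor",
    "AnchorSet",
    "RTMap",
    "AnchorConfigurationError",
    "build_rt_map",
    "correct_rt",
    "update_library",
]


class AnchorConfigurationError(ValueError):
    """Invalid anchor set (too many anchors, or a non-monotone pair)."""


@dataclass(frozen=True)
class Anchor:
    name: str
    rt_old: float  # seconds, reference-library retention time
    rt_new: float  # seconds, observed retention time in this batch


@dataclass(frozen=True)
class AnchorSet:
    """1-8 anchors forming a strictly monotone rt_old -> rt_new map."""

    anchors: tuple[Anchor, ...]

    def __init__(self, anchors: Iterable[Anchor]) -> None:
        ordered = tuple(sorted(anchors, key=lambda a: a.rt_old))
        if not 1 <= len(ordered) <= MAX_ANCHORS:
            raise AnchorConfigurationError(
                f"need between 1 and {MAX_ANCHORS} anchors, got {len(ordered)}"
            )
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.rt_old <= prev.rt_old:
                raise AnchorConfigurationError(
                    f"anchor rt_old not strictly increasing: "
                    f"{prev.name} ({prev.rt_old} s) vs {cur.name} ({cur.rt_old} s)"
                )
            if cur.rt_new <= prev.rt_new:
                raise AnchorConfigurationError(
                    f"anchor rt_new not strictly increasing: "
                    f"{prev.name} ({prev.rt_new} s) vs {cur.name} ({cur.rt_new} s)"
                )
        object.__setattr__(self, "anchors", ordered)

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class RTMap:
    """Total strictly monotone map from old to new retention time.

    Piecewise linear between anchors; boundary segments extended beyond the
    anchor range; a single anchor gives a constant offset.
    """

    rt_old: np.ndarray
    rt_new: np.ndarray
    rule: str = "piecewise-linear/boundary-extension"

    def inverse(self) -> "RTMap":
        """Map with anchor roles swapped (new -> old)."""
        return RTMap(self.rt_new.copy(), self.rt_old.copy(), self.rule)


def build_rt_map(anchors: AnchorSet) -> RTMap:
    old = np.array([a.rt_old for a in anchors.anchors], dtype=float)
    new = np.array([a.rt_new for a in anchors.anchors], dtype=float)
    return RTMap(old, new)


def correct_rt(rt_old, rt_map: RTMap):
    """Map retention time(s) through the anchor map.

    Accepts a scalar or array; returns the same shape.  A single anchor
    applies a uniform offset; with several anchors, queries below the first
    or above the last anchor follow the nearest segment's affine law.
    """
    t = np.asarray(rt_old, dtype=float)
    o, n = rt_map.rt_old, rt_map.rt_new
    if o.size == 1:
        out = t + (n[0] - o[0])
    else:
        inner = np.interp(t, o, n)
        slope_lo = (n[1] - n[0]) / (o[1] - o[0])
        slope_hi = (n[-1] - n[-2]) / (o[-1] - o[-2])
        lo = n[0] + slope_lo * (t - o[0])
        hi = n[-1] + slope_hi * (t - o[-1])
        out = np.where(t < o[0], lo, np.where(t > o[-1], hi, inner))
    return float(out) if np.isscalar(rt_old) or np.ndim(rt_old) == 0 else out


def update_library(library: Sequence, rt_map: RTMap) -> list:
    """Return a new library with every entry's RT passed through the map.

    Entries are any dataclass with an ``rt`` field (``ReferenceEntry`` in
    practice); spectra and metadata are untouched and the input sequence is
    not mutated.
    """
    return [replace(entry, rt=correct_rt(entry.rt, rt_map)) for entry in library]
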