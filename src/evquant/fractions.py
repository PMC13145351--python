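"""Size-exclusion chromatography fraction-profile analysis.

A profile is a fixed grid of 20 fraction readings (protein A280,
percent dye-positive particles, or raw FL1 signal), each fraction a
fixed elution volume (45 µL by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

N_FRACTIONS = 20


@dataclass(frozen=True)
class FractionProfile:
    values: tuple[float, ...]
    fraction_volume_ul: float = 45.0
    value_kind: str = "protein_a280"  # protein_a280 | pct_cfda_positive | fl1_intensity

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) != N_FRACTIONS:
            raise ValueError(f"profile must have exactly {N_FRACTIONS} values")
        if any(v < 0 or not np.isfinite(v) for v in vals):
            raise ValueError("fraction values must be finite and >= 0")
        if self.fraction_volume_ul <= 0:
            raise ValueError("fraction_volume_ul must be > 0")
        object.__setattr__(self, "values", vals)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class ElutionWindow:
    """Contiguous fraction interval around the peak, plus what it misses."""

    start: int
    stop: int            # inclusive, 1-based
    tail_mass: float     # fraction of total signal outside the window

    def __iter__(self):
        return iter((self.start, self.stop))

    @property
    def n_fractions(self) -> int:
        return self.stop - self.start + 1


def normalize_profile(p: FractionProfile) -> FractionProfile:
    """Scale a profile so its maximum is 1 (shape-preserving, idempotent)."""
    arr = p.as_array()
    peak = arr.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return replace(p, values=tuple(arr / peak))


def peak_fraction(p: FractionProfile) -> int:
    """1-based index of the profile maximum; ties go to the earlier fraction."""
    return int(np.argmax(p.as_array())) + 1


def elution_window(p: FractionProfile, rel_threshold: float = 0.1) -> ElutionWindow:
    """Contiguous fraction range around the peak with values >= threshold·max.

    The window grows outward from the peak while fraction values stay at
    or above ``rel_threshold`` of the profile maximum; signal outside it
    is reported as ``tail_mass`` (fraction of total).
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    arr = p.as_array()
    total = arr.sum()
    if total <= 0:
        raise ValueError("degenerate (all-zero) profile")
    cut = rel_threshold * arr.max()
    peak = int(np.argmax(arr))  # 0-based
    lo = peak
    while lo > 0 and arr[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi < arr.size - 1 and arr[hi + 1] >= cut:
        hi += 1
    inside = arr[lo : hi + 1].sum()
    return ElutionWindow(start=lo + 1, stop=hi + 1,
                         tail_mass=float(1.0 - inside / total))


def profile_overlap(a: FractionProfile, b: FractionProfile) -> float:
    """Co-elution overlap coefficient: Σ min(aᵢ, bᵢ) / min(Σa, Σb).

    Normalising by the smaller total mass scores a fully nested narrow
    peak as 1 — the quantity of interest is co-elution risk, not shape
    identity.  Arguments are normalised profiles on the same grid.
    """
    va, vb = a.as_array(), b.as_array()
    ma, mb = va.sum(), vb.sum()
    if ma <= 0 or mb <= 0:
        raise ValueError("profiles must have positive total mass")
    return float(np.minimum(va, vb).sum() / min(ma, mb))


def fractions_to_volume(
    fraction_range: Sequence[int] | tuple[int, int], p: FractionProfile
) -> float:
    """Total eluate volume (µL) of an inclusive 1-based fraction interval."""
    lo, hi = int(fraction_range[0]), int(fraction_range[1])
    if not 1 <= lo <= hi <= N_FRACTIONS:
        raise ValueError(f"invalid fraction interval [{lo}, {hi}]")
    return (hi - lo + 1) * p.fraction_volume_ul
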