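"""Threshold gating and the quadrant double-positive statistic.

The positive-particle definition follows the negative-control rule: the
threshold is the maximum signal observed in the control, and an event
is positive when its intensity is strictly above it (so the control's
own maximum event classifies negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .events import EventTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdSpec:
    channel: str
    value: float
    provenance: str = ""
    rule: str = "max-of-control"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("threshold value must be >= 0")


@dataclass(frozen=True)
class QuadrantResult:
    """Counts from a two-threshold quadrant gate.

    ``display_pct`` is the assay statistic: the percentage of
    FL1-positive (dye-labelled) events that are also FL4-positive
    (antibody-labelled).  It is ``None`` — undefined, not zero — when
    there are no FL1-positive events.
    """

    n_total: int
    n_fl1_pos: int
    n_fl4_pos: int
    n_double: int

    def __post_init__(self) -> None:
        if not (self.n_double <= min(self.n_fl1_pos, self.n_fl4_pos) <= self.n_total):
            raise ValueError("inconsistent quadrant counts")

    @property
    def display_pct(self) -> float | None:
        if self.n_fl1_pos == 0:
            return None
        return 100.0 * self.n_double / self.n_fl1_pos

    @property
    def pct_cfda(self) -> float:
        """Percent of all events above the FL1 threshold (%positive-marker)."""
        if self.n_total == 0:
            return 0.0
        return 100.0 * self.n_fl1_pos / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_fl1_pos": self.n_fl1_pos,
            "n_fl4_pos": self.n_fl4_pos,
            "n_double": self.n_double,
            "display_pct": self.display_pct,
            "pct_cfda": self.pct_cfda,
        }


def threshold_from_control(
    control: EventTable,
    channel: str,
    rule: str = "max-of-control",
    percentile: float = 99.9,
) -> ThresholdSpec:
    """Derive a positivity threshold from a negative-control acquisition.

    ``rule="max-of-control"`` (default) uses the maximum signal in the
    control.  ``rule="percentile"`` uses the given percentile instead —
    a robustness option, clearly not the published rule.
    """
    if len(control) == 0:
        raise ValueError("cannot derive a threshold from an empty control")
    values = control.channel(channel)
    if rule == "max-of-control":
        value = float(np.max(values))
    elif rule == "percentile":
        value = float(np.percentile(values, percentile))
        rule = f"percentile-{percentile}"
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    return ThresholdSpec(
        channel=channel, value=value,
        provenance=control.meta.sample_id, rule=rule,
    )


def percent_positive(sample: EventTable, thr: ThresholdSpec) -> float:
    """Percent of events with ``channel`` strictly above the threshold."""
    if len(sample) == 0:
        logger.warning("percent_positive on empty table: returning 0")
        return 0.0
    values = sample.channel(thr.channel)
    return 100.0 * float(np.count_nonzero(values > thr.value)) / len(sample)


def quadrant(
    sample: EventTable, thr_fl1: ThresholdSpec, thr_fl4: ThresholdSpec
) -> QuadrantResult:
    """Apply the two-threshold quadrant gate and count double positives."""
    if thr_fl1.channel == thr_fl4.channel:
        raise ValueError("quadrant thresholds must be on distinct channels")
    fl1 = sample.channel(thr_fl1.channel) > thr_fl1.value
    fl4 = sample.channel(thr_fl4.channel) > thr_fl4.value
    return QuadrantResult(
        n_total=len(sample),
        n_fl1_pos=int(fl1.sum()),
        n_fl4_pos=int(fl4.sum()),
        n_double=int((fl1 & fl4).sum()),
    )


def detergent_specificity(
    pct_sample: float,
    pct_detergent_treated: float,
    pct_control: float,
    tolerance: float = 5.0,
) -> str:
    """Classify a detergent-sensitivity check.

    ``ev_specific``: signal above control and abolished by detergent
    (membrane-bound, lysable).  ``protein_contaminated``: signal
    survives detergent (protein-activated dye).  ``no_signal``: nothing
    above control to start with.
    """
    for name, p in (("pct_sample", pct_sample),
                    ("pct_detergent_treated", pct_detergent_treated),
                    ("pct_control", pct_control)):
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {p}")
    cutoff = pct_control + tolerance
    if pct_sample > cutoff and pct_detergent_treated <= cutoff:
        return "ev_specific"
    if pct_sample > cutoff and pct_detergent_treated > cutoff:
        return "protein_contaminated"
    return "no_signal"
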