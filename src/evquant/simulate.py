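"""Synthetic flow-event, bead, dilution, elution and cohort generators.

Every generator takes an explicit integer seed and is bit-reproducible:
the same config and seed always produce the same output.  Intensity
distributions are log-normal (the cytometry convention); the default
noise floor is arbitrary instrument-scale and exposed in the specs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventMeta, EventTable


@dataclass(frozen=True)
class PopulationSpec:
    """A log-normal event population on the FL1 x FSC plane."""

    n_events_expected: float
    fl1_log10_mean: float
    fl1_log10_sd: float
    fsc_log10_mean: float
    fsc_log10_sd: float
    population_kind: str  # noise | ev | protein_particle

    def __post_init__(self) -> None:
        if self.n_events_expected < 0:
            raise ValueError("n_events_expected must be >= 0")
        if self.fl1_log10_sd < 0 or self.fsc_log10_sd < 0:
            raise ValueError("log10 SDs must be >= 0")
        if self.population_kind not in {"noise", "ev", "protein_particle"}:
            raise ValueError(f"unknown population_kind {self.population_kind!r}")


#: instrument noise floor — arbitrary defaults, configurable per population
NOISE_POPULATION = PopulationSpec(
    n_events_expected=1000,
    fl1_log10_mean=1.0,
    fl1_log10_sd=0.25,
    fsc_log10_mean=2.9,
    fsc_log10_sd=0.20,
    population_kind="noise",
)

EV_POPULATION = replace(
    NOISE_POPULATION,
    fl1_log10_mean=2.5,
    fl1_log10_sd=0.35,
    fsc_log10_mean=3.0,
    population_kind="ev",
)

#: protein(BSA)-activated particles: FL1 indistinguishable from EVs
BSA_POPULATION = replace(EV_POPULATION, population_kind="protein_particle")

#: FL4 noise floor shared by all antibody-free events
FL4_NOISE_LOG10_MEAN = 0.8
FL4_NOISE_LOG10_SD = 0.25


@dataclass(frozen=True)
class AntibodyModel:
    """FL4 labelling model: bright-event median scales with antibody amount."""

    amount_ug: float = 1.0
    display_prob: float = 0.5
    fl4_log10_median_at_ref: float = 2.5
    ref_amount_ug: float = 1.0
    fl4_log10_sd: float = 0.30
    isotype_nonspecific_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.amount_ug <= 0 or self.ref_amount_ug <= 0:
            raise ValueError("antibody amounts must be > 0")
        for p in (self.display_prob, self.isotype_nonspecific_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.fl4_log10_sd < 0:
            raise ValueError("fl4_log10_sd must be >= 0")

    @property
    def fl4_log10_median(self) -> float:
        """Bright-event log10 FL4 median: proportional to antibody amount."""
        return self.fl4_log10_median_at_ref + math.log10(
            self.amount_ug / self.ref_amount_ug
        )


@dataclass(frozen=True)
class SampleConfig:
    populations: tuple[PopulationSpec, ...] = (EV_POPULATION,)
    antibody: AntibodyModel | None = None
    detergent: bool = False
    trypan_blue: bool = False
    bsa_present: bool = False
    seed: int = 0
    sample_id: str = "synthetic"
    analyzed_volume_ul: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))


def _lognormal(rng: np.random.Generator, log10_mean: float, log10_sd: float, n: int):
    return np.power(10.0, rng.normal(log10_mean, log10_sd, size=n))


def gen_sample_events(config: SampleConfig) -> EventTable:
    """Simulate one stained sample as an :class:`EventTable`.

    Mechanics:

    * each population contributes ``Poisson(n_events_expected)`` events
      with log-normal FL1 and FSC-H;
    * with an antibody model, EV events carry the epitope with
      ``display_prob`` (plus an independent non-specific fraction); FL4
      of labelled events is log-normal with median proportional to the
      antibody amount, others sit on the FL4 noise floor;
    * ``detergent`` lyses EVs: their FL1 is redrawn from the noise
      distribution while protein particles keep theirs;
    * ``trypan_blue`` quenches all FL1 to the noise floor and pushes
      protein-bearing events into FL4 (dye-protein red shift);
    * ``bsa_present`` appends a protein-particle population.

    Generated tables use zero acquisition triggers so population sizes
    stay exactly Poisson; ingestion-time trigger filtering is a
    property of instrument files, not of the simulator.
    """
    rng = np.random.default_rng(config.seed)
    populations = list(config.populations)
    if config.bsa_present:
        populations.append(BSA_POPULATION)
    noise_ref = next(
        (p for p in populations if p.population_kind == "noise"), NOISE_POPULATION
    )

    frames = []
    for pop in populations:
        n = int(rng.poisson(pop.n_events_expected))
        fl1 = _lognormal(rng, pop.fl1_log10_mean, pop.fl1_log10_sd, n)
        fsc = _lognormal(rng, pop.fsc_log10_mean, pop.fsc_log10_sd, n)
        ssc = fsc * _lognormal(rng, -0.3, 0.1, n)
        fl2 = _lognormal(rng, FL4_NOISE_LOG10_MEAN, FL4_NOISE_LOG10_SD, n)
        fl3 = _lognormal(rng, FL4_NOISE_LOG10_MEAN, FL4_NOISE_LOG10_SD, n)
        fl4 = _lognormal(rng, FL4_NOISE_LOG10_MEAN, FL4_NOISE_LOG10_SD, n)

        if config.antibody is not None and pop.population_kind == "ev":
            ab = config.antibody
            labelled = rng.random(n) < ab.display_prob
            if ab.isotype_nonspecific_prob > 0:
                labelled |= rng.random(n) < ab.isotype_nonspecific_prob
            n_lab = int(labelled.sum())
            fl4[labelled] = _lognormal(
                rng, ab.fl4_log10_median, ab.fl4_log10_sd, n_lab
            )

        if config.detergent and pop.population_kind == "ev":
            fl1 = _lognormal(
                rng, noise_ref.fl1_log10_mean, noise_ref.fl1_log10_sd, n
            )
        if config.trypan_blue:
            fl1 = _lognormal(
                rng, noise_ref.fl1_log10_mean, noise_ref.fl1_log10_sd, n
            )
            if pop.population_kind == "protein_particle":
                fl4 = _lognormal(rng, 2.2, 0.3, n)

        frames.append(
            pd.DataFrame(
                {"fsc_h": fsc, "ssc_h": ssc, "fl1": fl1,
                 "fl2": fl2, "fl3": fl3, "fl4": fl4}
            )
        )

    tags = set()
    if config.detergent:
        tags.add("detergent")
    if config.trypan_blue:
        tags.add("trypan_blue")
    if config.bsa_present:
        tags.add("bsa")
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["fsc_h", "ssc_h", "fl1", "fl2", "fl3", "fl4"])
    )
    meta = EventMeta(
        sample_id=config.sample_id,
        analyzed_volume_ul=config.analyzed_volume_ul,
        trigger_fsc_h=0.0,
        trigger_ssc_h=0.0,
        condition_tags=frozenset(tags),
    )
    return EventTable(df, meta)


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort of display percentages with technical replicates."""

    mean_pos: float = 21.5   # pregnant group display %
    sd_pos: float = 3.0
    mean_neg: float = 33.0   # non-pregnant controls
    sd_neg: float = 5.9
    isotype_mean: float = 12.6
    isotype_sd: float = 3.4
    n_per_group: int = 6
    replicates: int = 3
    replicate_sd: float = 1.5
    seed: int = 0
    include_isotype: bool = False

    def __post_init__(self) -> None:
        if min(self.sd_pos, self.sd_neg, self.isotype_sd, self.replicate_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if self.n_per_group < 1 or self.replicates < 1:
            raise ValueError("n_per_group and replicates must be >= 1")


def gen_cohort(config: CohortConfig) -> pd.DataFrame:
    """Per-sample display percentages by group, one row per replicate.

    Each biological sample draws a value from its group normal; each
    technical replicate adds independent noise of SD ``replicate_sd``.
    All values are truncated to [0, 100].

    Returns a long DataFrame with columns
    ``sample_id, group, replicate, display_pct``.
    """
    rng = np.random.default_rng(config.seed)
    groups = [("pregnant", config.mean_pos, config.sd_pos),
              ("control", config.mean_neg, config.sd_neg)]
    if config.include_isotype:
        groups.append(("isotype", config.isotype_mean, config.isotype_sd))
    rows = []
    for group, mean, sd in groups:
        sample_values = np.clip(
            rng.normal(mean, sd, size=config.n_per_group), 0.0, 100.0
        )
        for i, value in enumerate(sample_values):
            reps = np.clip(
                value + rng.normal(0.0, config.replicate_sd, size=config.replicates),
                0.0, 100.0,
            )
            for r, rep in enumerate(reps):
                rows.append(
                    {"sample_id": f"{group}_{i + 1}", "group": group,
                     "replicate": r + 1, "display_pct": float(rep)}
                )
    return pd.DataFrame(rows)


def gen_bead_events(
    sizes_nm: Sequence[float],
    events_per_bead: int = 1000,
    fsc_cv: float = 0.05,
    law: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
) -> tuple[EventTable, np.ndarray]:
    """Simulate a mixed polystyrene-bead acquisition.

    ``law = (a, b)`` sets the noiseless cluster median
    ``FSC-H = a * size_nm ** b``; ``fsc_cv`` is the multiplicative
    (log-normal) coefficient of variation.  Returns the event table
    plus the true cluster label of every event, for oracle use.
    """
    sizes = [float(s) for s in sizes_nm]
    if len(set(sizes)) != len(sizes) or any(s <= 0 for s in sizes):
        raise ValueError("bead sizes must be distinct and > 0")
    a, b = law
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(fsc_cv**2))  # log-normal sigma from CV
    fscs, labels, fl1s = [], [], []
    for label, size in enumerate(sizes):
        median = a * size**b
        fsc = median * np.exp(rng.normal(0.0, sigma, size=events_per_bead))
        fscs.append(fsc)
        # beads are identified by their own fluorescence, one level per size
        fl1s.append(
            _lognormal(rng, 3.0 + 0.3 * label, 0.05, events_per_bead)
        )
        labels.append(np.full(events_per_bead, label))
    fsc = np.concatenate(fscs)
    n = fsc.size
    df = pd.DataFrame(
        {"fsc_h": fsc, "ssc_h": fsc * 0.5,
         "fl1": np.concatenate(fl1s),
         "fl2": np.ones(n), "fl3": np.ones(n), "fl4": np.ones(n)}
    )
    meta = EventMeta(sample_id="beads", trigger_fsc_h=0.0, trigger_ssc_h=0.0)
    return EventTable(df, meta), np.concatenate(labels)


def gen_dilution_series(
    base_count: float,
    dilution_factors: Sequence[float],
    saturation_count: float = math.inf,
    seed: int = 0,
) -> pd.DataFrame:
    """Detected event counts along a dilution ladder with coincidence loss.

    The expected detected count at a true count ``T`` is
    ``T * exp(-T / saturation_count)`` — detection is near-proportional
    when dilute and undercounts (swarm) when concentrated — then Poisson
    sampled.  ``saturation_count = inf`` disables the loss.
    """
    factors = np.asarray(list(dilution_factors), dtype=float)
    if np.any((factors <= 0) | (factors > 1)):
        raise ValueError("dilution factors must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    true = base_count * factors
    if math.isinf(saturation_count):
        expected = true
    else:
        expected = true * np.exp(-true / saturation_count)
    detected = rng.poisson(expected).astype(int)
    return pd.DataFrame(
        {"dilution_factor": factors, "expected_count": expected,
         "detected_count": detected}
    )


def gen_fraction_profile(
    peak_fraction: float,
    width_fractions: float,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    kind: str = "protein_a280",
    n_fractions: int = 20,
    fraction_volume_ul: float = 45.0,
):
    """Deterministic Gaussian elution profile over ``n_fractions`` fractions.

    ``value_i = baseline + amplitude * exp(-(i - peak)^2 / (2 sigma^2))``
    for fraction indices i = 1..n.
    """
    from .fractions import FractionProfile

    if not 1 <= peak_fraction <= n_fractions:
        raise ValueError(f"peak_fraction must lie in [1, {n_fractions}]")
    if width_fractions < 0:
        raise ValueError("width_fractions must be >= 0")
    i = np.arange(1, n_fractions + 1, dtype=float)
    if width_fractions == 0:
        shape = (i == peak_fraction).astype(float)
    else:
        shape = np.exp(-((i - peak_fraction) ** 2) / (2 * width_fractions**2))
    values = baseline + amplitude * shape
    return FractionProfile(values, fraction_volume_ul=fraction_volume_ul,
                           value_kind=kind)
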