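"""Bead-based size calibration, concentration arithmetic and dilution QC.

Size calibration is an ordinary least-squares line in
(log10 size, log10 FSC-H) space fitted on beads of known diameter;
scatter scales as a power of diameter, so the log-log fit linearises a
power law.  A semilog variant (linear size axis) is available because
the size-axis transform is an instrument-convention choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .events import EventTable


@dataclass(frozen=True)
class SizeCalibration:
    """log10(FSC-H) = slope * x(size) + intercept, x = log10 or identity."""

    slope: float
    intercept: float
    r_squared: float
    basis: str = "median"            # which FSC statistic was fitted
    size_transform: str = "log10"    # log10 | linear
    beads: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len({s for s, _ in self.beads}) < 2:
            raise ValueError("calibration requires >= 2 distinct bead sizes")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")


def _size_axis(sizes: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log10":
        return np.log10(sizes)
    if transform == "linear":
        return sizes
    raise ValueError(f"unknown size_transform {transform!r}")


def fit_size_calibration(
    beads: Sequence[tuple[float, float]],
    basis: str = "median",
    size_transform: str = "log10",
) -> SizeCalibration:
    """OLS fit of log10 FSC statistic against (transformed) bead size.

    ``beads`` is a sequence of ``(size_nm, fsc_stat)`` pairs where
    ``fsc_stat`` is the mean or median FSC-H of that bead population
    (``basis`` records which).  With beads exactly on
    ``fsc = a * size**b`` the log-log fit returns slope ``b`` and
    intercept ``log10(a)`` with r² = 1.
    """
    pairs = [(float(s), float(f)) for s, f in beads]
    if len({s for s, _ in pairs}) < 2:
        raise ValueError("need >= 2 distinct bead sizes")
    if any(s <= 0 or f <= 0 for s, f in pairs):
        raise ValueError("bead sizes and FSC statistics must be > 0")
    sizes = np.array([s for s, _ in pairs])
    fscs = np.array([f for _, f in pairs])
    x = _size_axis(sizes, size_transform)
    y = np.log10(fscs)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return SizeCalibration(
        slope=float(slope), intercept=float(intercept),
        r_squared=min(max(r2, 0.0), 1.0), basis=basis,
        size_transform=size_transform, beads=tuple(pairs),
    )


def predict_fsc(size_nm: float, cal: SizeCalibration) -> float:
    """Forward map: expected FSC statistic at a given size."""
    if size_nm <= 0:
        raise ValueError("size must be > 0")
    x = math.log10(size_nm) if cal.size_transform == "log10" else size_nm
    return 10.0 ** (cal.slope * x + cal.intercept)


def estimate_size(fsc_stat: float, cal: SizeCalibration) -> float:
    """Invert the calibration line to a particle size in nm."""
    if fsc_stat <= 0:
        raise ValueError("fsc_stat must be > 0")
    if cal.slope == 0:
        raise ValueError("degenerate calibration: slope is zero")
    x = (math.log10(fsc_stat) - cal.intercept) / cal.slope
    return 10.0**x if cal.size_transform == "log10" else x


# ---------------------------------------------------------------------------
# peak-bead instrument validation


@dataclass(frozen=True)
class PeakReport:
    n_peaks_found: int
    n_peaks_expected: int
    peak_means: tuple[float, ...]      # linear-scale means, ascending
    peak_cvs: tuple[float, ...]        # SD/mean per peak, same order
    passed: bool
    message: str = ""

    @property
    def brightest_cv(self) -> float:
        return self.peak_cvs[-1]


def _kmeans_1d(values: np.ndarray, k: int, n_iter: int = 200) -> np.ndarray:
    """Deterministic 1-D k-means with quantile initialization.

    Returns integer labels ordered so cluster 0 has the lowest centre.
    Quantile init makes the partition reproducible without a seed.
    """
    qs = (np.arange(k) + 0.5) / k
    centres = np.quantile(values, qs)
    labels = np.zeros(values.size, dtype=int)
    for _ in range(n_iter):
        d = np.abs(values[:, None] - centres[None, :])
        new_labels = np.argmin(d, axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            mask = labels == j
            if mask.any():
                centres[j] = values[mask].mean()
    order = np.argsort(centres)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels]


def validate_peak_beads(
    beads: EventTable,
    n_expected_peaks: int,
    channel: str = "fl1",
    cv_limit: float = 0.05,
) -> PeakReport:
    """Check a multi-peak validation-bead acquisition.

    Events are clustered on log10 intensity into the expected number of
    groups; the run passes when every expected peak is populated and the
    brightest peak's linear-scale CV (SD/mean) is below ``cv_limit``.
    """
    if n_expected_peaks < 1:
        raise ValueError("n_expected_peaks must be >= 1")
    values = beads.channel(channel)
    if np.any(values <= 0):
        raise ValueError("peak validation requires positive intensities")
    logv = np.log10(values)
    if n_expected_peaks == 1:
        labels = np.zeros(values.size, dtype=int)
    else:
        labels = _kmeans_1d(logv, n_expected_peaks)
    means, cvs, log_means, log_sds, sizes = [], [], [], [], []
    for j in range(n_expected_peaks):
        grp = values[labels == j]
        sizes.append(grp.size)
        if grp.size == 0:
            continue
        means.append(float(grp.mean()))
        cvs.append(float(grp.std(ddof=1) / grp.mean()) if grp.size > 1 else 0.0)
        lg = logv[labels == j]
        log_means.append(float(lg.mean()))
        log_sds.append(float(lg.std(ddof=1)) if lg.size > 1 else 0.0)
    # adjacent clusters closer than twice their combined log-spread are a
    # single unresolved peak that k-means split, not two instrument peaks
    n_merged = sum(
        1
        for j in range(len(log_means) - 1)
        if (log_means[j + 1] - log_means[j])
        < 2.0 * (log_sds[j] + log_sds[j + 1])
    )
    n_found = len(means) - n_merged
    if n_found < n_expected_peaks:
        return PeakReport(
            n_peaks_found=n_found, n_peaks_expected=n_expected_peaks,
            peak_means=tuple(means), peak_cvs=tuple(cvs), passed=False,
            message=f"only {n_found} resolvable peaks, "
                    f"expected {n_expected_peaks}",
        )
    passed = cvs[-1] < cv_limit
    msg = "" if passed else (
        f"brightest peak CV {cvs[-1]:.3f} >= limit {cv_limit:.3f}"
    )
    return PeakReport(
        n_peaks_found=n_found, n_peaks_expected=n_expected_peaks,
        peak_means=tuple(means), peak_cvs=tuple(cvs), passed=passed,
        message=msg,
    )


# ---------------------------------------------------------------------------
# concentration arithmetic


def mixture_concentration(parts: Sequence[tuple[float, float]]) -> float:
    """Volume-weighted concentration of a mixture.

    ``parts`` is a sequence of ``(volume_ul, concentration)``; the
    result is ``sum(v_i * c_i) / sum(v_i)``, unit-preserving.
    """
    parts = [(float(v), float(c)) for v, c in parts]
    if any(v < 0 or c < 0 for v, c in parts):
        raise ValueError("volumes and concentrations must be >= 0")
    total = sum(v for v, _ in parts)
    if total <= 0:
        raise ValueError("total volume must be > 0")
    return sum(v * c for v, c in parts) / total


@dataclass(frozen=True)
class DilutionChain:
    """Ordered dilution steps; each step takes ``aliquot_ul`` into ``final_ul``."""

    steps: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        steps = tuple((float(a), float(f)) for a, f in self.steps)
        for a, f in steps:
            if a <= 0 or f <= 0:
                raise ValueError("volumes must be > 0")
            if a > f:
                raise ValueError("aliquot volume cannot exceed final volume")
        object.__setattr__(self, "steps", steps)

    @property
    def factor(self) -> float:
        """Overall dilution factor: product of aliquot/final per step."""
        out = 1.0
        for a, f in self.steps:
            out *= a / f
        return out


def particles_per_ml_source(
    count_above_threshold: int,
    analyzed_volume_ul: float,
    chain: DilutionChain | None = None,
) -> float:
    """Back-calculate source-fluid particle concentration (per mL).

    ``(count / analyzed µL) * 1000 / chain.factor``; an empty chain
    (factor 1) reports the concentration of the acquired tube itself.
    """
    if analyzed_volume_ul <= 0:
        raise ValueError("analyzed_volume_ul must be > 0")
    factor = chain.factor if chain is not None else 1.0
    return (count_above_threshold / analyzed_volume_ul) * 1000.0 / factor


# ---------------------------------------------------------------------------
# dilution-series linearity / swarm assessment


@dataclass(frozen=True)
class LinearityResult:
    dilution_factors: tuple[float, ...]
    normalized_counts: tuple[float, ...]   # counts / max(count)
    slope: float                            # zero-intercept fit on normalized
    r_squared: float
    deviations: tuple[float, ...]           # observed/predicted - 1 per point
    swarm_flags: tuple[bool, ...]
    fit_range: tuple[float, float]


def linearity_assessment(
    series: Sequence[tuple[float, float]],
    fit_range: tuple[float, float],
    tolerance: float = 0.2,
) -> LinearityResult:
    """Assess dilution-series proportionality and flag coincidence loss.

    Counts are normalised to the series maximum; a zero-intercept least
    squares line (a blank holds zero particles, so dilution of one
    stock must pass through the origin) is fitted to points whose
    dilution factor lies in ``fit_range``.  Any point whose observed
    count falls below ``(1 - tolerance)`` of the fitted prediction is
    flagged as swarm-affected; within the fit range such shortfalls
    would indicate a failed fit, outside it (more concentrated) they
    indicate coincidence undercounting.
    """
    pairs = [(float(f), float(c)) for f, c in series]
    lo, hi = float(fit_range[0]), float(fit_range[1])
    if not lo < hi:
        raise ValueError("degenerate fit_range")
    in_range = [(f, c) for f, c in pairs if lo <= f <= hi]
    if len(in_range) < 3:
        raise ValueError("need >= 3 points inside fit_range")
    max_count = max(c for _, c in pairs)
    if max_count <= 0:
        raise ValueError("all counts are zero")
    factors = np.array([f for f, _ in pairs])
    norm = np.array([c for _, c in pairs]) / max_count
    mask = (factors >= lo) & (factors <= hi)
    x, y = factors[mask], norm[mask]
    slope = float(np.sum(x * y) / np.sum(x * x))
    resid = y - slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    predicted = slope * factors
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(predicted > 0, norm / predicted, np.nan)
    deviations = ratio - 1.0
    flags = np.where(np.isnan(ratio), False, ratio < 1.0 - tolerance)
    return LinearityResult(
        dilution_factors=tuple(factors.tolist()),
        normalized_counts=tuple(norm.tolist()),
        slope=slope, r_squared=r2,
        deviations=tuple(np.nan_to_num(deviations, nan=0.0).tolist()),
        swarm_flags=tuple(bool(b) for b in flags),
        fit_range=(lo, hi),
    )


# ---------------------------------------------------------------------------
# size-distribution summaries


@dataclass(frozen=True)
class SizeSummary:
    mean: float
    mode: float
    d10: float
    d50: float
    d90: float

    def __post_init__(self) -> None:
        if not self.d10 <= self.d50 <= self.d90:
            raise ValueError("D-values must be ordered d10 <= d50 <= d90")


def _d_value(sorted_sizes: np.ndarray, pct: float) -> float:
    # lowest size s.t. >= pct% of observations are <= it:
    # the ceil(pct*n/100)-th order statistic, no interpolation
    n = sorted_sizes.size
    k = max(1, math.ceil(pct * n / 100.0))
    return float(sorted_sizes[k - 1])


def size_summary(sizes: Sequence[float], mode_bin_nm: float = 1.0) -> SizeSummary:
    """Mean, histogram mode and D10/D50/D90 of a size sample (nm).

    D-values follow the minimum-size-including-p% convention: the value
    at the ``ceil(p*n/100)``-th order statistic.  The mode is the centre
    of the fullest histogram bin (``mode_bin_nm`` wide; ties resolve to
    the smaller bin).
    """
    arr = np.asarray(list(sizes), dtype=float)
    if arr.size == 0:
        raise ValueError("size_summary requires a non-empty sample")
    srt = np.sort(arr)
    lo, hi = float(srt[0]), float(srt[-1])
    if hi == lo:
        mode = lo
    else:
        n_bins = max(1, int(math.ceil((hi - lo) / mode_bin_nm)))
        counts, edges = np.histogram(arr, bins=n_bins, range=(lo, hi))
        j = int(np.argmax(counts))
        mode = float((edges[j] + edges[j + 1]) / 2.0)
    return SizeSummary(
        mean=float(arr.mean()), mode=mode,
        d10=_d_value(srt, 10), d50=_d_value(srt, 50), d90=_d_value(srt, 90),
    )
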