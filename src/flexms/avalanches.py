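"""Neuronal-avalanche detection and branching-ratio estimation.

The analysis chain implemented here turns a continuous region-of-interest
(ROI) time-series matrix into a sequence of neuronal avalanches:

1. each ROI signal is z-transformed over the full recording;
2. samples with ``|z| > z_threshold`` (default 3) are marked as events;
3. the event raster is binned in time (logical OR within each bin);
4. an avalanche is a maximal run of consecutive bins in which at least one
   ROI is active, delimited by all-quiet bins.

For each avalanche the branching ratio is the geometric mean of successive
bin-count ratios,

    sigma_i = prod_{j=1..N_bin-1} (n_events(j+1) / n_events(j))^(1/(N_bin-1)),

and the recording-level branching ratio is the geometric mean of the
per-avalanche values.  sigma = 1 is the hallmark of critical dynamics and is
used to select the time-bin length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "EventRaster",
    "BinnedRaster",
    "Avalanche",
    "AvalancheSet",
    "AnalysisConfig",
    "zscore_transform",
    "binarize",
    "bin_raster",
    "extract_avalanches",
    "branching_ratio_single",
    "branching_ratio_overall",
    "select_bin_length",
]

Pattern = frozenset  # recruited-ROI index set; frozenset is the canonical form


@dataclass
class RoiTimeSeries:
    """Continuous activity of ``n_rois`` regions sampled on a common clock."""

    values: np.ndarray  # (n_rois, n_samples)
    sampling_rate: float = 1024.0
    roi_labels: list[str] | None = None
    subject_id: str = ""
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_rois, n_samples) matrix")
        n_rois, n_samples = self.values.shape
        if n_rois < 1 or n_samples < 2:
            raise ValueError("need at least 1 ROI and 2 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain NaN or infinite entries")
        if self.roi_labels is None:
            self.roi_labels = [f"roi_{i}" for i in range(n_rois)]
        if len(self.roi_labels) != n_rois:
            raise ValueError("roi_labels length does not match n_rois")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class EventRaster:
    """Binary suprathreshold-event matrix at sample resolution."""

    active: np.ndarray  # (n_rois, n_samples) bool
    threshold: float

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.ndim != 2:
            raise ValueError("active must be 2-D")

    @property
    def n_rois(self) -> int:
        return self.active.shape[0]

    @property
    def n_samples(self) -> int:
        return self.active.shape[1]


@dataclass
class BinnedRaster:
    """Binary activity matrix after merging ``bin_length`` samples per bin."""

    active: np.ndarray  # (n_rois, n_bins) bool
    bin_length: int
    n_dropped_samples: int = 0

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.ndim != 2:
            raise ValueError("active must be 2-D")
        if self.bin_length < 1:
            raise ValueError("bin_length must be >= 1")

    @property
    def n_rois(self) -> int:
        return self.active.shape[0]

    @property
    def n_bins(self) -> int:
        return self.active.shape[1]


@dataclass
class Avalanche:
    """One contiguous burst of activity on the binned raster.

    ``events_per_bin[j]`` counts the ROIs active in the j-th bin of the
    avalanche (an ROI contributes at most one event per bin), and ``pattern``
    is the set of all ROIs recruited at any moment during the burst.
    """

    start_bin: int  # 0-based, inclusive
    end_bin: int  # 0-based, inclusive
    events_per_bin: np.ndarray
    pattern: Pattern

    def __post_init__(self) -> None:
        self.events_per_bin = np.asarray(self.events_per_bin, dtype=int)
        if self.end_bin - self.start_bin + 1 != len(self.events_per_bin):
            raise ValueError("bin extent inconsistent with events_per_bin")
        if (self.events_per_bin < 1).any():
            raise ValueError("every avalanche bin must contain >= 1 event")
        if not self.pattern:
            raise ValueError("pattern must be non-empty")

    @property
    def n_bins(self) -> int:
        return len(self.events_per_bin)

    @property
    def size(self) -> int:
        """Total number of events across all bins."""
        return int(self.events_per_bin.sum())


@dataclass
class AvalancheSet:
    """All avalanches of one recording plus estimator bookkeeping."""

    avalanches: list[Avalanche] = field(default_factory=list)
    n_rois: int = 0
    sigma: float | None = None
    n_excluded_single_bin: int = 0
    n_truncated_discarded: int = 0

    @property
    def n_avalanches(self) -> int:
        return len(self.avalanches)


@dataclass
class AnalysisConfig:
    """Tunable knobs of the avalanche pipeline with their default settings."""

    z_threshold: float = 3.0
    threshold_sweep: tuple[float, ...] = (2.5, 2.75, 3.0, 3.25, 3.5)
    bin_candidates: tuple[int, ...] = (1, 2, 3, 4, 5)
    bin_length_policy: str = "critical-select"  # or "fixed"
    fixed_bin_length: int = 3
    truncation_policy: str = "discard"  # or "keep"
    pooling_policy: str = "union"  # or "per-recording"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if any(b < 1 for b in self.bin_candidates):
            raise ValueError("bin candidates must be >= 1")
        if self.bin_length_policy not in ("fixed", "critical-select"):
            raise ValueError(f"unknown bin_length_policy {self.bin_length_policy!r}")
        if self.truncation_policy not in ("discard", "keep"):
            raise ValueError(f"unknown truncation_policy {self.truncation_policy!r}")
        if self.pooling_policy not in ("union", "per-recording"):
            raise ValueError(f"unknown pooling_policy {self.pooling_policy!r}")


def zscore_transform(series: RoiTimeSeries) -> RoiTimeSeries:
    """Z-transform each ROI over the full recording (population SD).

    Raises ``ValueError`` naming the first zero-variance ROI, since a flat
    channel signals a degenerate input rather than quiet dynamics.
    """
    values = series.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD (ddof=0)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        label = series.roi_labels[flat[0]]
        raise ValueError(f"ROI {label!r} (index {flat[0]}) has zero variance")
    return RoiTimeSeries(
        values=(values - mean) / sd,
        sampling_rate=series.sampling_rate,
        roi_labels=list(series.roi_labels),
        subject_id=series.subject_id,
        recording_id=series.recording_id,
    )


def binarize(z_series: RoiTimeSeries, z_threshold: float = 3.0) -> EventRaster:
    """Mark events where ``|z| > z_threshold`` (strict, two-tailed)."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    return EventRaster(active=np.abs(z_series.values) > z_threshold, threshold=z_threshold)


def bin_raster(raster: EventRaster | BinnedRaster, bin_length: int) -> BinnedRaster:
    """Merge ``bin_length`` consecutive samples per bin (logical OR).

    Bin ``b`` covers samples ``[b*L, (b+1)*L)``; a trailing partial bin is
    dropped and reported in ``n_dropped_samples``.
    """
    if bin_length < 1:
        raise ValueError("bin_length must be >= 1")
    active = raster.active
    n_samples = active.shape[1]
    if bin_length > n_samples:
        raise ValueError(f"bin_length {bin_length} exceeds n_samples {n_samples}")
    n_bins = n_samples // bin_length
    n_dropped = n_samples - n_bins * bin_length
    trimmed = active[:, : n_bins * bin_length]
    binned = trimmed.reshape(active.shape[0], n_bins, bin_length).any(axis=2)
    return BinnedRaster(active=binned, bin_length=bin_length, n_dropped_samples=n_dropped)


def extract_avalanches(binned: BinnedRaster, truncation_policy: str = "discard") -> AvalancheSet:
    """Segment the binned raster into avalanches.

    An avalanche is a maximal run of consecutive bins with at least one
    active ROI.  Under ``truncation_policy="discard"`` runs touching the
    first or last bin are removed (their true extent is unobservable) and
    counted in ``n_truncated_discarded``.
    """
    if truncation_policy not in ("discard", "keep"):
        raise ValueError(f"unknown truncation_policy {truncation_policy!r}")
    active = binned.active
    n_bins = active.shape[1]
    any_active = active.any(axis=0)
    result = AvalancheSet(n_rois=binned.n_rois)
    if not any_active.any():
        return result
    # run boundaries on the padded activity indicator
    padded = np.concatenate(([False], any_active, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1  # inclusive
    for start, end in zip(starts, ends):
        if truncation_policy == "discard" and (start == 0 or end == n_bins - 1):
            result.n_truncated_discarded += 1
            continue
        chunk = active[:, start : end + 1]
        result.avalanches.append(
            Avalanche(
                start_bin=int(start),
                end_bin=int(end),
                events_per_bin=chunk.sum(axis=0),
                pattern=frozenset(np.flatnonzero(chunk.any(axis=1)).tolist()),
            )
        )
    return result


def branching_ratio_single(avalanche: Avalanche) -> float | None:
    """Geometric mean of successive bin-count ratios within one avalanche.

    Returns ``None`` for single-bin avalanches, where the ratio product is
    empty and the branching ratio is undefined.
    """
    n = avalanche.events_per_bin
    if len(n) < 2:
        return None
    log_ratios = np.log(n[1:] / n[:-1])
    return float(math.exp(log_ratios.mean()))


def branching_ratio_overall(avalanche_set: AvalancheSet) -> float:
    """Geometric mean of the defined per-avalanche branching ratios.

    Single-bin avalanches are excluded (their sigma_i is undefined) and
    counted in ``n_excluded_single_bin``.  Computed in log space.  Raises if
    no avalanche has a defined sigma_i.
    """
    logs = []
    n_excluded = 0
    for av in avalanche_set.avalanches:
        sigma_i = branching_ratio_single(av)
        if sigma_i is None:
            n_excluded += 1
        else:
            logs.append(math.log(sigma_i))
    avalanche_set.n_excluded_single_bin = n_excluded
    if not logs:
        raise ValueError("sigma undefined: no avalanche spans more than one bin")
    sigma = float(math.exp(np.mean(logs)))
    avalanche_set.sigma = sigma
    return sigma


def select_bin_length(
    raster: EventRaster,
    bin_candidates: Sequence[int] = (1, 2, 3, 4, 5),
    truncation_policy: str = "discard",
) -> tuple[int, dict[int, float]]:
    """Pick the bin length whose branching ratio is closest to 1.

    Critical dynamics are marked by sigma = 1, so the candidate minimising
    ``|sigma - 1|`` is selected; ties break toward the smaller bin length to
    preserve temporal resolution.  Returns the chosen length and the full
    ``{bin_length: sigma}`` table (NaN where sigma was undefined).
    """
    if not bin_candidates:
        raise ValueError("need at least one bin-length candidate")
    table: dict[int, float] = {}
    best: int | None = None
    best_dist = math.inf
    for length in sorted(int(b) for b in bin_candidates):
        try:
            binned = bin_raster(raster, length)
            sigma = branching_ratio_overall(extract_avalanches(binned, truncation_policy))
        except ValueError:
            table[length] = math.nan
            continue
        table[length] = sigma
        dist = abs(sigma - 1.0)
        if dist < best_dist:
            best, best_dist = length, dist
    if best is None:
        raise ValueError("sigma undefined at every candidate bin length")
    return best, table
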