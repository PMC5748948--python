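"""Core GFP quantification: threshold sweep, automatic threshold selection,
area/intensity measurement, and the proliferation index.

The measurement problem: xenografted GFP-labeled tumor cells sit in the embryo
yolk, which is itself dimly autofluorescent.  A naive pixel count at threshold
0 mixes the two.  The sweep records the GFP pixel count nGFP(t) at every
integer threshold t in [0, t_max]; as t rises past the autofluorescence
intensities the count collapses, then flattens once only the bright cell mass
remains.  The selection rule finds the start of that flat tail: the smallest
threshold from which every remaining unit step loses less than ``tolerance``
of the threshold-0 area.

Two images of the same embryo (0 hpi and 72 hpi) may select different
thresholds; the higher one is applied to both so that the areas are
comparable, and the proliferation index is

    PI = (nGFP_72 * GMV_72) / (nGFP_0 * GMV_0)

where GMV is the mean intensity of the counted pixels.  PI > 1 reads as
proliferation, PI < 1 as cell death, PI = 1 as a stable graft.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import EmptySignalError, PairingError, UndefinedBaselineError
from .image import EmbryoImageRecord, IntensityImage

__all__ = [
    "ThresholdSweep",
    "ThresholdSelection",
    "GFPMeasurement",
    "ProliferationResult",
    "compute_sweep",
    "select_threshold",
    "measure_gfp",
    "proliferation_index",
    "DEFAULT_T_MAX",
    "DEFAULT_TOLERANCE",
    "DEFAULT_STABILITY_EPS",
]

DEFAULT_T_MAX = 50
DEFAULT_TOLERANCE = 0.10
#: Half-width of the "stable" band around PI = 1.  Effectively strict.
DEFAULT_STABILITY_EPS = 1e-9


@dataclass(frozen=True)
class ThresholdSweep:
    """nGFP as a function of integer threshold t in [0, t_max].

    ``area[t]`` is the number of pixels with intensity strictly greater
    than t, so it is non-increasing in t.
    """

    area: np.ndarray  # shape (t_max + 1,), ints

    def __post_init__(self) -> None:
        arr = np.asarray(self.area, dtype=np.int64)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("sweep needs area values for at least t = 0 and t = 1")
        if (arr < 0).any():
            raise ValueError("pixel counts cannot be negative")
        if (np.diff(arr) > 0).any():
            raise ValueError("area must be non-increasing in the threshold")
        object.__setattr__(self, "area", arr)

    @property
    def t_max(self) -> int:
        return self.area.size - 1

    def step_decay(self) -> np.ndarray:
        """d(t) = (area(t-1) - area(t)) / area(0) for t = 1..t_max."""
        a0 = self.area[0]
        if a0 == 0:
            raise EmptySignalError("area(0) = 0: nothing fluorescent to threshold")
        return -np.diff(self.area) / a0


@dataclass(frozen=True)
class ThresholdSelection:
    threshold: int
    tolerance: float = DEFAULT_TOLERANCE
    #: True when the sweep never decayed beyond tolerance anywhere — no
    #: detectable autofluorescence shoulder; the no-autofluorescence
    #: correction (threshold fixed at 1) was applied.
    flat_curve: bool = False
    #: True when the stability criterion was never met inside the sweep and
    #: the threshold was pinned at t_max.
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("selected threshold must be >= 1")
        if self.flat_curve and self.saturated:
            raise ValueError("flat_curve and saturated are mutually exclusive")


@dataclass(frozen=True)
class GFPMeasurement:
    """(threshold, nGFP, GMV) for one image.

    nGFP counts pixels strictly above the threshold; GMV is their mean
    intensity (0 when nGFP = 0).
    """

    threshold: int
    nGFP: int
    GMV: float


@dataclass(frozen=True)
class ProliferationResult:
    embryo_id: str
    shared_threshold: int
    m0: GFPMeasurement
    m72: GFPMeasurement
    PI: float
    classification: Literal["death", "stable", "proliferation"]
    flags: dict = field(default_factory=dict)


def compute_sweep(image: IntensityImage, t_max: int = DEFAULT_T_MAX) -> ThresholdSweep:
    """Count GFP pixels at every integer threshold from 0 (no threshold) to t_max.

    area(t) = #{pixels with intensity > t}.  Computed from a single cumulative
    histogram rather than t_max + 1 full-image scans.
    """
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1, got {t_max}")
    px = image.pixels
    # pixel contributes to area(t) for all integer t < intensity, i.e. for
    # t <= ceil(intensity) - 1; bucket by floor for exact-integer safety.
    counts = np.zeros(t_max + 2, dtype=np.int64)
    idx = np.minimum(np.ceil(px).astype(np.int64), t_max + 1)
    np.add.at(counts, idx.ravel(), 1)
    # area(t) = number of pixels with ceil(intensity) > t = sum of buckets > t
    tail = np.cumsum(counts[::-1])[::-1]
    area = tail[1:]  # area(t) for t = 0..t_max
    # ceil(x) > t  <=>  x > t  for integer t, except x exactly integer: ceil(x)=x > t ok.
    return ThresholdSweep(area=area)


def select_threshold(
    sweep: ThresholdSweep, tolerance: float = DEFAULT_TOLERANCE
) -> ThresholdSelection:
    """Pick the smallest threshold from which the sweep is stable.

    Stability from t means every unit step decay d(t') = (area(t'-1) -
    area(t')) / area(0) for t' in [t, t_max] stays below ``tolerance``.  A
    curve that is stable from the very start (threshold 1) carries the
    ``flat_curve`` flag — the no-autofluorescence case, where threshold 1
    still strips true-black background but keeps all signal.  If no stable
    suffix exists the threshold is pinned at t_max with ``saturated`` set and
    a warning, rather than silently returning an unstable measurement.
    """
    if not 0 < tolerance < 1:
        raise ValueError(f"tolerance must be in (0, 1), got {tolerance}")
    decays = sweep.step_decay()  # raises EmptySignalError when area(0) == 0
    unstable = np.flatnonzero(decays >= tolerance)  # indices are t - 1
    if unstable.size == 0:
        return ThresholdSelection(threshold=1, tolerance=tolerance, flat_curve=True)
    last_unstable_t = int(unstable[-1]) + 1
    if last_unstable_t == sweep.t_max:
        warnings.warn(
            f"sweep never stabilized within t_max = {sweep.t_max}; "
            "threshold pinned at t_max",
            stacklevel=2,
        )
        return ThresholdSelection(
            threshold=sweep.t_max, tolerance=tolerance, saturated=True
        )
    return ThresholdSelection(threshold=last_unstable_t + 1, tolerance=tolerance)


def measure_gfp(image: IntensityImage, threshold: float) -> GFPMeasurement:
    """nGFP and GMV of the pixels strictly above ``threshold``."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    mask = image.pixels > threshold
    n = int(mask.sum())
    gmv = float(image.pixels[mask].mean()) if n else 0.0
    return GFPMeasurement(threshold=int(threshold), nGFP=n, GMV=gmv)


def _order_pair(
    rec_a: EmbryoImageRecord, rec_b: EmbryoImageRecord
) -> tuple[EmbryoImageRecord, EmbryoImageRecord]:
    if rec_a.embryo_id != rec_b.embryo_id:
        raise PairingError(
            f"records belong to different embryos: {rec_a.embryo_id!r} vs {rec_b.embryo_id!r}"
        )
    if {rec_a.timepoint, rec_b.timepoint} != {"0hpi", "72hpi"}:
        raise PairingError(
            f"need one 0hpi and one 72hpi record for embryo {rec_a.embryo_id!r}, "
            f"got {rec_a.timepoint!r} and {rec_b.timepoint!r}"
        )
    return (rec_a, rec_b) if rec_a.timepoint == "0hpi" else (rec_b, rec_a)


def proliferation_index(
    rec0: EmbryoImageRecord,
    rec72: EmbryoImageRecord,
    tolerance: float = DEFAULT_TOLERANCE,
    t_max: int = DEFAULT_T_MAX,
    stability_eps: float = DEFAULT_STABILITY_EPS,
) -> ProliferationResult:
    """Full per-embryo pipeline: sweep, per-timepoint selection, shared
    threshold (the max of the two), measurement and PI.

    A blank 0 hpi image (or one whose signal all sits below the shared
    threshold) has a zero denominator and raises ``UndefinedBaselineError`` —
    such an embryo would have been discarded as incorrectly injected.  A blank
    72 hpi image is a legitimate total-death outcome: its selection step is
    skipped and the 0 hpi threshold is used.
    """
    rec0, rec72 = _order_pair(rec0, rec72)

    sweep0 = compute_sweep(rec0.image, t_max=t_max)
    if sweep0.area[0] == 0:
        raise UndefinedBaselineError(
            f"embryo {rec0.embryo_id!r}: 0 hpi image has no signal above zero"
        )
    sel0 = select_threshold(sweep0, tolerance=tolerance)

    sweep72 = compute_sweep(rec72.image, t_max=t_max)
    flags: dict = {
        "flat_curve_0": sel0.flat_curve,
        "saturated_0": sel0.saturated,
        "threshold_0": sel0.threshold,
    }
    if sweep72.area[0] > 0:
        sel72 = select_threshold(sweep72, tolerance=tolerance)
        shared = max(sel0.threshold, sel72.threshold)
        flags.update(
            flat_curve_72=sel72.flat_curve,
            saturated_72=sel72.saturated,
            threshold_72=sel72.threshold,
        )
    else:  # total signal loss at 72 hpi: nothing to select on
        shared = sel0.threshold
        flags.update(flat_curve_72=False, saturated_72=False, threshold_72=None)

    m0 = measure_gfp(rec0.image, shared)
    m72 = measure_gfp(rec72.image, shared)
    if m0.nGFP == 0 or m0.GMV == 0:
        raise UndefinedBaselineError(
            f"embryo {rec0.embryo_id!r}: no 0 hpi signal above the shared "
            f"threshold {shared}; PI denominator is zero"
        )
    pi = (m72.nGFP * m72.GMV) / (m0.nGFP * m0.GMV)
    if pi < 1 - stability_eps:
        cls = "death"
    elif pi > 1 + stability_eps:
        cls = "proliferation"
    else:
        cls = "stable"
    return ProliferationResult(
        embryo_id=rec0.embryo_id,
        shared_threshold=shared,
        m0=m0,
        m72=m72,
        PI=pi,
        classification=cls,
        flags=flags,
    )
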