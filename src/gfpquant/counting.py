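"""Cell counting in injection-droplet micrographs via the circular Hough
transform.

A drop of the cell suspension is photographed before injection; the cells are
roughly circular with a known approximate radius.  Edges are extracted with a
gradient-magnitude cutoff *relative* to the strongest gradient in the image
(so the count is invariant to uniform exposure changes), a Hough accumulator
is built over integer radii in [r_min, r_max], and peaks are greedily picked
with Euclidean non-maximum suppression.  Touching cells may merge into a
single detection; the output is an estimate, which is all a dose check needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import sobel
from skimage.transform import hough_circle

from .image import IntensityImage

__all__ = ["CircleDetection", "CellCountResult", "count_cells"]

#: Minimum normalized accumulator score (fraction of the circle perimeter
#: supported by edges) for a peak to count as a detection.
DEFAULT_ACCUMULATOR_CUTOFF = 0.6


@dataclass(frozen=True)
class CircleDetection:
    center_row: float
    center_col: float
    radius: float
    score: float


@dataclass(frozen=True)
class CellCountResult:
    detections: list[CircleDetection]
    params: dict

    @property
    def count(self) -> int:
        return len(self.detections)


def _greedy_nms(
    rows: np.ndarray, cols: np.ndarray, scores: np.ndarray, min_separation: float
) -> np.ndarray:
    """Indices of peaks surviving greedy suppression by Euclidean distance."""
    order = np.argsort(scores)[::-1]
    kept: list[int] = []
    kept_rc: list[tuple[float, float]] = []
    min_sq = min_separation * min_separation
    for i in order:
        r, c = rows[i], cols[i]
        ok = True
        for kr, kc in kept_rc:
            if (r - kr) ** 2 + (c - kc) ** 2 < min_sq:
                ok = False
                break
        if ok:
            kept.append(i)
            kept_rc.append((r, c))
    return np.asarray(kept, dtype=np.intp)


def count_cells(
    image: IntensityImage,
    r_min: int,
    r_max: int,
    edge_strength: float = 0.5,
    min_separation: float | None = None,
    accumulator_cutoff: float = DEFAULT_ACCUMULATOR_CUTOFF,
) -> CellCountResult:
    """Estimate the number of cells in a droplet micrograph.

    Parameters
    ----------
    r_min, r_max : int
        Radius bounds in pixels for the circles to detect (integer sweep).
    edge_strength : float in (0, 1]
        Relative gradient-magnitude cutoff: a pixel is an edge when its Sobel
        magnitude exceeds ``edge_strength`` times the image maximum.
    min_separation : float, optional
        Non-maximum-suppression distance between detection centers; defaults
        to ``r_min``.
    accumulator_cutoff : float
        Minimum normalized Hough score for a candidate circle.
    """
    if r_min < 1 or r_min > r_max:
        raise ValueError(f"need 1 <= r_min <= r_max, got r_min={r_min}, r_max={r_max}")
    if not 0 < edge_strength <= 1:
        raise ValueError(f"edge_strength must be in (0, 1], got {edge_strength}")
    if min_separation is None:
        min_separation = float(r_min)
    params = {
        "r_min": r_min,
        "r_max": r_max,
        "edge_strength": edge_strength,
        "min_separation": min_separation,
        "accumulator_cutoff": accumulator_cutoff,
    }

    grad = sobel(image.pixels)
    gmax = grad.max()
    if gmax <= 0:  # constant image: no edges, no cells
        return CellCountResult(detections=[], params=params)
    edges = grad > edge_strength * gmax

    radii = np.arange(int(r_min), int(r_max) + 1)
    accum = hough_circle(edges, radii, normalize=True, full_output=False)
    # best radius per center position, then one global peak list
    best_r_idx = np.argmax(accum, axis=0)
    best_score = np.take_along_axis(accum, best_r_idx[None], axis=0)[0]

    cand = np.argwhere(best_score >= accumulator_cutoff)
    if cand.size == 0:
        return CellCountResult(detections=[], params=params)
    rows = cand[:, 0].astype(float)
    cols = cand[:, 1].astype(float)
    scores = best_score[cand[:, 0], cand[:, 1]]
    keep = _greedy_nms(rows, cols, scores, min_separation)
    detections = [
        CircleDetection(
            center_row=rows[i],
            center_col=cols[i],
            radius=float(radii[best_r_idx[int(rows[i]), int(cols[i])]]),
            score=float(scores[i]),
        )
        for i in keep
    ]
    return CellCountResult(detections=detections, params=params)
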