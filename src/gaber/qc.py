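"""Quality control: eyes where the EDM measurement is unreliable.

The distance-map reading of border advance breaks down in two
situations, both of which are detected algorithmically here and lead
to whole-eye exclusion from pooled analyses:

* **Margin merging** — separate lesions grow into one another, or two
  margin segments of the same lesion close onto each other.  After a
  merge the shortest distance to the baseline border no longer tracks
  the path the border actually traveled.  Detected as (a) a decrease
  in the 8-connected component count from baseline to follow-up, or
  (b) an increase in the number of enclosed background holes (the
  topological signature of a margin folding onto itself).
* **Nonlinear growth** — the straight segment from a follow-up border
  pixel to its nearest baseline lesion pixel passes through retina
  that is non-atrophic at both visits, so the EDM distance cuts a
  corner the lesion did not take.  Detected by tracing each segment
  and flagging the eye when more than a configurable fraction
  (default 1%) of segments leave the union of the two lesion masks.

These rules formalize criteria that were designed for manual review;
they are deterministic proxies, not a claim of grader equivalence.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.draw import line

from .ber import DistanceMap, euclidean_distance_map
from .geometry import COMPONENT_STRUCTURE, border_mask
from .registration import EyePair

#: Default fraction of offending shortest-path segments above which an
#: eye is flagged for nonlinear growth.
NONLINEAR_FRACTION_THRESHOLD = 0.01

HOLE_STRUCTURE = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclasses.dataclass(frozen=True)
class QCReport:
    """Per-eye quality-control outcome."""

    merging_flag: bool
    merging_reason: str | None  # "component_count_decrease" | "self_merge"
    nonlinear_flag: bool
    n_nonlinear_px: int
    n_segments: int

    @property
    def excluded(self) -> bool:
        return self.merging_flag or self.nonlinear_flag


def count_holes(mask: np.ndarray) -> int:
    """Number of background components fully enclosed by the lesion.

    Background is labeled with 4-connectivity (the complement of the
    8-connectivity used for the lesion, avoiding topological
    paradoxes); components touching the frame are open to the outside
    and do not count as holes.
    """
    labels, n = ndimage.label(~np.asarray(mask, dtype=bool), structure=HOLE_STRUCTURE)
    edge_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    open_to_frame = set(edge_labels.tolist()) - {0}
    return int(n - len(open_to_frame))


def detect_margin_merging(pair: EyePair) -> tuple[bool, str | None]:
    """Flag eyes whose lesion margins merged over follow-up."""
    _, n_base = ndimage.label(pair.baseline.mask, structure=COMPONENT_STRUCTURE)
    _, n_follow = ndimage.label(pair.followup.mask, structure=COMPONENT_STRUCTURE)
    if n_follow < n_base:
        return True, "component_count_decrease"
    if count_holes(pair.followup.mask) > count_holes(pair.baseline.mask):
        return True, "self_merge"
    return False, None


def detect_nonlinear_growth(
    pair: EyePair,
    dmap: DistanceMap | None = None,
    fraction_threshold: float = NONLINEAR_FRACTION_THRESHOLD,
) -> tuple[bool, int, int]:
    """Flag eyes whose shortest growth paths cross non-atrophic retina.

    For every follow-up border pixel the straight segment to its
    nearest baseline lesion pixel (the first minimizer in row-major
    scan order; the feasibility of the segment, not the choice of
    minimizer, drives the flag) is rasterized and checked against the
    union of the two lesion masks.  Returns ``(flag, n_offending,
    n_segments)``.
    """
    del dmap  # the EDT is recomputed with nearest-pixel indices
    base = pair.baseline.mask
    if not base.any():
        raise ValueError("baseline mask is empty")
    _, indices = ndimage.distance_transform_edt(~base, return_indices=True)
    union = base | pair.followup.mask
    border_points = np.argwhere(border_mask(pair.followup.mask))
    n_offending = 0
    for r, c in border_points:
        nr, nc = indices[0, r, c], indices[1, r, c]
        rr, cc = line(int(r), int(c), int(nr), int(nc))
        if not union[rr, cc].all():
            n_offending += 1
    n_segments = len(border_points)
    flag = n_segments > 0 and n_offending / n_segments > fraction_threshold
    return flag, n_offending, n_segments


def run_qc(
    pair: EyePair,
    fraction_threshold: float = NONLINEAR_FRACTION_THRESHOLD,
) -> QCReport:
    """Run both exclusion rules on one registered eye pair."""
    merging, reason = detect_margin_merging(pair)
    nonlinear, n_off, n_seg = detect_nonlinear_growth(
        pair, fraction_threshold=fraction_threshold
    )
    return QCReport(
        merging_flag=merging,
        merging_reason=reason,
        nonlinear_flag=nonlinear,
        n_nonlinear_px=n_off,
        n_segments=n_seg,
    )
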