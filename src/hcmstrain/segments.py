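"""AHA 16-segment model of the left ventricle.

Basal and mid short-axis slices are divided into six 60-degree sectors,
the apical slice into four 90-degree sectors; the true apex (segment 17)
is excluded.  Segment ids follow the standardized numbering (1-16).

Angular convention: angles are measured counter-clockwise, in radians,
from the anterior RV-insertion point (the anchor exported by the phantom
and supplied with real contour sets).  Sector 1 of each slice starts at
the anchor and sweeps through anterior -> anteroseptal -> inferoseptal ->
inferior -> inferolateral -> anterolateral territory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SLICES = ("basal", "mid", "apical")

#: segment ids per short-axis slice, in angular order starting at the
#: anterior RV-insertion anchor
SEGMENT_IDS = {
    "basal": (1, 2, 3, 4, 5, 6),
    "mid": (7, 8, 9, 10, 11, 12),
    "apical": (13, 14, 15, 16),
}

SEGMENT_NAMES = {
    1: "basal anterior",
    2: "basal anteroseptal",
    3: "basal inferoseptal",
    4: "basal inferior",
    5: "basal inferolateral",
    6: "basal anterolateral",
    7: "mid anterior",
    8: "mid anteroseptal",
    9: "mid inferoseptal",
    10: "mid inferior",
    11: "mid inferolateral",
    12: "mid anterolateral",
    13: "apical anterior",
    14: "apical septal",
    15: "apical inferior",
    16: "apical lateral",
}

#: septal / lateral membership used by the septal-to-lateral (SL) wall
#: thickness ratio; maxima are taken across all analyzed slices
SEPTAL_SEGMENTS = (2, 3, 8, 9, 14)
LATERAL_SEGMENTS = (5, 6, 11, 12, 16)

BASAL_SEGMENTS = SEGMENT_IDS["basal"]


@dataclass(frozen=True)
class SegmentModel:
    """Angular layout of one short-axis slice of the 16-segment model.

    Parameters
    ----------
    slice_label : {"basal", "mid", "apical"}
    anchor_angle : float
        Angle (rad, CCW from the +x image axis) of the anterior
        RV-insertion point that anchors sector 1.
    """

    slice_label: str
    anchor_angle: float = np.pi / 2

    def __post_init__(self) -> None:
        if self.slice_label not in SLICES:
            raise ValueError(f"unknown slice label {self.slice_label!r}")

    @property
    def segment_ids(self) -> tuple[int, ...]:
        return SEGMENT_IDS[self.slice_label]

    @property
    def n_segments(self) -> int:
        return len(self.segment_ids)

    @property
    def sector_width(self) -> float:
        return 2.0 * np.pi / self.n_segments

    def segment_of_angle(self, theta):
        """Map angles (rad) to segment ids of this slice (vectorized)."""
        theta = np.asarray(theta, dtype=float)
        rel = np.mod(theta - self.anchor_angle, 2.0 * np.pi)
        idx = np.minimum((rel / self.sector_width).astype(int), self.n_segments - 1)
        ids = np.asarray(self.segment_ids)[idx]
        return ids if ids.ndim else int(ids)

    def segment_center_angle(self, segment_id: int) -> float:
        """Angle (rad) of the middle of a segment's sector."""
        pos = self.segment_ids.index(segment_id)
        return self.anchor_angle + (pos + 0.5) * self.sector_width

    def sector_bounds(self, segment_id: int) -> tuple[float, float]:
        pos = self.segment_ids.index(segment_id)
        lo = self.anchor_angle + pos * self.sector_width
        return lo, lo + self.sector_width


def slice_of_segment(segment_id: int) -> str:
    for label, ids in SEGMENT_IDS.items():
        if segment_id in ids:
            return label
    raise ValueError(f"segment id {segment_id} outside 1-16")
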