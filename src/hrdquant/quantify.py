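"""Per-volume HRD quantification over fovea-centred regions of interest.

Classified components are aggregated into area (mm²) and count for each
class (total HRD, hard exudate, small HRD) over three regions: the full
6x6 mm scan and the 3 mm and 1 mm diameter circles centred on the fovea.
Area is measured in the b-scan plane (pixels x axial x lateral spacing)
and summed across b-scans; a component belongs entirely to every region
containing its en-face centroid.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hrd_classify import ConnectedComponent, HRDClass

REGIONS = ("full_6x6", "circle_3mm", "circle_1mm")
CIRCLE_DIAMETERS_MM = {"circle_3mm": 3.0, "circle_1mm": 1.0}
CLASSES = ("total_hrd", "hard_exudate", "small_hrd")


@dataclasses.dataclass
class ROISpec:
    """Fovea centre (en-face, mm) and the regions to report."""

    fovea_center_mm: tuple[float, float] | None = None  # None -> scan centre
    regions: tuple[str, ...] = REGIONS

    def center(self, shape: Sequence[int], spacing_um: Sequence[float]) -> tuple[float, float]:
        if self.fovea_center_mm is not None:
            return self.fovea_center_mm
        sb, _, sx = spacing_um
        return (shape[0] * sb / 2000.0, shape[2] * sx / 2000.0)


@dataclasses.dataclass
class HRDSummary:
    """Area (mm²) and count per class per region for one volume."""

    area_mm2: dict[str, dict[str, float]]
    count: dict[str, dict[str, int]]

    @staticmethod
    def zero() -> "HRDSummary":
        return HRDSummary(
            area_mm2={r: {c: 0.0 for c in CLASSES} for r in REGIONS},
            count={r: {c: 0 for c in CLASSES} for r in REGIONS},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"roi": r, "class": c,
                 "area_mm2": self.area_mm2[r][c], "count": self.count[r][c]}
                for r in REGIONS for c in CLASSES]
        return pd.DataFrame(rows, columns=["roi", "class", "area_mm2", "count"])

    def series(self) -> dict[str, float]:
        """Flat {roi/class/metric: value} map (the agreement module's input)."""
        out = {}
        for r in REGIONS:
            for c in CLASSES:
                out[f"{r}/{c}/area_mm2"] = self.area_mm2[r][c]
                out[f"{r}/{c}/count"] = float(self.count[r][c])
        return out

    def __add__(self, other: "HRDSummary") -> "HRDSummary":
        return HRDSummary(
            area_mm2={r: {c: self.area_mm2[r][c] + other.area_mm2[r][c] for c in CLASSES}
                      for r in REGIONS},
            count={r: {c: self.count[r][c] + other.count[r][c] for c in CLASSES}
                   for r in REGIONS},
        )


def enface_centroid(component: ConnectedComponent, spacing_um: Sequence[float]) -> tuple[float, float]:
    """En-face physical centroid (slow-axis mm, lateral mm) of a component.

    Pixel centres sit at (index + 0.5) x spacing; the slow-axis position is
    the b-scan's own centre.
    """
    sb, _, sx = spacing_um
    slow = (component.bscan + 0.5) * sb / 1000.0
    lateral = float(np.mean(component.pixels[:, 1] + 0.5)) * sx / 1000.0
    return (slow, lateral)


def roi_membership(centroid_mm: tuple[float, float], roi: ROISpec,
                   shape: Sequence[int], spacing_um: Sequence[float]) -> set[str]:
    """Regions containing a centroid: the full scan always; each circle iff
    the en-face distance to the fovea centre is below its radius."""
    cy, cx = roi.center(shape, spacing_um)
    dist = math.hypot(centroid_mm[0] - cy, centroid_mm[1] - cx)
    out = {"full_6x6"} & set(roi.regions)
    for name, diam in CIRCLE_DIAMETERS_MM.items():
        if name in roi.regions and dist < diam / 2.0:
            out.add(name)
    return out


def summarize(components: Iterable[ConnectedComponent], spacing_um: Sequence[float],
              shape: Sequence[int], roi: ROISpec | None = None) -> HRDSummary:
    """Aggregate classified, noise-free components into an :class:`HRDSummary`.

    count = components whose centroid lies in the region; area = sum of
    n_pixels x axial x lateral spacing, in mm². The total-HRD row is the
    exact sum of the hard-exudate and small-HRD rows.
    """
    roi = roi or ROISpec()
    _, sz, sx = spacing_um
    pixel_area_mm2 = sz * sx * 1e-6
    summary = HRDSummary.zero()
    for comp in components:
        if comp.hrd_class is None:
            raise ValueError(f"component {comp.id} on b-scan {comp.bscan} is unclassified")
        if comp.hrd_class is HRDClass.NOISE:
            continue
        cls = comp.hrd_class.value
        area = comp.n_pixels * pixel_area_mm2
        for region in roi_membership(enface_centroid(comp, spacing_um), roi, shape, spacing_um):
            for key in (cls, "total_hrd"):
                summary.area_mm2[region][key] += area
                summary.count[region][key] += 1
    return summary
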