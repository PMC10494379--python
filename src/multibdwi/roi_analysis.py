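"""ROI measurement protocol: per-lesion mean parameters, per reader.

The measurement unit of every downstream statistic is one lesion measured
by one reader: the mean of each parameter map over the ROI voxels on the
three consecutive axial slices holding the most lesion, repeated three
times and averaged. Repeats are identical for a fixed mask and differ only
when each repeat uses its own (jittered) mask, as when emulating a second
reader's tracings.

Axial slices are indexed along the third voxel axis; volumes read from
disk are reoriented to canonical axes first (see :mod:`multibdwi.io`), so
the tie-break "toward the inferior-most triple" means toward lower slice
index. Masks are strictly binary (any nonzero voxel is in-ROI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model_fitting import MAP_NAMES, ParameterMaps

__all__ = [
    "RoiMeasurement",
    "ROI_AREA_RANGE",
    "select_maximal_slices",
    "measure_lesion",
    "build_lesion_table",
    "LESION_TABLE_COLUMNS",
]

#: Expected per-slice ROI area range, mm^2 (typical lesion tracing).
ROI_AREA_RANGE = (45.0, 65.0)

LESION_TABLE_COLUMNS = ["subject", "group", "reader"] + list(MAP_NAMES)


@dataclass(frozen=True)
class RoiMeasurement:
    subject: str
    reader: str
    parameter: str
    value: float
    area_mm2: float
    slices: tuple[int, ...]
    group: str = ""

    def __post_init__(self) -> None:
        if not self.area_mm2 > 0:
            raise ValueError("ROI area must be positive")


def select_maximal_slices(mask: np.ndarray) -> tuple[int, ...]:
    """Consecutive axial slice triple maximizing in-mask voxel count.

    Ties go to the inferior-most (lowest-index) triple. A mask spanning
    fewer than three slices returns all slices it touches, with a warning.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    counts = mask.sum(axis=(0, 1))
    occupied = np.nonzero(counts)[0]
    if occupied[-1] - occupied[0] + 1 < 3 or mask.shape[2] < 3:
        warnings.warn(
            "mask spans fewer than three axial slices; using all of them",
            stacklevel=2,
        )
        return tuple(int(i) for i in occupied)
    window = counts[:-2] + counts[1:-1] + counts[2:]
    start = int(np.argmax(window))  # argmax takes the first (inferior) tie
    return (start, start + 1, start + 2)


def measure_lesion(
    maps: ParameterMaps,
    mask: np.ndarray | Sequence[np.ndarray],
    reader: str,
    subject: str,
    group: str = "",
    repeats: int = 3,
) -> list[RoiMeasurement]:
    """Per-parameter ROI means, averaged over ``repeats`` measurements.

    ``mask`` may be a single binary mask (repeats are then identical) or a
    sequence of per-repeat masks of length ``repeats``. NaN map voxels
    (masked out or failed fits) are excluded from the means; a repeat with
    no finite voxels for a parameter fails QC and raises.
    """
    if isinstance(mask, np.ndarray):
        masks = [mask] * repeats
    else:
        masks = list(mask)
        if len(masks) != repeats:
            raise ValueError(f"expected {repeats} masks, got {len(masks)}")
    for m in masks:
        if np.asarray(m).shape != maps.shape:
            raise ValueError("mask and maps are not co-registered (shape mismatch)")

    per_repeat_values: dict[str, list[float]] = {name: [] for name in MAP_NAMES}
    areas, slice_sets = [], []
    for m in masks:
        m = np.asarray(m).astype(bool)
        slices = select_maximal_slices(m)
        slice_sets.append(slices)
        sel = np.zeros_like(m)
        sel[:, :, list(slices)] = m[:, :, list(slices)]
        n_vox = sel.sum()
        area = n_vox / len(slices) * maps.in_plane_voxel_area
        areas.append(area)
        if not (ROI_AREA_RANGE[0] <= area <= ROI_AREA_RANGE[1]):
            warnings.warn(
                f"{subject}/{reader}: mean per-slice ROI area {area:.1f} mm^2 "
                f"outside {ROI_AREA_RANGE}",
                stacklevel=2,
            )
        for name in MAP_NAMES:
            vals = maps.maps[name][sel]
            finite = vals[np.isfinite(vals)]
            if finite.size == 0:
                raise ValueError(
                    f"QC failure: no finite {name} voxels in ROI of {subject}"
                )
            per_repeat_values[name].append(float(finite.mean()))

    slices = slice_sets[0]
    area = float(np.mean(areas))
    return [
        RoiMeasurement(
            subject=subject,
            reader=reader,
            parameter=name,
            value=float(np.mean(per_repeat_values[name])),
            area_mm2=area,
            slices=slices,
            group=group,
        )
        for name in MAP_NAMES
    ]


def build_lesion_table(measurements: Sequence[RoiMeasurement]) -> pd.DataFrame:
    """Wide per-(subject, reader) table of the six parameter means.

    Deterministically ordered by subject then reader; conflicting duplicate
    (subject, reader, parameter) entries are an error. An empty input gives
    an empty (but correctly shaped) table.
    """
    if not measurements:
        return pd.DataFrame(columns=LESION_TABLE_COLUMNS)
    rows: dict[tuple[str, str], dict] = {}
    for m in measurements:
        key = (m.subject, m.reader)
        row = rows.setdefault(key, {"subject": m.subject, "reader": m.reader, "group": m.group})
        if m.parameter in row and not np.isclose(row[m.parameter], m.value):
            raise ValueError(
                f"conflicting duplicate measurement for {key} / {m.parameter}"
            )
        row[m.parameter] = m.value
        if m.group:
            row["group"] = m.group
    table = pd.DataFrame(list(rows.values()))
    table = table.sort_values(["subject", "reader"], kind="stable").reset_index(drop=True)
    return table[LESION_TABLE_COLUMNS]
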