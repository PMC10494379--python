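"""Reading and writing of NIfTI volumes, b-value tables and map sets."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .model_fitting import MAP_NAMES, ParameterMaps
from .signal_models import BValueScheme

__all__ = [
    "read_bvals",
    "write_bvals",
    "load_volume",
    "save_volume",
    "save_maps",
    "load_maps",
]


def read_bvals(path: str | Path) -> BValueScheme:
    """Read a b-value table.

    Accepts either one value per line or a single whitespace-separated line
    (FSL-style .bval layout); units s/mm^2.
    """
    text = Path(path).read_text().split()
    if not text:
        raise ValueError(f"empty b-value table: {path}")
    return BValueScheme(values=tuple(float(t) for t in text))


def write_bvals(scheme: BValueScheme, path: str | Path) -> None:
    Path(path).write_text("\n".join(f"{v:g}" for v in scheme.values) + "\n")


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI image reoriented to canonical (RAS) axes.

    Returns (data, affine); with canonical orientation the third voxel axis
    is the axial (inferior-to-superior) direction, which the ROI slice
    logic relies on.
    """
    img = nib.as_closest_canonical(nib.load(str(path)))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_volume(
    data: np.ndarray, affine: np.ndarray, path: str | Path
) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def save_maps(maps: ParameterMaps, out_dir: str | Path, stem: str) -> list[Path]:
    """Write one NIfTI per parameter plus the fit-quality map.

    Files are named ``<stem>_adc.nii.gz``, ``<stem>_d.nii.gz``, ... and
    ``<stem>_quality.nii.gz``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in MAP_NAMES:
        p = out_dir / f"{stem}_{name.replace('d_star', 'dstar')}.nii.gz"
        save_volume(maps.maps[name], maps.affine, p)
        written.append(p)
    p = out_dir / f"{stem}_quality.nii.gz"
    save_volume(maps.quality, maps.affine, p)
    written.append(p)
    return written


def load_maps(
    out_dir: str | Path, stem: str, voxel_size: tuple[float, float, float]
) -> ParameterMaps:
    out_dir = Path(out_dir)
    maps = {}
    affine = np.eye(4)
    for name in MAP_NAMES:
        p = out_dir / f"{stem}_{name.replace('d_star', 'dstar')}.nii.gz"
        data, affine = load_volume(p)
        maps[name] = data
    quality, _ = load_volume(out_dir / f"{stem}_quality.nii.gz")
    return ParameterMaps(
        maps=maps, quality=quality, affine=affine, voxel_size=voxel_size
    )
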