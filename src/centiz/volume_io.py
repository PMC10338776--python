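"""3D volume container, NIfTI I/O, and geometry-aware resampling.

Conventions
-----------
* Voxel coordinates are 0-based indices; ``affine`` maps voxel index to
  world millimetres; index ``i`` addresses the *center* of voxel ``i``.
* World coordinates are always millimetres.
* Resampling uses the pull-back convention: the supplied transform maps
  *target* world coordinates into *source* world coordinates, and the
  source volume is interpolated there.  Out-of-field voxels are filled
  with 0, matching the implicit-zero convention of the surrounding
  neuroimaging tool ecosystem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["Volume3D", "VOIMask", "read_nifti", "write_nifti", "resample"]


@dataclass
class Volume3D:
    """A scalar 3D grid with an explicit voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        Finite scalar field (PET counts in arbitrary units, structural
        intensity, Z units, ...).
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm matrix; must be invertible.
    space_label : str
        Free-text space tag, conventionally ``"native"`` or ``"template"``.
    """

    data: np.ndarray
    affine: np.ndarray
    space_label: str = "native"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"data must be 3D with all sizes >= 1, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values; sanitize on load")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def center_of_mass_world(self) -> np.ndarray:
        """Intensity-weighted centroid in world mm (nonnegative weights)."""
        w = np.clip(self.data, 0, None)
        total = w.sum()
        if total <= 0:
            com_ijk = (np.asarray(self.shape, float) - 1) / 2.0
        else:
            com_ijk = np.asarray(ndimage.center_of_mass(w), dtype=float)
        return self.world_coords(com_ijk)[0]

    def copy(self, data: np.ndarray | None = None) -> "Volume3D":
        return Volume3D(
            data=self.data.copy() if data is None else np.asarray(data, float),
            affine=self.affine.copy(),
            space_label=self.space_label,
        )

    def same_grid(self, other: "Volume3D", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=tol)


@dataclass
class VOIMask:
    """Binary volume of interest on a grid, e.g. the cortical target (CTX)
    or whole-cerebellum (WhlCbl) reference region."""

    data: np.ndarray
    affine: np.ndarray
    name: str = "VOI"

    def __post_init__(self):
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            # probabilistic masks are thresholded at > 0.5
            logger.info("mask %r has non-binary values; thresholding at > 0.5", self.name)
            arr = (arr > 0.5).astype(np.uint8)
        self.data = arr.astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def n_voxels(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self):
        if self.n_voxels() == 0:
            raise ValueError(f"mask {self.name!r} has no nonzero voxels")

    def as_volume(self) -> Volume3D:
        return Volume3D(self.data.astype(np.float64), self.affine, space_label="template")

    def same_grid(self, other, tol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=tol)


def _best_affine(img: nib.Nifti1Image) -> np.ndarray:
    """NIfTI transform precedence: sform if valid, else qform, else scaled identity."""
    hdr = img.header
    if int(hdr["sform_code"]) > 0:
        return img.get_sform()
    if int(hdr["qform_code"]) > 0:
        logger.info("no valid sform; using qform")
        return img.get_qform()
    logger.warning("no valid sform/qform; using voxel-size scaled identity")
    zooms = hdr.get_zooms()[:3]
    aff = np.diag(list(zooms) + [1.0])
    return aff


def read_nifti(path, space_label: str = "native") -> Volume3D:
    """Read a 3D NIfTI-1 volume.

    4D files are accepted only when they carry a single frame.  NaN voxels
    are replaced by 0 (a count is logged); infinite voxels are an error.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(f"expected a 3D image (or single-frame 4D), got {data.shape[3]} frames")
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim} dimensions")
    data = np.asarray(data, dtype=np.float64)
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        logger.warning("%s: replaced %d NaN voxels with 0", path, n_nan)
        data = np.nan_to_num(data, nan=0.0)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: image contains infinite values")
    affine = _best_affine(img)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: non-invertible affine")
    return Volume3D(data=data, affine=affine, space_label=space_label)


def write_nifti(vol: Volume3D | VOIMask, path) -> None:
    """Write a volume (float32) or mask (uint8) as NIfTI-1."""
    if isinstance(vol, VOIMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_sform(vol.affine, code=1)
    img.header.set_qform(vol.affine, code=1)
    nib.save(img, str(path))


def read_mask(path, name: str = "VOI") -> VOIMask:
    vol = read_nifti(path, space_label="template")
    return VOIMask(data=vol.data, affine=vol.affine, name=name)


def _source_voxel_coords(
    source_affine: np.ndarray,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    matrix: np.ndarray,
) -> np.ndarray:
    """Voxel coordinates in the source grid for every target voxel.

    ``matrix`` is the 4x4 world->world pull-back (target world -> source
    world).  Returns an array of shape (3, Ni, Nj, Nk).
    """
    full = np.linalg.inv(source_affine) @ matrix @ target_affine
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in target_shape], indexing="ij")
    coords = np.empty((3,) + tuple(target_shape))
    for r in range(3):
        coords[r] = (
            full[r, 0] * grids[0] + full[r, 1] * grids[1] + full[r, 2] * grids[2] + full[r, 3]
        )
    return coords


def resample(
    vol,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    transform=None,
    interp: str = "trilinear",
    space_label: str | None = None,
):
    """Resample a volume or mask onto a target grid through a transform chain.

    Parameters
    ----------
    vol : Volume3D or VOIMask
        Source image.  Masks force nearest-neighbour interpolation.
    target_affine, target_shape
        Geometry of the output grid.
    transform : TransformChain, rigid/affine params, 4x4 matrix, or None
        Pull-back mapping from target world coordinates to source world
        coordinates; ``None`` means identity.
    interp : {"trilinear", "nearest"}
        Interpolation order (masks always use nearest).

    All component transforms are composed into a single matrix and the
    source is interpolated exactly once.
    """
    from centiz.transforms import as_matrix  # local import to avoid cycle

    if interp not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interp mode {interp!r}")

    is_mask = isinstance(vol, VOIMask)
    order = 0 if (is_mask or interp == "nearest") else 1
    matrix = as_matrix(transform)
    data = vol.data.astype(np.float64)
    coords = _source_voxel_coords(vol.affine, np.asarray(target_affine, float), tuple(target_shape), matrix)
    out = ndimage.map_coordinates(data, coords, order=order, mode="constant", cval=0.0, prefilter=False)
    label = space_label if space_label is not None else getattr(vol, "space_label", "native")
    if is_mask:
        return VOIMask(data=out > 0.5, affine=np.asarray(target_affine, float), name=vol.name)
    return Volume3D(data=out, affine=np.asarray(target_affine, float), space_label=label)


def in_field_fraction(vol, target_affine, target_shape, transform=None) -> float:
    """Fraction of target voxels whose pulled-back position lies inside the
    source field of view (used for VOI coverage accounting)."""
    from centiz.transforms import as_matrix

    matrix = as_matrix(transform)
    coords = _source_voxel_coords(vol.affine, np.asarray(target_affine, float), tuple(target_shape), matrix)
    shape = np.asarray(vol.data.shape, float).reshape(3, 1, 1, 1)
    inside = np.all((coords >= -0.5) & (coords <= shape - 0.5), axis=0)
    return float(inside.mean())
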