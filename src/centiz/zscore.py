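"""Normative database construction and voxel-wise Z-score mapping.

Spatially standardized PET images are smoothed (default 8-mm FWHM),
count-normalized by the reference-VOI mean, and compared voxel-by-voxel
with an amyloid-negative control database:

    Z = (individual count - database mean count) / database SD count

inside an analysis mask that removes white-matter areas with high
normal counts.  Supra-threshold clusters can be filtered by size, and
the scalar summary is the mean of strictly positive Z values inside the
cortical target VOI.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from centiz.volume_io import Volume3D, VOIMask, read_nifti, read_mask, write_nifti

logger = logging.getLogger(__name__)

__all__ = [
    "NormalDatabase",
    "ZMapResult",
    "Cluster",
    "smooth",
    "normalize_to_reference",
    "build_database",
    "compute_zmap",
    "cluster_threshold",
    "mean_positive_z",
]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class Cluster:
    """A connected supra-threshold component of a statistical map."""

    size_voxels: int
    peak_value: float
    peak_index: tuple[int, int, int]

    def to_dict(self) -> dict:
        return {
            "size_voxels": self.size_voxels,
            "peak_value": self.peak_value,
            "peak_index": list(self.peak_index),
        }


@dataclass
class NormalDatabase:
    """Voxel-wise normative statistics from amyloid-negative controls."""

    mean_img: Volume3D
    sd_img: Volume3D
    analysis_mask: VOIMask
    n: int
    fwhm_mm: float
    reference_name: str

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("database needs n >= 2")
        if not self.mean_img.same_grid(self.sd_img):
            raise ValueError("mean and SD grids differ")
        if np.any(self.sd_img.data < 0):
            raise ValueError("SD image has negative values")

    def save(self, directory) -> None:
        """Serialize as a directory: mean/sd/mask NIfTI + metadata JSON."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_nifti(self.mean_img, d / "mean.nii.gz")
        write_nifti(self.sd_img, d / "sd.nii.gz")
        write_nifti(self.analysis_mask, d / "mask.nii.gz")
        digest = hashlib.sha256(
            self.mean_img.data.tobytes() + self.sd_img.data.tobytes()
        ).hexdigest()[:16]
        meta = {
            "n": self.n,
            "fwhm_mm": self.fwhm_mm,
            "reference_name": self.reference_name,
            "build_hash": digest,
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "NormalDatabase":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        return cls(
            mean_img=read_nifti(d / "mean.nii.gz", space_label="template"),
            sd_img=read_nifti(d / "sd.nii.gz", space_label="template"),
            analysis_mask=read_mask(d / "mask.nii.gz", name="analysis"),
            n=int(meta["n"]),
            fwhm_mm=float(meta["fwhm_mm"]),
            reference_name=str(meta["reference_name"]),
        )


@dataclass
class ZMapResult:
    """Z map plus cluster table and the positive-Z summary."""

    zmap: Volume3D
    clusters: list
    mean_positive_z: float
    n_positive_voxels: int

    def to_dict(self) -> dict:
        return {
            "mean_positive_z": self.mean_positive_z,
            "n_positive_voxels": self.n_positive_voxels,
            "clusters": [c.to_dict() for c in self.clusters],
        }


def smooth(vol: Volume3D, fwhm_mm: float) -> Volume3D:
    """Separable Gaussian smoothing with zero-padded boundaries.

    Anisotropic voxels are handled per axis:
    sigma_axis(voxels) = FWHM / (sqrt(8 ln 2) * voxel_size_axis).
    An FWHM below half the smallest voxel is treated as no-op (warning).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be positive")
    vox = vol.voxel_sizes
    if fwhm_mm < 0.5 * float(vox.min()):
        logger.warning("smooth: FWHM %.3g mm below half a voxel; returning input unchanged", fwhm_mm)
        return vol.copy()
    sigmas = fwhm_mm * FWHM_TO_SIGMA / vox
    out = ndimage.gaussian_filter(vol.data, sigma=sigmas, mode="constant", cval=0.0)
    return vol.copy(out)


def normalize_to_reference(vol: Volume3D, ref: VOIMask) -> Volume3D:
    """Divide every voxel by the reference-VOI mean (count normalization).

    The reference mean of the output is exactly 1.
    """
    ref.require_nonempty()
    if not ref.same_grid(vol, tol=1e-3):
        raise ValueError("reference mask is not on the volume grid")
    m = float(vol.data[ref.data].mean())
    if m <= 0:
        raise ValueError(f"reference mean must be positive, got {m}")
    return vol.copy(vol.data / m)


def build_database(
    controls: list,
    ref: VOIMask,
    brain_mask: VOIMask,
    fwhm_mm: float = 8.0,
    wm_exclusion_quantile: float = 0.85,
) -> NormalDatabase:
    """Build the normative database from template-space control PETs.

    Each control is smoothed then reference-normalized; voxel-wise mean
    and sample SD (n-1) are computed.  The analysis mask is the brain
    mask minus "white-matter-like" voxels whose database mean exceeds
    the given quantile of in-brain mean values — a data-driven proxy for
    removing white matter areas with high counts.
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 controls")
    grid = controls[0]
    for c in controls[1:]:
        if not c.same_grid(grid):
            raise ValueError("controls are not on a common grid")
    if not brain_mask.same_grid(grid, tol=1e-3):
        raise ValueError("brain mask not on the control grid")
    processed = np.stack(
        [normalize_to_reference(smooth(c, fwhm_mm), ref).data for c in controls]
    )
    mean = processed.mean(axis=0)
    sd = processed.std(axis=0, ddof=1)
    brain = brain_mask.data
    cutoff = np.quantile(mean[brain], wm_exclusion_quantile)
    analysis = brain & (mean <= cutoff)
    logger.info(
        "build_database: n=%d, excluded %d/%d in-brain voxels above mean quantile %.2f",
        len(controls), int(brain.sum() - analysis.sum()), int(brain.sum()), wm_exclusion_quantile,
    )
    return NormalDatabase(
        mean_img=Volume3D(mean, grid.affine, space_label="template"),
        sd_img=Volume3D(sd, grid.affine, space_label="template"),
        analysis_mask=VOIMask(analysis, grid.affine, name="analysis"),
        n=len(controls),
        fwhm_mm=fwhm_mm,
        reference_name=ref.name,
    )


def compute_zmap(
    subject: Volume3D,
    db: NormalDatabase,
    sd_floor: float = 1e-3,
    target: VOIMask | None = None,
    z_thresh: float = 2.0,
    min_voxels: int = 1,
    connectivity: int = 18,
) -> ZMapResult:
    """Voxel-wise Z map of a (smoothed, reference-normalized) subject.

    Z is computed inside the analysis mask only and is 0 outside.  The
    SD is floored at ``max(sd_floor, 0.05 * median in-mask SD)`` to
    prevent Z explosions in near-constant voxels.  If ``target`` is
    given the mean-positive-Z summary is computed over it, otherwise
    over the analysis mask.
    """
    if not subject.same_grid(db.mean_img):
        raise ValueError("subject grid differs from database grid")
    mask = db.analysis_mask.data
    sd = db.sd_img.data.copy()
    in_mask_sd = sd[mask]
    floor = max(sd_floor, 0.05 * float(np.median(in_mask_sd))) if in_mask_sd.size else sd_floor
    sd = np.maximum(sd, floor)
    z = np.zeros_like(subject.data)
    z[mask] = (subject.data[mask] - db.mean_img.data[mask]) / sd[mask]
    zvol = Volume3D(z, subject.affine, space_label="template")
    clusters = cluster_threshold(zvol, z_thresh, min_voxels, connectivity)
    summary_mask = target if target is not None else db.analysis_mask
    mpz, n_pos = mean_positive_z(zvol, summary_mask)
    return ZMapResult(zmap=zvol, clusters=clusters, mean_positive_z=mpz, n_positive_voxels=n_pos)


_CONNECTIVITY_STRUCTS = {6: 1, 18: 2, 26: 3}


def cluster_threshold(zmap: Volume3D, z_thresh: float, min_voxels: int = 1, connectivity: int = 18):
    """Connected components of {Z >= z_thresh}, dropping those smaller
    than ``min_voxels``; sorted by size descending.  Connectivity is 6
    (faces), 18 (faces+edges, the common default) or 26 (full)."""
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_STRUCTS)}")
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_STRUCTS[connectivity])
    above = zmap.data >= z_thresh
    labels, n = ndimage.label(above, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        idx = labels == lab
        size = int(idx.sum())
        if size < min_voxels:
            continue
        flat = np.where(idx.ravel())[0]
        peak_flat = flat[np.argmax(zmap.data.ravel()[flat])]
        peak = np.unravel_index(peak_flat, zmap.shape)
        clusters.append(Cluster(size_voxels=size, peak_value=float(zmap.data[peak]), peak_index=tuple(int(i) for i in peak)))
    clusters.sort(key=lambda c: (-c.size_voxels, -c.peak_value))
    return clusters


def mean_positive_z(zmap: Volume3D, target: VOIMask):
    """Mean of strictly positive Z inside the target VOI.

    Returns ``(mean_positive_z, n_positive)``; (0.0, 0) when no voxel is
    positive.
    """
    target.require_nonempty()
    if not target.same_grid(zmap, tol=1e-3):
        raise ValueError("target mask not on the zmap grid")
    vals = zmap.data[target.data]
    pos = vals[vals > 0]
    if pos.size == 0:
        return 0.0, 0
    return float(pos.mean()), int(pos.size)
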