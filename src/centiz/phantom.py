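"""Synthetic brain phantoms with known ground-truth SUVR / Centiloid.

The generator emulates, at desk scale, the inputs of an amyloid-PET
quantification study: a template with standard VOI masks (cortical
target ``CTX``, whole-cerebellum reference ``WhlCbl``, brain and
white-matter masks), per-subject structural images with MRI- or CT-like
contrast, and PET images whose regional uptake is set so that the
target/reference ratio equals a requested true SUVR before noise.

Geometry is a nested-ellipsoid "brain": an outer brain ellipsoid, a
cortical shell, a central white-matter core with *higher* uptake than
cortex (the florbetapir-negative pattern; amyloid-positive subjects
raise cortical uptake toward and above white matter), and an inferior
"cerebellum" blob serving as the reference region.  PET regions are
piecewise constant and the quantification VOIs are eroded inward from
the painted regions, so region means survive the interpolation blur of
registration and resampling.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from centiz.centiloid import suvr_to_centiloid
from centiz.transforms import RigidParams, AffineParams, TransformChain
from centiz.volume_io import Volume3D, VOIMask, resample

__all__ = [
    "PhantomSpec",
    "SubjectRecord",
    "make_template",
    "make_subject",
    "make_database",
    "make_validation_set",
]

# uptake of the white-matter core relative to the reference region
WHITE_MATTER_UPTAKE = 1.55


@dataclass
class PhantomSpec:
    """Recipe for one synthetic subject."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    true_suvr: float = 1.0
    noise_sd_frac: float = 0.02          # fraction of the reference-region mean
    applied_transform: RigidParams | AffineParams | None = None   # head pose, native->template pull-back
    pet_misalign: RigidParams | None = None                       # extra PET-vs-structural rigid offset
    modality: str = "MRI"
    seed: int = 0

    def __post_init__(self):
        if self.true_suvr <= 0:
            raise ValueError("true_suvr must be > 0")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        if self.modality not in ("MRI", "CT"):
            raise ValueError("modality must be 'MRI' or 'CT'")


@dataclass
class SubjectRecord:
    """One generated subject: images plus recorded ground truth."""

    pet: Volume3D
    structural: Volume3D | None
    truth: dict
    spec: PhantomSpec | None = None


def _centered_affine(grid_shape, voxel_mm) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -(np.asarray(grid_shape) - 1) / 2.0 * voxel_mm
    return aff


def _world_grids(grid_shape, affine):
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in grid_shape], indexing="ij")
    x = affine[0, 0] * idx[0] + affine[0, 3]
    y = affine[1, 1] * idx[1] + affine[1, 3]
    z = affine[2, 2] * idx[2] + affine[2, 3]
    return x, y, z


def _ellipsoid(x, y, z, center, radii, scale=1.0):
    cx, cy, cz = center
    rx, ry, rz = (np.asarray(radii, float) * scale)
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


# canonical geometry in world mm (template space, grid centered on 0)
_BRAIN_C, _BRAIN_R = (0.0, 0.0, 4.0), (48.0, 56.0, 44.0)
_WM_C, _WM_R = (0.0, 4.0, 8.0), (26.0, 32.0, 22.0)
# cerebellum blob lies fully inside the brain ellipsoid so the eroded
# reference VOI keeps a wide margin from any zero-background boundary
_CBL_C, _CBL_R = (0.0, -20.0, -22.0), (24.0, 16.0, 12.0)
_CTX_OUTER, _CTX_INNER = 0.92, 0.80    # VOI shell, fraction of brain ellipsoid
_CBL_VOI_SCALE = 0.60
_CTX_ZMIN = -4.0                        # cortical shell is supratentorial


def make_template(grid_shape=(64, 64, 64), voxel_mm=2.0, seed=0):
    """Build the MRI-like template and the standard mask set.

    Returns ``(template, masks)`` where ``masks`` holds ``"CTX"``,
    ``"WhlCbl"``, ``"brain"`` and ``"white_matter"`` :class:`VOIMask`
    objects on the template grid.  CTX and WhlCbl are disjoint by
    construction.  Deterministic given ``seed``.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if min(grid_shape) * voxel_mm < 100.0:
        raise ValueError("grid too small to contain the phantom structures (need >= 100 mm extent)")
    affine = _centered_affine(grid_shape, voxel_mm)
    x, y, z = _world_grids(grid_shape, affine)

    brain = _ellipsoid(x, y, z, _BRAIN_C, _BRAIN_R)
    wm = _ellipsoid(x, y, z, _WM_C, _WM_R)
    cbl_region = _ellipsoid(x, y, z, _CBL_C, _CBL_R) & brain
    ctx_voi = (
        _ellipsoid(x, y, z, _BRAIN_C, _BRAIN_R, scale=_CTX_OUTER)
        & ~_ellipsoid(x, y, z, _BRAIN_C, _BRAIN_R, scale=_CTX_INNER)
        & (z > _CTX_ZMIN)
        & ~wm
        & ~cbl_region
    )
    cbl_voi = _ellipsoid(x, y, z, _CBL_C, _CBL_R, scale=_CBL_VOI_SCALE) & brain

    for name, m in (("CTX", ctx_voi), ("WhlCbl", cbl_voi), ("brain", brain), ("white_matter", wm)):
        if not m.any():
            raise ValueError(f"phantom mask {name!r} is empty; enlarge the grid")

    template = _structural_field(x, y, z, modality="MRI", rng=np.random.default_rng(seed), noise_frac=0.0)
    tvol = Volume3D(template, affine, space_label="template")
    masks = {
        "CTX": VOIMask(ctx_voi, affine, name="CTX"),
        "WhlCbl": VOIMask(cbl_voi, affine, name="WhlCbl"),
        "brain": VOIMask(brain, affine, name="brain"),
        "white_matter": VOIMask(wm, affine, name="white_matter"),
    }
    return tvol, masks


def _structural_field(x, y, z, modality, rng, noise_frac):
    """MRI-like (WM bright) or CT-like (bright skull rim, compressed
    soft-tissue contrast) structural intensity field."""
    brain = _ellipsoid(x, y, z, _BRAIN_C, _BRAIN_R)
    wm = _ellipsoid(x, y, z, _WM_C, _WM_R)
    skull = _ellipsoid(x, y, z, _BRAIN_C, _BRAIN_R, scale=1.10) & ~_ellipsoid(
        x, y, z, _BRAIN_C, _BRAIN_R, scale=1.02
    )
    out = np.zeros_like(x)
    if modality == "MRI":
        out[brain] = 0.70      # gray matter
        out[wm] = 1.00         # white matter bright on T1
        out[skull] = 0.12
    else:
        out[brain] = 0.45      # compressed soft-tissue range
        out[wm] = 0.42         # WM slightly darker than GM on CT
        out[skull] = 2.00      # bone bright
    # real structural images have smooth tissue transitions; a 1-voxel
    # Gaussian keeps the field faithful under trilinear resampling and
    # avoids a sharp-vs-blurred asymmetry in the registration metric
    out = ndimage.gaussian_filter(out, sigma=1.0, mode="constant", cval=0.0)
    if noise_frac > 0:
        out = out + rng.normal(0.0, noise_frac * 0.7, size=out.shape)
    return out


def _pet_field(x, y, z, true_suvr):
    """Piecewise-constant PET counts; reference region mean is exactly 1."""
    brain = _ellipsoid(x, y, z, _BRAIN_C, _BRAIN_R)
    wm = _ellipsoid(x, y, z, _WM_C, _WM_R)
    cbl = _ellipsoid(x, y, z, _CBL_C, _CBL_R) & brain
    out = np.zeros_like(x)
    out[brain] = true_suvr                 # cortex + deep gray carry the target level
    out[wm] = WHITE_MATTER_UPTAKE          # high-normal WM uptake (negative pattern)
    out[cbl] = 1.0                         # reference
    return out


def make_subject(template: Volume3D, masks: dict, spec: PhantomSpec) -> SubjectRecord:
    """Generate one subject: structural + PET in native space, with truth.

    The PET is painted in template space so that the CTX/WhlCbl ratio is
    exactly ``spec.true_suvr`` before noise, then both images are pulled
    into "native" space through ``spec.applied_transform`` (head pose); the
    PET additionally passes through ``spec.pet_misalign`` (PET-vs-structural
    rigid offset).  Gaussian noise (SD = ``noise_sd_frac`` x reference mean)
    is added after resampling.
    """
    rng = np.random.default_rng(spec.seed)
    affine = template.affine
    x, y, z = _world_grids(template.shape, affine)

    pet_t = _pet_field(x, y, z, spec.true_suvr)
    struct_t = _structural_field(x, y, z, spec.modality, rng, noise_frac=0.0)

    pose = spec.applied_transform
    pet_chain = TransformChain([t for t in (spec.pet_misalign, pose) if t is not None])
    struct_chain = TransformChain([pose] if pose is not None else [])

    pet_src = Volume3D(pet_t, affine, space_label="template")
    struct_src = Volume3D(struct_t, affine, space_label="template")
    pet = resample(pet_src, affine, template.shape, pet_chain, space_label="native")
    structural = resample(struct_src, affine, template.shape, struct_chain, space_label="native")

    if spec.noise_sd_frac > 0:
        pet = pet.copy(pet.data + rng.normal(0.0, spec.noise_sd_frac, size=pet.data.shape))
        structural = structural.copy(
            structural.data + rng.normal(0.0, spec.noise_sd_frac * 0.5, size=structural.data.shape)
        )

    truth = {
        "suvr": float(spec.true_suvr),
        "cl": float(suvr_to_centiloid(spec.true_suvr)),
        "seed": int(spec.seed),
        "modality": spec.modality,
    }
    return SubjectRecord(pet=pet, structural=structural, truth=truth, spec=spec)


def make_database(
    n: int = 20,
    suvr_mean: float = 0.986,
    suvr_sd: float = 0.052,
    noise_sd_frac: float = 0.02,
    seed: int = 0,
    grid_shape=(64, 64, 64),
    voxel_mm: float = 2.0,
):
    """Amyloid-negative control subjects directly in template space.

    True SUVRs are drawn Normal(``suvr_mean``, ``suvr_sd``) truncated below
    at 0.8.  Defaults match a young-control florbetapir cohort
    (0.986 +/- 0.052).  Returns ``(template, masks, subjects)`` with
    ``subjects`` a list of :class:`SubjectRecord` (PET only, template space).
    """
    if n < 2:
        raise ValueError("database needs n >= 2 controls")
    rng = np.random.default_rng(seed)
    template, masks = make_template(grid_shape, voxel_mm, seed=seed)
    x, y, z = _world_grids(template.shape, template.affine)
    subjects = []
    for i in range(n):
        true_suvr = rng.normal(suvr_mean, suvr_sd)
        while true_suvr < 0.8:           # truncation keeps the ratio physical
            true_suvr = rng.normal(suvr_mean, suvr_sd)
        pet = _pet_field(x, y, z, true_suvr)
        if noise_sd_frac > 0:
            pet = pet + rng.normal(0.0, noise_sd_frac, size=pet.shape)
        vol = Volume3D(pet, template.affine, space_label="template")
        truth = {"suvr": float(true_suvr), "cl": float(suvr_to_centiloid(true_suvr))}
        subjects.append(SubjectRecord(pet=vol, structural=None, truth=truth))
    return template, masks, subjects


def _random_rigid(rng, max_trans_mm, max_rot_deg, center):
    """Rigid draw with |translation| <= max_trans_mm (uniform in the ball)
    and per-axis rotations uniform within +/- max_rot_deg."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = max_trans_mm * rng.uniform() ** (1.0 / 3.0)
    rot = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg, size=3))
    return RigidParams(translations=direction * radius, rotations=rot, center=np.asarray(center, float))


def make_validation_set(
    n: int = 20,
    cl_min: float = -20.0,
    cl_max: float = 120.0,
    misalign_mm: float = 5.0,
    misalign_deg: float = 5.0,
    noise_sd_frac: float = 0.02,
    seed: int = 0,
    grid_shape=(64, 64, 64),
    voxel_mm: float = 2.0,
    modality: str = "MRI",
):
    """Calibration set: true CL evenly spaced over [cl_min, cl_max], each
    subject given a random rigid head pose and a random rigid
    PET-vs-structural misalignment, both within the stated bounds.

    Returns ``(template, masks, subjects)``.
    """
    if n < 3:
        raise ValueError("validation set needs n >= 3")
    if not (cl_max > cl_min):
        raise ValueError("degenerate CL range")
    rng = np.random.default_rng(seed)
    template, masks = make_template(grid_shape, voxel_mm, seed=seed)
    from centiz.centiloid import centiloid_to_suvr

    cls = np.linspace(cl_min, cl_max, n)
    subjects = []
    for i, cl in enumerate(cls):
        pose = _random_rigid(rng, misalign_mm, misalign_deg, center=(0.0, 0.0, 0.0))
        misalign = _random_rigid(rng, misalign_mm, misalign_deg, center=(0.0, 0.0, 0.0))
        spec = PhantomSpec(
            grid_shape=template.shape,
            voxel_size_mm=voxel_mm,
            true_suvr=float(centiloid_to_suvr(cl)),
            noise_sd_frac=noise_sd_frac,
            applied_transform=pose,
            pet_misalign=misalign,
            modality=modality,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(make_subject(template, masks, spec))
    return template, masks, subjects
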