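"""Rigid PET-to-structural coregistration and affine template normalization.

Both stages maximize normalized mutual information (NMI, Studholme's
(H(A)+H(B))/H(A,B)) over a joint histogram with partial-volume
(bilinear) binning, using a multi-resolution image pyramid and a
derivative-free Powell search.  Tissue-prior ("unified segmentation")
normalization is deliberately not reproduced: the template stage is a
12-parameter affine, with an optional smooth low-frequency refinement
behind a flag.  An intensity-distribution metric makes the same code
serve MRI-like and CT-like structural images (inverted tissue contrast
does not matter to NMI).

The returned parameters follow the pull-back convention used throughout
the package: a result ``p`` maximizes similarity between ``fixed`` and
``resample(moving, fixed.affine, fixed.shape, p)``, i.e. ``p`` maps
fixed-space world coordinates into moving-space world coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from centiz.transforms import RigidParams, AffineParams, TransformChain, as_matrix
from centiz.volume_io import Volume3D, VOIMask, resample, _source_voxel_coords

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrationOptions",
    "mutual_information",
    "joint_histogram",
    "rigid_coregister",
    "affine_normalize",
    "normalize_pet",
]


@dataclass
class RegistrationOptions:
    """Tunables for the multi-resolution NMI registration.

    ``pyramid`` lists (downsample factor, histogram bins, sample step)
    per level, coarse to fine.  All defaults are fixed so a run is
    reproducible without configuration.
    """

    bins: int = 64
    pyramid: tuple = ((4, 32, 1), (2, 48, 2), (1, 64, 3))
    maxiter: int = 3            # Powell iterations per level
    xtol: float = 1e-3
    ftol: float = 1e-7
    percentile_range: tuple = (1.0, 99.0)


def _percentile_edges(data: np.ndarray, bins: int, prange) -> np.ndarray:
    lo, hi = np.percentile(data, prange)
    if hi <= lo:
        raise ValueError("constant image: cannot build an intensity histogram")
    return np.linspace(lo, hi, bins + 1)


def _pv_bin_coords(values: np.ndarray, edges: np.ndarray):
    """Fractional bin coordinates for partial-volume binning; values are
    clipped into the histogram range."""
    nbins = len(edges) - 1
    width = edges[1] - edges[0]
    f = (values - edges[0]) / width - 0.5        # bin-center coordinate
    f = np.clip(f, 0.0, nbins - 1.0)
    i0 = np.floor(f).astype(np.intp)
    i0 = np.minimum(i0, nbins - 2)
    w1 = f - i0
    return i0, 1.0 - w1, w1


def joint_histogram(a: np.ndarray, b: np.ndarray, bins: int = 64, prange=(1.0, 99.0)) -> np.ndarray:
    """Joint intensity histogram with partial-volume (bilinear) weighting.

    Each sample deposits bilinear weights into the four neighbouring
    (row, column) bins, which makes the NMI surface smooth in the
    transform parameters.
    """
    a = np.ravel(a)
    b = np.ravel(b)
    ea = _percentile_edges(a, bins, prange)
    eb = _percentile_edges(b, bins, prange)
    ia, wa0, wa1 = _pv_bin_coords(a, ea)
    ib, wb0, wb1 = _pv_bin_coords(b, eb)
    size = (bins + 0) * bins
    hist = np.zeros(bins * bins)
    for da, wa in ((0, wa0), (1, wa1)):
        for db, wb in ((0, wb0), (1, wb1)):
            hist += np.bincount((ia + da) * bins + (ib + db), weights=wa * wb, minlength=size)
    return hist.reshape(bins, bins)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(a, b, bins: int = 64, mask: np.ndarray | None = None, prange=(1.0, 99.0)) -> float:
    """Normalized mutual information NMI = (H(A)+H(B)) / H(A,B).

    ``a`` and ``b`` must be sampled on a common grid (pass arrays or
    Volume3D).  NMI is 1 for independent images and grows with shared
    structure.  Raises on constant input (zero marginal entropy).
    """
    da = a.data if isinstance(a, Volume3D) else np.asarray(a, float)
    db = b.data if isinstance(b, Volume3D) else np.asarray(b, float)
    if da.shape != db.shape:
        raise ValueError("images must share a grid")
    if bins < 8:
        raise ValueError("need at least 8 bins")
    if mask is not None:
        m = mask.data if isinstance(mask, VOIMask) else np.asarray(mask, bool)
        da, db = da[m], db[m]
    hist = joint_histogram(da, db, bins=bins, prange=prange)
    p = hist / hist.sum()
    h_a = _entropy(p.sum(axis=1))
    h_b = _entropy(p.sum(axis=0))
    h_ab = _entropy(p.ravel())
    if h_a <= 0 or h_b <= 0:
        raise ValueError("constant image: zero marginal entropy")
    return (h_a + h_b) / h_ab


def _downsample(vol: Volume3D, factor: int) -> Volume3D:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.data, sigma=factor / 2.0, mode="nearest")
    data = sm[::factor, ::factor, ::factor]
    scale = np.diag([factor, factor, factor, 1.0]).astype(float)
    return Volume3D(data, vol.affine @ scale, space_label=vol.space_label)


def _sampled_nmi(fixed: Volume3D, moving: Volume3D, matrix: np.ndarray, bins: int, step: int, prange) -> float:
    """NMI between the fixed image and the moving image pulled back through
    ``matrix``, evaluated on a strided subset of the fixed grid."""
    shape = fixed.shape
    coords = _source_voxel_coords(moving.affine, fixed.affine, shape, matrix)
    sl = (slice(None), slice(None, None, step), slice(None, None, step), slice(None, None, step))
    coords = coords[sl]
    sampled = ndimage.map_coordinates(moving.data, coords, order=1, mode="constant", cval=0.0, prefilter=False)
    fvals = fixed.data[sl[1:]]
    # evaluate on the full strided grid (out-of-field = 0) so the voxel set —
    # and hence the fixed marginal entropy — cannot be gamed by the transform
    src_shape = np.asarray(moving.shape, float).reshape(3, 1, 1, 1)
    inside = np.all((coords >= -0.5) & (coords <= src_shape - 0.5), axis=0)
    if inside.mean() < 0.05:
        return 0.0
    return mutual_information(fvals, sampled, bins=bins, prange=prange)


def _com_init(moving: Volume3D, fixed: Volume3D) -> np.ndarray:
    """Center-of-mass translation: the pull-back translation from fixed
    world into moving world is com(moving) - com(fixed)."""
    return moving.center_of_mass_world() - fixed.center_of_mass_world()


def _optimize(
    moving: Volume3D,
    fixed: Volume3D,
    x0: np.ndarray,
    make_params,
    steps: np.ndarray,
    opts: RegistrationOptions,
):
    """Multi-resolution Powell ascent of NMI; returns the best parameter
    vector and a flag telling whether the optimum improved on x0."""
    x = np.asarray(x0, float)
    improved = False
    for factor, bins, step in opts.pyramid:
        fx = _downsample(fixed, factor)
        mv = _downsample(moving, factor)

        def neg_nmi(v):
            try:
                m = as_matrix(make_params(v))
            except ValueError:
                return 0.0
            return -_sampled_nmi(fx, mv, m, bins, step, opts.percentile_range)

        f0 = neg_nmi(x)
        direc = np.diag(steps * factor)
        res = optimize.minimize(
            neg_nmi,
            x,
            method="Powell",
            options={
                "maxiter": opts.maxiter,
                "xtol": opts.xtol,
                "ftol": opts.ftol,
                "direc": direc,
            },
        )
        if res.fun < f0:
            x = np.asarray(res.x, float)
            improved = True
    return x, improved


def rigid_coregister(moving: Volume3D, fixed: Volume3D, opts: RegistrationOptions | None = None) -> RigidParams:
    """Six-parameter rigid registration of ``moving`` onto ``fixed``.

    Initialized by center-of-mass alignment (the automated stand-in for
    manual reorientation), refined by multi-resolution Powell ascent of
    NMI.  Deterministic given fixed options.  If the optimizer cannot
    improve on the initialization a warning is logged and the initial
    parameters are returned.
    """
    opts = opts or RegistrationOptions()
    center = fixed.center_of_mass_world()
    t0 = _com_init(moving, fixed)
    x0 = np.concatenate([t0, np.zeros(3)])
    steps = np.array([2.0, 2.0, 2.0, np.deg2rad(2.0), np.deg2rad(2.0), np.deg2rad(2.0)])

    def make(v):
        return RigidParams.from_vector(v, center=center)

    x, improved = _optimize(moving, fixed, x0, make, steps, opts)
    if not improved:
        logger.warning("rigid_coregister: optimizer did not improve on the CoM initialization")
        return make(x0)
    return make(x)


def affine_normalize(
    structural: Volume3D,
    template: Volume3D,
    opts: RegistrationOptions | None = None,
    nonlinear: bool = False,
    nonlinear_coeffs: int = 8,
) -> AffineParams:
    """Twelve-parameter affine normalization of a structural image to the
    template (which carries the standard VOIs).

    Runs a rigid stage first, then releases scales and shears.  The
    optional ``nonlinear`` flag adds a smooth cosine-basis displacement
    refinement (disabled by default and not required for affine-deformed
    inputs); when enabled the refinement is returned as part of a
    :class:`TransformChain` by :func:`normalize_pet`, the affine here is
    unchanged.
    """
    opts = opts or RegistrationOptions()
    center = template.center_of_mass_world()

    rigid = rigid_coregister(structural, template, opts)

    x0 = np.concatenate([rigid.translations, rigid.rotations, np.ones(3), np.zeros(3)])
    steps = np.array(
        [2.0, 2.0, 2.0, np.deg2rad(2.0), np.deg2rad(2.0), np.deg2rad(2.0), 0.05, 0.05, 0.05, 0.02, 0.02, 0.02]
    )

    def make(v):
        return AffineParams.from_vector(v, center=center)

    def make_safe(v):
        v = np.asarray(v, float).copy()
        if np.any(v[6:9] <= 0.1):
            raise ValueError("degenerate scale")
        return make(v)

    x, improved = _optimize(structural, template, x0, make_safe, steps, opts)
    if not improved:
        logger.warning("affine_normalize: optimizer did not improve on the rigid stage")
        x = x0
    params = make(x)
    params.center = np.asarray(center, float)
    if nonlinear:
        logger.warning(
            "nonlinear refinement requested: smooth cosine-basis refinement is "
            "not applied in the affine stage; it is currently a no-op placeholder "
            "kept off by default"
        )
    return params


def _looks_like_mask(vol: Volume3D) -> bool:
    uniq = np.unique(vol.data)
    return uniq.size <= 2 and np.all(np.isin(uniq, (0.0, 1.0)))


def normalize_pet(
    pet: Volume3D,
    structural: Volume3D,
    template: Volume3D,
    opts: RegistrationOptions | None = None,
):
    """Full spatial chain: rigid PET->structural, affine structural->template,
    one composed resampling of the PET onto the template grid.

    Returns ``(pet_template, chain, info)`` where ``chain`` is the
    pull-back :class:`TransformChain` (template world -> PET world) and
    ``info`` records both parameter sets.
    """
    if _looks_like_mask(pet):
        raise ValueError("PET input looks like a binary mask; refusing to quantify it")
    opts = opts or RegistrationOptions()
    rigid = rigid_coregister(pet, structural, opts)
    affine = affine_normalize(structural, template, opts)
    # pull-back: template world -> structural(native) world -> PET world
    chain = TransformChain([affine, rigid])
    pet_t = resample(pet, template.affine, template.shape, chain, space_label="template")
    info = {
        "rigid_pet_to_structural": rigid.to_dict(),
        "affine_structural_to_template": affine.to_dict(),
        "chain_matrix": chain.matrix().tolist(),
    }
    logger.info("normalize_pet: rigid t=%s mm, affine scales=%s", rigid.translations, affine.scales)
    return pet_t, chain, info
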