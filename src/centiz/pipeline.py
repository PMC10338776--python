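"""End-to-end orchestration of the two quantification processes.

``run_centiloid`` executes reorient-initialization -> rigid PET->MRI/CT
coregistration -> affine template normalization -> one composed
resampling -> SUVR -> CL, and ``run_zscore`` continues with smoothing,
reference-count normalization and the normative Z map, sharing the same
spatial transform chain (computed once).

Inputs may be given as file paths (NIfTI) or in-memory objects, so the
same code path serves the CLI and programmatic use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from centiz.centiloid import compute_suvr, QuantResult
from centiz.spatial_norm import RegistrationOptions, normalize_pet
from centiz.volume_io import Volume3D, VOIMask, read_nifti, read_mask, write_nifti
from centiz.zscore import NormalDatabase, ZMapResult, compute_zmap, normalize_to_reference, smooth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_centiloid", "run_zscore"]


@dataclass
class PipelineConfig:
    """Configuration for both pipeline processes.

    Paths may be left None when template/masks/database are passed as
    objects.  Defaults are serialized into every report for provenance.
    """

    template_path: str | None = None
    ctx_mask_path: str | None = None
    whlcbl_mask_path: str | None = None
    database_dir: str | None = None
    output_dir: str | None = None
    fwhm_mm: float = 8.0
    z_display_range: tuple = (2.0, 7.0)
    z_cluster_min_voxels: int = 100
    z_cluster_connectivity: int = 18
    sd_floor: float = 1e-3
    coverage_floor: float = 0.9
    seed: int = 0
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        reg = raw.pop("registration", None)
        cfg = cls(**raw)
        if reg:
            cfg.registration = RegistrationOptions(**reg)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["registration"] = asdict(self.registration)
        return d


def _as_volume(x, space_label="native") -> Volume3D:
    if isinstance(x, Volume3D):
        return x
    return read_nifti(x, space_label=space_label)


def _load_template(config, template=None, ctx=None, whlcbl=None):
    if template is None:
        if not config.template_path or not Path(config.template_path).exists():
            raise FileNotFoundError(f"template not found: {config.template_path}")
        template = read_nifti(config.template_path, space_label="template")
    if ctx is None:
        ctx = read_mask(config.ctx_mask_path, name="CTX")
    if whlcbl is None:
        whlcbl = read_mask(config.whlcbl_mask_path, name="WhlCbl")
    return template, ctx, whlcbl


def run_centiloid(
    pet,
    structural,
    config: PipelineConfig | None = None,
    template: Volume3D | None = None,
    ctx: VOIMask | None = None,
    whlcbl: VOIMask | None = None,
):
    """Centiloid process for one subject.

    Returns ``(QuantResult, artifacts)`` where ``artifacts`` carries the
    normalized PET, the transform chain/info and the JSON-able report.
    Writes NIfTI/JSON outputs when ``config.output_dir`` is set.
    """
    config = config or PipelineConfig()
    template, ctx, whlcbl = _load_template(config, template, ctx, whlcbl)
    pet = _as_volume(pet)
    structural = _as_volume(structural)

    logger.info("stage: spatial normalization")
    pet_t, chain, reg_info = normalize_pet(pet, structural, template, config.registration)
    logger.info("stage: SUVR / CL quantification")
    quant = compute_suvr(pet_t, ctx, whlcbl, coverage_floor=config.coverage_floor)

    report = {
        "process": "centiloid",
        "result": quant.to_dict(),
        "registration": reg_info,
        "config": config.to_dict(),
    }
    artifacts = {"pet_template": pet_t, "chain": chain, "report": report}
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_nifti(pet_t, out / "pet_mni.nii.gz")
        (out / "centiloid_report.json").write_text(json.dumps(report, indent=2))
        (out / "transforms.json").write_text(json.dumps(reg_info, indent=2))
    return quant, artifacts


def run_zscore(
    pet,
    structural,
    database: NormalDatabase | str | None = None,
    config: PipelineConfig | None = None,
    template: Volume3D | None = None,
    ctx: VOIMask | None = None,
    whlcbl: VOIMask | None = None,
    pet_template: Volume3D | None = None,
):
    """Z-score process for one subject.

    The spatial chain is shared with :func:`run_centiloid`: pass
    ``pet_template`` from its artifacts to skip re-registration, else it
    is computed here.  The subject is smoothed and reference-normalized
    with the *database's* FWHM and reference VOI; a mismatch between the
    database metadata and the config is an error.
    """
    config = config or PipelineConfig()
    if database is None:
        database = config.database_dir
    if not isinstance(database, NormalDatabase):
        if database is None or not Path(str(database)).exists():
            raise FileNotFoundError(f"database directory not found: {database}")
        database = NormalDatabase.load(database)
    if abs(database.fwhm_mm - config.fwhm_mm) > 1e-6:
        raise ValueError(
            f"database FWHM {database.fwhm_mm} mm differs from configured {config.fwhm_mm} mm"
        )
    template, ctx, whlcbl = _load_template(config, template, ctx, whlcbl)
    if database.reference_name != whlcbl.name:
        raise ValueError(
            f"database reference {database.reference_name!r} differs from configured {whlcbl.name!r}"
        )

    if pet_template is None:
        pet = _as_volume(pet)
        structural = _as_volume(structural)
        pet_template, chain, reg_info = normalize_pet(pet, structural, template, config.registration)
    else:
        reg_info = {"note": "transform chain reused from the centiloid process"}

    logger.info("stage: smoothing + reference normalization")
    subj = normalize_to_reference(smooth(pet_template, database.fwhm_mm), whlcbl)
    logger.info("stage: Z map")
    result = compute_zmap(
        subj,
        database,
        sd_floor=config.sd_floor,
        target=ctx,
        z_thresh=config.z_display_range[0],
        min_voxels=config.z_cluster_min_voxels,
        connectivity=config.z_cluster_connectivity,
    )
    report = {
        "process": "zscore",
        "result": result.to_dict(),
        "database": {"n": database.n, "fwhm_mm": database.fwhm_mm, "reference": database.reference_name},
        "registration": reg_info,
        "config": config.to_dict(),
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_nifti(result.zmap, out / "zmap.nii.gz")
        _write_cluster_csv(result, out / "clusters.csv")
        (out / "zscore_report.json").write_text(json.dumps(report, indent=2))
    return result, {"report": report, "subject_normalized": subj}


def _write_cluster_csv(result: ZMapResult, path) -> None:
    import pandas as pd

    aff = result.zmap.affine
    rows = []
    for c in result.clusters:
        ijk = np.asarray(c.peak_index, float)
        world = ijk @ aff[:3, :3].T + aff[:3, 3]
        rows.append(
            {
                "size_voxels": c.size_voxels,
                "peak_z": c.peak_value,
                "peak_i": c.peak_index[0],
                "peak_j": c.peak_index[1],
                "peak_k": c.peak_index[2],
                "peak_x_mm": world[0],
                "peak_y_mm": world[1],
                "peak_z_mm": world[2],
            }
        )
    pd.DataFrame(rows, columns=[
        "size_voxels", "peak_z", "peak_i", "peak_j", "peak_k", "peak_x_mm", "peak_y_mm", "peak_z_mm",
    ]).to_csv(path, index=False)
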