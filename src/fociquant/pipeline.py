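"""End-to-end orchestration: prep → segment → postprocess → overlay → quantify.

For every image in a run manifest the pipeline selects the highest-mean
DAPI plane, builds the 3-slice maximum projection of the foci channel,
produces nuclei and foci masks (from trained U-nets, or from supplied
ground-truth masks when segmentation is bypassed), post-processes the
nuclei into instances, overlays foci on nuclei and writes per-object
measurement tables plus per-image summaries.  A failing image is recorded
in the manifest with its error and skipped; the run continues.  Given fixed
models and seed the outputs are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .io import (
    Channel,
    Condition,
    ImageMeta,
    LabelMap,
    SemanticMask,
    ZStack,
    read_mask,
    read_zstack,
    write_mask,
    write_measurements,
)
from .metrics import MatchConfig
from .postprocess import PostprocessConfig, filter_regions, postprocess_nuclei
from .quantify import (
    FocusRecord,
    ImageSummary,
    NucleusRecord,
    measure_nuclei,
    overlay_foci,
    records_to_frame,
    summarize_image,
)
from .unet import TrainedModel, load_model, predict_mask
from .zstack import max_project_around, select_focus_plane

logger = logging.getLogger("fociquant")

__all__ = ["RunConfig", "RunManifest", "ImageResult", "run_pipeline", "validate_config", "process_scene"]


@dataclass(frozen=True)
class RunConfig:
    manifest: str
    output_dir: str
    pixel_size_um: float
    z_step_um: float
    nuclei_model_dir: str | None = None
    foci_model_dir: str | None = None
    use_gt: bool = False
    projection_half_width: int = 1
    threshold: float = 0.5
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    alpha: float = 0.05
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v) for k, v in asdict(self).items()
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ImageResult:
    meta: ImageMeta
    selected_index: int | None = None
    projection_height_um: float | None = None
    outputs: dict[str, str] = field(default_factory=dict)
    wall_time_s: float = 0.0
    error: str | None = None


@dataclass
class RunManifest:
    config_hash: str
    images: list[ImageResult] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)


def validate_config(path: str | Path) -> RunConfig:
    """Parse and range-check a YAML run config, reporting all violations at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    problems: list[str] = []
    for key in raw:
        if key not in known:
            logger.warning("unknown config key %r ignored", key)
    raw = {k: v for k, v in raw.items() if k in known}
    for req in ("manifest", "output_dir", "pixel_size_um", "z_step_um"):
        if req not in raw:
            problems.append(f"missing required field {req!r}")
    if "postprocess" in raw and isinstance(raw["postprocess"], dict):
        try:
            raw["postprocess"] = PostprocessConfig(**raw["postprocess"])
        except (TypeError, ValueError) as e:
            problems.append(f"postprocess: {e}")
    if "match" in raw and isinstance(raw["match"], dict):
        try:
            raw["match"] = MatchConfig(**raw["match"])
        except (TypeError, ValueError) as e:
            problems.append(f"match: {e}")
    for fname, lo in (("pixel_size_um", 0.0), ("z_step_um", 0.0)):
        if fname in raw and not (isinstance(raw[fname], (int, float)) and raw[fname] > lo):
            problems.append(f"{fname} must be a number > {lo}")
    if "threshold" in raw and not (0 <= raw.get("threshold", 0.5) <= 1):
        problems.append("threshold must lie in [0, 1]")
    if "projection_half_width" in raw and raw["projection_half_width"] < 0:
        problems.append("projection_half_width must be ≥ 0")
    if problems:
        raise ValueError("invalid run config:\n  - " + "\n  - ".join(problems))
    cfg = RunConfig(**raw)
    if not cfg.use_gt and (cfg.nuclei_model_dir is None or cfg.foci_model_dir is None):
        raise ValueError("invalid run config:\n  - model directories required unless use_gt is set")
    return cfg


def process_scene(
    dapi: ZStack,
    foci: ZStack,
    *,
    nuclei_model: TrainedModel | None = None,
    foci_model: TrainedModel | None = None,
    gt_nuclei: LabelMap | None = None,
    gt_foci: SemanticMask | None = None,
    postprocess_config: PostprocessConfig | None = None,
    threshold: float = 0.5,
    projection_half_width: int = 1,
    meta: ImageMeta | None = None,
) -> tuple[list[NucleusRecord], list[FocusRecord], ImageSummary, dict]:
    """Run the per-image pipeline in memory.

    Provide trained models, or ground-truth masks to bypass segmentation
    (the gt nuclei label map skips hole-filling/watershed and only passes
    through the exclusion filter).
    """
    postprocess_config = postprocess_config or PostprocessConfig()
    index, dapi_plane = select_focus_plane(dapi)
    projection = max_project_around(foci, index, projection_half_width)
    if gt_nuclei is not None:
        nuclei_labels = filter_regions(gt_nuclei, postprocess_config)
    else:
        if nuclei_model is None:
            raise ValueError("need nuclei_model or gt_nuclei")
        nuclei_mask = predict_mask(nuclei_model, dapi_plane, threshold)
        nuclei_labels = postprocess_nuclei(nuclei_mask, postprocess_config)
    if gt_foci is not None:
        foci_mask = gt_foci
    else:
        if foci_model is None:
            raise ValueError("need foci_model or gt_foci")
        foci_mask = predict_mask(foci_model, projection.plane, threshold)
    focus_records = overlay_foci(foci_mask, nuclei_labels, meta)
    nucleus_records = measure_nuclei(nuclei_labels, focus_records, projection.height_um, meta)
    summary = summarize_image(
        nucleus_records, focus_records, meta or ImageMeta("unknown", "control", 0.0, 0), projection.height_um
    )
    info = {
        "selected_index": index,
        "projection_height_um": projection.height_um,
        "nuclei_labels": nuclei_labels,
        "foci_mask": foci_mask,
    }
    return nucleus_records, focus_records, summary, info


def _read_manifest(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"dapi", "foci", "patient_id", "condition", "dose_Gy", "image_index"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    return frame


def run_pipeline(config: RunConfig) -> RunManifest:
    """Process every manifest entry and write masks, measurement CSVs and a manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = _read_manifest(config.manifest)
    nuclei_model = foci_model = None
    if not config.use_gt:
        if config.nuclei_model_dir is None or config.foci_model_dir is None:
            raise ValueError("model directories required unless use_gt is set")
        nuclei_model = load_model(config.nuclei_model_dir)
        foci_model = load_model(config.foci_model_dir)
    manifest = RunManifest(config_hash=config.config_hash())
    all_nuclei: list[NucleusRecord] = []
    all_foci: list[FocusRecord] = []
    summaries: list[ImageSummary] = []
    manifest_dir = Path(config.manifest).parent
    for _, row in frame.iterrows():
        meta = ImageMeta(str(row["patient_id"]), Condition(row["condition"]), float(row["dose_Gy"]), int(row["image_index"]))
        key = f"{meta.patient_id}_{meta.condition.value}_{meta.image_index}"
        result = ImageResult(meta=meta)
        t0 = time.perf_counter()
        try:
            def _resolve(p: str) -> Path:
                p = Path(p)
                return p if p.is_absolute() else manifest_dir / p

            dapi = read_zstack(_resolve(row["dapi"]), config.pixel_size_um, config.z_step_um, Channel.DAPI)
            foci = read_zstack(_resolve(row["foci"]), config.pixel_size_um, config.z_step_um, Channel.FOCI)
            if dapi.shape != foci.shape:
                raise ValueError(f"channel shape mismatch: {dapi.shape} vs {foci.shape}")
            gt_nuclei = gt_foci = None
            if config.use_gt:
                gt_nuclei = read_mask(_resolve(row["gt_nuclei"]), config.pixel_size_um, kind="labels")
                gt_foci = read_mask(_resolve(row["gt_foci"]), config.pixel_size_um, kind="semantic")
            nuc_recs, foc_recs, summary, info = process_scene(
                dapi,
                foci,
                nuclei_model=nuclei_model,
                foci_model=foci_model,
                gt_nuclei=gt_nuclei,
                gt_foci=gt_foci,
                postprocess_config=config.postprocess,
                threshold=config.threshold,
                projection_half_width=config.projection_half_width,
                meta=meta,
            )
            labels_path = write_mask(info["nuclei_labels"], out_dir / f"{key}_nuclei_labels.tif")
            foci_path = write_mask(info["foci_mask"], out_dir / f"{key}_foci_mask.tif")
            result.selected_index = info["selected_index"]
            result.projection_height_um = info["projection_height_um"]
            result.outputs = {"nuclei_labels": str(labels_path), "foci_mask": str(foci_path)}
            all_nuclei += nuc_recs
            all_foci += foc_recs
            summaries.append(summary)
            logger.info("image %s: %d nuclei, %d foci", key, len(nuc_recs), len(foc_recs))
        except Exception as e:  # noqa: BLE001 — per-image failures must not kill the run
            result.error = f"{type(e).__name__}: {e}"
            logger.error("image %s failed: %s", key, result.error)
        result.wall_time_s = time.perf_counter() - t0
        manifest.images.append(result)

    nuclei_csv = write_measurements(records_to_frame(all_nuclei), out_dir / "nuclei_measurements.csv")
    foci_csv = write_measurements(records_to_frame(all_foci), out_dir / "foci_measurements.csv")
    summary_rows = [
        {
            "patient_id": s.meta.patient_id,
            "condition": s.meta.condition.value,
            "image_index": s.meta.image_index,
            "n_nuclei": s.n_nuclei,
            "n_foci": s.n_foci,
            "mean_foci_per_um3": s.mean_foci_per_um3,
            "median_foci_per_um3": s.median_foci_per_um3,
            "mean_focus_area_um2": s.mean_focus_area_um2,
            "median_focus_area_um2": s.median_focus_area_um2,
            "projection_height_um": s.projection_height_um,
        }
        for s in summaries
    ]
    summary_csv = out_dir / "image_summaries.csv"
    pd.DataFrame(
        summary_rows,
        columns=[
            "patient_id", "condition", "image_index", "n_nuclei", "n_foci",
            "mean_foci_per_um3", "median_foci_per_um3", "mean_focus_area_um2",
            "median_focus_area_um2", "projection_height_um",
        ],
    ).to_csv(summary_csv, index=False, float_format="%.17g")
    manifest.outputs = {
        "nuclei_measurements": str(nuclei_csv),
        "foci_measurements": str(foci_csv),
        "image_summaries": str(summary_csv),
    }
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(
        json.dumps(
            {
                "config_hash": manifest.config_hash,
                "outputs": manifest.outputs,
                "images": [
                    {
                        "patient_id": r.meta.patient_id,
                        "condition": r.meta.condition.value,
                        "image_index": r.meta.image_index,
                        "selected_index": r.selected_index,
                        "projection_height_um": r.projection_height_um,
                        "outputs": r.outputs,
                        "wall_time_s": round(r.wall_time_s, 4),
                        "error": r.error,
                    }
                    for r in manifest.images
                ],
            },
            indent=2,
        )
    )
    return manifest
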