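"""Pipeline orchestration: acquire -> classify -> select -> detect ->
map -> calibrate -> position, with structured run reports.

The acquisition trigger of the original workflow (polling the vendor
GUI) is replaced by a file-based contract: a store directory with a
manifest is watched until the listed acquisition is complete, then
ingested with monotonically increasing image ids.  Everything else runs
against either a live store or an in-memory synthetic scene.

One seed in :class:`PipelineConfig` drives the scene, the stage noise
and any sampling, so two runs with the same config produce byte
identical report payloads.  No move command is ever emitted after a
stage error: the driver aborts and records the failing stage and cause.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifier import classify_stack, load_model
from .detector import Detection, baseline_detect, evaluate_detections, \
    fovea_x_from_detection
from .errors import AcquisitionError, FovelocError, ParameterError
from .geometry import ScanLineConfig, FoveaLocation, detect_scan_line, \
    fundus_px_to_mm, map_fovea_to_fundus
from .runs import select_central
from .scene import (FundusImage, OctVolume, Scene, SceneParams, SimulatedStage,
                    StageModel, generate_scene, load_scene)
from .stage import Calibration, calibrate, plan_move, position_target


@dataclass(frozen=True)
class StageConfig:
    true_steps_per_mm: tuple[float, float] = (80.0, 80.0)
    obs_noise_sd_mm: float = 0.0
    probe_steps: tuple[int, int] = (400, 400)
    calib_repeats: int = 5
    travel_limit_mm: float = 25.0
    n_average: int = 3


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of one automated sampling run."""

    scene: SceneParams = field(default_factory=SceneParams)
    scene_store: str | None = None  # ingest from disk instead of generating
    classifier_mode: str = "baseline"  # "baseline" | "model"
    model_path: str | None = None
    threshold: float = 0.5
    min_pit_depth_px: float = 6.0
    scanline: ScanLineConfig = field(default_factory=ScanLineConfig)
    stage: StageConfig = field(default_factory=StageConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier_mode not in ("baseline", "model"):
            raise ParameterError("classifier_mode: 'baseline' or 'model'")
        if self.classifier_mode == "model" and not self.model_path:
            raise ParameterError("model_path: required in model mode")


def _from_mapping(cls, data: dict):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if isinstance(value, dict):
            sub = {"scene": SceneParams, "scanline": ScanLineConfig,
                   "stage": StageConfig}.get(key)
            if sub is None:
                raise ParameterError(f"unexpected mapping for key '{key}'")
            value = _from_mapping(sub, value)
        elif isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_mapping(PipelineConfig, data)


def config_to_yaml(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(asdict(config))))


# --------------------------------------------------------------------------
# acquisition watcher


def watch_acquisition(store: str | Path, timeout_s: float = 10.0,
                      poll_s: float = 0.05) -> Scene:
    """Block until the acquisition in ``store`` is complete, then ingest.

    Completeness means: ``manifest.json`` exists and every file it lists
    exists with nonzero size.  Partial stacks are never ingested.  On
    ingest, images receive ids continuing after the store's persistent
    id registry, so re-runs never overwrite earlier identifiers.
    """
    store = Path(store)
    deadline = time.monotonic() + timeout_s
    while True:
        manifest_path = store / "manifest.json"
        if manifest_path.exists():
            try:
                manifest = json.loads(manifest_path.read_text())
                files = manifest["bscans"] + manifest["fundus"] + [manifest["meta"]]
                if all((store / f).exists() and (store / f).stat().st_size > 0
                       for f in files):
                    break
            except (json.JSONDecodeError, KeyError):
                pass  # manifest still being written
        if time.monotonic() >= deadline:
            raise AcquisitionError(f"{store}: acquisition incomplete after "
                                   f"{timeout_s:.1f}s")
        time.sleep(poll_s)

    scene = load_scene(store)
    registry = store / "ids.json"
    next_id = 1
    if registry.exists():
        next_id = int(json.loads(registry.read_text())["max_id"]) + 1
    ids = list(range(next_id, next_id + len(scene.volume)))
    scene.volume.ids = ids
    registry.write_text(json.dumps({"max_id": ids[-1]}))
    return scene


# --------------------------------------------------------------------------
# run report


@dataclass
class RunReport:
    """Everything one automated sampling run produced or why it aborted."""

    image_ids: list[int]
    probabilities: list[float] | None
    flags: list[bool] | None
    selection: dict | None
    detection: dict | None
    scanline: dict | None
    fovea_location: dict | None
    calibration: dict | None
    move_command: dict | None
    residual_offset_mm: list[float] | None
    localization_error_mm: float | None
    truth_fovea_mm: list[float] | None
    aborted: bool
    abort_stage: str | None
    abort_reason: str | None
    fingerprint: dict = field(default_factory=dict)

    def payload_bytes(self) -> bytes:
        """Canonical JSON payload (no timestamps; byte-reproducible)."""
        return json.dumps(_jsonable(asdict(self)), sort_keys=True,
                          separators=(",", ":")).encode()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(_jsonable(asdict(self)), indent=2,
                                         sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def _config_fingerprint(config: PipelineConfig) -> dict:
    blob = json.dumps(_jsonable(asdict(config)), sort_keys=True)
    return {"version": __version__,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest()}


# --------------------------------------------------------------------------
# pipeline driver


def run_pipeline(config: PipelineConfig, scene: Scene | None = None,
                 model=None) -> RunReport:
    """Execute the full locate-and-position flow; abort-safe.

    ``scene`` and ``model`` may be passed pre-built (tests, CLI reuse);
    otherwise the scene comes from the config (store or generator) and
    the model from ``config.model_path``.
    """
    report = RunReport(image_ids=[], probabilities=None, flags=None,
                       selection=None, detection=None, scanline=None,
                       fovea_location=None, calibration=None,
                       move_command=None, residual_offset_mm=None,
                       localization_error_mm=None, truth_fovea_mm=None,
                       aborted=False, abort_stage=None, abort_reason=None,
                       fingerprint=_config_fingerprint(config))

    def abort(stage_name: str, exc: Exception) -> RunReport:
        report.aborted = True
        report.abort_stage = stage_name
        report.abort_reason = f"{type(exc).__name__}: {exc}"
        return report

    # --- acquire -----------------------------------------------------
    try:
        if scene is None:
            if config.scene_store is not None:
                scene = watch_acquisition(config.scene_store)
            else:
                params = dataclasses.replace(config.scene, seed=config.seed)
                scene = generate_scene(params)
        volume, fundus, truth = scene.volume, scene.fundus, scene.truth
        report.image_ids = list(volume.ids)
        if truth is not None:
            report.truth_fovea_mm = list(truth.fovea_mm)
    except FovelocError as exc:
        return abort("acquire", exc)

    # --- classify ----------------------------------------------------
    try:
        if config.classifier_mode == "model":
            mdl = model
            if mdl is None:
                mdl, _spec = load_model(config.model_path)
            flags, probs = classify_stack(volume, mdl, config.threshold)
        else:
            dets = [baseline_detect(b, config.min_pit_depth_px)
                    for b in volume.bscans]
            flags = [d is not None for d in dets]
            probs = np.array([d.confidence if d else 0.0 for d in dets])
        report.flags = [bool(f) for f in flags]
        report.probabilities = [float(p) for p in probs]
    except FovelocError as exc:
        return abort("classify", exc)

    # --- select longest positive run ---------------------------------
    try:
        selection = select_central(flags)
        report.selection = asdict(selection)
    except FovelocError as exc:
        return abort("select", exc)

    # --- detect the pit in the central image -------------------------
    try:
        central = selection.central_index
        detection = baseline_detect(volume.bscans[central],
                                    config.min_pit_depth_px)
        if detection is None:
            raise FovelocError("no pit found in the selected central image")
        report.detection = {"box": list(detection.box),
                            "confidence": detection.confidence,
                            "class_label": detection.class_label,
                            "bscan_index": central}
        bscan_col = fovea_x_from_detection(detection)
    except FovelocError as exc:
        return abort("detect", exc)

    # --- locate on the fundus and convert to mm ----------------------
    try:
        fimg = fundus[central]
        fit = detect_scan_line(fimg, config.scanline)
        report.scanline = asdict(fit)
        row, col = map_fovea_to_fundus(bscan_col, volume.bscans[central].shape[1],
                                       fit, fimg.scan_col_start,
                                       fimg.scan_col_end)
        reference_px = truth.reference_px if truth is not None \
            else scene.layout.reference_px
        mm = fundus_px_to_mm((row, col), reference_px, fimg.mm_per_px)
        location = FoveaLocation(fundus_px=(row, col),
                                 physical_mm=(float(mm[0]), float(mm[1])),
                                 source_bscan=central)
        report.fovea_location = asdict(location)
    except FovelocError as exc:
        return abort("locate", exc)

    # --- calibrate the stage and position the target -----------------
    try:
        sc = config.stage
        stage_seed = int(np.random.SeedSequence([config.seed, 0xC411]
                                                ).generate_state(1)[0] % (2**31))
        model_stage = StageModel(true_steps_per_mm=sc.true_steps_per_mm,
                                 obs_noise_sd_mm=sc.obs_noise_sd_mm,
                                 seed=stage_seed)
        true_mm = truth.fovea_mm if truth is not None else location.physical_mm
        sim = SimulatedStage(model_stage, true_mm)
        cal = calibrate(sim, sc.probe_steps, sc.calib_repeats, sc.n_average)
        report.calibration = asdict(cal)

        limit = tuple(int(np.floor(sc.travel_limit_mm * s))
                      for s in cal.steps_per_mm)
        cmd = plan_move(np.asarray(location.physical_mm), cal, limit)
        report.move_command = {"steps": list(cmd.steps)}
        sim.move_steps(np.asarray(cmd.steps))
        residual = position_target(sim, cal, travel_limit_steps=limit,
                                   n_average=sc.n_average)
        report.residual_offset_mm = [float(residual[0]), float(residual[1])]
        if truth is not None:
            spm = np.asarray(model_stage.true_steps_per_mm, dtype=float)
            true_residual = (np.asarray(truth.fovea_mm)
                             - model_stage.position_steps / spm)
            report.localization_error_mm = float(np.linalg.norm(true_residual))
    except FovelocError as exc:
        return abort("position", exc)

    return report


# --------------------------------------------------------------------------
# metrics over many runs


def summarize_metrics(reports: list[RunReport],
                      scenes: list[Scene] | None = None,
                      iou_threshold: float = 0.5) -> dict:
    """Aggregate run reports into the headline pipeline metrics.

    Returns success rate (fraction of non-aborted runs), localization
    error mean +/- sample SD over successful runs with ground truth,
    per-B-scan classification accuracy against scene truth, and
    detection precision/recall of the central-image detection against
    the true pit box (runs that selected the wrong B-scan count as one
    false positive plus one missed fovea).
    """
    if not reports:
        raise ParameterError("reports: need at least one run report")
    n = len(reports)
    successes = [r for r in reports if not r.aborted]
    out: dict = {"n_runs": n, "success_rate": len(successes) / n}

    errors = [r.localization_error_mm for r in successes
              if r.localization_error_mm is not None]
    if errors:
        out["localization_error_mean_mm"] = float(np.mean(errors))
        out["localization_error_sd_mm"] = (float(np.std(errors, ddof=1))
                                           if len(errors) > 1 else 0.0)
    else:
        out["localization_error_mean_mm"] = None
        out["localization_error_sd_mm"] = None

    if scenes is not None:
        if len(scenes) != n:
            raise ParameterError("scenes: must align with reports")
        correct = total = 0
        preds, truths = [], []
        for r, s in zip(reports, scenes):
            truth_flags = [k in set(s.truth.positive_indices)
                           for k in range(len(s.volume))]
            if r.flags is not None:
                correct += sum(f == t for f, t in zip(r.flags, truth_flags))
                total += len(truth_flags)
            if r.detection is not None and s.truth.fovea_box is not None:
                det = Detection(box=tuple(r.detection["box"]),
                                confidence=r.detection["confidence"])
                on_fovea = (r.detection["bscan_index"]
                            == s.truth.fovea_bscan_index)
                preds.append([det])
                truths.append([s.truth.fovea_box] if on_fovea else [])
                if not on_fovea:
                    preds.append([])
                    truths.append([s.truth.fovea_box])
        out["classification_accuracy"] = correct / total if total else None
        if preds:
            p, r_ = evaluate_detections(preds, truths, iou_threshold)
            out["detection_precision"], out["detection_recall"] = p, r_
        else:
            out["detection_precision"] = out["detection_recall"] = None
    return out
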