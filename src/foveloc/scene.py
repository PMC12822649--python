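"""Synthetic eyecup imagery with exact ground truth.

This module emulates what a vertically mounted Spectralis-style OCT
produces when imaging an ex vivo human eyecup: an ordered stack of
cross-sectional B-scans rastered across the posterior pole, and, for each
B-scan, an en-face fundus image carrying the rendered green line that
marks where that B-scan was taken.  A foveal pit of configurable depth
and width is rendered as a local thinning of the inner retinal layers,
and every quantity a downstream stage must recover (which B-scans cross
the pit, the pit column in the central B-scan, the fundus pixel and the
physical millimetre position of the fovea relative to a reference
marker) is computed analytically at generation time and returned as
:class:`SceneTruth`.

A simulated two-axis stepper stage (:class:`StageModel`) with a known
steps-per-mm constant and optional Gaussian observation noise closes the
loop: it lets calibration and targeting be exercised end to end without
hardware.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``.
* Physical coordinates are millimetres in the en-face plane,
  ``x`` along columns and ``y`` along rows, origin at the reference
  marker (the small retinal impression used to register the punch axis
  against the imaging axis).
* B-scan acquisition order maps to increasing fundus row.
* The same :class:`SceneParams` (including ``seed``) always produces
  bit-identical pixel arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ParameterError

_BG = 0.05          # vitreous / sub-retinal background intensity
_SURFACE_FRAC = 0.28  # inner retinal surface sits at this fraction of B-scan rows

_FUNDUS_BASE = (0.55, 0.34, 0.22)   # dull reddish retina background
_MARKER_COLOR = (0.15, 0.08, 0.06)  # dark impression left by the reference punch
_LINE_COLOR = (0.05, 0.85, 0.10)    # rendered green scan-line overlay
_LINE_HALFWIDTH = 1                 # scan line drawn 3 px thick (clipped symmetric)

_GAUSS_K = 4.0 * np.log(2.0)  # FWHM-parameterized Gaussian: exp(-K (d/w)^2)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic eyecup scene.

    ``fovea_center`` is ``(x_mm, y_mm)`` relative to the reference
    marker.  ``pit_width`` is the full width of the pit at half depth;
    ``pit_depth`` is the maximum inner-surface depression.  The layer
    profile lists ``(thickness_mm, brightness)`` pairs from the inner
    surface outward; the pit thins the innermost layers while deeper
    layer boundaries stay fixed, which is what a foveal pit looks like
    in a real B-scan (inner-layer displacement over a continuous
    photoreceptor layer).
    """

    fovea_center: tuple[float, float] = (0.8, 1.2)
    pit_depth: float = 0.10
    pit_width: float = 0.8
    n_bscans: int = 61
    bscan_shape: tuple[int, int] = (196, 256)
    fundus_shape: tuple[int, int] = (288, 384)
    mm_per_px_fundus: float = 0.025
    mm_per_px_bscan_x: float = 0.0125
    mm_per_px_bscan_row: float = 0.0055
    bscan_spacing_mm: float = 0.1
    layer_profile: tuple[tuple[float, float], ...] = (
        (0.12, 0.90),
        (0.05, 0.40),
        (0.06, 0.70),
        (0.08, 0.35),
        (0.07, 0.60),
    )
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class OctVolume:
    """Ordered B-scan stack with pixel scaling and per-image ids."""

    bscans: list[np.ndarray]
    ids: list[int]
    mm_per_px_x: float
    spacing_mm: float

    def __post_init__(self) -> None:
        if len(self.bscans) != len(self.ids):
            raise ParameterError("ids: one id per B-scan required")
        if any(b <= a for a, b in zip(self.ids, self.ids[1:])):
            raise ParameterError("ids: must be strictly increasing and unique")
        shapes = {b.shape for b in self.bscans}
        if len(shapes) > 1:
            raise ParameterError("bscans: all images must share one shape")

    def __len__(self) -> int:
        return len(self.bscans)


@dataclass
class FundusImage:
    """En-face RGB image with the rendered scan-line overlay metadata."""

    pixels: np.ndarray
    scanline_row: int
    scan_col_start: int
    scan_col_end: int
    mm_per_px: float

    def __post_init__(self) -> None:
        rows = self.pixels.shape[0]
        if not 0 <= self.scanline_row < rows:
            raise ParameterError("scanline_row: outside image")
        if not self.scan_col_start < self.scan_col_end:
            raise ParameterError("scan_col_start: must be < scan_col_end")


@dataclass
class SceneTruth:
    """Exact ground truth of a generated scene.

    ``fovea_bscan_index`` is ``None`` when the fovea lies outside the
    rastered scan region (then ``positive_indices`` is empty and the
    pipeline is expected to abort with a no-fovea error).
    ``fovea_box`` is the ground-truth bounding box of the pit in the
    fovea B-scan, half-open ``(row_min, col_min, row_max, col_max)``.
    """

    fovea_bscan_index: int | None
    fovea_col_px: int
    fovea_fundus_px: tuple[int, int]
    fovea_mm: tuple[float, float]
    positive_indices: tuple[int, ...]
    reference_px: tuple[int, int]
    fovea_box: tuple[int, int, int, int] | None


@dataclass(frozen=True)
class SceneLayout:
    """Raster geometry derived from :class:`SceneParams`."""

    scan_col_start: int
    scan_col_end: int
    scanline_rows: tuple[int, ...]
    reference_px: tuple[int, int]
    x_left_mm: float  # en-face x of B-scan column 0, relative to the marker


@dataclass
class Scene:
    params: SceneParams
    volume: OctVolume
    fundus: list[FundusImage]
    truth: SceneTruth
    layout: SceneLayout

    def __iter__(self):
        # allow  volume, fundus, truth = generate_scene(...)
        return iter((self.volume, self.fundus, self.truth))


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{field_name}: {msg}")


def compute_layout(params: SceneParams) -> SceneLayout:
    """Validate params and derive the fundus raster geometry."""
    p = params
    _require(p.n_bscans >= 1, "n_bscans", "must be >= 1")
    for name in ("mm_per_px_fundus", "mm_per_px_bscan_x", "mm_per_px_bscan_row",
                 "bscan_spacing_mm"):
        _require(getattr(p, name) > 0, name, "must be > 0")
    _require(p.pit_depth >= 0, "pit_depth", "must be >= 0")
    _require(p.pit_width >= 0, "pit_width", "must be >= 0")
    _require(p.noise_sd >= 0, "noise_sd", "must be >= 0")
    _require(len(p.layer_profile) > 0, "layer_profile", "must be non-empty")
    total_thickness = sum(t for t, _ in p.layer_profile)
    _require(all(t > 0 for t, _ in p.layer_profile),
             "layer_profile", "thicknesses must be > 0")
    _require(p.pit_depth < total_thickness,
             "pit_depth", "must be smaller than total retinal thickness")

    h, w = p.fundus_shape
    br, bc = p.bscan_shape
    _require(br >= 8 and bc >= 8, "bscan_shape", "too small to render layers")

    spacing_px = p.bscan_spacing_mm / p.mm_per_px_fundus
    _require(p.n_bscans == 1 or spacing_px >= 1.0,
             "bscan_spacing_mm", "raster rows would not be strictly increasing")

    scan_width_px = int(round(bc * p.mm_per_px_bscan_x / p.mm_per_px_fundus))
    _require(1 <= scan_width_px <= w,
             "mm_per_px_bscan_x", "scan line wider than the fundus image")
    scan_col_start = (w - scan_width_px) // 2
    scan_col_end = scan_col_start + scan_width_px

    span = (p.n_bscans - 1) * spacing_px
    row_first = int(round((h - 1 - span) / 2))
    rows = tuple(row_first + int(round(k * spacing_px)) for k in range(p.n_bscans))
    _require(0 <= rows[0] and rows[-1] < h,
             "n_bscans", "scan raster does not fit in the fundus image")

    ref_row = int(round(row_first + (p.n_bscans - 1) / 2 * spacing_px))
    ref_col = (scan_col_start + scan_col_end) // 2
    x_left_mm = (scan_col_start - ref_col) * p.mm_per_px_fundus

    # fovea must lie within the B-scan x extent and the fundus frame
    fx, fy = p.fovea_center
    _require(x_left_mm <= fx <= x_left_mm + (bc - 1) * p.mm_per_px_bscan_x,
             "fovea_center", "x outside the scanned B-scan extent")
    fovea_row = ref_row + int(round(fy / p.mm_per_px_fundus))
    _require(0 <= fovea_row < h, "fovea_center", "y outside the fundus frame")

    return SceneLayout(scan_col_start, scan_col_end, rows,
                       (ref_row, ref_col), x_left_mm)


def _pit_gain(d: np.ndarray | float, width: float) -> np.ndarray | float:
    """Gaussian pit profile, parameterized by full width at half depth."""
    if width == 0.0:
        return np.where(np.abs(np.asarray(d, dtype=float)) < 1e-12, 1.0, 0.0)
    return np.exp(-_GAUSS_K * (np.asarray(d, dtype=float) / width) ** 2)


def _layer_boundaries_px(params: SceneParams, base_row: int) -> list[int]:
    bounds = [base_row]
    acc = 0.0
    for thickness, _ in params.layer_profile:
        acc += thickness
        bounds.append(base_row + int(round(acc / params.mm_per_px_bscan_row)))
    return bounds


def render_bscan(params: SceneParams, layout: SceneLayout, k: int,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render B-scan ``k`` of the raster as a float32 image in [0, 1]."""
    p = params
    rows, cols = p.bscan_shape
    fx, fy = p.fovea_center
    y_k = (layout.scanline_rows[k] - layout.reference_px[0]) * p.mm_per_px_fundus
    x = layout.x_left_mm + np.arange(cols) * p.mm_per_px_bscan_x

    depth_mm = p.pit_depth * _pit_gain(fy - y_k, p.pit_width)
    dip_px = np.rint(depth_mm * _pit_gain(x - fx, p.pit_width)
                     / p.mm_per_px_bscan_row).astype(int)

    base_row = int(round(_SURFACE_FRAC * rows))
    bounds = _layer_boundaries_px(p, base_row)
    profile = np.full(rows, _BG, dtype=np.float32)
    for (lo, hi), (_, bright) in zip(zip(bounds, bounds[1:]), p.layer_profile):
        profile[max(lo, 0):max(min(hi, rows), 0)] = bright

    img = np.tile(profile[:, None], (1, cols))
    surface = base_row + dip_px  # pit thins inner layers; deep boundaries fixed
    img[np.arange(rows)[:, None] < surface[None, :]] = _BG
    if p.noise_sd > 0 and rng is not None:
        img = img + rng.normal(0.0, p.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def render_fundus(params: SceneParams, layout: SceneLayout, k: int,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Render the en-face fundus image shown while acquiring B-scan ``k``."""
    p = params
    h, w = p.fundus_shape
    img = np.empty((h, w, 3), dtype=np.float32)
    img[...] = _FUNDUS_BASE

    rr, cc = layout.reference_px
    yy, xx = np.ogrid[:h, :w]
    img[(yy - rr) ** 2 + (xx - cc) ** 2 <= 2 ** 2] = _MARKER_COLOR

    r = layout.scanline_rows[k]
    hw = min(_LINE_HALFWIDTH, r, h - 1 - r)  # keep the stripe symmetric at borders
    img[r - hw:r + hw + 1, layout.scan_col_start:layout.scan_col_end] = _LINE_COLOR

    if p.noise_sd > 0 and rng is not None:
        img = img + rng.normal(0.0, p.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def _truth(params: SceneParams, layout: SceneLayout) -> SceneTruth:
    p = params
    fx, fy = p.fovea_center
    ref_row, ref_col = layout.reference_px
    rows = np.asarray(layout.scanline_rows)
    y_scan = (rows - ref_row) * p.mm_per_px_fundus

    half = p.pit_width / 2 + 1e-12
    positives = tuple(int(k) for k in np.nonzero(np.abs(y_scan - fy) <= half)[0])
    if positives:
        d = np.abs(y_scan - fy)
        fovea_k: int | None = int(np.argmin(d))
    else:
        fovea_k = None

    fovea_col = int(round((fx - layout.x_left_mm) / p.mm_per_px_bscan_x))
    fovea_fundus = (ref_row + int(round(fy / p.mm_per_px_fundus)),
                    ref_col + int(round(fx / p.mm_per_px_fundus)))

    box = None
    if fovea_k is not None:
        br, bc = p.bscan_shape
        base_row = int(round(_SURFACE_FRAC * br))
        depth_px = max(1, int(round(p.pit_depth / p.mm_per_px_bscan_row)))
        half_w_px = max(1, int(round(p.pit_width / 2 / p.mm_per_px_bscan_x)))
        box = (max(0, base_row), max(0, fovea_col - half_w_px),
               min(br, base_row + depth_px + 1), min(bc, fovea_col + half_w_px + 1))

    return SceneTruth(
        fovea_bscan_index=fovea_k,
        fovea_col_px=fovea_col,
        fovea_fundus_px=fovea_fundus,
        fovea_mm=(float(fx), float(fy)),
        positive_indices=positives,
        reference_px=(ref_row, ref_col),
        fovea_box=box,
    )


def generate_scene(params: SceneParams) -> Scene:
    """Generate a full synthetic scene (B-scan stack, fundus set, truth).

    Deterministic: the same ``params`` (including ``params.seed``) yield
    bit-identical pixel arrays.
    """
    layout = compute_layout(params)
    ss = np.random.SeedSequence(params.seed)
    rng_oct, rng_fundus = (np.random.default_rng(s) for s in ss.spawn(2))

    bscans = [render_bscan(params, layout, k, rng_oct)
              for k in range(params.n_bscans)]
    fundus = [FundusImage(render_fundus(params, layout, k, rng_fundus),
                          scanline_row=layout.scanline_rows[k],
                          scan_col_start=layout.scan_col_start,
                          scan_col_end=layout.scan_col_end,
                          mm_per_px=params.mm_per_px_fundus)
              for k in range(params.n_bscans)]
    volume = OctVolume(bscans=bscans, ids=list(range(1, params.n_bscans + 1)),
                       mm_per_px_x=params.mm_per_px_bscan_x,
                       spacing_mm=params.bscan_spacing_mm)
    return Scene(params, volume, fundus, _truth(params, layout), layout)


def snap_fovea_to_scanline(params: SceneParams, k: int) -> SceneParams:
    """Return params with the fovea y moved exactly onto scan line ``k``."""
    layout = compute_layout(params)
    y = (layout.scanline_rows[k] - layout.reference_px[0]) * params.mm_per_px_fundus
    return SceneParams(**{**asdict(params),
                          "fovea_center": (params.fovea_center[0], float(y))})


def make_labeled_bscans(n_pos: int, n_neg: int, seed: int = 0,
                        noise_sd: float = 0.02,
                        base: SceneParams | None = None,
                        ) -> tuple[list[np.ndarray], np.ndarray]:
    """Generate a labeled classifier training set of single B-scans.

    Positives are fovea-crossing B-scans with randomized pit position,
    width and depth; negatives are pit-free scans of the same retina.
    Returns ``(images, labels)`` with label 1 for fovea.
    """
    base = base or SceneParams()
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        depth = float(rng.uniform(0.08, 0.12)) if positive else 0.0
        width = float(rng.uniform(0.6, 1.0))
        fx = float(rng.uniform(-1.2, 1.2))
        params = SceneParams(**{**asdict(base),
                                "fovea_center": (fx, 0.0),
                                "pit_depth": depth,
                                "pit_width": width,
                                "n_bscans": 1,
                                "noise_sd": noise_sd,
                                "seed": int(rng.integers(2 ** 31))})
        layout = compute_layout(params)
        img_rng = np.random.default_rng(params.seed)
        images.append(render_bscan(params, layout, 0, img_rng))
        labels.append(1.0 if positive else 0.0)
    return images, np.asarray(labels, dtype=np.float32)


# --------------------------------------------------------------------------
# simulated stepper stage


@dataclass
class StageModel:
    """Two-axis stepper stage with integer step positions.

    ``observe`` reports the fovea's apparent offset from the punch axis:
    moving the stage by a positive step count shifts the observed fovea
    in the negative direction of that axis (the stage carries the sample
    under a fixed optical/punch axis).
    """

    true_steps_per_mm: tuple[float, float] = (80.0, 80.0)
    position_steps: np.ndarray = field(
        default_factory=lambda: np.zeros(2, dtype=np.int64))
    obs_noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        spm = np.asarray(self.true_steps_per_mm, dtype=float)
        if spm.shape != (2,) or np.any(spm <= 0):
            raise ParameterError("true_steps_per_mm: two positive components required")
        if self.obs_noise_sd_mm < 0:
            raise ParameterError("obs_noise_sd_mm: must be >= 0")
        self.position_steps = np.asarray(self.position_steps, dtype=np.int64).copy()
        self._rng = np.random.default_rng(self.seed)

    def move_steps(self, steps) -> None:
        steps = np.asarray(steps)
        if steps.shape != (2,) or not np.issubdtype(steps.dtype, np.integer):
            raise ParameterError("steps: two integer components required")
        self.position_steps = self.position_steps + steps.astype(np.int64)


def simulate_observation(stage: StageModel, fovea_mm) -> np.ndarray:
    """Observe the fovea offset (mm) through the simulated stage.

    Returns ``fovea_mm - position_steps / true_steps_per_mm`` plus
    zero-mean Gaussian noise of sd ``obs_noise_sd_mm`` (exact when the
    noise sd is zero).
    """
    fovea_mm = np.asarray(fovea_mm, dtype=float)
    spm = np.asarray(stage.true_steps_per_mm, dtype=float)
    obs = fovea_mm - stage.position_steps / spm
    if stage.obs_noise_sd_mm > 0:
        obs = obs + stage._rng.normal(0.0, stage.obs_noise_sd_mm, 2)
    return obs


class SimulatedStage:
    """Stage interface (``move_steps`` / ``observe_fovea``) over a model.

    This is the contract the calibration and positioning routines are
    written against; a hardware backend would implement the same two
    methods.
    """

    def __init__(self, model: StageModel, fovea_mm) -> None:
        self.model = model
        self.fovea_mm = np.asarray(fovea_mm, dtype=float)

    def move_steps(self, steps) -> None:
        self.model.move_steps(steps)

    def observe_fovea(self, n_average: int = 1) -> np.ndarray:
        obs = [simulate_observation(self.model, self.fovea_mm)
               for _ in range(max(1, n_average))]
        return np.mean(obs, axis=0)


# --------------------------------------------------------------------------
# scene persistence (8-bit PNGs + JSON ground truth + manifest)


def _to_u8(img: np.ndarray) -> np.ndarray:
    return np.rint(np.clip(img, 0, 1) * 255).astype(np.uint8)


def from_u8(img: np.ndarray) -> np.ndarray:
    return (img.astype(np.float32) / 255.0)


def save_scene(scene: Scene, out_dir: str | Path) -> Path:
    """Write a scene store: PNG images, JSON truth/meta and a manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bscan_files, fundus_files = [], []
    for i, (b, f) in enumerate(zip(scene.volume.bscans, scene.fundus)):
        bname, fname = f"bscan_{i:03d}.png", f"fundus_{i:03d}.png"
        iio.imwrite(out / bname, _to_u8(b))
        iio.imwrite(out / fname, _to_u8(f.pixels))
        bscan_files.append(bname)
        fundus_files.append(fname)

    meta = {
        "params": asdict(scene.params),
        "truth": asdict(scene.truth),
        "layout": asdict(scene.layout),
        "ids": scene.volume.ids,
    }
    (out / "scene.json").write_text(json.dumps(meta, indent=2))
    manifest = {"bscans": bscan_files, "fundus": fundus_files,
                "meta": "scene.json"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_scene(store: str | Path) -> Scene:
    """Load a scene store written by :func:`save_scene`.

    Pixel data are the 8-bit quantized images; truth and geometry are
    exact from the JSON sidecar.
    """
    import imageio.v3 as iio

    store = Path(store)
    manifest = json.loads((store / "manifest.json").read_text())
    meta = json.loads((store / manifest["meta"]).read_text())
    meta["params"]["fovea_center"] = tuple(meta["params"]["fovea_center"])
    meta["params"]["bscan_shape"] = tuple(meta["params"]["bscan_shape"])
    meta["params"]["fundus_shape"] = tuple(meta["params"]["fundus_shape"])
    meta["params"]["layer_profile"] = tuple(
        tuple(lp) for lp in meta["params"]["layer_profile"])
    params = SceneParams(**meta["params"])
    layout = SceneLayout(
        scan_col_start=meta["layout"]["scan_col_start"],
        scan_col_end=meta["layout"]["scan_col_end"],
        scanline_rows=tuple(meta["layout"]["scanline_rows"]),
        reference_px=tuple(meta["layout"]["reference_px"]),
        x_left_mm=meta["layout"]["x_left_mm"],
    )
    t = meta["truth"]
    truth = SceneTruth(
        fovea_bscan_index=t["fovea_bscan_index"],
        fovea_col_px=t["fovea_col_px"],
        fovea_fundus_px=tuple(t["fovea_fundus_px"]),
        fovea_mm=tuple(t["fovea_mm"]),
        positive_indices=tuple(t["positive_indices"]),
        reference_px=tuple(t["reference_px"]),
        fovea_box=tuple(t["fovea_box"]) if t["fovea_box"] else None,
    )
    bscans = [from_u8(iio.imread(store / f)) for f in manifest["bscans"]]
    fundus = [FundusImage(from_u8(iio.imread(store / f)),
                          scanline_row=layout.scanline_rows[i],
                          scan_col_start=layout.scan_col_start,
                          scan_col_end=layout.scan_col_end,
                          mm_per_px=params.mm_per_px_fundus)
              for i, f in enumerate(manifest["fundus"])]
    volume = OctVolume(bscans=bscans, ids=list(meta["ids"]),
                       mm_per_px_x=params.mm_per_px_bscan_x,
                       spacing_mm=params.bscan_spacing_mm)
    return Scene(params, volume, fundus, truth, layout)
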