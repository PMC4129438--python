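"""Synthetic fluorescence stacks and burst-period sequences.

Every downstream stage of the pipeline is testable without real data.  This
module fabricates (a) 12-bit multi-plane fluorescence "phantom" stacks of the
bilateral detection domain — soma-like bright discs plus dendrite shafts and
auto-fluorescent debris, with full ground truth — and (b) cycle-period
sequences with either stable (multiplicatively jittered) periods or a
bi-exponential slowing drift like that of a progressively lesioned slice.

Geometry follows the imaging rig being emulated: two disjoint 412 x 412 um
hemi-fields (left/right), focal planes every 10 um of depth (plane 0 at the
surface), intensities on the 12-bit range [0, 4095].  The preBotzinger-complex
preset places 26-50 somata per focal plane per side.

Shape classes are constructed to be separable by the downstream circularity
cutoff of 0.75: somata are Gaussian-profiled discs truncated at half maximum
(near-circular masks), dendrites are thin rectangles with aspect ratio >= 5,
and debris are spiky star polygons; both of the latter score well below the
cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from skimage.draw import polygon as draw_polygon

__all__ = [
    "ImageStack",
    "GroundTruthObject",
    "StackConfig",
    "PREBOTC_PRESET",
    "make_stack",
    "make_period_sequence",
    "biexponential_params",
    "write_stack",
    "read_stack",
    "write_ground_truth",
]

MAX_INTENSITY = 4095  # 12-bit
DEFAULT_PIXEL_SIZE_UM = 0.8
DEFAULT_Z_STEP_UM = 10.0
DEFAULT_FIELD_EXTENT_UM = 412.0
NOMINAL_PEAK = 3000.0


@dataclass
class ImageStack:
    """Ordered focal planes of 12-bit intensities; plane 0 is the slice
    surface and depth increases with plane index (``depth = index * z_step``).

    ``planes`` has shape (n_planes, height, width); the left hemi-field
    occupies x in [0, field_extent) um and the right hemi-field the adjacent
    window of equal width.
    """

    planes: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    field_extent_um: float = DEFAULT_FIELD_EXTENT_UM

    def __post_init__(self):
        p = np.asarray(self.planes)
        if p.ndim != 3 or p.shape[0] < 1:
            raise ValueError("stack needs >= 1 plane of identical 2-D grids")
        if p.min() < 0 or p.max() > MAX_INTENSITY:
            raise ValueError("intensities must lie in [0, 4095]")
        self.planes = p.astype(np.uint16)

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    def depth_of_plane(self, index: int) -> float:
        return index * self.z_step_um

    def side_of_x(self, x_um: float) -> str:
        return "left" if x_um < self.field_extent_um else "right"


@dataclass
class GroundTruthObject:
    """One rendered object with its truth record.

    ``kind`` is soma / dendrite / debris; ``center`` is (x um, y um, plane
    index of the deepest footprint); ``plane_span`` lists every plane the
    object intersects (contiguous); ``params`` are shape parameters (radius_um
    for somata; length_um/width_um/angle for dendrites; star radii seed for
    debris).
    """

    kind: str
    center: tuple
    side: str
    plane_span: list
    params: dict = field(default_factory=dict)


@dataclass
class StackConfig:
    count_range: tuple = (26, 50)  # somata per focal plane per side
    n_planes: int = 8
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    field_extent_um: float = DEFAULT_FIELD_EXTENT_UM
    dendrite_fraction: float = 0.25  # relative to soma count
    debris_fraction: float = 0.15
    two_plane_fraction: float = 0.25  # somata duplicated in the shallower plane
    soma_radius_um: tuple = (3.5, 5.5)
    psbr: float | None = None  # peak-signal-to-background ratio; None = noiseless
    seed: int = 0

    def validate(self):
        lo, hi = self.count_range
        if not (1 <= lo <= hi <= 200):
            raise ValueError("counts-per-plane range must lie within [1, 200]")
        if self.n_planes < 1:
            raise ValueError("need at least one focal plane")
        for name in ("dendrite_fraction", "debris_fraction", "two_plane_fraction"):
            f = getattr(self, name)
            if not 0 <= f <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.psbr is not None and self.psbr <= 0:
            raise ValueError("peak-signal-to-background ratio must be positive")
        # rough packing bound: each soma needs ~pi*(r+gap)^2 of field area
        rmax = self.soma_radius_um[1]
        need = hi * np.pi * (2 * rmax + 4.0) ** 2
        if need > 0.5 * self.field_extent_um**2:
            raise ValueError("field too small for the requested counts")


#: study conditions of the bilateral preBotzinger-complex detection domain
PREBOTC_PRESET = StackConfig()


# ---------------------------------------------------------------- rendering

def _render_soma(canvas, cx_px, cy_px, r_px, peak):
    """Gaussian-profiled disc truncated at half maximum (sharp-edged mask)."""
    h, w = canvas.shape
    sigma = r_px / np.sqrt(2 * np.log(2))
    r_int = int(np.ceil(r_px)) + 1
    y0, y1 = max(0, int(cy_px) - r_int), min(h, int(cy_px) + r_int + 1)
    x0, x1 = max(0, int(cx_px) - r_int), min(w, int(cx_px) + r_int + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy_px) ** 2 + (xx - cx_px) ** 2
    prof = peak * np.exp(-d2 / (2 * sigma**2))
    prof[d2 > r_px**2] = 0.0  # half-max truncation
    np.maximum(canvas[y0:y1, x0:x1], prof, out=canvas[y0:y1, x0:x1])


def _render_polygon(canvas, xs_px, ys_px, value):
    """Fill a polygon, keeping only its dominant 4-connected component so a
    rasterized spike tip can never shed an isolated stray pixel."""
    from scipy import ndimage

    rr, cc = draw_polygon(ys_px, xs_px, shape=canvas.shape)
    if rr.size == 0:
        return
    mask = np.zeros(canvas.shape, dtype=bool)
    mask[rr, cc] = True
    lab, n = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (1 + int(np.argmax(sizes)))
        rr, cc = np.nonzero(mask)
    canvas[rr, cc] = np.maximum(canvas[rr, cc], value)


def _dendrite_corners(cx, cy, length, width, angle):
    dx, dy = np.cos(angle), np.sin(angle)
    px, py = -dy, dx
    hl, hw = length / 2, width / 2
    xs = np.array([cx - hl * dx - hw * px, cx + hl * dx - hw * px,
                   cx + hl * dx + hw * px, cx - hl * dx + hw * px])
    ys = np.array([cy - hl * dy - hw * py, cy + hl * dy - hw * py,
                   cy + hl * dy + hw * py, cy - hl * dy + hw * py])
    return xs, ys


def _star_vertices(cx, cy, radii, phase):
    k = radii.size
    ang = phase + np.linspace(0, 2 * np.pi, k, endpoint=False)
    return cx + radii * np.cos(ang), cy + radii * np.sin(ang)


# ---------------------------------------------------------------- placement

class _Placer:
    """Rejection-samples object centers so footprints never touch."""

    def __init__(self, rng, field_um, margin_um=8.0, gap_um=4.0):
        self.rng = rng
        self.field = field_um
        self.margin = margin_um
        self.gap = gap_um
        self.placed: dict[int, list] = {}  # plane -> [(x, y, radius), ...]

    def reserve(self, plane, x, y, radius):
        self.placed.setdefault(plane, []).append((x, y, radius))

    def sample(self, plane, radius, x_offset_um, max_tries=200):
        # keep clear of footprints in the same AND adjacent planes so that
        # distinct objects never overlap in (x, y) across neighboring planes
        # (cross-plane overlap is reserved for deliberate two-plane somata)
        neighbors = [q for q in (plane - 1, plane, plane + 1) if q in self.placed]
        for _ in range(max_tries):
            x = x_offset_um + self.rng.uniform(self.margin, self.field - self.margin)
            y = self.rng.uniform(self.margin, self.field - self.margin)
            ok = all(
                (x - px) ** 2 + (y - py) ** 2 >= (radius + pr + self.gap) ** 2
                for q in neighbors
                for px, py, pr in self.placed.get(q, [])
            )
            if ok:
                self.reserve(plane, x, y, radius)
                return x, y
        raise RuntimeError("field too crowded: could not place object")


def make_stack(config: StackConfig | None = None, **overrides):
    """Render a synthetic stack and its ground truth.

    Deterministic for a fixed config (including seed).  Returns
    ``(ImageStack, list[GroundTruthObject])``; the ground truth lists every
    rendered object exactly once, two-plane somata included (their duplicate
    footprint in the adjacent shallower plane is part of the same object and
    overlaps its deep footprint by >= 50% in area so the cross-plane priority
    rule is exercised).
    """
    cfg = config or StackConfig()
    if overrides:
        cfg = StackConfig(**{**asdict(cfg), **overrides})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    px = cfg.pixel_size_um
    side_px = int(round(cfg.field_extent_um / px))
    shape = (cfg.n_planes, side_px, 2 * side_px)
    clean = np.zeros(shape, dtype=float)
    placer = _Placer(rng, cfg.field_extent_um)
    objects: list[GroundTruthObject] = []

    sides = [("left", 0.0), ("right", cfg.field_extent_um)]
    # deepest first so a two-plane soma can reserve its shallower footprint
    for plane in range(cfg.n_planes - 1, -1, -1):
        for side, x_off in sides:
            n_somata = int(rng.integers(cfg.count_range[0], cfg.count_range[1] + 1))
            n_dend = int(round(cfg.dendrite_fraction * n_somata))
            n_debris = int(round(cfg.debris_fraction * n_somata))

            for _ in range(n_somata):
                r = rng.uniform(*cfg.soma_radius_um)
                x, y = placer.sample(plane, r, x_off)
                peak = rng.uniform(0.55, 1.0) * NOMINAL_PEAK
                span = [plane]
                _render_soma(clean[plane], x / px, y / px, r / px, peak)
                if plane > 0 and rng.random() < cfg.two_plane_fraction:
                    # duplicate footprint one plane shallower, small shift
                    # keeps areal overlap >= 50% (shift <= 0.3 r)
                    sx = x + rng.uniform(-0.3, 0.3) * r
                    sy = y + rng.uniform(-0.3, 0.3) * r
                    placer.reserve(plane - 1, sx, sy, r)
                    _render_soma(clean[plane - 1], sx / px, sy / px, r / px,
                                 peak * rng.uniform(0.7, 0.95))
                    span = [plane - 1, plane]
                objects.append(GroundTruthObject(
                    "soma", (x, y, plane), side, span, {"radius_um": r}))

            for _ in range(n_dend):
                length = rng.uniform(16.0, 30.0)
                # aspect >= 5; floor keeps thin shafts connected under
                # 4-connected rasterization
                width = max(2.4, length / rng.uniform(5.0, 8.0))
                angle = rng.uniform(0, np.pi)
                x, y = placer.sample(plane, length / 2 + 1, x_off)
                xs, ys = _dendrite_corners(x, y, length, width, angle)
                _render_polygon(clean[plane], xs / px, ys / px,
                                rng.uniform(0.4, 0.8) * NOMINAL_PEAK)
                objects.append(GroundTruthObject(
                    "dendrite", (x, y, plane), side, [plane],
                    {"length_um": length, "width_um": width, "angle": angle}))

            for _ in range(n_debris):
                r0 = rng.uniform(3.5, 5.0)
                n_spikes = int(rng.integers(5, 9))
                radii = np.empty(2 * n_spikes)
                # spikes wide enough to rasterize as a genuine star (deeper
                # notches collapse to round blobs at this pixel size)
                radii[0::2] = r0 * rng.uniform(1.5, 1.9, n_spikes)   # tips
                radii[1::2] = r0 * rng.uniform(0.55, 0.75, n_spikes)  # notches
                phase = rng.uniform(0, 2 * np.pi)
                x, y = placer.sample(plane, radii.max() + 1, x_off)
                xs, ys = _star_vertices(x, y, radii, phase)
                _render_polygon(clean[plane], xs / px, ys / px,
                                rng.uniform(0.4, 0.8) * NOMINAL_PEAK)
                objects.append(GroundTruthObject(
                    "debris", (x, y, plane), side, [plane],
                    {"radii_um": radii.tolist(), "phase": phase}))

    if cfg.psbr is not None:
        background = NOMINAL_PEAK / cfg.psbr
        clean = rng.poisson(clean + background).astype(float)
    data = np.clip(np.round(clean), 0, MAX_INTENSITY).astype(np.uint16)
    stack = ImageStack(data, pixel_size_um=px, z_step_um=cfg.z_step_um,
                       field_extent_um=cfg.field_extent_um)
    return stack, objects


# ------------------------------------------------------- period sequences

def biexponential_params(start_s: float, end_s: float, n_cycles: int,
                         fast_fraction: float = 0.1,
                         tau_ratio: float = 3.0) -> dict:
    """Solve bi-exponential drift parameters so the expected period runs from
    ``start_s`` at cycle 0 to ``end_s`` at cycle ``n_cycles - 1``.

    The drift model is T_k = a1 exp(k/tau1) + a2 exp(k/tau2) with
    tau1 = tau_ratio * tau2 (one slow, one fast exponential), a2 =
    fast_fraction * start.  Typical lesioned-slice presets span instantaneous
    frequencies from ~0.22 Hz down to ~0.007 Hz (periods ~4.5 s to ~143 s).
    """
    if not (start_s > 0 and end_s > start_s and n_cycles >= 2):
        raise ValueError("need 0 < start < end and n_cycles >= 2")
    a2 = fast_fraction * start_s
    a1 = start_s - a2
    k = n_cycles - 1

    def endpoint(tau2):
        return a1 * np.exp(k / (tau_ratio * tau2)) + a2 * np.exp(k / tau2) - end_s

    # lower bracket keeps the exponent below overflow (exp(700) is finite)
    tau2 = brentq(endpoint, k / 700.0, 1e6)
    return {"a1": a1, "tau1": tau_ratio * tau2, "a2": a2, "tau2": tau2}


def make_period_sequence(model: str, base_period_s: float, jitter: float,
                         n_cycles: int, seed=None,
                         drift: dict | None = None) -> np.ndarray:
    """Generate a cycle-period sequence.

    ``model='stable'``: multiplicative log-normal jitter around the base
    period (jitter 0 reproduces the base exactly).  ``model=
    'biexponential_drift'``: expected period follows a sum of two rising
    exponentials in cycle index (see :func:`biexponential_params`), with the
    same multiplicative jitter on top; the expected sequence is monotonically
    nondecreasing.
    """
    if base_period_s <= 0:
        raise ValueError("base period must be positive")
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    if jitter < 0:
        raise ValueError("jitter coefficient must be non-negative")
    rng = np.random.default_rng(seed)
    k = np.arange(n_cycles, dtype=float)
    if model == "stable":
        mean = np.full(n_cycles, float(base_period_s))
    elif model == "biexponential_drift":
        if drift is None:
            drift = biexponential_params(base_period_s, 30.0 * base_period_s,
                                         max(n_cycles, 2))
        mean = (drift["a1"] * np.exp(k / drift["tau1"])
                + drift["a2"] * np.exp(k / drift["tau2"]))
    else:
        raise ValueError(f"unknown period model: {model!r}")
    if jitter == 0:
        return mean
    return mean * np.exp(jitter * rng.standard_normal(n_cycles))


# ------------------------------------------------------------------- I/O

def write_stack(stack: ImageStack, tiff_path, config: StackConfig | None = None):
    """Write the stack as a multi-page 16-bit TIFF (holding 12-bit values)
    plus a JSON sidecar with geometry and, when given, the generator config."""
    import tifffile

    tifffile.imwrite(str(tiff_path), stack.planes, photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "field_extent_um": stack.field_extent_um,
    }
    if config is not None:
        meta["generator_config"] = asdict(config)
    sidecar = str(tiff_path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2)


def read_stack(tiff_path) -> ImageStack:
    import os

    import tifffile

    planes = tifffile.imread(str(tiff_path))
    if planes.ndim == 2:
        planes = planes[None]
    kwargs = {}
    sidecar = str(tiff_path) + ".json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
        kwargs = {k: meta[k] for k in
                  ("pixel_size_um", "z_step_um", "field_extent_um") if k in meta}
    return ImageStack(planes, **kwargs)


def write_ground_truth(objects, csv_path):
    """One CSV row per object: kind, x_um, y_um, plane, side, plane_span, params."""
    import pandas as pd

    rows = []
    for o in objects:
        rows.append({
            "kind": o.kind, "x_um": o.center[0], "y_um": o.center[1],
            "plane": o.center[2], "side": o.side,
            "plane_span": ";".join(str(p) for p in o.plane_span),
            "params": json.dumps(o.params),
        })
    pd.DataFrame(rows).to_csv(csv_path, index=False)
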