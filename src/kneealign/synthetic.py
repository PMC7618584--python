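"""Synthetic knee-landmark and pseudo-radiograph generator.

Clinical knee radiographs and their annotations cannot be redistributed, so
this module provides a procedural stand-in with *known ground truth*: a
deterministic left-knee landmark template per schema (femoral and tibial
shaft axes exactly vertical, hence aFTA exactly zero), a rigid-rotation
mechanism to inject any true aFTA, degradation models (shaft truncation,
whole-image rotation, per-point Gaussian annotation jitter), a simple
polygon-based radiograph renderer, and a direct simulator for paired
measurement series used to exercise the agreement statistics.

The template geometry is procedural (parametric polylines/arcs), not traced
from any image; only the role topology and point counts match the schemas.
All stochastic operations are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .agreement import PairedMeasurements
from .landmarks import LandmarkSet, SchemaId, validate, write_pts
from .measurement import detect_lateral_sign

__all__ = [
    "KneeTemplate",
    "SimulationConfig",
    "PairedSimConfig",
    "make_template",
    "inject_alignment",
    "degrade",
    "render",
    "simulate_paired",
    "simulate_dataset",
    "template_layout",
]


# --------------------------------------------------------------------------
# geometry helpers

def _rot_matrix(deg: float) -> np.ndarray:
    """In-plane rotation matrix in image coordinates (y down).

    Applied to an image-down unit vector it *decreases* the raw axis angle
    atan2(vx, vy) by ``deg``, so rotating the femur by ``lateral_sign * t``
    injects an aFTA of exactly ``+t``.
    """
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s], [s, c]])


def _sample_polyline(waypoints: Sequence[tuple[float, float]], n: int) -> np.ndarray:
    """``n`` points spread by arc length along a polyline (ends included)."""
    w = np.asarray(waypoints, dtype=float)
    seg = np.linalg.norm(np.diff(w, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, cum[-1], n)
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k] = np.interp(t, cum, w[:, k])
    return out


def _ellipse(centre: tuple[float, float], rx: float, ry: float, n: int) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack([centre[0] + rx * np.cos(ang),
                            centre[1] + ry * np.sin(ang)])


# --------------------------------------------------------------------------
# template layout

@dataclass(frozen=True)
class TemplateLayout:
    """Schema-specific index bookkeeping shared by the generator and renderer.

    ``polygons`` lists (index path, material) pairs used to rasterise
    pseudo-radiographs; ``femoral_indices`` is the rigid femur subset moved
    by :func:`inject_alignment`; the ``*_scalable`` sets are the shaft
    points moved toward the knee by shaft truncation.
    """

    schema_id: SchemaId
    femoral_indices: tuple[int, ...]
    femoral_scalable: tuple[int, ...]
    tibial_scalable: tuple[int, ...]
    polygons: tuple[tuple[tuple[int, ...], str], ...]


def _layout(schema_id: SchemaId) -> TemplateLayout:
    pre = schema_id in (SchemaId.PRE_ORIGINAL, SchemaId.PRE_EXTENDED)
    extended = schema_id in (SchemaId.PRE_EXTENDED, SchemaId.POST_EXTENDED)
    if pre:
        femur = tuple(range(0, 45))
        tibia = tuple(range(45, 86))
        fibula = tuple(range(100, 110))
        polys = [(femur, "bone"), (tibia, "bone"), (fibula, "bone")]
        fem_idx = list(femur)
        fem_scal = [0, 1, 43, 44]
        tib_scal = [45, 85]
        if extended:
            fem_idx += list(range(110, 122))
            fem_scal += list(range(110, 122))
            tib_scal += list(range(122, 134))
            polys += [((115, 110, 116, 121), "bone"),   # femoral extension column
                      ((110, 0, 44, 116), "bone"),      # gap to original shaft top
                      ((122, 127, 133, 128), "bone"),   # tibial extension column
                      ((45, 122, 128, 85), "bone")]
    else:
        femur = tuple(range(0, 29))
        tibia = tuple(range(29, 51))
        fibula = tuple(range(147, 157))
        implant_fem = tuple(range(51, 117))
        tray = tuple(range(117, 140))
        polys = [(femur, "bone"), (tibia, "bone"), (fibula, "bone"),
                 (implant_fem, "implant"), (tray, "implant")]
        fem_idx = list(femur) + list(implant_fem)
        fem_scal = [0, 1, 27, 28]
        tib_scal = [29, 30, 49, 50]
        if extended:
            fem_idx += list(range(157, 169))
            fem_scal += list(range(157, 169))
            tib_scal += list(range(169, 181))
            polys += [((162, 157, 163, 168), "bone"),
                      ((157, 0, 28, 163), "bone"),
                      ((169, 174, 180, 175), "bone"),
                      ((29, 169, 175, 50), "bone")]
    return TemplateLayout(
        schema_id=schema_id,
        femoral_indices=tuple(fem_idx),
        femoral_scalable=tuple(fem_scal),
        tibial_scalable=tuple(tib_scal),
        polygons=tuple((tuple(p), m) for p, m in polys),
    )


_LAYOUTS = {sid: _layout(sid) for sid in SchemaId}


def template_layout(schema_id: "SchemaId | str") -> TemplateLayout:
    return _LAYOUTS[SchemaId(schema_id)]


@dataclass
class KneeTemplate:
    """Deterministic left-knee landmark template with exactly zero aFTA."""

    schema_id: SchemaId
    base: LandmarkSet
    knee_centre: np.ndarray
    size: float
    layout: TemplateLayout = field(repr=False)

    @property
    def femoral_indices(self) -> tuple[int, ...]:
        return self.layout.femoral_indices


def _pre_points(S: float, extended: bool) -> np.ndarray:
    cx = S / 2.0
    wf, wt = 0.055 * S, 0.05 * S
    n = 134 if extended else 110
    p = np.zeros((n, 2))
    # femoral shaft, medial edge (indices 0-2), lateral edge (42-44)
    p[0] = (cx - wf, 0.30 * S); p[1] = (cx - wf, 0.35 * S); p[2] = (cx - wf, 0.40 * S)
    p[42] = (cx + wf, 0.40 * S); p[43] = (cx + wf, 0.35 * S); p[44] = (cx + wf, 0.30 * S)
    # medial condyle down to the notch
    p[3:22] = _sample_polyline([
        (cx - wf, 0.412 * S), (cx - 0.16 * S, 0.455 * S), (cx - 0.10 * S, 0.480 * S),
        (cx - 0.03 * S, 0.462 * S), (cx - 0.016 * S, 0.448 * S)], 19)
    # intercondylar notch pair (midpoint exactly on the axis)
    p[22] = (cx - 0.015 * S, 0.44 * S)
    p[23] = (cx + 0.015 * S, 0.44 * S)
    # lateral condyle back up to the shaft
    p[24:42] = _sample_polyline([
        (cx + 0.016 * S, 0.448 * S), (cx + 0.03 * S, 0.462 * S),
        (cx + 0.10 * S, 0.480 * S), (cx + 0.16 * S, 0.455 * S),
        (cx + wf, 0.412 * S)], 18)
    # tibia: medial shaft edge (45-47), lateral (83-85)
    p[45] = (cx - wt, 0.70 * S); p[46] = (cx - wt, 0.62 * S); p[47] = (cx - wt, 0.58 * S)
    p[83] = (cx + wt, 0.58 * S); p[84] = (cx + wt, 0.62 * S); p[85] = (cx + wt, 0.70 * S)
    p[48:65] = _sample_polyline([
        (cx - wt, 0.565 * S), (cx - 0.15 * S, 0.535 * S), (cx - 0.15 * S, 0.525 * S),
        (cx - 0.03 * S, 0.525 * S), (cx - 0.012 * S, 0.530 * S)], 17)
    p[65] = (cx, 0.535 * S)  # tibial spine groove, on the axis
    p[66:83] = _sample_polyline([
        (cx + 0.012 * S, 0.530 * S), (cx + 0.03 * S, 0.525 * S),
        (cx + 0.15 * S, 0.525 * S), (cx + 0.15 * S, 0.535 * S),
        (cx + wt, 0.565 * S)], 17)
    # plateau detail rows (not part of any axis)
    xs = np.linspace(cx - 0.09 * S, cx + 0.09 * S, 7)
    p[86:93] = np.column_stack([xs, np.full(7, 0.545 * S)])
    p[93:100] = np.column_stack([xs, np.full(7, 0.555 * S)])
    # fibula, lateral of the tibia
    p[100:110] = _ellipse((cx + 0.19 * S, 0.68 * S), 0.022 * S, 0.12 * S, 10)
    if extended:
        ys_up = np.linspace(0.26 * S, 0.08 * S, 6)
        p[110:116] = np.column_stack([np.full(6, cx - wf), ys_up])   # 115 topmost
        p[116:122] = np.column_stack([np.full(6, cx + wf), ys_up])   # 121 topmost
        ys_dn = np.linspace(0.74 * S, 0.92 * S, 6)
        p[122:128] = np.column_stack([np.full(6, cx - wt), ys_dn])   # 127 bottom
        p[128:134] = np.column_stack([np.full(6, cx + wt), ys_dn])   # 133 bottom
    return p


def _post_points(S: float, extended: bool) -> np.ndarray:
    cx = S / 2.0
    wf, wt = 0.055 * S, 0.05 * S
    n = 181 if extended else 157
    p = np.zeros((n, 2))
    # femoral shaft edges
    p[0] = (cx - wf, 0.30 * S); p[1] = (cx - wf, 0.35 * S); p[2] = (cx - wf, 0.40 * S)
    p[26] = (cx + wf, 0.40 * S); p[27] = (cx + wf, 0.35 * S); p[28] = (cx + wf, 0.30 * S)
    p[3:14] = _sample_polyline([
        (cx - wf, 0.412 * S), (cx - 0.16 * S, 0.455 * S), (cx - 0.10 * S, 0.480 * S),
        (cx - 0.03 * S, 0.475 * S)], 11)
    p[14] = (cx, 0.475 * S)
    p[15:26] = _sample_polyline([
        (cx + 0.03 * S, 0.475 * S), (cx + 0.10 * S, 0.480 * S),
        (cx + 0.16 * S, 0.455 * S), (cx + wf, 0.412 * S)], 11)
    # tibia
    p[29] = (cx - wt, 0.70 * S); p[30] = (cx - wt, 0.66 * S); p[31] = (cx - wt, 0.62 * S)
    p[48] = (cx + wt, 0.62 * S); p[49] = (cx + wt, 0.66 * S); p[50] = (cx + wt, 0.70 * S)
    p[32:39] = _sample_polyline([
        (cx - wt, 0.575 * S), (cx - 0.15 * S, 0.540 * S), (cx - 0.15 * S, 0.530 * S),
        (cx - 0.03 * S, 0.530 * S)], 7)
    p[39] = (cx - 0.012 * S, 0.545 * S)
    p[40] = (cx + 0.012 * S, 0.545 * S)
    p[41:48] = _sample_polyline([
        (cx + 0.03 * S, 0.530 * S), (cx + 0.15 * S, 0.530 * S),
        (cx + 0.15 * S, 0.540 * S), (cx + wt, 0.575 * S)], 7)
    # femoral implant outline, notch pair 83/84 on the axis
    p[51:83] = _sample_polyline([
        (cx - 0.065 * S, 0.415 * S), (cx - 0.17 * S, 0.450 * S),
        (cx - 0.11 * S, 0.490 * S), (cx - 0.03 * S, 0.468 * S),
        (cx - 0.016 * S, 0.452 * S)], 32)
    p[83] = (cx - 0.015 * S, 0.445 * S)
    p[84] = (cx + 0.015 * S, 0.445 * S)
    p[85:117] = _sample_polyline([
        (cx + 0.016 * S, 0.452 * S), (cx + 0.03 * S, 0.468 * S),
        (cx + 0.11 * S, 0.490 * S), (cx + 0.17 * S, 0.450 * S),
        (cx + 0.065 * S, 0.415 * S)], 32)
    # tibial tray top edge: slight arc, 117/139 symmetric, centre on axis
    t = np.linspace(-1.0, 1.0, 23)
    p[117:140] = np.column_stack([cx + 0.13 * S * t,
                                  0.520 * S + 0.008 * S * (1.0 - t ** 2)])
    # tibial stem column (on the axis, no role)
    p[140:147] = np.column_stack([np.full(7, cx), np.linspace(0.55 * S, 0.61 * S, 7)])
    p[147:157] = _ellipse((cx + 0.19 * S, 0.68 * S), 0.022 * S, 0.12 * S, 10)
    if extended:
        ys_up = np.linspace(0.26 * S, 0.08 * S, 6)
        p[157:163] = np.column_stack([np.full(6, cx - wf), ys_up])   # 162 topmost
        p[163:169] = np.column_stack([np.full(6, cx + wf), ys_up])   # 168 topmost
        ys_dn = np.linspace(0.74 * S, 0.92 * S, 6)
        p[169:175] = np.column_stack([np.full(6, cx - wt), ys_dn])   # 174 bottom
        p[175:181] = np.column_stack([np.full(6, cx + wt), ys_dn])   # 180 bottom
    return p


def make_template(schema_id: "SchemaId | str", size: float = 512.0) -> KneeTemplate:
    """Deterministic left-knee template for a schema.

    Both shaft axes are exactly vertical, all axis endpoints resolve onto
    the midline, so every applicable aFTA definition reads exactly zero.
    The fibula sits lateral (larger x: left-knee orientation).  ``size``
    scales the whole configuration; landmarks span roughly [0.08, 0.92] of
    it vertically.
    """
    sid = SchemaId(schema_id)
    S = float(size)
    if sid in (SchemaId.PRE_ORIGINAL, SchemaId.PRE_EXTENDED):
        pts = _pre_points(S, extended=(sid is SchemaId.PRE_EXTENDED))
    else:
        pts = _post_points(S, extended=(sid is SchemaId.POST_EXTENDED))
    base = validate(LandmarkSet(sid, pts, image_id=f"template_{sid.value}",
                                source="manual"))
    return KneeTemplate(schema_id=sid, base=base,
                        knee_centre=np.array([S / 2.0, 0.5 * S]),
                        size=S, layout=template_layout(sid))


# --------------------------------------------------------------------------
# ground-truth injection and degradation

def inject_alignment(t: KneeTemplate, true_aFTA_deg: float) -> LandmarkSet:
    """Rotate the femur rigidly about the knee centre to set a known aFTA.

    The rotation angle is ``lateral_sign * true_aFTA_deg``; tibia and fibula
    are untouched, so every definition whose femoral endpoints lie on the
    femur reads exactly ``true_aFTA_deg`` afterwards.
    """
    if not abs(true_aFTA_deg) < 45.0:
        raise ValueError("true aFTA must satisfy |angle| < 45 degrees")
    if true_aFTA_deg == 0.0:
        return t.base.copy(image_id=f"{t.schema_id.value}_afta+0.00")
    lat = detect_lateral_sign(t.base)
    R = _rot_matrix(lat * true_aFTA_deg)
    pts = t.base.points.copy()
    idx = list(t.femoral_indices)
    pts[idx] = (pts[idx] - t.knee_centre) @ R.T + t.knee_centre
    return t.base.copy(points=pts,
                       image_id=f"{t.schema_id.value}_afta{true_aFTA_deg:+.2f}")


@dataclass
class SimulationConfig:
    """Degradations applied to one landmark set (in this order):
    shaft truncation, global in-plane rotation, iid Gaussian point jitter.

    ``femoral_shaft_fraction`` / ``tibial_shaft_fraction`` scale the visible
    shaft length toward the knee (1.0 = full length); ``point_noise_sd_px``
    emulates annotation error per coordinate.
    """

    true_aFTA_deg: float = 0.0
    point_noise_sd_px: float = 1.0
    global_rotation_deg: float = 0.0
    femoral_shaft_fraction: float = 1.0
    tibial_shaft_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.femoral_shaft_fraction, self.tibial_shaft_fraction):
            if not 0.0 < f <= 1.0:
                raise ValueError("shaft fractions must be in (0, 1]")
        if self.point_noise_sd_px < 0:
            raise ValueError("noise sd must be >= 0")


def _truncate_along_axis(pts: np.ndarray, idx: Sequence[int],
                         anchor: np.ndarray, direction: np.ndarray,
                         fraction: float) -> None:
    """Scale the axis-parallel offset of ``idx`` points about ``anchor``."""
    u = direction / np.linalg.norm(direction)
    rel = pts[list(idx)] - anchor
    along = rel @ u
    pts[list(idx)] += np.outer((fraction - 1.0) * along, u)


def degrade(ls: LandmarkSet, cfg: SimulationConfig) -> LandmarkSet:
    """Apply the configured degradations to a landmark set (seeded)."""
    layout = template_layout(ls.schema_id)
    schema = ls.schema
    pts = ls.points.copy()

    def role_mid(name: str) -> np.ndarray:
        return pts[list(schema.role(name))].mean(axis=0)

    if cfg.femoral_shaft_fraction < 1.0:
        anchor = role_mid("femoral_shaft_distal_pair")
        direction = role_mid("femoral_shaft_proximal_pair") - anchor
        _truncate_along_axis(pts, layout.femoral_scalable, anchor, direction,
                             cfg.femoral_shaft_fraction)
    if cfg.tibial_shaft_fraction < 1.0:
        anchor = role_mid("tibial_shaft_proximal_pair")
        direction = role_mid("tibial_shaft_distal_pair") - anchor
        _truncate_along_axis(pts, layout.tibial_scalable, anchor, direction,
                             cfg.tibial_shaft_fraction)
    if cfg.global_rotation_deg != 0.0:
        centroid = pts.mean(axis=0)
        R = _rot_matrix(cfg.global_rotation_deg)
        pts = (pts - centroid) @ R.T + centroid
    if cfg.point_noise_sd_px > 0.0:
        rng = np.random.default_rng(cfg.seed)
        pts = pts + rng.normal(0.0, cfg.point_noise_sd_px, pts.shape)
    return ls.copy(points=pts)


# --------------------------------------------------------------------------
# rendering

_MATERIAL_LEVELS = {"bone": 110.0, "implant": 210.0}
BACKGROUND_LEVEL = 30.0


def render(ls: LandmarkSet, size: int, blur_sd: float = 2.0,
           noise_sd: float = 2.0, seed: int = 0) -> np.ndarray:
    """Rasterise a landmark set into a grayscale pseudo-radiograph.

    Bone (and, post-operatively, implant) outlines are filled polygons
    brighter than the background, followed by Gaussian blur and additive
    Gaussian noise.  Deterministic per seed.  Returns a float array of
    shape (size, size) in arbitrary intensity units (~[0, 255]).
    """
    pts = ls.points
    if np.any(pts < 0) or np.any(pts >= size):
        raise ValueError("landmarks out of frame for the requested image size")
    img = np.full((size, size), BACKGROUND_LEVEL)
    for idx, material in template_layout(ls.schema_id).polygons:
        poly = pts[list(idx)]
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=img.shape)
        img[rr, cc] = _MATERIAL_LEVELS[material]
    if blur_sd > 0:
        img = gaussian_filter(img, blur_sd)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


# --------------------------------------------------------------------------
# paired-measurement simulation

@dataclass
class PairedSimConfig:
    """Generative model for two noisy measurements of the same true angles.

    ``a_i = t_i + eps_a``, ``b_i = t_i + bias + eps_b`` with
    ``t_i ~ Normal(true_mean, true_sd)`` and independent Gaussian errors.
    Defaults emulate a mixed pre-operative TKA population (wide spread of
    true alignment) measured by two methods of ~1 degree precision.
    """

    n: int = 50
    true_mean_deg: float = 2.0
    true_sd_deg: float = 5.0
    bias_deg: float = 0.0
    err_sd_a_deg: float = 1.0
    err_sd_b_deg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if min(self.true_sd_deg, self.err_sd_a_deg, self.err_sd_b_deg) < 0:
            raise ValueError("standard deviations must be >= 0")


def simulate_paired(cfg: PairedSimConfig) -> PairedMeasurements:
    """Draw a paired measurement series under the config's generative model."""
    rng = np.random.default_rng(cfg.seed)
    t = rng.normal(cfg.true_mean_deg, cfg.true_sd_deg, cfg.n)
    a = t + rng.normal(0.0, cfg.err_sd_a_deg, cfg.n)
    b = t + cfg.bias_deg + rng.normal(0.0, cfg.err_sd_b_deg, cfg.n)
    ids = [f"sim_{i:04d}" for i in range(cfg.n)]
    return PairedMeasurements(ids=ids, a_deg=a, b_deg=b)


# --------------------------------------------------------------------------
# dataset emission

def simulate_dataset(out_dir: "str | Path", schema_id: "SchemaId | str",
                     n: int, seed: int = 0, *,
                     true_mean_deg: float = 2.0, true_sd_deg: float = 5.0,
                     point_noise_sd_px: float = 1.0,
                     rotation_sd_deg: float = 2.0,
                     femoral_shaft_fraction: float = 1.0,
                     tibial_shaft_fraction: float = 1.0,
                     size: int = 512, write_images: bool = False,
                     blur_sd: float = 2.0, image_noise_sd: float = 2.0):
    """Emit a synthetic dataset directory: pts files, a batch manifest CSV,
    a ground-truth CSV and (optionally) rendered PNG images.

    Returns a pandas DataFrame with one row per generated image (the ground
    truth table).  The written landmarks include all degradations;
    ``true_aFTA_deg`` in the truth table is the injected angle.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = SchemaId(schema_id)
    tpl = make_template(sid, size=float(size))
    rng = np.random.default_rng(seed)
    rows = []
    manifest = []
    for i in range(n):
        true_afta = float(rng.normal(true_mean_deg, true_sd_deg))
        rot = float(rng.normal(0.0, rotation_sd_deg))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SimulationConfig(true_aFTA_deg=true_afta,
                               point_noise_sd_px=point_noise_sd_px,
                               global_rotation_deg=rot,
                               femoral_shaft_fraction=femoral_shaft_fraction,
                               tibial_shaft_fraction=tibial_shaft_fraction,
                               seed=sub_seed)
        ls = degrade(inject_alignment(tpl, true_afta), cfg)
        image_id = f"synth_{i:04d}"
        ls.image_id = image_id
        pts_path = out / f"{image_id}.pts"
        write_pts(ls, pts_path)
        row = dict(image_id=image_id, true_aFTA_deg=true_afta,
                   point_noise_sd_px=point_noise_sd_px,
                   global_rotation_deg=rot,
                   femoral_shaft_fraction=femoral_shaft_fraction,
                   tibial_shaft_fraction=tibial_shaft_fraction,
                   seed=sub_seed)
        man = dict(image_id=image_id, pts_path=pts_path.name,
                   schema_id=sid.value, flipped=False, image_width=size)
        if write_images:
            import imageio.v3 as iio
            img = render(ls, size=size, blur_sd=blur_sd,
                         noise_sd=image_noise_sd, seed=sub_seed)
            img_path = out / f"{image_id}.png"
            iio.imwrite(img_path, np.clip(img, 0, 255).astype(np.uint8))
            man["image_path"] = img_path.name
        rows.append(row)
        manifest.append(man)
    truth = pd.DataFrame(rows)
    truth.to_csv(out / "truth.csv", index=False)
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    return truth
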