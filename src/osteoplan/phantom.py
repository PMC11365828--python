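"""Synthetic lower-limb phantoms with known deformity.

Generates two-leg standing "patients" — femur/tibia surrogates built from
capsules, spheres and an articular plateau slab, wrapped in a soft-tissue
envelope — with analytic ground truth for the hip/knee/ankle joint centers,
the frontal-plane mechanical axis deviation (varus/valgus) and the posterior
tibial slope.  The phantom cohort stands in for a patient CT cohort so that
every downstream stage (radiograph simulation, network training, deformity
measurement, osteotomy planning) can be trained and validated at desk scale.

Patient frame (right-handed, millimetres, voxel-center convention):
  +X medial->lateral axis pointing to the patient's left (the right leg sits
     at negative X, the left leg at positive X, midline at X = 0),
  +Y posterior->anterior,
  +Z inferior->superior.
Frontal projections integrate along Y, sagittal projections along X.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Label codes
# ---------------------------------------------------------------------------

BG = 0
SOFT_LEFT = 1
SOFT_RIGHT = 2
FEMUR_LEFT = 3
FEMUR_RIGHT = 4
TIBIA_LEFT = 5
TIBIA_RIGHT = 6
PROX_TIBIA_LEFT = 7
PROX_TIBIA_RIGHT = 8
FIBULA_LEFT = 9
FIBULA_RIGHT = 10

LEFT_LABELS = (SOFT_LEFT, FEMUR_LEFT, TIBIA_LEFT, PROX_TIBIA_LEFT, FIBULA_LEFT)
RIGHT_LABELS = (SOFT_RIGHT, FEMUR_RIGHT, TIBIA_RIGHT, PROX_TIBIA_RIGHT, FIBULA_RIGHT)
BONE_LABELS = (
    FEMUR_LEFT, FEMUR_RIGHT, TIBIA_LEFT, TIBIA_RIGHT,
    PROX_TIBIA_LEFT, PROX_TIBIA_RIGHT, FIBULA_LEFT, FIBULA_RIGHT,
)
TIBIA_LABELS = {
    "left": (TIBIA_LEFT, PROX_TIBIA_LEFT),
    "right": (TIBIA_RIGHT, PROX_TIBIA_RIGHT),
}
PROX_TIBIA_LABELS = {"left": PROX_TIBIA_LEFT, "right": PROX_TIBIA_RIGHT}
SIDE_LABELS = {"left": LEFT_LABELS, "right": RIGHT_LABELS}

SIDES = ("left", "right")


class SizingError(ValueError):
    """Phantom geometry would place a landmark outside the voxel grid."""


class PlacementError(ValueError):
    """Two legs overlap at the requested stance separation."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomParams:
    """Geometric and intensity parameters of a single synthetic leg.

    Lengths in millimetres, angles in degrees, intensities dimensionless
    in [0, 1].  ``varus_angle`` is the frontal-plane deviation of the tibial
    mechanical axis from the femoral one (positive = varus, i.e. the ankle
    deviates toward the body midline); ``slope_angle`` is the posterior
    inclination of the tibial plateau.
    """

    leg_length: float = 700.0
    femur_radius: float = 14.0
    tibia_radius: float = 12.0
    head_radius: float = 22.0
    plateau_width: float = 60.0
    plateau_depth: float = 45.0
    plateau_thickness: float = 14.0
    varus_angle: float = 5.0
    slope_angle: float = 6.0
    soft_tissue_radius: float = 45.0
    bone_intensity: float = 0.9
    soft_intensity: float = 0.25
    voxel_spacing: float = 3.0
    prox_tibia_extent: float = 120.0
    with_fibula: bool = False   # low-priority surrogate, off by default
    fibula_radius: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("leg_length", "femur_radius", "tibia_radius", "head_radius",
                     "plateau_width", "plateau_depth", "plateau_thickness",
                     "soft_tissue_radius", "voxel_spacing", "prox_tibia_extent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.soft_intensity < self.bone_intensity <= 1.0):
            raise ValueError("require 0 <= soft_intensity < bone_intensity <= 1")
        if abs(self.varus_angle) > 20.0:
            raise ValueError("|varus_angle| must be <= 20 degrees")
        if not (0.0 <= self.slope_angle <= 20.0):
            raise ValueError("slope_angle must lie in [0, 20] degrees")

    def replace(self, **kw) -> "PhantomParams":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet3D:
    """Hip/knee/ankle joint centers per side, mm, patient frame."""

    points: dict  # side -> {"HC"|"KC"|"AC": np.ndarray (3,)}

    def __getitem__(self, side: str) -> dict:
        return self.points[side]

    @property
    def sides(self) -> tuple:
        return tuple(self.points)

    def validate(self) -> None:
        for side, lm in self.points.items():
            if not (lm["HC"][2] > lm["KC"][2] > lm["AC"][2]):
                raise ValueError(f"{side}: landmarks must be ordered superior->inferior")

    def copy(self) -> "LandmarkSet3D":
        return LandmarkSet3D({s: {k: v.copy() for k, v in lm.items()}
                              for s, lm in self.points.items()})

    def to_json(self) -> str:
        return json.dumps({s: {k: list(map(float, v)) for k, v in lm.items()}
                           for s, lm in self.points.items()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LandmarkSet3D":
        raw = json.loads(text)
        return cls({s: {k: np.asarray(v, float) for k, v in lm.items()}
                    for s, lm in raw.items()})


# ---------------------------------------------------------------------------
# Annotated volume
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedVolume:
    """Voxel intensity + per-bone labels + 3D joint-center landmarks.

    Arrays are indexed ``[ix, iy, iz]``; world coordinate of voxel (i,j,k)
    is ``origin + (i,j,k) * spacing`` (voxel-center convention).
    """

    intensity: np.ndarray  # float32, values in [0, 1]
    labels: np.ndarray     # uint8
    spacing: np.ndarray    # (3,) mm
    origin: np.ndarray     # (3,) mm
    landmarks: LandmarkSet3D

    def __post_init__(self) -> None:
        if self.intensity.shape != self.labels.shape:
            raise ValueError("intensity and labels must share shape")
        self.spacing = np.asarray(self.spacing, float)
        self.origin = np.asarray(self.origin, float)

    @property
    def shape(self) -> tuple:
        return self.intensity.shape

    def world_bounds(self) -> tuple:
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return lo, hi

    def world_to_index(self, p: np.ndarray) -> np.ndarray:
        return (np.asarray(p, float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.spacing

    def contains_point(self, p: np.ndarray) -> bool:
        lo, hi = self.world_bounds()
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def masked_intensity(self, keep_labels) -> np.ndarray:
        """Intensity with voxels outside ``keep_labels`` zeroed."""
        mask = np.isin(self.labels, np.asarray(list(keep_labels), dtype=self.labels.dtype))
        return np.where(mask, self.intensity, 0.0).astype(np.float32)

    def copy(self) -> "AnnotatedVolume":
        return AnnotatedVolume(self.intensity.copy(), self.labels.copy(),
                               self.spacing.copy(), self.origin.copy(),
                               self.landmarks.copy())

    # -- I/O ---------------------------------------------------------------

    def save(self, stem: Path) -> None:
        """Write ``<stem>_intensity.mha``, ``<stem>_labels.mha``, ``<stem>_landmarks.json``."""
        import SimpleITK as sitk

        stem = Path(stem)
        for arr, name in ((self.intensity, "intensity"), (self.labels, "labels")):
            img = sitk.GetImageFromArray(np.transpose(arr, (2, 1, 0)))
            img.SetSpacing(tuple(self.spacing))
            img.SetOrigin(tuple(self.origin))
            sitk.WriteImage(img, str(stem) + f"_{name}.mha", useCompression=True)
        Path(str(stem) + "_landmarks.json").write_text(self.landmarks.to_json())

    @classmethod
    def load(cls, stem: Path) -> "AnnotatedVolume":
        import SimpleITK as sitk

        stem = str(stem)
        imgs = {}
        for name in ("intensity", "labels"):
            img = sitk.ReadImage(stem + f"_{name}.mha")
            imgs[name] = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        img = sitk.ReadImage(stem + "_intensity.mha")
        lms = LandmarkSet3D.from_json(Path(stem + "_landmarks.json").read_text())
        return cls(imgs["intensity"].astype(np.float32), imgs["labels"].astype(np.uint8),
                   np.array(img.GetSpacing()), np.array(img.GetOrigin()), lms)


# ---------------------------------------------------------------------------
# Analytic leg geometry
# ---------------------------------------------------------------------------

FEMUR_FRACTION = 0.52  # hip->knee share of leg_length; knee->ankle gets the rest


def _medial_sign(side: str) -> float:
    # medial (toward midline) is +X for the right leg (at negative X), -X for the left
    return 1.0 if side == "right" else -1.0


@dataclass
class LegGeometry:
    """Analytic description of one leg: landmarks, axes and primitive shapes."""

    side: str
    params: PhantomParams
    HC: np.ndarray
    KC: np.ndarray
    AC: np.ndarray
    plateau_normal: np.ndarray

    @property
    def ma_true(self) -> float:
        return float(self.params.varus_angle)

    @property
    def ts_true(self) -> float:
        return float(self.params.slope_angle)


def leg_geometry(params: PhantomParams, side: str, x_offset: float = 0.0) -> LegGeometry:
    """Construct landmark points and the plateau plane for one leg.

    The femoral mechanical axis is vertical; the tibial axis is tilted by
    ``varus_angle`` in the frontal (XZ) plane so that positive angles move the
    ankle medially (true varus).  The plateau outward normal is tilted
    posteriorly by ``slope_angle`` in the sagittal (YZ) plane.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    p = params
    femur_len = FEMUR_FRACTION * p.leg_length
    tibia_len = (1.0 - FEMUR_FRACTION) * p.leg_length
    m = _medial_sign(side)
    v = np.deg2rad(p.varus_angle)
    s = np.deg2rad(p.slope_angle)

    KC = np.array([x_offset, 0.0, tibia_len])
    HC = KC + np.array([0.0, 0.0, femur_len])
    tibia_dir = np.array([m * np.sin(v), 0.0, -np.cos(v)])  # unit, K -> A
    AC = KC + tibia_len * tibia_dir
    # posterior tilt: normal leans toward -Y by slope_angle
    normal = np.array([0.0, -np.sin(s), np.cos(s)])
    return LegGeometry(side, p, HC, KC, AC, normal)


def measure_constructed_ma(geom: LegGeometry) -> float:
    """Frontal-plane angle of the constructed H-K-A polyline, degrees.

    Returns 180 deg minus the angle between (H-K) and (A-K) projected to XZ,
    signed so that positive = varus for the leg's side.  Used as a closed-form
    cross-check that construction and measurement agree.
    """
    u = (geom.HC - geom.KC)[[0, 2]]
    w = (geom.AC - geom.KC)[[0, 2]]
    ang = np.arctan2(abs(u[0] * w[1] - u[1] * w[0]), u[0] * w[0] + u[1] * w[1])
    dev = np.rad2deg(np.pi - ang)
    # positive when the ankle is displaced medially relative to straight
    sign = 1.0 if _medial_sign(geom.side) * w[0] >= 0 else -1.0
    return float(dev * sign)


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def _dist_to_segment(px, py, pz, a, b):
    """Distance from grid points to segment a-b (broadcasting ogrid arrays)."""
    ab = b - a
    denom = float(ab @ ab)
    apx, apy, apz = px - a[0], py - a[1], pz - a[2]
    t = (apx * ab[0] + apy * ab[1] + apz * ab[2]) / denom
    t = np.clip(t, 0.0, 1.0)
    dx = apx - t * ab[0]
    dy = apy - t * ab[1]
    dz = apz - t * ab[2]
    return np.sqrt(dx * dx + dy * dy + dz * dz)


def _paint_leg(intensity, labels, grids, geom: LegGeometry) -> None:
    p = geom.params
    px, py, pz = grids
    side = geom.side
    soft_lbl, femur_lbl, tibia_lbl, prox_lbl = (
        (SOFT_LEFT, FEMUR_LEFT, TIBIA_LEFT, PROX_TIBIA_LEFT) if side == "left"
        else (SOFT_RIGHT, FEMUR_RIGHT, TIBIA_RIGHT, PROX_TIBIA_RIGHT))

    soft = (_dist_to_segment(px, py, pz, geom.HC, geom.KC) <= p.soft_tissue_radius)
    soft |= (_dist_to_segment(px, py, pz, geom.KC, geom.AC) <= p.soft_tissue_radius)

    femur_end = geom.KC + np.array([0.0, 0.0, p.plateau_thickness])
    femur = (_dist_to_segment(px, py, pz, geom.HC, femur_end) <= p.femur_radius)
    head = ((px - geom.HC[0]) ** 2 + (py - geom.HC[1]) ** 2
            + (pz - geom.HC[2]) ** 2) <= p.head_radius ** 2
    femur |= head

    tibia = (_dist_to_segment(px, py, pz, geom.KC, geom.AC) <= p.tibia_radius)
    # plateau slab: elliptic cylinder about KC with outward normal geom.plateau_normal
    n = geom.plateau_normal
    rx, ry, rz = px - geom.KC[0], py - geom.KC[1], pz - geom.KC[2]
    h = rx * n[0] + ry * n[1] + rz * n[2]
    # in-plane coordinates (e1 = +X since n has no X component)
    e2 = np.cross(n, np.array([1.0, 0.0, 0.0]))
    ip1 = rx - h * n[0]
    ip2 = rx * 0 + ry * e2[1] + rz * e2[2]
    slab = ((np.abs(h) <= 0.5 * p.plateau_thickness)
            & ((ip1 / (0.5 * p.plateau_width)) ** 2
               + (ip2 / (0.5 * p.plateau_depth)) ** 2 <= 1.0))
    tibia |= slab

    labels[soft & (labels == BG)] = soft_lbl
    labels[femur] = femur_lbl
    labels[tibia] = tibia_lbl
    dk = np.sqrt(rx * rx + ry * ry + rz * rz)
    labels[tibia & (dk <= p.prox_tibia_extent)] = prox_lbl

    intensity[soft] = np.maximum(intensity[soft], p.soft_intensity)
    bone = femur | tibia
    if p.with_fibula:
        fib_lbl = FIBULA_LEFT if side == "left" else FIBULA_RIGHT
        lat = -_medial_sign(side)
        off_top = np.array([lat * 22.0, -8.0, -25.0])
        off_bot = np.array([lat * 16.0, -6.0, 12.0])
        fibula = (_dist_to_segment(px, py, pz, geom.KC + off_top,
                                   geom.AC + off_bot) <= p.fibula_radius)
        labels[fibula & ~femur & ~tibia] = fib_lbl
        bone = bone | fibula
    intensity[bone] = np.maximum(intensity[bone], p.bone_intensity)


def _voxelize(geoms, spacing: float, pad_anterior: float = 70.0,
              margin: float = 12.0) -> AnnotatedVolume:
    """Rasterize analytic legs onto a shared voxel grid.

    ``pad_anterior`` reserves room in +Y for the right-leg anterior-shift
    augmentation so it normally needs no re-padding.
    """
    soft_r = max(g.params.soft_tissue_radius for g in geoms)
    pts = np.array([q for g in geoms for q in (g.HC, g.KC, g.AC)])
    lo = pts.min(axis=0) - (soft_r + max(g.params.head_radius for g in geoms)) - margin
    hi = pts.max(axis=0) + (soft_r + max(g.params.head_radius for g in geoms)) + margin
    hi[1] += pad_anterior
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    origin = lo
    px = (origin[0] + spacing * np.arange(shape[0]))[:, None, None]
    py = (origin[1] + spacing * np.arange(shape[1]))[None, :, None]
    pz = (origin[2] + spacing * np.arange(shape[2]))[None, None, :]

    intensity = np.zeros(tuple(shape), np.float32)
    labels = np.zeros(tuple(shape), np.uint8)
    for g in geoms:
        _paint_leg(intensity, labels, (px, py, pz), g)

    lms = LandmarkSet3D({g.side: {"HC": g.HC.copy(), "KC": g.KC.copy(), "AC": g.AC.copy()}
                         for g in geoms})
    vol = AnnotatedVolume(intensity, labels, np.full(3, float(spacing)), origin, lms)
    for side in lms.sides:
        for name, pt in lms[side].items():
            if not vol.contains_point(pt):
                raise SizingError(f"landmark {side}/{name} outside grid")
    return vol


# ---------------------------------------------------------------------------
# Public generation API
# ---------------------------------------------------------------------------


def generate_leg(params: PhantomParams, side: str):
    """Build a single synthetic leg.

    Returns ``(AnnotatedVolume, truth)`` where ``truth`` holds the analytic
    ground truth ``{"MA_true": deg, "TS_true": deg}`` computed from the
    constructed landmark/plane geometry (not re-measured from voxels).
    """
    geom = leg_geometry(params, side)
    vol = _voxelize([geom], params.voxel_spacing)
    truth = {"MA_true": geom.ma_true, "TS_true": geom.ts_true}
    return vol, truth


DEFAULT_HIP_SEPARATION = 200.0  # mm between the two hip centers


def generate_subject(params_left: PhantomParams, params_right: PhantomParams,
                     seed: int = 0, hip_separation: float = DEFAULT_HIP_SEPARATION):
    """Both legs in a standing pose, pelvis-width apart, on one grid.

    Returns ``(AnnotatedVolume, truths)`` with per-side analytic ground truth.
    ``seed`` is accepted for interface symmetry; the construction itself is
    deterministic given the parameters.
    """
    if not np.isclose(params_left.voxel_spacing, params_right.voxel_spacing):
        raise ValueError("left/right voxel spacings must match")
    min_gap = params_left.soft_tissue_radius + params_right.soft_tissue_radius
    if hip_separation <= min_gap:
        raise PlacementError(
            f"hip_separation {hip_separation} mm overlaps soft tissue (need > {min_gap})")
    gl = leg_geometry(params_left, "left", x_offset=+0.5 * hip_separation)
    gr = leg_geometry(params_right, "right", x_offset=-0.5 * hip_separation)
    vol = _voxelize([gl, gr], params_left.voxel_spacing)
    truths = {"left": {"MA_true": gl.ma_true, "TS_true": gl.ts_true},
              "right": {"MA_true": gr.ma_true, "TS_true": gr.ts_true}}
    return vol, truths


# parameter -> (distribution, *args); distributions: uniform(lo, hi), normal(mu, sd)
DEFAULT_VARIABILITY = {
    "leg_length": ("normal", 700.0, 35.0),
    "femur_radius": ("normal", 14.0, 1.2),
    "tibia_radius": ("normal", 12.0, 1.0),
    "head_radius": ("normal", 22.0, 1.5),
    "plateau_width": ("normal", 60.0, 4.0),
    "plateau_depth": ("normal", 45.0, 3.0),
    "soft_tissue_radius": ("normal", 45.0, 3.0),
    "varus_angle": ("uniform", 2.0, 10.0),
    "slope_angle": ("uniform", 2.0, 12.0),
}


def _draw_params(base: PhantomParams, variability: dict, rng: np.random.Generator,
                 seed: int) -> PhantomParams:
    kw = {"seed": seed}
    for name, spec in variability.items():
        kind, a, b = spec
        if kind == "uniform":
            val = rng.uniform(a, b)
        elif kind == "normal":
            val = rng.normal(a, b)
        else:
            raise ValueError(f"unknown distribution {kind!r}")
        if name == "varus_angle":
            val = float(np.clip(val, -20.0, 20.0))
        elif name == "slope_angle":
            val = float(np.clip(val, 0.0, 20.0))
        else:
            val = float(max(val, 0.25 * abs(a)))
        kw[name] = val
    return base.replace(**kw)


@dataclass
class Cohort:
    """A list of synthetic patients plus the parameter manifest."""

    volumes: list           # list[AnnotatedVolume]
    truths: list            # list[dict side -> {"MA_true","TS_true"}]
    manifest: pd.DataFrame  # one row per patient/side with drawn parameters
    seed: int

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self) -> Iterator:
        return iter(self.volumes)


def generate_cohort(n_patients: int, base_params: PhantomParams | None = None,
                    variability: dict | None = None, seed: int = 0,
                    hip_separation: float = DEFAULT_HIP_SEPARATION) -> Cohort:
    """Draw ``n_patients`` subjects with per-patient parameter variation.

    Left and right legs of a patient share size parameters but draw deformity
    angles independently (HTO candidates typically present asymmetric varus).
    The drawn values are recorded in the manifest, one row per (patient, side).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    base = base_params or PhantomParams()
    var = variability if variability is not None else DEFAULT_VARIABILITY
    rng = np.random.default_rng(seed)
    volumes, truths, rows = [], [], []
    for i in range(n_patients):
        pl = _draw_params(base, var, rng, seed=int(rng.integers(2**31)))
        angles = {k: var[k] for k in ("varus_angle", "slope_angle") if k in var}
        pr = pl
        for name, spec in angles.items():
            kind, a, b = spec
            val = rng.uniform(a, b) if kind == "uniform" else rng.normal(a, b)
            pr = pr.replace(**{name: float(np.clip(val, -20.0 if name == "varus_angle" else 0.0, 20.0))})
        vol, truth = generate_subject(pl, pr, hip_separation=hip_separation)
        volumes.append(vol)
        truths.append(truth)
        for side, pp in (("left", pl), ("right", pr)):
            row = {"patient": i, "side": side}
            row.update({k: getattr(pp, k) for k in
                        ("leg_length", "femur_radius", "tibia_radius", "head_radius",
                         "plateau_width", "plateau_depth", "soft_tissue_radius",
                         "varus_angle", "slope_angle", "voxel_spacing")})
            rows.append(row)
    return Cohort(volumes, truths, pd.DataFrame(rows), seed)
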