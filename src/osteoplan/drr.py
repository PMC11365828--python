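"""Biplanar radiograph simulation (EOS-style) and dataset assembly.

Digitally reconstructed radiographs are line integrals of the phantom
intensity volume.  The imaging device is modelled after a calibrated biplanar
system whose two views are orthogonal (frontal rays along -Y, sagittal rays
along -X) and share the vertical Z axis: the emitter is a horizontal fan
translated vertically, so magnification — in fan mode — acts only on the
horizontal detector coordinate while the vertical coordinate maps 1:1.

The module also implements the clinical acquisition quirks used for training
data: the right leg is shifted anteriorly (40-60 mm) and rotated (10-20 deg)
in the sagittal plane, mimicking the instruction that patients place the
right foot slightly in front of the left; and single-leg sagittal target
images pass through a logistic contrast transform
``f(x) = 1 / (1 + exp(-(x - 0.45)/0.12))`` that isolates bone from the
soft-tissue envelope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .phantom import (AnnotatedVolume, Cohort, LandmarkSet3D,
                      RIGHT_LABELS, SIDE_LABELS)

log = logging.getLogger("osteoplan.drr")

# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

#: axis whose coordinate becomes the horizontal detector coordinate u
_U_AXIS = {"frontal": 0, "sagittal": 1}
#: axis along which rays travel (integrated out)
_RAY_AXIS = {"frontal": 1, "sagittal": 0}


@dataclass(frozen=True)
class ProjectionGeometry:
    """Calibrated projection model for one view.

    ``iso_center`` is the world point that maps to the detector center; both
    views of a study must share it (and the Z axis) for biplanar consistency.
    In fan mode the source sits at ``source_axis_distance`` from the iso
    center along the ray axis and the detector ``axis_detector_distance``
    beyond it on the opposite side.
    """

    view: str                      # "frontal" | "sagittal"
    mode: str = "parallel"         # "parallel" | "fan"
    detector_size: tuple = (128, 128)   # (nu, nv) pixels
    pixel_spacing: float = 6.0     # mm
    source_axis_distance: float = 1300.0
    axis_detector_distance: float = 300.0
    vertical_translation_step: float = 6.0
    iso_center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.view not in ("frontal", "sagittal"):
            raise ValueError("view must be frontal|sagittal")
        if self.mode not in ("parallel", "fan"):
            raise ValueError("mode must be parallel|fan")
        if self.mode == "fan" and (self.source_axis_distance <= 0
                                   or self.axis_detector_distance <= 0):
            raise ValueError("fan mode requires positive distances")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")

    @property
    def u_axis(self) -> int:
        return _U_AXIS[self.view]

    @property
    def ray_axis(self) -> int:
        return _RAY_AXIS[self.view]

    @property
    def magnification(self) -> float:
        d = self.source_axis_distance
        return (d + self.axis_detector_distance) / d

    def with_iso(self, iso_center) -> "ProjectionGeometry":
        return replace(self, iso_center=tuple(float(c) for c in iso_center))


def geometry_pair(volume: AnnotatedVolume, mode: str = "parallel",
                  detector_size: tuple = (128, 128),
                  pixel_spacing: float = 6.0) -> tuple:
    """Frontal + sagittal geometries sharing the volume's world center."""
    lo, hi = volume.world_bounds()
    iso = tuple(0.5 * (lo + hi))
    mk = lambda view: ProjectionGeometry(view=view, mode=mode,
                                         detector_size=detector_size,
                                         pixel_spacing=pixel_spacing,
                                         vertical_translation_step=pixel_spacing,
                                         iso_center=iso)
    return mk("frontal"), mk("sagittal")


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Radiograph
# ---------------------------------------------------------------------------


@dataclass
class Radiograph:
    """A single simulated radiograph; ``pixels[v, u]`` with values in [0, 1].

    u runs along +X (frontal) or +Y (sagittal); v runs top-down (-Z).
    """

    pixels: np.ndarray
    view: str
    geometry: ProjectionGeometry
    meta: dict = field(default_factory=dict)

    @property
    def pixel_spacing(self) -> float:
        return self.geometry.pixel_spacing

    def copy(self) -> "Radiograph":
        return Radiograph(self.pixels.copy(), self.view, self.geometry, dict(self.meta))

    def save(self, path) -> None:
        from PIL import Image
        arr = np.clip(self.pixels, 0.0, 1.0)
        Image.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(str(path))


# ---------------------------------------------------------------------------
# Point projection
# ---------------------------------------------------------------------------


def project_point(p, geom: ProjectionGeometry):
    """Map a 3D world point (mm) to continuous detector coordinates (u, v) px.

    The vertical coordinate depends on Z only (translating-emitter property);
    in fan mode the horizontal coordinate magnifies with depth along the ray.
    """
    p = np.asarray(p, float)
    c = np.asarray(geom.iso_center, float)
    nu, nv = geom.detector_size
    s = geom.pixel_spacing
    rel = p - c
    if geom.mode == "parallel":
        u_mm = rel[geom.u_axis]
    else:
        depth = rel[geom.ray_axis]
        if depth >= geom.source_axis_distance:
            raise GeometryError("point lies at or behind the fan source")
        u_mm = rel[geom.u_axis] * (geom.source_axis_distance
                                   + geom.axis_detector_distance) / (
                                       geom.source_axis_distance - depth)
    u = u_mm / s + 0.5 * (nu - 1)
    v = -rel[2] / s + 0.5 * (nv - 1)
    return float(u), float(v)


# ---------------------------------------------------------------------------
# DRR projection
# ---------------------------------------------------------------------------


def _parallel_integral(vol: AnnotatedVolume, inten: np.ndarray,
                       geom: ProjectionGeometry) -> np.ndarray:
    ray = geom.ray_axis
    integ = inten.sum(axis=ray) * vol.spacing[ray]   # axes: (other, z)
    # remaining axes after removing ray axis: for frontal (x, z); sagittal (y, z)
    nu, nv = geom.detector_size
    s = geom.pixel_spacing
    c = np.asarray(geom.iso_center, float)
    uu = (np.arange(nu) - 0.5 * (nu - 1)) * s + c[geom.u_axis]
    vv = c[2] - (np.arange(nv) - 0.5 * (nv - 1)) * s
    iu = (uu - vol.origin[geom.u_axis]) / vol.spacing[geom.u_axis]
    iz = (vv - vol.origin[2]) / vol.spacing[2]
    gi, gz = np.meshgrid(iu, iz)            # (nv, nu)
    return ndimage.map_coordinates(integ, [gi.ravel(), gz.ravel()], order=1,
                                   mode="constant", cval=0.0).reshape(nv, nu)


def _fan_integral(vol: AnnotatedVolume, inten: np.ndarray,
                  geom: ProjectionGeometry) -> np.ndarray:
    nu, nv = geom.detector_size
    s = geom.pixel_spacing
    c = np.asarray(geom.iso_center, float)
    ua, ra = geom.u_axis, geom.ray_axis
    sad, add = geom.source_axis_distance, geom.axis_detector_distance
    # sample each source->pixel ray at the volume's native resolution
    lo, hi = vol.world_bounds()
    n_samp = int(np.ceil((hi[ra] - lo[ra]) / vol.spacing[ra])) + 2
    depth = np.linspace(hi[ra], lo[ra], n_samp) - c[ra]        # along ray axis
    u_det = (np.arange(nu) - 0.5 * (nu - 1)) * s               # mm on detector
    # horizontal world coordinate along the ray: x(depth) for detector column u
    frac = (sad - depth) / (sad + add)                         # (n_samp,)
    u_world = u_det[None, :] * frac[:, None] + c[ua]           # (n_samp, nu)
    ray_world = depth[:, None] + c[ra]
    vv = c[2] - (np.arange(nv) - 0.5 * (nv - 1)) * s
    iz = (vv - vol.origin[2]) / vol.spacing[2]

    iu = (u_world - vol.origin[ua]) / vol.spacing[ua]          # (n_samp, nu)
    ir = (np.broadcast_to(ray_world, u_world.shape) - vol.origin[ra]) / vol.spacing[ra]
    # path-length factor per column: ds = dr * sqrt(1 + (du/dr)^2)
    dr = abs(depth[1] - depth[0])
    dl = dr * np.sqrt(1.0 + (u_det / (sad + add)) ** 2)        # (nu,)

    out = np.empty((nv, nu), np.float32)
    coords_u = iu.ravel()
    coords_r = ir.ravel()
    plane_axes = (ua, ra)
    for j, z in enumerate(iz):
        # interpolate the volume in the z slab at index z
        z0 = int(np.floor(z))
        tz = z - z0
        def slab(zi):
            if zi < 0 or zi >= vol.shape[2]:
                return None
            return inten[:, :, zi] if ua == 0 else inten[:, :, zi].T
        a, b = slab(z0), slab(z0 + 1)
        if a is None and b is None:
            out[j] = 0.0
            continue
        if a is None:
            sl = b * tz
        elif b is None:
            sl = a * (1.0 - tz)
        else:
            sl = a * (1.0 - tz) + b * tz
        vals = ndimage.map_coordinates(sl, [coords_u, coords_r], order=1,
                                       mode="constant", cval=0.0)
        out[j] = vals.reshape(u_world.shape).sum(axis=0) * dl
    return out


def project(volume: AnnotatedVolume, geom: ProjectionGeometry,
            mask=None, normalize: bool = True) -> Radiograph:
    """Simulate one radiograph as line integrals of the intensity volume.

    ``mask`` optionally restricts the integrand to voxels carrying the given
    label codes.  Parallel mode integrates along the view's ray axis exactly;
    fan mode traces per-row fans from a point source translated vertically.
    Pixels are min-max normalized to [0, 1] (the range is kept in ``meta`` so
    linearity can be assessed pre-normalization); an empty volume yields an
    all-zero image.
    """
    inten = volume.masked_intensity(mask) if mask is not None else volume.intensity
    raw = (_parallel_integral if geom.mode == "parallel" else _fan_integral)(
        volume, inten, geom)
    lo, hi = float(raw.min()), float(raw.max())
    meta = {"raw_min": lo, "raw_max": hi, "normalized": normalize}
    if normalize and hi > lo:
        pix = (raw - lo) / (hi - lo)
    elif normalize:
        pix = np.zeros_like(raw)
    else:
        pix = raw
    return Radiograph(pix.astype(np.float32), geom.view, geom, meta)


# ---------------------------------------------------------------------------
# Contrast transform
# ---------------------------------------------------------------------------


def contrast_enhance(image: Radiograph, midpoint: float = 0.45,
                     width: float = 0.12) -> Radiograph:
    """Logistic contrast transform suppressing soft tissue around bone.

    ``f(x) = 1 / (1 + exp(-(x - midpoint)/width))`` applied per pixel; the
    defaults are the empirically chosen reference parameters.
    """
    out = image.copy()
    out.pixels = (1.0 / (1.0 + np.exp(-(image.pixels - midpoint) / width))
                  ).astype(np.float32)
    out.meta["contrast_enhanced"] = {"midpoint": midpoint, "width": width}
    return out


# ---------------------------------------------------------------------------
# Right-leg augmentation
# ---------------------------------------------------------------------------


def _rot_x(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def augment_right_leg(volume: AnnotatedVolume, rng: np.random.Generator,
                      shift_range=(40.0, 60.0), rotation_range=(10.0, 20.0),
                      enabled: bool = True):
    """Shift the right leg anteriorly and rotate it in the sagittal plane.

    The shift is drawn U(40, 60) mm along +Y, the rotation U(10, 20) degrees
    (sign drawn uniformly) about the medial-lateral axis through the sagittal
    image center.  Right-leg voxels and landmarks move; the left leg is left
    untouched.  Returns ``(augmented_volume, record)`` with the applied
    transform recorded; ``enabled=False`` is the identity (bit-equal copy).
    """
    if enabled and not np.isin(volume.labels, RIGHT_LABELS).any():
        raise ValueError("no right-leg labels present")
    out = volume.copy()
    if not enabled:
        return out, {"shift_mm": 0.0, "rotation_deg": 0.0, "enabled": False}

    shift = float(rng.uniform(*shift_range))
    rot = float(rng.uniform(*rotation_range)) * float(rng.choice([-1.0, 1.0]))
    lo, hi = volume.world_bounds()
    center = 0.5 * (lo + hi)       # sagittal image center (its Y, Z matter)
    R = _rot_x(np.deg2rad(rot))
    t = np.array([0.0, shift, 0.0])

    def fwd(p):
        return R @ (p - center) + center + t

    # predicted right-leg bounds after transform; pad if needed
    rmask = np.isin(volume.labels, RIGHT_LABELS)
    idx = np.argwhere(rmask)
    wpts = volume.origin + idx * volume.spacing
    corners = wpts[[wpts[:, 1].argmin(), wpts[:, 1].argmax(),
                    wpts[:, 2].argmin(), wpts[:, 2].argmax()]]
    moved = np.array([fwd(q) for q in corners])
    pad_lo = np.maximum(np.ceil((lo - moved.min(axis=0) + volume.spacing)
                                / volume.spacing), 0).astype(int)
    pad_hi = np.maximum(np.ceil((moved.max(axis=0) - hi + volume.spacing)
                                / volume.spacing), 0).astype(int)
    if pad_lo.any() or pad_hi.any():
        warnings.warn("right-leg augmentation exceeds grid; padding applied")
        pads = tuple((int(a), int(b)) for a, b in zip(pad_lo, pad_hi))
        out.intensity = np.pad(out.intensity, pads)
        out.labels = np.pad(out.labels, pads)
        out.origin = out.origin - pad_lo * out.spacing

    rints = np.where(rmask, volume.intensity, 0.0).astype(np.float32)
    rlbls = np.where(rmask, volume.labels, 0).astype(np.uint8)
    # inverse index-space affine for scipy (output index -> input index)
    Rinv = R.T
    sp = out.spacing
    mat = Rinv  # isotropic same spacing on both grids
    off = (Rinv @ (out.origin - center - t) + center - volume.origin) / volume.spacing
    moved_int = ndimage.affine_transform(rints, mat, offset=off,
                                         output_shape=out.shape, order=1, cval=0.0)
    moved_lbl = ndimage.affine_transform(rlbls, mat, offset=off,
                                         output_shape=out.shape, order=0, cval=0)
    base_keep = ~np.isin(out.labels, RIGHT_LABELS)
    out.intensity = np.where(base_keep, out.intensity, 0.0).astype(np.float32)
    out.labels = np.where(base_keep, out.labels, 0).astype(np.uint8)
    put = moved_lbl > 0
    out.labels[put] = moved_lbl[put]
    out.intensity = np.maximum(out.intensity, moved_int).astype(np.float32)

    for name, pt in out.landmarks["right"].items():
        out.landmarks["right"][name] = fwd(pt)
    record = {"shift_mm": shift, "rotation_deg": rot, "enabled": True,
              "center": [float(x) for x in center]}
    return out, record


# ---------------------------------------------------------------------------
# Heatmaps
# ---------------------------------------------------------------------------


@dataclass
class HeatmapStack:
    """Per-landmark Gaussian channels in image space; values in [0, 1]."""

    data: np.ndarray   # (C, H, W)
    names: list        # channel -> landmark name

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]


def make_heatmaps(landmarks2d: dict, sigma: float, shape: tuple) -> HeatmapStack:
    """Gaussian target heatmaps, one channel per landmark, peak value 1.

    ``landmarks2d`` maps landmark name -> (u, v); ``shape`` is (H, W).
    Each channel is an unnormalized Gaussian centred on the landmark and
    rescaled so the maximal pixel is exactly 1 (hence the channel argmax is
    the landmark rounded to the nearest pixel).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    h, w = shape
    vv, uu = np.mgrid[0:h, 0:w]
    chans, names = [], []
    for name, (u0, v0) in landmarks2d.items():
        g = np.exp(-((uu - u0) ** 2 + (vv - v0) ** 2) / (2.0 * sigma ** 2))
        m = g.max()
        chans.append(g / m if m > 0 else g)
        names.append(name)
    return HeatmapStack(np.stack(chans), names)


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

LANDMARK_NAMES = ("HC", "KC", "AC")


@dataclass
class BiplanarStudy:
    """One simulated biplanar acquisition plus its training targets.

    ``landmarks2d`` holds continuous (u, v) pixel coordinates per view:
    ``frontal`` carries 6 entries (``left/HC`` ... ``right/AC``), each
    single-leg sagittal view 3.  ``extras`` is a scratch area the dataset
    builder uses for per-leg ground-truth crops.
    """

    case_id: str
    I_fron: Radiograph
    I_sag: Radiograph
    I_sag_L: Radiograph | None
    I_sag_R: Radiograph | None
    landmarks2d: dict
    landmarks3d: LandmarkSet3D
    augmentation: dict
    single_leg: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def patient_id(self) -> str:
        return self.case_id.split("/")[0]


def make_study(volume: AnnotatedVolume, geom_frontal: ProjectionGeometry,
               geom_sagittal: ProjectionGeometry, case_id: str = "case",
               augmentation: dict | None = None) -> BiplanarStudy:
    """Project a two-leg volume into a full biplanar training study.

    Frontal and sagittal images come from the full volume; the separated-leg
    sagittal targets from single-leg masked volumes passed through the
    contrast transform.  All 2D landmarks are projected per view.
    """
    if geom_frontal.detector_size != geom_sagittal.detector_size:
        raise ValueError("views must share detector_size")
    sides = volume.landmarks.sides
    single = len(sides) < 2

    I_fron = project(volume, geom_frontal)
    I_sag = project(volume, geom_sagittal)
    seps = {}
    for side in sides:
        img = project(volume, geom_sagittal, mask=SIDE_LABELS[side])
        seps[side] = contrast_enhance(img)
    lms = {"frontal": {}, "sagittal_left": {}, "sagittal_right": {}}
    for side in sides:
        for name in LANDMARK_NAMES:
            p = volume.landmarks[side][name]
            lms["frontal"][f"{side}/{name}"] = project_point(p, geom_frontal)
            lms[f"sagittal_{side}"][name] = project_point(p, geom_sagittal)
    return BiplanarStudy(
        case_id=case_id, I_fron=I_fron, I_sag=I_sag,
        I_sag_L=seps.get("left"), I_sag_R=seps.get("right"),
        landmarks2d=lms, landmarks3d=volume.landmarks.copy(),
        augmentation=augmentation or {"enabled": False},
        single_leg=single)


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------


@dataclass
class DatasetSplit:
    """Patient-level train/val/test partition (augmented copies stay together)."""

    train: list
    val: list
    test: list
    seed: int

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split partitions must be disjoint")

    def partition_of(self, patient_id) -> str:
        for name in ("train", "val", "test"):
            if patient_id in getattr(self, name):
                return name
        raise KeyError(patient_id)


def split_patients(patient_ids, seed: int = 0) -> DatasetSplit:
    """90/10 test split, then 80/20 train/val, all at patient level.

    Counts use ``round`` with a minimum of one test patient (the reference
    protocol states the fractions only).
    """
    ids = list(patient_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 patients to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    n_test = max(int(round(0.10 * len(ids))), 1)
    test = [ids[i] for i in order[:n_test]]
    pool = order[n_test:]
    n_val = max(int(round(0.20 * len(pool))), 1)
    val = [ids[i] for i in pool[:n_val]]
    train = [ids[i] for i in pool[n_val:]]
    return DatasetSplit(sorted(train), sorted(val), sorted(test), seed)


# ---------------------------------------------------------------------------
# Reconstruction crops
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReconSpec:
    """Geometry of the per-leg knee-centred reconstruction sample.

    A ``crop_px`` x ``crop_px`` window (detector pixels) is cut around the
    knee from the frontal image and from that leg's sagittal image, upsampled
    ``upsample``-fold for the network (whose two pooled 2D levels bring it
    back down), and the output cube of edge ``crop_px * upsample / 4`` voxels
    covers the same world region at detector pixel spacing.  The window is
    centred ``v_offset_px`` below the knee so the crop favours the proximal
    tibia rather than the distal femur.
    """

    crop_px: int = 32
    upsample: int = 4
    v_offset_px: int = 10

    @property
    def cube(self) -> int:
        return self.crop_px * self.upsample // 4


def crop_window(center_uv, spec: ReconSpec):
    """Integer (row0, col0) of the crop window for a continuous (u, v) center."""
    u, v = center_uv
    half = spec.crop_px // 2
    return int(round(v)) - half, int(round(u)) - half


def extract_by_window(image: Radiograph, row0: int, col0: int, size: int):
    """Zero-padded window ``[row0:row0+size, col0:col0+size]``."""
    out = np.zeros((size, size), np.float32)
    h, w = image.pixels.shape
    r0, r1 = max(row0, 0), min(row0 + size, h)
    c0, c1 = max(col0, 0), min(col0 + size, w)
    if r1 > r0 and c1 > c0:
        out[r0 - row0:r1 - row0, c0 - col0:c1 - col0] = image.pixels[r0:r1, c0:c1]
    return out


def extract_crop(image: Radiograph, center_uv, spec: ReconSpec):
    row0, col0 = crop_window(center_uv, spec)
    return extract_by_window(image, row0, col0, spec.crop_px), (row0, col0)


def upsample_crop(crop: np.ndarray, factor: int) -> np.ndarray:
    return np.repeat(np.repeat(crop, factor, axis=0), factor, axis=1)


def knee_crop_centers(study: BiplanarStudy, side: str,
                      spec: ReconSpec | None = None) -> dict:
    """Ground-truth crop centers: knee (u, v) per view, sharing the frontal v."""
    spec = spec or ReconSpec()
    uf, vf = study.landmarks2d["frontal"][f"{side}/KC"]
    us, _ = study.landmarks2d[f"sagittal_{side}"]["KC"]
    vc = vf + spec.v_offset_px
    return {"frontal": (uf, vc), "sagittal": (us, vc)}


def recon_grid(study: BiplanarStudy, side: str, centers: dict,
               spec: ReconSpec | None = None) -> dict:
    """World-frame description of the reconstruction cube.

    The cube axes follow the network tensor layout (Y, V, X): index ``iy``
    advances along +Y (sagittal u), ``iv`` downward (-Z, shared between the
    views), ``ix`` along +X (frontal u); voxel size equals the detector pixel
    spacing.
    """
    spec = spec or ReconSpec()
    gf, gs = study.I_fron.geometry, study.I_sag.geometry
    s = gf.pixel_spacing
    nu, nv = gf.detector_size
    rf0, cf0 = crop_window(centers["frontal"], spec)
    rs0, cs0 = crop_window((centers["sagittal"][0], centers["frontal"][1]), spec)
    cf = np.asarray(gf.iso_center, float)
    cs = np.asarray(gs.iso_center, float)
    x0 = cf[0] + (cf0 - 0.5 * (nu - 1)) * s
    y0 = cs[1] + (cs0 - 0.5 * (nu - 1)) * s
    z_top = cf[2] - (rf0 - 0.5 * (nv - 1)) * s
    return {"x0": float(x0), "y0": float(y0), "z_top": float(z_top),
            "spacing": float(s), "n": spec.cube,
            "windows": {"frontal": (rf0, cf0), "sagittal": (rf0, cs0)}}


def rasterize_prox_tibia(volume: AnnotatedVolume, side: str,
                         grid: dict) -> np.ndarray:
    """Sample the proximal-tibia label of one side onto a recon grid.

    Returns a binary uint8 array in the (Y, V, X) network layout.
    """
    from .phantom import PROX_TIBIA_LABELS

    n, s = grid["n"], grid["spacing"]
    iy, iv, ix = np.mgrid[0:n, 0:n, 0:n]
    pts = np.stack([grid["x0"] + ix * s,
                    grid["y0"] + iy * s,
                    grid["z_top"] - iv * s], axis=-1)
    idx = np.rint((pts - volume.origin) / volume.spacing).astype(int)
    valid = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=-1)
    out = np.zeros((n, n, n), np.uint8)
    ii = idx[valid]
    out[valid] = (volume.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
                  == PROX_TIBIA_LABELS[side]).astype(np.uint8)
    return out


def attach_recon_targets(study: BiplanarStudy, volume: AnnotatedVolume,
                         spec: ReconSpec | None = None) -> None:
    """Stash ground-truth recon crops/targets for each side on the study."""
    spec = spec or ReconSpec()
    rec = {}
    for side in volume.landmarks.sides:
        centers = knee_crop_centers(study, side, spec)
        grid = recon_grid(study, side, centers, spec)
        target = rasterize_prox_tibia(volume, side, grid)
        rec[side] = {"centers": centers, "grid": grid, "target": target}
    study.extras["recon"] = rec
    study.extras["recon_spec"] = spec


def build_dataset(cohort: Cohort, n_aug: int = 3, seed: int = 0,
                  mode: str = "parallel", detector_size=(128, 128),
                  pixel_spacing: float = 6.0, augment: bool = True,
                  recon_spec: "ReconSpec | None" = None,
                  with_recon_targets: bool = False):
    """Augmented biplanar studies + one shared patient-level split.

    Per patient, ``n_aug`` independently augmented acquisitions are simulated
    (right-leg anterior shift/rotation redrawn each time), mirroring the
    3x-repetition that turns 175 patients into 525 image pairs.  The same
    split serves all three networks.
    """
    if n_aug < 1:
        raise ValueError("n_aug must be >= 1")
    rng = np.random.default_rng(seed)
    studies = []
    for i, vol in enumerate(cohort.volumes):
        pid = f"p{i:03d}"
        for a in range(n_aug):
            av, rec = augment_right_leg(vol, rng, enabled=augment)
            gf, gs = geometry_pair(av, mode=mode, detector_size=detector_size,
                                   pixel_spacing=pixel_spacing)
            study = make_study(av, gf, gs, case_id=f"{pid}/a{a}", augmentation=rec)
            study.extras["patient_index"] = i
            if with_recon_targets:
                attach_recon_targets(study, av, recon_spec)
            studies.append(study)
    split = split_patients([f"p{i:03d}" for i in range(len(cohort.volumes))],
                           seed=seed)
    return studies, split
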