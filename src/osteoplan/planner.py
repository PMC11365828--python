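"""Automated medial opening-wedge high-tibial-osteotomy planning.

A plan is a 12-parameter vector: the osteotomy (hinge) axis position in the
frontal plane (2) and orientation (2 angles), the opening angle (1), the
inclination of the cutting plane about the axis (1), and the fixation-plate
pose (3 translations + 3 rotations).  Plan quality is a three-component
fitness: deviation from the target mechanical axis, deviation from the
target tibial slope, and the mean distance between the plate and the bone
surface.  The search runs a non-dominated-sorting genetic algorithm
(NSGA-II: simulated binary crossover, polynomial mutation, crowding-distance
selection) over the plan space under configurable clinical feasibility
rules.

Conventions: the wedge opens medially, the hinge sits near the lateral
cortex, and the **distal** fragment (everything below the cutting plane,
including the ankle center) rotates about the hinge axis; positive opening
angles reduce varus on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as tm

from . import metrics as mx

INF_FITNESS = float("inf")


def _medial_sign(side: str) -> float:
    return 1.0 if side == "right" else -1.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanningTargets:
    """Target mechanical axis and tibial slope, degrees."""

    MA: float = 0.0
    TS: float = 5.0

    def __post_init__(self):
        if not (np.isfinite(self.MA) and np.isfinite(self.TS)):
            raise ValueError("targets must be finite")


_FIELDS = ("entry_x", "entry_z", "axis_azimuth", "axis_elevation",
           "opening_angle", "plane_inclination",
           "plate_x", "plate_y", "plate_z",
           "plate_rx", "plate_ry", "plate_rz")


@dataclass
class OsteotomyPlan:
    """The 12 osteotomy parameters (mm / degrees).

    ``(entry_x, entry_z)`` place the hinge axis in the frontal plane (its
    depth is taken at the knee-center Y); ``axis_azimuth/elevation`` orient
    it relative to the anteroposterior (+Y) direction; ``opening_angle`` is
    the wedge angle; ``plane_inclination`` tilts the cutting plane about the
    axis; the remaining six are the fixation-plate pose.
    """

    entry_x: float
    entry_z: float
    axis_azimuth: float = 0.0
    axis_elevation: float = 0.0
    opening_angle: float = 0.0
    plane_inclination: float = 0.0
    plate_x: float = 0.0
    plate_y: float = 0.0
    plate_z: float = 0.0
    plate_rx: float = 0.0
    plate_ry: float = 0.0
    plate_rz: float = 0.0
    case_id: str | None = None

    def __post_init__(self):
        if self.opening_angle < 0:
            raise ValueError("opening_angle must be >= 0")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _FIELDS], float)

    @classmethod
    def from_vector(cls, v, case_id=None) -> "OsteotomyPlan":
        v = np.asarray(v, float)
        if v.shape != (12,):
            raise ValueError("plan vector must have length 12")
        return cls(**dict(zip(_FIELDS, map(float, v))), case_id=case_id)

    def axis_direction(self) -> np.ndarray:
        az = np.deg2rad(self.axis_azimuth)
        el = np.deg2rad(self.axis_elevation)
        return np.array([np.sin(az) * np.cos(el),
                         np.cos(az) * np.cos(el),
                         np.sin(el)])

    def axis_point(self, y_depth: float) -> np.ndarray:
        return np.array([self.entry_x, y_depth, self.entry_z])

    def plane_normal(self) -> np.ndarray:
        """Normal of the cutting plane (contains the axis), oriented +Z-ish."""
        d = self.axis_direction()
        n0 = np.array([0.0, 0.0, 1.0]) - d[2] * d
        n0 /= np.linalg.norm(n0)
        return _rotate_about(n0, d, np.deg2rad(self.plane_inclination))

    def to_json_dict(self) -> dict:
        out = {f: float(getattr(self, f)) for f in _FIELDS}
        out["case_id"] = self.case_id
        return out

    @classmethod
    def from_json_dict(cls, d) -> "OsteotomyPlan":
        return cls(**{f: d[f] for f in _FIELDS}, case_id=d.get("case_id"))


@dataclass(frozen=True)
class FitnessVector:
    """Objectives, all minimized and >= 0 (inf marks an infeasible plan)."""

    dMA: float
    dTS: float
    plate_gap: float

    def as_tuple(self):
        return (self.dMA, self.dTS, self.plate_gap)

    @property
    def feasible(self) -> bool:
        return all(np.isfinite(self.as_tuple()))


@dataclass
class PlateModel:
    """A rigid rectangular plate footprint sampled as a planar point set.

    ``points`` live in the plate-local frame (footprint in the local XZ
    plane, outward face normal +Y-local); at least 20 samples so the mean
    plate-bone distance is a stable objective.
    """

    length: float = 60.0   # mm, along local z
    width: float = 16.0    # mm, along local x
    n_length: int = 7
    n_width: int = 4

    def __post_init__(self):
        if self.n_length * self.n_width < 20:
            raise ValueError("plate needs >= 20 sample points")

    @property
    def points(self) -> np.ndarray:
        xs = np.linspace(-self.width / 2, self.width / 2, self.n_width)
        zs = np.linspace(-self.length / 2, self.length / 2, self.n_length)
        gx, gz = np.meshgrid(xs, zs)
        return np.stack([gx.ravel(), np.zeros(gx.size), gz.ravel()], axis=1)

    def world_points(self, plan: OsteotomyPlan) -> np.ndarray:
        R = _euler_xyz(plan.plate_rx, plan.plate_ry, plan.plate_rz)
        t = np.array([plan.plate_x, plan.plate_y, plan.plate_z])
        return self.points @ R.T + t


@dataclass
class PlanningCase:
    """One leg to plan on: proximal-tibia mesh + joint-center landmarks."""

    mesh: tm.Trimesh
    landmarks: dict          # {"HC","KC","AC"} -> (3,) mm
    side: str = "right"
    case_id: str | None = None
    _plane: mx.Plane | None = field(default=None, repr=False)

    @property
    def plateau_plane(self) -> mx.Plane:
        # the proximal fragment never moves, so the articular plane is fixed
        if self._plane is None:
            self._plane = mx.fit_plateau_plane(self.mesh, self.landmarks["KC"])
        return self._plane

    def preop(self) -> mx.DeformityMeasurements:
        ma = mx.mechanical_axis_angle(self.landmarks["HC"], self.landmarks["KC"],
                                      self.landmarks["AC"], side=self.side)
        ts = mx.tibial_slope(self.plateau_plane, self.landmarks["KC"],
                             self.landmarks["AC"])
        return mx.DeformityMeasurements(MA=ma, TS=ts)


# ---------------------------------------------------------------------------
# Rigid helpers
# ---------------------------------------------------------------------------


def _rotate_about(v, axis, angle_rad):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return (v * c + np.cross(axis, v) * s
            + axis * (axis @ v) * (1.0 - c))


def _euler_xyz(rx_deg, ry_deg, rz_deg):
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _rotation_matrix(axis, angle_rad):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C]])


# ---------------------------------------------------------------------------
# Correction simulation
# ---------------------------------------------------------------------------


@dataclass
class CorrectionResult:
    landmarks: dict
    mesh: tm.Trimesh
    achieved: mx.DeformityMeasurements | None
    feasible: bool
    reason: str = ""


def simulate_correction(landmarks: dict, mesh: tm.Trimesh,
                        plan: OsteotomyPlan, side: str = "right",
                        plateau_plane: mx.Plane | None = None) -> CorrectionResult:
    """Apply a medial opening wedge and re-measure the deformity.

    The part of the tibia distal to the cutting plane — plus the ankle
    center — rotates rigidly about the hinge axis by the opening angle (the
    rotation sense is chosen per side so positive angles reduce varus).  MA
    and TS are recomputed from the corrected geometry; the articular plane is
    the (unmoved) proximal plateau's.  A hinge outside the bone yields an
    infeasible flag rather than an exception.
    """
    K = np.asarray(landmarks["KC"], float)
    P = plan.axis_point(K[1])
    lo, hi = mesh.bounds
    pad = 2.0
    if not (np.all(P >= lo - pad) and np.all(P <= hi + pad)):
        return CorrectionResult(landmarks, mesh, None, False,
                                "hinge axis outside the bone")
    if plan.opening_angle >= 25.0:
        return CorrectionResult(landmarks, mesh, None, False,
                                "opening angle out of range")
    d = plan.axis_direction()
    n = plan.plane_normal()
    angle = np.deg2rad(plan.opening_angle) * _medial_sign(side)
    R = _rotation_matrix(d, angle)

    verts = np.asarray(mesh.vertices, float).copy()
    below = (verts - P) @ n < 0.0
    verts[below] = (verts[below] - P) @ R.T + P
    corrected = tm.Trimesh(vertices=verts, faces=mesh.faces.copy(),
                           process=False)

    new_lm = {k: np.asarray(v, float).copy() for k, v in landmarks.items()}
    A = new_lm["AC"]
    if (A - P) @ n < 0.0:
        new_lm["AC"] = R @ (A - P) + P

    plane = plateau_plane
    if plane is None:
        plane = mx.fit_plateau_plane(mesh, K)
    ma = mx.mechanical_axis_angle(new_lm["HC"], new_lm["KC"], new_lm["AC"],
                                  side=side)
    ts = mx.tibial_slope(plane, new_lm["KC"], new_lm["AC"])
    return CorrectionResult(new_lm, corrected,
                            mx.DeformityMeasurements(MA=ma, TS=ts), True)


# ---------------------------------------------------------------------------
# Fitness and constraints
# ---------------------------------------------------------------------------


def fitness(plan: OsteotomyPlan, case: PlanningCase, targets: PlanningTargets,
            plate: PlateModel) -> FitnessVector:
    """Evaluate the three objectives of one plan on one case.

    ``dMA``/``dTS`` are absolute deviations of the corrected deformity from
    the targets; ``plate_gap`` is the mean distance of the plate sample
    points to the corrected bone surface.  Infeasible plans map to an
    all-infinite sentinel vector.
    """
    res = simulate_correction(case.landmarks, case.mesh, plan, side=case.side,
                              plateau_plane=case.plateau_plane)
    if not res.feasible:
        return FitnessVector(INF_FITNESS, INF_FITNESS, INF_FITNESS)
    gap = float(mx.closest_point_distances(plate.world_points(plan),
                                           res.mesh).mean())
    return FitnessVector(abs(res.achieved.MA - targets.MA),
                         abs(res.achieved.TS - targets.TS), gap)


@dataclass(frozen=True)
class ConstraintRules:
    """Configurable clinical feasibility thresholds (mm)."""

    hinge_lateral_clearance: float = 10.0   # hinge must sit this far medial
    plane_below_plateau: float = 15.0       # cut depth below the knee center
    z_band_mm: float = 6.0                  # cortex-probing band half-height


@dataclass
class FeasibilityReport:
    rules: dict  # name -> {"ok": bool, "value": float, "threshold": float}

    @property
    def feasible(self) -> bool:
        return all(r["ok"] for r in self.rules.values())


def check_constraints(plan: OsteotomyPlan, case: PlanningCase,
                      rules: ConstraintRules | None = None,
                      plate: PlateModel | None = None) -> FeasibilityReport:
    """Per-rule feasibility report (never raises).

    Default rules: the hinge keeps a minimum clearance from the lateral
    cortex; the cutting plane passes at least a minimum depth below the
    plateau; the plate footprint stays on the medial cortex.
    """
    rules = rules or ConstraintRules()
    plate = plate or PlateModel()
    K = np.asarray(case.landmarks["KC"], float)
    m = _medial_sign(case.side)
    verts = np.asarray(case.mesh.vertices, float)
    report = {}

    band = np.abs(verts[:, 2] - plan.entry_z) <= rules.z_band_mm
    if band.any():
        lat_x = verts[band, 0].min() if m > 0 else verts[band, 0].max()
        clearance = m * (plan.entry_x - lat_x)
    else:
        clearance = -np.inf
    report["hinge_lateral_clearance"] = {
        "ok": bool(clearance >= rules.hinge_lateral_clearance),
        "value": float(clearance),
        "threshold": rules.hinge_lateral_clearance}

    n = plan.plane_normal()
    P = plan.axis_point(K[1])
    if abs(n[2]) < 1e-6:
        depth = -np.inf
    else:
        z_cut = P[2] - (n[0] * (K[0] - P[0]) + n[1] * (K[1] - P[1])) / n[2]
        depth = K[2] - z_cut
    report["plane_below_plateau"] = {
        "ok": bool(depth >= rules.plane_below_plateau),
        "value": float(depth),
        "threshold": rules.plane_below_plateau}

    pts = plate.world_points(plan)
    zlo, zhi = verts[:, 2].min() - 5.0, verts[:, 2].max() + 5.0
    on_medial = bool(np.all(m * (pts[:, 0] - K[0]) > 0)
                     and np.all((pts[:, 2] >= zlo) & (pts[:, 2] <= zhi)))
    report["plate_on_medial_cortex"] = {
        "ok": on_medial, "value": float(np.min(m * (pts[:, 0] - K[0]))),
        "threshold": 0.0}
    return FeasibilityReport(report)


# ---------------------------------------------------------------------------
# NSGA-II
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GAConfig:
    population: int = 100
    generations: int = 100
    seed: int = 0
    crossover_eta: float = 15.0
    mutation_eta: float = 20.0
    crossover_prob: float = 0.9
    mutation_prob: float = 1.0 / 12.0
    init_budget_factor: int = 50  # random probes per slot before giving up


class OptimizationError(RuntimeError):
    pass


def plan_bounds(case: PlanningCase) -> tuple:
    """Per-parameter search bounds derived from the case geometry.

    The cortex is probed in the hinge-height band (below the plateau), not
    over the whole mesh — the plateau is much wider than the shaft, so the
    global extremes would place most hinge/plate samples outside the bone.
    """
    K = np.asarray(case.landmarks["KC"], float)
    m = _medial_sign(case.side)
    verts = np.asarray(case.mesh.vertices, float)
    z_lo, z_hi = K[2] - 85.0, K[2] - 20.0
    band = verts[(verts[:, 2] >= z_lo) & (verts[:, 2] <= z_hi)]
    if len(band) == 0:
        band = verts
    x_lat = band[:, 0].min() if m > 0 else band[:, 0].max()
    x_med = band[:, 0].max() if m > 0 else band[:, 0].min()
    width = abs(x_med - x_lat)
    lo = np.empty(12)
    hi = np.empty(12)
    ex = sorted([x_lat + m * 12.0, x_lat + m * (12.0 + 0.6 * width)])
    lo[0], hi[0] = ex
    lo[1], hi[1] = K[2] - 80.0, K[2] - 22.0
    lo[2], hi[2] = -20.0, 20.0      # azimuth
    lo[3], hi[3] = -15.0, 15.0      # elevation
    lo[4], hi[4] = 0.0, 20.0        # opening angle
    lo[5], hi[5] = -20.0, 20.0      # plane inclination
    px = sorted([x_med - m * 2.0, x_med + m * 8.0])
    lo[6], hi[6] = px
    lo[7], hi[7] = K[1] - 25.0, K[1] + 25.0
    lo[8], hi[8] = K[2] - 85.0, K[2] - 25.0
    lo[9:], hi[9:] = -20.0, 20.0    # plate orientation
    return lo, hi


def _dominates(a, b) -> bool:
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def _non_dominated_sort(objs):
    n = len(objs)
    S = [[] for _ in range(n)]
    counts = np.zeros(n, int)
    fronts = [[]]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if _dominates(objs[i], objs[j]):
                S[i].append(j)
            elif _dominates(objs[j], objs[i]):
                counts[i] += 1
        if counts[i] == 0:
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt = []
        for i in fronts[k]:
            for j in S[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        k += 1
        fronts.append(nxt)
    return fronts[:-1]


def _crowding(objs, front):
    dist = np.zeros(len(front))
    arr = np.array([objs[i] for i in front], float)
    arr[~np.isfinite(arr)] = 1e12
    for k in range(arr.shape[1]):
        order = np.argsort(arr[:, k])
        dist[order[0]] = dist[order[-1]] = np.inf
        span = arr[order[-1], k] - arr[order[0], k]
        if span <= 0:
            continue
        for r in range(1, len(front) - 1):
            dist[order[r]] += (arr[order[r + 1], k]
                               - arr[order[r - 1], k]) / span
    return dist


def _sbx(p1, p2, lo, hi, eta, rng):
    c1, c2 = p1.copy(), p2.copy()
    for k in range(len(p1)):
        if rng.random() > 0.5 or abs(p1[k] - p2[k]) < 1e-12:
            continue
        x1, x2 = sorted([p1[k], p2[k]])
        u = rng.random()
        beta = ((2 * u) ** (1 / (eta + 1)) if u <= 0.5
                else (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
        c1[k] = 0.5 * ((x1 + x2) - beta * (x2 - x1))
        c2[k] = 0.5 * ((x1 + x2) + beta * (x2 - x1))
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutation(x, lo, hi, eta, prob, rng):
    y = x.copy()
    for k in range(len(x)):
        if rng.random() >= prob:
            continue
        u = rng.random()
        span = hi[k] - lo[k]
        if span <= 0:
            continue
        if u < 0.5:
            delta = (2 * u) ** (1 / (eta + 1)) - 1
        else:
            delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        y[k] = np.clip(x[k] + delta * span, lo[k], hi[k])
    return y


@dataclass
class OptimizationResult:
    pareto_front: list          # list of (OsteotomyPlan, FitnessVector)
    selected: OsteotomyPlan
    selected_fitness: FitnessVector
    log: dict


def _select_from_front(front_pairs):
    # explicit convention: minimize dMA, break ties by dTS then plate_gap
    return min(front_pairs, key=lambda pf: pf[1].as_tuple())


def optimize(case: PlanningCase, targets: PlanningTargets,
             plate: PlateModel | None = None,
             ga: GAConfig | None = None,
             rules: ConstraintRules | None = None) -> OptimizationResult:
    """NSGA-II search over the 12-parameter plan space.

    Individuals violating the feasibility rules (or with an infeasible wedge
    simulation) receive infinite objectives and are dominated by any feasible
    plan.  Returns the final non-dominated front plus one selected plan
    (lowest dMA, ties broken by dTS then plate gap).  Fully deterministic for
    a fixed seed.
    """
    plate = plate or PlateModel()
    ga = ga or GAConfig()
    rules = rules or ConstraintRules()
    rng = np.random.default_rng(ga.seed)
    lo, hi = plan_bounds(case)

    def evaluate(vec):
        plan = OsteotomyPlan.from_vector(vec, case_id=case.case_id)
        if not check_constraints(plan, case, rules, plate).feasible:
            return FitnessVector(INF_FITNESS, INF_FITNESS, INF_FITNESS)
        return fitness(plan, case, targets, plate)

    # initialization: rejection-sample feasible individuals
    pop = []
    tries = 0
    budget = ga.init_budget_factor * ga.population
    while len(pop) < ga.population and tries < budget:
        vec = rng.uniform(lo, hi)
        plan = OsteotomyPlan.from_vector(vec, case_id=case.case_id)
        if check_constraints(plan, case, rules, plate).feasible:
            pop.append(vec)
        tries += 1
    if not pop:
        raise OptimizationError("no feasible individual found during "
                                f"initialization ({budget} probes)")
    while len(pop) < ga.population:
        pop.append(pop[rng.integers(len(pop))].copy())
    pop = np.array(pop)
    objs = [evaluate(v).as_tuple() for v in pop]

    history = []
    for gen in range(ga.generations):
        fronts = _non_dominated_sort(objs)
        rank = np.empty(len(pop), int)
        crowd = np.empty(len(pop))
        for fi, front in enumerate(fronts):
            cd = _crowding(objs, front)
            for j, idx in enumerate(front):
                rank[idx] = fi
                crowd[idx] = cd[j]

        def tournament():
            i, j = rng.integers(len(pop), size=2)
            if rank[i] < rank[j] or (rank[i] == rank[j]
                                     and crowd[i] > crowd[j]):
                return i
            return j

        children = []
        while len(children) < ga.population:
            p1, p2 = pop[tournament()], pop[tournament()]
            if rng.random() < ga.crossover_prob:
                c1, c2 = _sbx(p1, p2, lo, hi, ga.crossover_eta, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for c in (c1, c2):
                children.append(_poly_mutation(c, lo, hi, ga.mutation_eta,
                                               ga.mutation_prob, rng))
        children = np.array(children[:ga.population])
        child_objs = [evaluate(v).as_tuple() for v in children]

        merged = np.concatenate([pop, children])
        merged_objs = objs + child_objs
        fronts = _non_dominated_sort(merged_objs)
        new_idx = []
        for front in fronts:
            if len(new_idx) + len(front) <= ga.population:
                new_idx.extend(front)
            else:
                cd = _crowding(merged_objs, front)
                order = np.argsort(-cd)
                need = ga.population - len(new_idx)
                new_idx.extend([front[o] for o in order[:need]])
                break
        pop = merged[new_idx]
        objs = [merged_objs[i] for i in new_idx]
        best = min(objs)
        history.append(best[0])

    fronts = _non_dominated_sort(objs)
    pairs = []
    seen = set()
    for i in fronts[0]:
        key = tuple(np.round(pop[i], 9))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((OsteotomyPlan.from_vector(pop[i], case_id=case.case_id),
                      FitnessVector(*objs[i])))
    selected, sel_fit = _select_from_front(pairs)
    log = {"seed": ga.seed, "population": ga.population,
           "generations": ga.generations, "crossover_eta": ga.crossover_eta,
           "mutation_eta": ga.mutation_eta, "best_dMA_history": history,
           "init_tries": tries}
    return OptimizationResult(pairs, selected, sel_fit, log)


# ---------------------------------------------------------------------------
# Plan comparison
# ---------------------------------------------------------------------------


def _angle_2d(a, b) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return float("nan")
    c = np.clip(abs(float(a @ b)) / (na * nb), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(c)))


def compare_plans(plan_a: OsteotomyPlan, plan_b: OsteotomyPlan) -> dict:
    """Geometric differences between two plans of the same case.

    Reports the frontal-plane hinge-axis offset (Euclidean plus
    medial-lateral and superior-inferior components), the cutting-plane
    normal difference projected to the frontal and sagittal planes, the
    correction-angle difference, and the plate translation (3D and per axis)
    and per-axis rotation differences.
    """
    dx = plan_a.entry_x - plan_b.entry_x
    dz = plan_a.entry_z - plan_b.entry_z
    na, nb = plan_a.plane_normal(), plan_b.plane_normal()
    dpos = np.array([plan_a.plate_x - plan_b.plate_x,
                     plan_a.plate_y - plan_b.plate_y,
                     plan_a.plate_z - plan_b.plate_z])
    return {
        "frame_mismatch": (plan_a.case_id is not None
                           and plan_b.case_id is not None
                           and plan_a.case_id != plan_b.case_id),
        "axis_offset_frontal": float(np.hypot(dx, dz)),
        "axis_offset_ml": abs(float(dx)),
        "axis_offset_si": abs(float(dz)),
        "plane_normal_diff_frontal": _angle_2d(na[[0, 2]], nb[[0, 2]]),
        "plane_normal_diff_sagittal": _angle_2d(na[[1, 2]], nb[[1, 2]]),
        "correction_angle_diff": abs(plan_a.opening_angle
                                     - plan_b.opening_angle),
        "plate_translation_3d": float(np.linalg.norm(dpos)),
        "plate_translation_xyz": [abs(float(v)) for v in dpos],
        "plate_rotation_xyz": [abs(plan_a.plate_rx - plan_b.plate_rx),
                               abs(plan_a.plate_ry - plan_b.plate_ry),
                               abs(plan_a.plate_rz - plan_b.plate_rz)],
    }
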