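"""End-to-end orchestration: phantom cohort -> DRRs -> training -> 3D
reconstruction -> deformity measurement -> osteotomy planning -> report.

Two entry levels:

* :func:`run_desk_experiment` — the in-memory study-scale experiment used by
  the test suite and the acceptance script: a synthetic cohort at desk sizes
  (128-pixel detector, 32-cube reconstruction), reduced epochs, fixed seeds.
* :func:`run_pipeline` — the stage-by-stage, resumable on-disk pipeline
  behind the command line, writing a manifest with config snapshot, derived
  per-stage seeds, artifact digests and timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import drr, metrics as mx, nets, phantom as ph, planner as pln

log = logging.getLogger("osteoplan.pipeline")

FRONTAL_LANDMARK_ORDER = [f"{side}/{n}" for side in ("left", "right")
                          for n in drr.LANDMARK_NAMES]
DEFAULT_HEATMAP_SIGMA = 5.0


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; presets: ``desk``, ``tiny``, ``full``."""

    preset: str = "desk"
    seed: int = 0
    out_root: str = "runs/desk"
    n_patients: int = 10
    n_aug: int = 1
    phantom_spacing: float = 4.0
    detector: int = 128
    pixel_spacing: float = 6.0
    crop_px: int = 32
    heatmap_sigma: float = DEFAULT_HEATMAP_SIGMA
    sep_epochs: int = 30
    sep_batch: int = 4          # few desk studies: batch 16 gives too few steps
    lmk_epochs: int = 45        # frontal net: left/right disambiguation is slow
    lmk_epochs_sagittal: int = 10
    recon_epochs: int = 3
    # short desk schedules need larger steps than the long reference ones
    sep_lr: float = 0.001
    lmk_lr: float = 0.002
    recon_lr: float = 0.003
    base_channels: int = 4
    lmk_base_channels: int = 8
    lmk_levels: int = 4
    n_plan_cases: int = 1
    ga_population: int = 40
    ga_generations: int = 30

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))

    @classmethod
    def preset_config(cls, name: str, **overrides) -> "PipelineConfig":
        presets = {
            "desk": {},
            "tiny": dict(preset="tiny", n_patients=4, phantom_spacing=8.0,
                         detector=64, pixel_spacing=12.0, crop_px=16,
                         sep_epochs=2, lmk_epochs=3, recon_epochs=2,
                         ga_population=16, ga_generations=8,
                         out_root="runs/tiny"),
            "full": dict(preset="full", n_patients=175, n_aug=3,
                          phantom_spacing=1.0, detector=512,
                          pixel_spacing=1.0, crop_px=128, sep_epochs=20,
                          lmk_epochs=20, recon_epochs=30, base_channels=32,
                          sep_lr=0.001, lmk_lr=0.0001, recon_lr=0.00005,
                          out_root="runs/full"),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}")
        kw = dict(presets[name])
        kw.update(overrides)
        return cls(**kw)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def recon_spec(self) -> drr.ReconSpec:
        return drr.ReconSpec(crop_px=self.crop_px, upsample=4)


# ---------------------------------------------------------------------------
# Training-sample builders
# ---------------------------------------------------------------------------


def studies_in(studies, split: drr.DatasetSplit, part: str):
    ids = set(getattr(split, part))
    return [s for s in studies if s.patient_id in ids]


def separation_samples(studies):
    """(two-leg sagittal) -> {right, left} contrast-enhanced targets."""
    out = []
    for s in studies:
        x = s.I_sag.pixels[None, None]
        t = {"right": s.I_sag_R.pixels[None, None],
             "left": s.I_sag_L.pixels[None, None]}
        out.append(((x,), t))
    return out


def landmark_samples(studies, view: str, sigma: float = DEFAULT_HEATMAP_SIGMA):
    """Heatmap-regression samples for the frontal (6ch) or sagittal (3ch) net."""
    out = []
    for s in studies:
        shape = s.I_fron.pixels.shape
        if view == "frontal":
            lms = {k: s.landmarks2d["frontal"][k]
                   for k in FRONTAL_LANDMARK_ORDER}
            hm = drr.make_heatmaps(lms, sigma, shape)
            out.append(((s.I_fron.pixels[None, None],), hm.data[None]))
        else:
            for side in ("left", "right"):
                img = s.I_sag_L if side == "left" else s.I_sag_R
                lms = {n: s.landmarks2d[f"sagittal_{side}"][n]
                       for n in drr.LANDMARK_NAMES}
                hm = drr.make_heatmaps(lms, sigma, shape)
                out.append(((img.pixels[None, None],), hm.data[None]))
    return out


def _recon_inputs(study, side, spec, sagittal_source: str):
    rec = study.extras["recon"][side]
    centers = rec["centers"]
    if sagittal_source == "oracle":
        sag_img = study.I_sag_L if side == "left" else study.I_sag_R
    elif sagittal_source == "raw":
        sag_img = study.I_sag
    else:
        raise ValueError(sagittal_source)
    fr, _ = drr.extract_crop(study.I_fron, centers["frontal"], spec)
    sg, _ = drr.extract_crop(sag_img,
                             (centers["sagittal"][0], centers["frontal"][1]),
                             spec)
    fr = drr.upsample_crop(fr, spec.upsample)[None, None]
    sg = drr.upsample_crop(sg, spec.upsample)[None, None]
    return fr, sg


def recon_samples(studies, spec: drr.ReconSpec, sagittal_source: str = "oracle"):
    """Per-leg (frontal crop, sagittal crop) -> one-hot proximal-tibia cube.

    ``sagittal_source='oracle'`` feeds the ground-truth separated sagittal
    (isolating what leg separation contributes); ``'raw'`` feeds the
    superimposed two-leg sagittal (the ablation condition).
    """
    out = []
    for s in studies:
        for side in ("left", "right"):
            if side not in s.extras.get("recon", {}):
                continue
            fr, sg = _recon_inputs(s, side, spec, sagittal_source)
            tgt = s.extras["recon"][side]["target"].astype(np.float32)
            onehot = np.stack([1.0 - tgt, tgt])[None]
            out.append(((fr, sg), onehot))
    return out


# ---------------------------------------------------------------------------
# Desk-scale experiment
# ---------------------------------------------------------------------------


def build_desk_cohort(cfg: PipelineConfig):
    cohort = ph.generate_cohort(cfg.n_patients,
                                ph.PhantomParams(voxel_spacing=cfg.phantom_spacing),
                                seed=cfg.stage_seed("phantom"))
    studies, split = drr.build_dataset(
        cohort, n_aug=cfg.n_aug, seed=cfg.stage_seed("drr"),
        detector_size=(cfg.detector, cfg.detector),
        pixel_spacing=cfg.pixel_spacing, recon_spec=cfg.recon_spec(),
        with_recon_targets=True)
    return cohort, studies, split


def train_separation(studies, split, cfg: PipelineConfig):
    ncfg = nets.separation_config(input_size=cfg.detector,
                                  epochs=cfg.sep_epochs,
                                  batch_size=cfg.sep_batch,
                                  learning_rate=cfg.sep_lr,
                                  base_channels=cfg.base_channels)
    model = nets.build_separation_model(ncfg, seed=cfg.stage_seed("sep_init"))
    data = {"train": separation_samples(studies_in(studies, split, "train")),
            "val": separation_samples(studies_in(studies, split, "val"))}
    return nets.train(model, data, ncfg, seed=cfg.stage_seed("sep_train"))


def train_landmarks(studies, split, view: str, cfg: PipelineConfig):
    nch = 6 if view == "frontal" else 3
    epochs = cfg.lmk_epochs if view == "frontal" else cfg.lmk_epochs_sagittal
    ncfg = nets.landmark_config(nch, input_size=cfg.detector,
                                epochs=epochs,
                                learning_rate=cfg.lmk_lr,
                                n_levels=cfg.lmk_levels,
                                base_channels=cfg.lmk_base_channels)
    model = nets.build_landmark_model(ncfg, nch,
                                      seed=cfg.stage_seed(f"lmk_{view}_init"))
    data = {"train": landmark_samples(studies_in(studies, split, "train"),
                                      view, cfg.heatmap_sigma),
            "val": landmark_samples(studies_in(studies, split, "val"),
                                    view, cfg.heatmap_sigma)}
    return nets.train(model, data, ncfg, seed=cfg.stage_seed(f"lmk_{view}"))


def train_reconstruction(studies, split, cfg: PipelineConfig,
                         sagittal_source: str = "oracle"):
    spec = cfg.recon_spec()
    ncfg = nets.reconstruction_config(input_size=spec.crop_px * spec.upsample,
                                      epochs=cfg.recon_epochs,
                                      learning_rate=cfg.recon_lr,
                                      base_channels=cfg.base_channels)
    model = nets.build_reconstruction_model(
        ncfg, seed=cfg.stage_seed("recon_init"))
    data = {"train": recon_samples(studies_in(studies, split, "train"),
                                   spec, sagittal_source),
            "val": recon_samples(studies_in(studies, split, "val"),
                                 spec, sagittal_source)}
    return nets.train(model, data, ncfg,
                      seed=cfg.stage_seed(f"recon_{sagittal_source}"))


def evaluate_reconstruction(model, studies, spec, sagittal_source="oracle"):
    """Held-out per-leg Dice of the reconstruction net."""
    rows = []
    for s in studies:
        for side in ("left", "right"):
            if side not in s.extras.get("recon", {}):
                continue
            fr, sg = _recon_inputs(s, side, spec, sagittal_source)
            out = model.forward(fr, sg).data[0]
            pred = (out.argmax(axis=0) == 1).astype(np.uint8)
            tgt = s.extras["recon"][side]["target"]
            rows.append({"case": s.case_id, "side": side,
                         "dice": mx.dice_score(pred, tgt)})
    return pd.DataFrame(rows)


def evaluate_landmarks(model_frontal, model_sagittal, studies):
    """Held-out 2D landmark errors (pixels) across all views."""
    rows = []
    for s in studies:
        hm = model_frontal.forward(s.I_fron.pixels[None, None]).data[0]
        for i, name in enumerate(FRONTAL_LANDMARK_ORDER):
            p = nets.extract_landmark(hm[i])
            t = s.landmarks2d["frontal"][name]
            err = (np.nan if p is None
                   else float(np.hypot(p[0] - t[0], p[1] - t[1])))
            rows.append({"case": s.case_id, "view": "frontal",
                         "landmark": name, "error_px": err})
        for side in ("left", "right"):
            img = s.I_sag_L if side == "left" else s.I_sag_R
            hm = model_sagittal.forward(img.pixels[None, None]).data[0]
            for i, name in enumerate(drr.LANDMARK_NAMES):
                p = nets.extract_landmark(hm[i])
                t = s.landmarks2d[f"sagittal_{side}"][name]
                err = (np.nan if p is None
                       else float(np.hypot(p[0] - t[0], p[1] - t[1])))
                rows.append({"case": s.case_id, "view": f"sagittal_{side}",
                             "landmark": name, "error_px": err})
    return pd.DataFrame(rows)


def _target_on_grid(rec: dict, grid_to: dict) -> np.ndarray:
    """Re-express a stored recon target on another grid of the same spacing.

    Prediction crops centred on *predicted* knees sit on a grid that is an
    integer-voxel translation of the training grid (same spacing, same
    axes), so the ground truth transfers by an exact shift.
    """
    tgt = rec["target"]
    ga, s = rec["grid"], rec["grid"]["spacing"]
    # offsets of grid_to relative to the stored grid, in voxels (Y, V, X)
    dy = int(round((grid_to["y0"] - ga["y0"]) / s))
    dv = int(round((ga["z_top"] - grid_to["z_top"]) / s))
    dx = int(round((grid_to["x0"] - ga["x0"]) / s))
    out = np.zeros_like(tgt)
    n = tgt.shape[0]

    def rng(d):
        if abs(d) >= n:
            return slice(0, 0), slice(0, 0)
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    (ady, asy), (adv, asv), (adx, asx) = rng(dy), rng(dv), rng(dx)
    out[ady, adv, adx] = tgt[asy, asv, asx]
    return out


def relative_improvement(full: float, ablation: float) -> float:
    """Relative metric change in percent: ``(full - ablation)/ablation*100``."""
    return (full - ablation) / ablation * 100.0


def run_desk_experiment(cfg: PipelineConfig | None = None, seed: int = 0,
                        n_patients: int = 40,
                        with_separation_net: bool = False) -> dict:
    """The desk-scale learning experiment: train, hold out, score.

    Trains the landmark nets and two reconstruction nets (ground-truth
    separated sagittals vs. the raw superimposed sagittal as the ablation)
    on a synthetic cohort and reports held-out Dice, 2D landmark errors and
    the separation-ablation Dice change.  Optionally also trains the
    separation network and reports its validation loss against the identity
    baseline (prediction = input).
    """
    cfg = cfg or PipelineConfig(seed=seed, n_patients=n_patients)
    t0 = time.time()
    cohort, studies, split = build_desk_cohort(cfg)
    test = studies_in(studies, split, "test")
    spec = cfg.recon_spec()

    lmf, _ = train_landmarks(studies, split, "frontal", cfg)
    lms, _ = train_landmarks(studies, split, "sagittal", cfg)
    lmk_df = evaluate_landmarks(lmf, lms, test)

    recon, hist_full = train_reconstruction(studies, split, cfg, "oracle")
    dice_full = evaluate_reconstruction(recon, test, spec, "oracle")
    recon_abl, hist_abl = train_reconstruction(studies, split, cfg, "raw")
    dice_abl = evaluate_reconstruction(recon_abl, test, spec, "raw")

    results = {
        "config": dataclasses.asdict(cfg),
        "n_studies": len(studies),
        "split": {"train": split.train, "val": split.val, "test": split.test},
        "mean_dice": float(dice_full["dice"].mean()),
        "sd_dice": float(dice_full["dice"].std()),
        "mean_dice_ablation": float(dice_abl["dice"].mean()),
        "dice_change_with_separation": float(dice_full["dice"].mean()
                                             - dice_abl["dice"].mean()),
        "relative_improvement_pct": relative_improvement(
            float(dice_full["dice"].mean()), float(dice_abl["dice"].mean())),
        "mean_landmark_error_px": float(lmk_df["error_px"].mean()),
        "landmark_table": lmk_df,
        "dice_table": dice_full,
        "dice_table_ablation": dice_abl,
        "recon_history": hist_full,
        "recon_history_ablation": hist_abl,
        "models": {"landmarks_frontal": lmf, "landmarks_sagittal": lms,
                   "recon": recon, "recon_ablation": recon_abl},
        "studies": studies,
        "elapsed_s": time.time() - t0,
    }
    if with_separation_net:
        sep, sep_hist = train_separation(studies, split, cfg)
        val = separation_samples(studies_in(studies, split, "val"))
        identity = float(np.mean([
            0.5 * sum(nets.separation_loss(t[s][0, 0], x[0][0, 0])
                      for s in ("right", "left"))
            for x, t in val]))
        results["separation_model"] = sep
        results["separation_val_loss"] = sep_hist.val[sep_hist.best_epoch]
        results["separation_identity_baseline"] = identity
    results["elapsed_s"] = time.time() - t0
    return results


# ---------------------------------------------------------------------------
# On-disk pipeline with manifest + resume
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, name, inputs, outputs, seconds, seed):
        self.stages[name] = {
            "inputs": {str(p): _digest(Path(p)) for p in inputs},
            "outputs": {str(p): _digest(Path(p)) for p in outputs},
            "seconds": round(seconds, 3),
            "seed": seed,
        }

    def save(self, path: Path):
        Path(path).write_text(json.dumps(
            {"config": self.config, "version": self.version,
             "seed": self.seed, "stages": self.stages}, indent=2))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        m = cls(d["config"], d["version"], d["seed"])
        m.stages = d["stages"]
        return m


STAGE_ORDER = ("phantom", "dataset", "train", "evaluate", "plan", "report")


def run_pipeline(cfg: PipelineConfig, resume: bool = True) -> RunManifest:
    """Execute all stages in dependency order under ``cfg.out_root``.

    Every stage writes its outputs plus a ``<stage>.done.json`` marker; with
    ``resume=True`` stages whose marker exists are skipped, so deleting one
    stage's outputs re-runs only that stage and its dependents' missing
    pieces.  All randomness derives from the global seed via per-stage
    hashes, and the manifest records config, seeds, digests and timings.
    """
    from . import __version__

    root = Path(cfg.out_root)
    root.mkdir(parents=True, exist_ok=True)
    manifest_path = root / "manifest.json"
    if resume and manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        manifest.config = dataclasses.asdict(cfg)
    else:
        manifest = RunManifest(dataclasses.asdict(cfg), __version__, cfg.seed)

    state: dict = {}

    def stage_done(name):
        return (root / f"{name}.done.json").exists()

    def finish(name, inputs, outputs, t0):
        manifest.record(name, inputs, outputs, time.time() - t0,
                        cfg.stage_seed(name))
        (root / f"{name}.done.json").write_text(json.dumps(
            {"outputs": [str(p) for p in outputs]}, indent=2))
        manifest.save(manifest_path)

    # ---- phantom + dataset (kept in memory; artifacts = manifests) -------
    t0 = time.time()
    cohort, studies, split = build_desk_cohort(cfg)
    state.update(cohort=cohort, studies=studies, split=split)
    if not stage_done("phantom"):
        out = root / "cohort_manifest.csv"
        cohort.manifest.to_csv(out, index=False)
        finish("phantom", [], [out], t0)
    if not stage_done("dataset"):
        t0 = time.time()
        out = root / "split.json"
        out.write_text(json.dumps({"train": split.train, "val": split.val,
                                   "test": split.test, "seed": split.seed},
                                  indent=2))
        img_dir = root / "studies"
        img_dir.mkdir(exist_ok=True)
        outs = [out]
        for s in studies[: min(4, len(studies))]:  # example images as artifacts
            stem = img_dir / s.case_id.replace("/", "_")
            s.I_fron.save(str(stem) + "_frontal.png")
            outs.append(Path(str(stem) + "_frontal.png"))
        finish("dataset", [root / "cohort_manifest.csv"], outs, t0)

    # ---- training --------------------------------------------------------
    models_dir = root / "models"
    models_dir.mkdir(exist_ok=True)
    if not stage_done("train") or not (models_dir / "recon.npz").exists():
        t0 = time.time()
        sep, sep_hist = train_separation(studies, split, cfg)
        lmf, lmf_hist = train_landmarks(studies, split, "frontal", cfg)
        lmsag, lms_hist = train_landmarks(studies, split, "sagittal", cfg)
        recon, rec_hist = train_reconstruction(studies, split, cfg, "oracle")
        outs = []
        for name, model, hist in (("separation", sep, sep_hist),
                                  ("landmarks_frontal", lmf, lmf_hist),
                                  ("landmarks_sagittal", lmsag, lms_hist),
                                  ("recon", recon, rec_hist)):
            path = models_dir / f"{name}.npz"
            model.save(path)
            hist.to_frame().to_csv(models_dir / f"{name}_history.csv",
                                   index=False)
            outs += [path, models_dir / f"{name}_history.csv"]
        state.update(sep=sep, lmf=lmf, lmsag=lmsag, recon=recon)
        finish("train", [root / "split.json"], outs, t0)
    else:
        sep = nets.build_separation_model(nets.separation_config(
            input_size=cfg.detector, base_channels=cfg.base_channels))
        sep.load(models_dir / "separation.npz")
        lmf = nets.build_landmark_model(nets.landmark_config(
            6, input_size=cfg.detector, n_levels=cfg.lmk_levels,
            base_channels=cfg.lmk_base_channels), 6)
        lmf.load(models_dir / "landmarks_frontal.npz")
        lmsag = nets.build_landmark_model(nets.landmark_config(
            3, input_size=cfg.detector, n_levels=cfg.lmk_levels,
            base_channels=cfg.lmk_base_channels), 3)
        lmsag.load(models_dir / "landmarks_sagittal.npz")
        recon = nets.build_reconstruction_model(nets.reconstruction_config(
            input_size=cfg.crop_px * 4, base_channels=cfg.base_channels))
        recon.load(models_dir / "recon.npz")
        state.update(sep=sep, lmf=lmf, lmsag=lmsag, recon=recon)

    # ---- evaluation ------------------------------------------------------
    test = studies_in(studies, split, "test")
    spec = cfg.recon_spec()
    if not stage_done("evaluate"):
        t0 = time.time()
        dice_df = evaluate_reconstruction(state["recon"], test, spec, "oracle")
        lmk_df = evaluate_landmarks(state["lmf"], state["lmsag"], test)
        dice_df.to_csv(root / "dice.csv", index=False)
        lmk_df.to_csv(root / "landmark_errors.csv", index=False)
        # full inference chain: trained separation net + predicted landmarks
        models = {"separation": state["sep"],
                  "landmarks_frontal": state["lmf"],
                  "landmarks_sagittal": state["lmsag"],
                  "recon_left": state["recon"],
                  "recon_right": state["recon"]}
        rows = []
        for s in test:
            pred = nets.predict_study(models, s, spec,
                                      separation_mode="network",
                                      crop_landmarks="predicted")
            for side in ("left", "right"):
                if side not in pred.probabilities:
                    continue
                out = (pred.probabilities[side].argmax(axis=0) == 1)
                tgt = _target_on_grid(s.extras["recon"][side],
                                      pred.grids[side])
                rows.append({"case": s.case_id, "side": side,
                             "dice": mx.dice_score(out.astype(np.uint8),
                                                   tgt)})
        pd.DataFrame(rows).to_csv(root / "dice_end_to_end.csv", index=False)
        finish("evaluate", [models_dir / "recon.npz"],
               [root / "dice.csv", root / "landmark_errors.csv",
                root / "dice_end_to_end.csv"], t0)

    # ---- planning --------------------------------------------------------
    if not stage_done("plan"):
        t0 = time.time()
        rows = []
        outs = []
        ga = pln.GAConfig(population=cfg.ga_population,
                          generations=cfg.ga_generations,
                          seed=cfg.stage_seed("plan"))
        for s in test[: cfg.n_plan_cases]:
            idx = s.extras["patient_index"]
            vol = cohort.volumes[idx]
            side = "right"
            lv = nets.LabelVolume(
                (vol.labels == ph.PROX_TIBIA_LABELS[side]).astype(np.uint8),
                vol.spacing, vol.origin)
            mesh = mx.marching_cubes(lv)
            lm = {k: v for k, v in vol.landmarks[side].items()}
            case = pln.PlanningCase(mesh, lm, side, case_id=s.case_id)
            pre = case.preop()
            targets = pln.PlanningTargets(MA=0.0, TS=pre.TS)
            result = pln.optimize(case, targets, ga=ga)
            plan_path = root / f"plan_{s.case_id.replace('/', '_')}.json"
            plan_path.write_text(json.dumps(result.selected.to_json_dict(),
                                            indent=2))
            outs.append(plan_path)
            rows.append({"case": s.case_id, "preop_MA": pre.MA,
                         "preop_TS": pre.TS,
                         **dict(zip(("dMA", "dTS", "plate_gap"),
                                    result.selected_fitness.as_tuple()))})
        pd.DataFrame(rows).to_csv(root / "plans.csv", index=False)
        finish("plan", [root / "dice.csv"], outs + [root / "plans.csv"], t0)

    # ---- report ----------------------------------------------------------
    if not stage_done("report"):
        t0 = time.time()
        rep = report(root)
        out = root / "report.json"
        out.write_text(json.dumps(rep, indent=2, default=float))
        finish("report", [root / "dice.csv", root / "plans.csv"], [out], t0)
    manifest.save(manifest_path)
    return manifest


def report(run_root) -> dict:
    """Mean +/- SD summary tables aggregated from a run directory."""
    root = Path(run_root)
    rep: dict = {"missing": []}
    dice_path = root / "dice.csv"
    if dice_path.exists():
        df = pd.read_csv(dice_path)
        rep["dice"] = {"mean": float(df["dice"].mean()),
                       "sd": float(df["dice"].std(ddof=0)),
                       "n": int(len(df))}
    else:
        rep["missing"].append("dice.csv")
    lmk_path = root / "landmark_errors.csv"
    if lmk_path.exists():
        df = pd.read_csv(lmk_path)
        rep["landmark_error_px"] = {"mean": float(df["error_px"].mean()),
                                    "sd": float(df["error_px"].std(ddof=0)),
                                    "n": int(len(df))}
    else:
        rep["missing"].append("landmark_errors.csv")
    e2e_path = root / "dice_end_to_end.csv"
    if e2e_path.exists():  # optional: full inference chain scores
        df = pd.read_csv(e2e_path)
        if len(df):
            rep["dice_end_to_end"] = {"mean": float(df["dice"].mean()),
                                      "sd": float(df["dice"].std(ddof=0)),
                                      "n": int(len(df))}
    plans_path = root / "plans.csv"
    if plans_path.exists():
        df = pd.read_csv(plans_path)
        rep["planning"] = {c: {"mean": float(df[c].mean()),
                               "sd": float(df[c].std(ddof=0))}
                           for c in ("dMA", "dTS", "plate_gap") if c in df}
    else:
        rep["missing"].append("plans.csv")
    return rep
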