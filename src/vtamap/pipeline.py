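"""End-to-end orchestration: simulate -> enhance -> segment -> metrics
-> fit behavioral model -> cohort statistics, with a reproducibility
manifest.

A run is driven by a single JSON config with per-stage sections. Every
random operation receives a seed derived deterministically from the
top-level seed, so the same config yields bit-identical outputs. The
manifest records the config (and its hash), the package version, the
derived seeds, per-stage wall time, and a content hash for every file
written.
"""

from __future__ import annotations

import hashlib
import json
import time
import sys
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .choice import TaskDesign, fit_discounting, zscore_fit_table
from .enhancement import compute_enhancement
from .errors import StageError, ValidationError
from .metrics import compute_roi_metrics, roi_volume
from .segmentation import AnatomicalConstraints, segment_vta_sn
from .stats import run_paper_battery
from .synthetic import CohortSpec, PhantomSpec, SubjectTruth, make_cohort, make_phantom, make_trials

__all__ = ["RunConfig", "run_full_pipeline", "build_subject_phantom_spec"]

_CONFIG_SECTIONS = {"out_dir", "seed", "cohort", "phantom", "task", "segmentation", "stats", "write_nifti", "verbosity"}


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    task: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    write_nifti: bool = False
    verbosity: int = 1

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _CONFIG_SECTIONS
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        if "out_dir" not in data:
            raise ValidationError("config is missing required field: out_dir")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds, each below 2**31."""
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_subject_phantom_spec(
    subject: SubjectTruth, base: PhantomSpec, seed: int
) -> PhantomSpec:
    """Phantom spec for one subject: the VTA/SN tiers carry the
    subject's planted intensities and the VTA semi-axes scale with the
    cube root of the planted volume. Brain geometry is shared across
    subjects, so brain-volume normalization is a no-op by construction
    (planted effects live on the normalized scale)."""
    tiers = dict(base.tier_means)
    tiers["vta"] = subject.true_vta_intensity
    # keep the ordering invariant even in the extreme tails of the draw
    tiers["sn"] = max(subject.true_sn_intensity, subject.true_vta_intensity + 0.005)
    base_vol_mm3 = _nucleus_volume_mm3(base, base.vta_geometry)
    scale = float(np.cbrt(subject.true_vta_volume / base_vol_mm3))
    # keep per-subject nuclei clear of the SN geometry and the midbrain
    scale = float(np.clip(scale, 0.8, 1.15))
    vta_geom = replace(
        base.vta_geometry,
        semi_axes_vox=tuple(max(1.0, a * scale) for a in base.vta_geometry.semi_axes_vox),
    )
    return replace(base, tier_means=tiers, vta_geometry=vta_geom, seed=seed)


def _nucleus_volume_mm3(spec: PhantomSpec, geom) -> float:
    a, b, c = geom.semi_axes_vox
    return 2.0 * (4.0 / 3.0) * np.pi * a * b * c * float(np.prod(spec.voxel_size_mm))


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the simulated end-to-end study and return the manifest.

    Stages: simulate cohort; per subject build a phantom, compute the
    enhancement image, segment VTA/SN, extract ROI metrics, simulate
    and fit the motivation task; join everything into the cohort table
    and run the statistical battery. Any stage failure aborts with the
    stage named; outputs written so far are preserved.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    log = (lambda msg: print(msg, file=sys.stderr)) if config.verbosity else (lambda msg: None)

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log(f"[vtamap] stage {name} ...")
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                manifest["stages"][name] = {"seconds": round(dt, 3), "ok": exc_type is None}
                log(f"[vtamap] stage {name} done in {dt:.1f}s" if exc_type is None else f"[vtamap] stage {name} FAILED")
                if exc_type is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                return False

        return _Timer()

    def register(path: Path):
        manifest["outputs"][str(path.relative_to(out_dir))] = _sha256(path)

    with stage("simulate_cohort"):
        cohort_seed, *subject_seeds_pool = _derive_seeds(config.seed, 1 + 4 * 256)
        cspec = CohortSpec(seed=cohort_seed, **config.cohort)
        subjects = make_cohort(cspec)
        if len(subjects) * 4 > len(subject_seeds_pool):
            raise ValidationError("cohort too large for the derived seed pool")

    base_phantom = PhantomSpec(**config.phantom)
    design = TaskDesign(**config.task)
    seg_kwargs = dict(config.segmentation)
    max_lat = seg_kwargs.pop("max_lateral_distance_mm", 8.0)

    metrics_rows = []
    fit_rows = []
    trials_frames = []
    seg_reports = {}

    with stage("image_and_segment"):
        measured = []
        for i, subj in enumerate(subjects):
            s_phantom, s_seg, s_trials, s_fit = subject_seeds_pool[4 * i : 4 * i + 4]
            pspec = build_subject_phantom_spec(subj, base_phantom, s_phantom)
            mt, non_mt, truth = make_phantom(pspec)
            enh, valid = compute_enhancement(mt, non_mt, truth.masks["brain"])
            constraints = AnatomicalConstraints(
                midbrain=truth.masks["midbrain"],
                midline_x=pspec.midline_x,
                max_lateral_distance_mm=max_lat,
            )
            seg = segment_vta_sn(enh, valid, constraints, seed=s_seg, **seg_kwargs)
            brain_vol = roi_volume(truth.masks["brain"])
            measured.append((subj, enh, seg, brain_vol, truth))
            if config.write_nifti:
                sdir = out_dir / subj.subject_id
                sdir.mkdir(exist_ok=True)
                for name, vol in (("mt", mt), ("non_mt", non_mt), ("enh", enh)):
                    vol.save(sdir / f"{name}.nii.gz")
                    register(sdir / f"{name}.nii.gz")
                for name, m in (("vta", seg.vta), ("sn", seg.sn)):
                    m.save(sdir / f"{name}.nii.gz")
                    register(sdir / f"{name}.nii.gz")
            seg_reports[subj.subject_id] = seg.report

    with stage("roi_metrics"):
        hc_brain = [bv for (s, _, _, bv, _) in measured if s.group == "HC"]
        reference_brain = float(np.mean(hc_brain)) if hc_brain else float(
            np.mean([bv for (_, _, _, bv, _) in measured])
        )
        for subj, enh, seg, brain_vol, truth in measured:
            for roi_name, mask in (("vta", seg.vta), ("sn", seg.sn)):
                m = compute_roi_metrics(
                    subj.subject_id, roi_name, mask, enh, brain_vol, reference_brain
                )
                metrics_rows.append(
                    {
                        "subject_id": m.subject_id,
                        "roi": m.roi,
                        "volume_mm3": m.volume_mm3,
                        "mean_intensity": m.mean_intensity,
                        "volume_norm": m.volume_norm,
                        "intensity_norm": m.intensity_norm,
                        "brain_volume_mm3": m.brain_volume_mm3,
                        "flags": ";".join(m.flags),
                    }
                )
        metrics_df = pd.DataFrame(metrics_rows)
        metrics_df.to_csv(out_dir / "roi_metrics.csv", index=False)
        register(out_dir / "roi_metrics.csv")

    with stage("fit_imt"):
        for i, subj in enumerate(subjects):
            s_trials, s_fit = subject_seeds_pool[4 * i + 2 : 4 * i + 4]
            trials = make_trials(subj, design, seed=s_trials)
            trials_frames.append(trials)
            for cond in design.conditions:
                fit = fit_discounting(trials, cond, seed=s_fit)
                fit_rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "condition": cond,
                        "bias": fit.bias,
                        "sigma": fit.sigma,
                        "loglik": fit.loglik,
                        "log_evidence": fit.log_evidence,
                        "converged": fit.converged,
                        "n_trials": fit.n_trials,
                        "flags": ";".join(fit.flags),
                    }
                )
        trials_df = pd.concat(trials_frames, ignore_index=True)
        trials_df.to_csv(out_dir / "trials.csv", index=False)
        register(out_dir / "trials.csv")
        fits_df = zscore_fit_table(pd.DataFrame(fit_rows))
        fits_df.to_csv(out_dir / "imt_fits.csv", index=False)
        register(out_dir / "imt_fits.csv")

    with stage("cohort_stats"):
        vta = metrics_df[metrics_df["roi"] == "vta"].set_index("subject_id")
        sn = metrics_df[metrics_df["roi"] == "sn"].set_index("subject_id")
        rows = []
        for subj in subjects:
            rec = {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "sex": subj.sex,
                "vta_volume_norm": vta.loc[subj.subject_id, "volume_norm"],
                "vta_intensity_norm": vta.loc[subj.subject_id, "intensity_norm"],
                "sn_intensity": sn.loc[subj.subject_id, "mean_intensity"],
                **subj.symptoms,
            }
            for cond in ("external", "internal"):
                frow = fits_df[
                    (fits_df["subject_id"] == subj.subject_id) & (fits_df["condition"] == cond)
                ]
                rec[f"bias_{cond}_z"] = float(frow["bias_z"].iloc[0]) if len(frow) else np.nan
                rec[f"sigma_{cond}_z"] = float(frow["sigma_z"].iloc[0]) if len(frow) else np.nan
            rows.append(rec)
        cohort_df = pd.DataFrame(rows)
        cohort_df.to_csv(out_dir / "cohort.csv", index=False)
        register(out_dir / "cohort.csv")
        battery = run_paper_battery(cohort_df, **config.stats)
        with open(out_dir / "battery.json", "w") as fh:
            json.dump(battery.to_dict(), fh, indent=2)
        register(out_dir / "battery.json")

    with open(out_dir / "segmentation_reports.json", "w") as fh:
        json.dump(seg_reports, fh, indent=2)
    register(out_dir / "segmentation_reports.json")

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
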