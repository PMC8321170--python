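"""End-to-end orchestration: phantom -> sample -> train -> classify -> preseg -> segment -> evaluate.

A single :class:`RunConfig` (built in code or loaded from YAML) drives the
whole workflow and every intermediate artifact is written to a run
directory, so any stage can be re-loaded and re-run in isolation. The
trained classifier is serialized once and may be reused across
segmentations. Identical config + seed always produces identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import yaml

from petas3d import active_surface, da_classifier, evaluation, phantom, presegmentation
from petas3d import tissue_sampling, volume_io
from petas3d.active_surface import ASParams
from petas3d.phantom import PhantomSpec
from petas3d.volume_io import Grid3D

__all__ = ["RunConfig", "run"]

log = logging.getLogger("petas3d.pipeline")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``phantom_spec`` (self-contained synthetic run) or
    ``volume_path`` (real input volume; ``gold_path`` needed for training
    and evaluation) must be set.
    """

    out_dir: str = "petas3d_run"
    seed: int = 0
    phantom_spec: PhantomSpec | None = None
    volume_path: str | None = None
    gold_path: str | None = None
    roi_path: str | None = None
    roi_margin_voxels: int = 6
    model_path: str | None = None  # reuse a previously trained model
    k_folds: int = 5
    gamma: float | None = None
    run_cv: bool = False
    preseg_frac: float = 0.4
    preseg_scale: float = 2.5
    as_params: ASParams = field(default_factory=ASParams)
    hd_units: str = "voxel"

    def __post_init__(self) -> None:
        if (self.phantom_spec is None) == (self.volume_path is None):
            raise ValueError("exactly one of phantom_spec or volume_path must be given")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "phantom_spec" in raw and raw["phantom_spec"] is not None:
            ps = dict(raw["phantom_spec"])
            if "grid" in ps:
                g = ps["grid"]
                ps["grid"] = Grid3D(tuple(g["shape"]), tuple(g["spacing"]))
            raw["phantom_spec"] = PhantomSpec(**ps)
        if "as_params" in raw and raw["as_params"] is not None:
            raw["as_params"] = ASParams(**raw["as_params"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("out_dir", None)  # path of the record itself; keeps runs comparable
        if self.phantom_spec is not None:
            ps = asdict(self.phantom_spec)
            ps["grid"] = {"shape": list(self.phantom_spec.grid.shape),
                          "spacing": list(self.phantom_spec.grid.spacing)}
            d["phantom_spec"] = ps
        return d


def _stage(name: str):
    log.info("stage: %s", name)
    return time.time()


def run(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as report.json).

    Artifacts written to ``config.out_dir``: the input volume and gold mask,
    sample class counts, the serialized DA model, the three classification
    maps, the converged tumor mask, the per-iteration history CSV, the
    resolved config, and the metrics report.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    summary: dict = {"seed": config.seed}
    stage = "input"
    try:
        _stage(stage)
        if config.phantom_spec is not None:
            spec = config.phantom_spec
            vol, gold = phantom.generate_phantom(spec)
            volume_io.write_volume(vol, os.path.join(out, "volume.nii.gz"))
            volume_io.write_volume(gold, os.path.join(out, "gold.nii.gz"))
        else:
            vol = volume_io.read_volume(config.volume_path)
            gold = volume_io.read_mask(config.gold_path) if config.gold_path else None

        stage = "roi"
        _stage(stage)
        if config.roi_path:
            roi = volume_io.read_mask(config.roi_path)
        elif gold is not None:
            roi = phantom.roi_around(gold, config.roi_margin_voxels)
        else:
            raise ValueError("no ROI: provide roi_path or a gold mask to derive one from")
        volume_io.write_volume(roi, os.path.join(out, "roi.nii.gz"))

        stage = "train"
        _stage(stage)
        if config.model_path:
            model = da_classifier.DAModel.from_json(config.model_path)
        else:
            if gold is None:
                raise ValueError("training requires a gold mask (or pass model_path)")
            samples = tissue_sampling.extract_samples(vol, gold)
            n_les, n_bor, n_bkg = tissue_sampling.class_counts(samples)
            summary["sample_counts"] = {"lesion": n_les, "border_line": n_bor, "background": n_bkg}
            model = da_classifier.train(samples, gamma=config.gamma, seed=config.seed)
            summary["classifier_holdout"] = model.holdout
            if config.run_cv:
                summary["cv"] = da_classifier.kfold_cv(
                    samples, k=config.k_folds, gamma=config.gamma, seed=config.seed
                )
        model.to_json(os.path.join(out, "model.json"))

        stage = "classify"
        _stage(stage)
        maps = da_classifier.classify_volume(model, vol)
        volume_io.write_volume(maps.lesion, os.path.join(out, "chi_lesion.nii.gz"))
        volume_io.write_volume(maps.border, os.path.join(out, "chi_border.nii.gz"))
        volume_io.write_volume(maps.background, os.path.join(out, "chi_background.nii.gz"))

        stage = "presegment"
        _stage(stage)
        peak = presegmentation.find_max_voxel(vol, roi)
        seed_mask = presegmentation.seed_region(vol, roi, frac=config.preseg_frac)
        ell = presegmentation.fit_ellipsoid(seed_mask, scale=config.preseg_scale, max_voxel=peak)
        phi0 = presegmentation.ellipsoid_to_levelset(ell, vol.grid)

        stage = "segment"
        _stage(stage)
        mask, history = active_surface.segment(vol, maps, phi0, config.as_params)
        volume_io.write_volume(mask, os.path.join(out, "btv_mask.nii.gz"))
        with open(os.path.join(out, "history.csv"), "w") as fh:
            fh.write("iteration,energy,flip_fraction\n")
            for i, (e, f) in enumerate(zip(history["energy"], history["flip_fraction"]), 1):
                fh.write(f"{i},{e!r},{f!r}\n")
        summary["segmentation"] = {
            "iterations": history["iterations"],
            "converged": history["converged"],
            "mask_voxels": mask.count(),
            "volume_ml": mask.count() * vol.grid.voxel_volume_mm3 / 1000.0,
        }

        stage = "evaluate"
        _stage(stage)
        if gold is not None:
            report = evaluation.evaluate_masks(mask, gold, units=config.hd_units)
            report_mm = evaluation.hausdorff(mask, gold, units="mm") if mask.count() else None
            summary["metrics"] = report.to_dict()
            summary["metrics"]["hd_mm"] = report_mm
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}; artifacts so far are in {out}"
        ) from exc

    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
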