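"""End-to-end pipeline: window -> vesselness -> seed -> grow -> evaluate.

Each stage writes its intermediate as NIfTI into the output directory, and a
JSON manifest records paths, the effective configuration (hashed), package
version, and per-stage status, so a run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .aorta import AortaSegmenter, fallback_aorta_detect, locate_seed, segment_aorta
from .errors import CorogrowError, InputError
from .growing import GrowthParams, region_grow
from .io import read_volume, write_mask, write_volume
from .metrics import average_voxel_error
from .vesselness import ScaleSpaceParams, VesselnessParams, vesselness_multiscale
from .windowing import WindowParams, apply_window

logger = logging.getLogger("corogrow")


@dataclass
class PipelineConfig:
    window: WindowParams = field(default_factory=WindowParams)
    scales: ScaleSpaceParams = field(default_factory=ScaleSpaceParams)
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    seed_search_radius: float = 5.0
    model_path: str | None = None  # None -> circularity fallback detector
    output_dir: str = "corogrow_out"
    rng_seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "window" in d:
            d["window"] = WindowParams(**d["window"])
        if "scales" in d:
            sp = dict(d["scales"])
            if "scales" in sp:
                sp["scales"] = tuple(sp["scales"])
            d["scales"] = ScaleSpaceParams(**sp)
        if "vesselness" in d:
            d["vesselness"] = VesselnessParams(**d["vesselness"])
        if "growth" in d:
            d["growth"] = GrowthParams(**d["growth"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    volume_path: str,
    config: PipelineConfig,
    reference_mask: np.ndarray | None = None,
) -> dict:
    """Execute the full pipeline on one NIfTI volume; returns the run manifest.

    On stage failure, the manifest carries a structured error naming the stage
    instead of raising, so batch callers can triage runs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {
        "input": volume_path,
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
        "outputs": {},
    }
    config.to_yaml(os.path.join(config.output_dir, "effective_config.yaml"))
    out = lambda name: os.path.join(config.output_dir, name)  # noqa: E731

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except (CorogrowError, OSError) as exc:
            manifest["stages"][name] = {"status": "error", "error": str(exc)}
            manifest["error_stage"] = name
            logger.error("stage %s failed: %s", name, exc)
            return None
        manifest["stages"][name] = {"status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        return result

    loaded = stage("read", lambda: read_volume(volume_path))
    if loaded is None:
        return _finish(manifest, config)
    volume, spacing = loaded

    def _window():
        enh = apply_window(volume, config.window)
        write_volume(enh, out("enhanced.nii.gz"), spacing)
        manifest["outputs"]["enhanced"] = out("enhanced.nii.gz")
        return enh

    enhanced = stage("window", _window)
    if enhanced is None:
        return _finish(manifest, config)

    def _vesselness():
        v = vesselness_multiscale(enhanced, config.scales, config.vesselness)
        write_volume(v.astype(np.float32), out("vesselness.nii.gz"), spacing)
        manifest["outputs"]["vesselness"] = out("vesselness.nii.gz")
        logger.info("vesselness: %d voxels above 0.1", int((v > 0.1).sum()))
        return v

    vmap = stage("vesselness", _vesselness)
    if vmap is None:
        return _finish(manifest, config)

    aorta_stack: dict = {}

    def _seed():
        if config.model_path:
            seg = AortaSegmenter.load(config.model_path)
            masks = segment_aorta(seg, [enhanced[z] for z in range(enhanced.shape[0])])
        else:
            masks = [fallback_aorta_detect(enhanced[z]) for z in range(enhanced.shape[0])]
        aorta_stack["mask"] = np.stack(masks).astype(bool)
        sp = locate_seed(aorta_stack["mask"], vmap, config.seed_search_radius)
        manifest["outputs"]["seed"] = list(sp)
        logger.info("seed located at %s", sp)
        return sp

    seed = stage("seed", _seed)
    if seed is None:
        return _finish(manifest, config)

    def _grow():
        # the aorta is the anchor, not the target: exclude it (dilated by one
        # voxel to cover its surface response) so growth traces the coronaries
        grow_map = vmap
        if aorta_stack.get("mask") is not None:
            from scipy import ndimage as _ndi

            excl = _ndi.binary_dilation(aorta_stack["mask"], iterations=1)
            grow_map = np.where(excl, 0.0, vmap)
        res = region_grow(enhanced, grow_map, seed, config.growth)
        if res.n_accepted <= 1:
            raise InputError("degenerate growth: mask is the seed alone")
        write_mask(res.mask.astype(np.uint8), out("mask.nii.gz"), spacing)
        manifest["outputs"]["mask"] = out("mask.nii.gz")
        manifest["outputs"]["n_accepted"] = res.n_accepted
        manifest["outputs"]["terminated_by"] = res.terminated_by.value
        logger.info("growth accepted %d voxels (%s)", res.n_accepted, res.terminated_by.value)
        return res

    growth = stage("grow", _grow)
    if growth is None:
        return _finish(manifest, config)

    if reference_mask is not None:
        def _evaluate():
            rep = average_voxel_error(volume, growth.mask, reference_mask)
            pred, ref = growth.mask.astype(bool), reference_mask.astype(bool)
            dice = 2 * np.count_nonzero(pred & ref) / max(
                1, np.count_nonzero(pred) + np.count_nonzero(ref)
            )
            metrics = {"voxel_error": rep.error, "dice": float(dice), "n_voxels": rep.n_voxels}
            with open(out("metrics.json"), "w") as fh:
                json.dump(metrics, fh, indent=2)
            manifest["outputs"]["metrics"] = metrics
            return metrics

        stage("evaluate", _evaluate)

    return _finish(manifest, config)


def _finish(manifest: dict, config: PipelineConfig) -> dict:
    path = os.path.join(config.output_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest_path"] = path
    return manifest
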