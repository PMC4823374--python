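"""End-to-end workflow: features -> classify -> regularize -> smooth.

``RunConfig`` gathers every stage parameter with documented defaults and
round-trips through YAML (unknown keys are rejected).  ``run_pipeline``
executes the stages in order, records stage timings and parameter
provenance in a JSON-serializable manifest, and is fully deterministic
under a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import crf
from .classifier import GaussianClassifierModel, argmax_labeling, predict_proba, train
from .features import ScaleSet, extract_features
from .smoothing import smooth_label_surface
from .volumes import ImageStack, LabelVolume

logger = logging.getLogger("vemseg")


@dataclass(frozen=True)
class RunConfig:
    """All tunable stage parameters.

    Units: sigma0 in pixels, margin/tile in voxels, thetas dimensionless
    energy weights.  ``theta_z=None`` means the anisotropy rule
    theta_xy / rho; ``forbidden_pairs`` lists label-id pairs that may not
    touch in the regularized output.
    """

    sigma0: float = 1.0
    n_scales: int = 4
    extractor: str = "auto"  # f2d | f3d | auto
    f3d_rho_threshold: float = 1.5
    variance_to_retain: float = 0.99
    theta_xy: float = 1.0
    theta_z: float | None = None
    forbidden_pairs: tuple[tuple[int, int], ...] = ((2, 3),)
    tile_shape: tuple[int, int, int] = (256, 256, 64)
    margin: int = 10
    smooth_tol: float = 1e-4
    smooth_max_iter: int = 1000
    connectivity: int = 6
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["forbidden_pairs"] = [list(p) for p in self.forbidden_pairs]
        data["tile_shape"] = list(self.tile_shape)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "forbidden_pairs" in raw:
            raw["forbidden_pairs"] = tuple(tuple(int(v) for v in p) for p in raw["forbidden_pairs"])
        if "tile_shape" in raw:
            raw["tile_shape"] = tuple(int(v) for v in raw["tile_shape"])
        return cls(**raw)

    def crf_config(self, label_ids: tuple[int, ...]) -> crf.CRFConfig:
        ids = list(label_ids)
        pairs = [
            (ids.index(a), ids.index(b))
            for a, b in self.forbidden_pairs
            if a in ids and b in ids
        ]
        return crf.CRFConfig(
            theta_xy=self.theta_xy,
            theta_z=self.theta_z,
            distance_matrix=crf.default_distance_matrix(len(ids), pairs),
            tile_shape=self.tile_shape,
            margin=self.margin,
        )


@dataclass
class PipelineResult:
    labels: LabelVolume
    probmap: object
    model: GaussianClassifierModel
    argmax: LabelVolume
    meshes: dict[int, object] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    stack: ImageStack,
    scribbles: LabelVolume,
    config: RunConfig = RunConfig(),
    regularize: bool = True,
    smooth: bool = False,
) -> PipelineResult:
    """Train on scribbles and segment the full stack.

    With ``regularize=False`` the output labeling is the plain per-voxel
    argmax of the posteriors.  With ``smooth=True`` a smoothed surface
    mesh is extracted per non-background label (the label volume itself
    is never altered by smoothing).
    """
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def _stage(name):
        t0 = time.perf_counter()

        def _done():
            dt = time.perf_counter() - t0
            manifest["stages"][name] = round(dt, 4)
            logger.info("stage %s: %.2fs", name, dt)

        return _done

    done = _stage("features")
    scale_set = ScaleSet(sigma0=config.sigma0, n=config.n_scales)
    feats = extract_features(stack, scale_set, config.extractor, config.f3d_rho_threshold)
    manifest["extractor"] = feats.extractor_tag
    done()

    done = _stage("train")
    model = train(
        feats, scribbles,
        variance_to_retain=config.variance_to_retain,
        seed=config.seed,
    )
    done()

    done = _stage("classify")
    probmap = predict_proba(model, feats)
    amax = argmax_labeling(probmap)
    done()

    if regularize:
        done = _stage("regularize")
        labels = crf.regularize_tiled(probmap, config.crf_config(probmap.label_ids), rho=stack.rho)
        done()
    else:
        labels = amax

    meshes: dict[int, object] = {}
    if smooth:
        done = _stage("smooth")
        for lab in labels.ids():
            if labels.label_table.get(lab) == "background":
                continue
            if not (labels.labels == lab).any():
                continue
            mesh, fld = smooth_label_surface(
                labels, lab, voxel_size=stack.voxel_size, rho=stack.rho,
                tol=config.smooth_tol, max_iter=config.smooth_max_iter,
            )
            meshes[lab] = mesh
            manifest.setdefault("smoothing", {})[str(lab)] = {
                "converged": bool(fld.converged),
                "iterations": int(fld.iterations),
            }
        done()

    manifest["rho"] = stack.rho
    manifest["shape"] = list(stack.shape)
    return PipelineResult(
        labels=labels, probmap=probmap, model=model, argmax=amax,
        meshes=meshes, manifest=manifest,
    )
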