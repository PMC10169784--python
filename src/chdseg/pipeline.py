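"""End-to-end pipeline: RoI crop -> 3D chambers net -> 2D blood pool ->
boundary refinement -> candidate skeleton graphs -> EMD template matching
-> label transfer -> region growing.

The pipeline is deterministic for a given configuration; a provenance
record (configuration hash, seeds, stage log) accompanies every run.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import io as cio
from .core import (BLOODPOOL_BOUNDARY, BLOODPOOL_INTERIOR, MYO,
                   IntensityVolume, LabelVolume)
from .matching import (MatchResult, grow_leftovers, match_graphs,
                       transfer_labels)
from .refine import DEFAULT_GROWTH_ITERS, refine_chambers, refine_myocardium
from .skeleton import (DEFAULT_SAMPLE_SPACING, SMOOTH_THRESHOLD,
                       candidate_graphs)
from .unet import (crop_roi, segment_bloodpool_2d, segment_chambers_3d,
                   upsample_labels)

log = logging.getLogger("chdseg")


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage."""

    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Tunables of one pipeline run (see docs/methods.md for defaults)."""
    refinement_iters: int = DEFAULT_GROWTH_ITERS
    smoothing_threshold: int = SMOOTH_THRESHOLD
    sample_spacing_mm: float = DEFAULT_SAMPLE_SPACING
    seed: int = 0

    def to_dict(self) -> dict:
        return {"refinement_iters": self.refinement_iters,
                "smoothing_threshold": self.smoothing_threshold,
                "sample_spacing_mm": self.sample_spacing_mm,
                "seed": self.seed}


@dataclass
class PipelineResult:
    labels: LabelVolume
    match: MatchResult
    unresolved_voxels: int
    vessel_pool: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


def _stage_runner(prov):
    def stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except Exception as exc:               # noqa: BLE001 - annotate stage
            raise StageError(name, exc) from exc
        dt = time.perf_counter() - t0
        prov["stages"][name] = round(dt, 3)
        log.info("stage %-18s %.2fs", name, dt)
        return out
    return stage


def extract_vessel_pool(image: IntensityVolume, chambers_backend,
                        bloodpool_backend,
                        config: PipelineConfig | None = None):
    """First half of the pipeline: learned stages plus refinement.

    Returns ``(refined, myo_mask, provenance)`` where ``refined`` carries
    the refined chamber labels and the vessel-only blood pool.
    """
    config = config or PipelineConfig()
    prov = {"config": config.to_dict(), "stages": {}}
    stage = _stage_runner(prov)

    roi, offset = stage("crop_roi", crop_roi, image, chambers_backend)
    chambers64 = stage("segment_chambers_3d", segment_chambers_3d,
                       roi, chambers_backend)
    bloodpool = stage("segment_bloodpool_2d", segment_bloodpool_2d,
                      image, bloodpool_backend)

    # place the 64^3 chamber labels back onto the full grid
    chambers_roi = upsample_labels(chambers64.data, roi.shape)
    chambers_full = np.zeros(image.shape, np.int16)
    sl = tuple(slice(offset[k], offset[k] + roi.shape[k]) for k in range(3))
    chambers_full[sl] = chambers_roi
    chambers_vol = LabelVolume(chambers_full, image.spacing, image.origin)

    bp_mask = np.isin(bloodpool.data, (BLOODPOOL_INTERIOR, BLOODPOOL_BOUNDARY))
    refined = stage("refine_chambers", refine_chambers, bp_mask, chambers_vol,
                    config.refinement_iters)
    myo_mask = stage("refine_myocardium", refine_myocardium,
                     chambers_full == MYO, refined.refined_labels)
    return refined, myo_mask, prov


def run_pipeline(image: IntensityVolume, library,
                 chambers_backend, bloodpool_backend,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full segmentation pipeline on one volume.

    ``chambers_backend`` / ``bloodpool_backend`` are oracle or trained
    backends for the two learned stages; ``library`` is the graph
    template library.
    """
    config = config or PipelineConfig()
    if not library:
        raise PipelineConfigError("graph template library is empty")
    refined, myo_mask, prov = extract_vessel_pool(
        image, chambers_backend, bloodpool_backend, config)
    stage = _stage_runner(prov)

    cands = stage("candidate_graphs", candidate_graphs, refined.vessel_pool,
                  image.spacing, config.sample_spacing_mm,
                  threshold=config.smoothing_threshold)
    match = stage("match_graphs", match_graphs, cands, library)
    vessels = stage("transfer_labels", transfer_labels, match,
                    refined.vessel_pool, image.spacing)
    vessels, unresolved = stage("grow_leftovers", grow_leftovers,
                                vessels, refined.vessel_pool)

    final = refined.refined_labels.data.copy()
    final[final == MYO] = 0
    final[myo_mask] = MYO
    vmask = vessels.data > 0
    final[vmask] = vessels.data[vmask]
    labels = LabelVolume(final, image.spacing, image.origin)

    prov["chosen_scale_k"] = match.candidate.provenance_k
    prov["chosen_template"] = {"id": match.template.id, "tag": match.template.tag}
    prov["emd"] = match.emd_value
    prov["unresolved_voxels"] = int(unresolved.sum())
    prov["config_hash"] = cio.config_hash(config.to_dict())
    return PipelineResult(labels=labels, match=match,
                          unresolved_voxels=int(unresolved.sum()),
                          vessel_pool=refined.vessel_pool,
                          provenance=prov)
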