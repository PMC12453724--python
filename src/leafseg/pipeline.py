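"""End-to-end leaf analysis pipeline: resize -> enhance -> segment (-> evaluate).

``run_pipeline`` is the library entry point behind the command line: it
reads an image, brings it to the working resolution, applies the
entropy-adaptive contrast enhancement, segments it with the gravity-kernel
clustering, writes the artifacts (enhanced image, label mask, binary lesion
mask, optional metrics JSON against a ground-truth mask), and returns the
in-memory results.  Configuration is a flat set of validated keys loadable
from JSON or YAML; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import ceahe, gwkdc, image_io, metrics

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline parameters (mirrors the component configs)."""

    side: int = 380
    e_max: float = 8.0
    clip_limit: float = 2.0
    min_tile: int = 2
    degree: int = 6
    b1: float | None = None
    b2: float | None = None
    merge_tau_space: float = 0.05
    merge_tau_int: float = 10.0
    max_iter: int = 50
    peak_subset: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        # delegate range validation to the owning component types
        ceahe.CeaheConfig(e_max=self.e_max, clip_limit=self.clip_limit, min_tile=self.min_tile)
        if not 2 <= self.degree <= 12:
            raise ValueError(f"degree must be in [2, 12], got {self.degree}")
        if self.side < 2:
            raise ValueError("side must be at least 2")
        if (self.b1 is not None and self.b1 <= 0) or (self.b2 is not None and self.b2 <= 0):
            raise ValueError("bandwidths must be positive when given")

    @property
    def ceahe_config(self) -> ceahe.CeaheConfig:
        return ceahe.CeaheConfig(
            e_max=self.e_max, clip_limit=self.clip_limit, min_tile=self.min_tile
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a JSON or YAML mapping; unknown keys are an error."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(
    in_path: str | Path,
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
    truth_path: str | Path | None = None,
) -> tuple[gwkdc.SegmentationResult, metrics.SegMetrics | None]:
    """Run resize -> enhance -> segment on one image and write the artifacts.

    Writes ``enhanced.png``, ``mask.png`` and ``lesion.png`` into
    ``out_dir`` and, when a ground-truth lesion mask is supplied,
    ``metrics.json`` with the four overlap metrics as percentages.  On any
    failure the partially written outputs are removed before re-raising.
    """
    cfg = cfg or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        img = image_io.read_image(in_path)
        img = image_io.resize(img, cfg.side)
        enhanced = ceahe.enhance(img, cfg.ceahe_config)
        result = gwkdc.segment(
            enhanced,
            n=cfg.degree,
            b1=cfg.b1,
            b2=cfg.b2,
            merge_tau_space=cfg.merge_tau_space,
            merge_tau_int=cfg.merge_tau_int,
            max_iter=cfg.max_iter,
            peak_subset=cfg.peak_subset,
            seed=cfg.seed,
        )
        for name, payload, writer in (
            ("enhanced.png", enhanced, image_io.write_image),
            ("mask.png", result.mask, image_io.write_mask),
            ("lesion.png", result.lesion_mask * 255, image_io.write_mask),
        ):
            target = out_dir / name
            written.append(target)
            writer(target, payload)

        scores = None
        if truth_path is not None:
            truth = image_io.read_mask(truth_path)
            if truth.shape != result.mask.shape:
                # nearest-neighbour resize keeps labels integral
                from PIL import Image

                truth = np.asarray(
                    Image.fromarray(truth.astype(np.uint8), mode="L").resize(
                        (cfg.side, cfg.side), Image.NEAREST
                    ),
                    dtype=np.int64,
                )
            # the highest label present is taken as the lesion class
            truth_bin = (truth == truth.max()).astype(np.uint8) if truth.max() > 1 else truth
            scores = metrics.mask_metrics(result.lesion_mask, truth_bin)
            target = out_dir / "metrics.json"
            written.append(target)
            target.write_text(json.dumps(scores.as_dict(percent=True), indent=2))
        return result, scores
    except Exception:
        for target in written:
            target.unlink(missing_ok=True)
        raise
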