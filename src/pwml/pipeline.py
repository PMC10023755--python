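"""End-to-end pipeline: phantom -> normalize -> extract -> compose ->
subsample -> augment -> split -> detect -> evaluate.

All randomness flows from one global seed through named substreams, so a
rerun with the same config reproduces every stage bit-for-bit.  The run
manifest records the config hash, per-stage counts and the evaluation
summary; optional image/annotation outputs go under ``out_dir``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import annotations as anno
from .augmentor import AugmentationSpec, augment_set
from .compositor import PasteConstraints, build_composites
from .evaluate import (
    MatchCriterion,
    average_precision,
    classify_fp_locations,
    compare_probabilities,
    fp_detections_at,
    summarize,
    sweep_thresholds,
)
from .lesion_bank import ExtractionParams, extract_lesions
from .phantom import (
    LesionSpec,
    PhantomParams,
    generate_backgrounds,
    generate_source_case,
)
from .preprocess import NormalizeParams, auto_contrast
from .refdetect import DetectorParams, detect
from .rng import substream
from .types import CompositeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """One config block per stage plus the global seed and output root."""

    seed: int = 0
    out_dir: str | None = None
    write_images: bool = False
    n_backgrounds: int = 72
    case_lesion_counts: tuple[int, ...] = (19, 17)
    case_slice_counts: tuple[int, ...] = (7, 6)
    set_sizes: tuple[int, ...] = (100, 200, 400, 600)
    train_frac: float = 0.8
    thresholds: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    lesions: LesionSpec = field(default_factory=LesionSpec)
    normalize: NormalizeParams = field(default_factory=NormalizeParams)
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    constraints: PasteConstraints = field(default_factory=PasteConstraints)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    detector: DetectorParams = field(default_factory=DetectorParams)
    match: MatchCriterion = field(default_factory=MatchCriterion)

    def __post_init__(self) -> None:
        if len(self.case_lesion_counts) != len(self.case_slice_counts):
            raise ValueError("case_lesion_counts and case_slice_counts differ in length")
        if any(s < 1 for s in self.set_sizes):
            raise ValueError("set_sizes must be positive")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj
        d = enc(self)
        d.pop("augmentation", None)  # the op set is fixed; not a config knob
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "phantom": PhantomParams,
            "lesions": LesionSpec,
            "normalize": NormalizeParams,
            "extraction": ExtractionParams,
            "constraints": PasteConstraints,
            "detector": DetectorParams,
            "match": MatchCriterion,
        }
        kwargs: dict[str, Any] = {}
        for key, val in d.items():
            if key in sub and isinstance(val, dict):
                val = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in val.items()}
                kwargs[key] = sub[key](**val)
            elif isinstance(val, list):
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def subsample_sets(
    composites: list[CompositeRecord],
    set_sizes: tuple[int, ...],
    seed: int = 0,
) -> dict[int, list[CompositeRecord]]:
    """Independent without-replacement subsets, one per requested size."""
    out: dict[int, list[CompositeRecord]] = {}
    for i, size in enumerate(set_sizes):
        if size > len(composites):
            raise ValueError(
                f"set size {size} exceeds composite count {len(composites)}"
            )
        rng = substream(seed, "subsample", i)
        idx = rng.choice(len(composites), size=size, replace=False)
        out[size] = [composites[j] for j in sorted(idx)]
    return out


def _strip_tissue(rec: CompositeRecord) -> CompositeRecord:
    return CompositeRecord(
        image=rec.image,
        boxes=rec.boxes,
        background_id=rec.background_id,
        lesion_slice_id=rec.lesion_slice_id,
        transform_tag=rec.transform_tag,
        tissue=None,
    )


def _write_record(rec: CompositeRecord, out: Path) -> None:
    iid = rec.image_id
    Image.fromarray(rec.image.pixels).save(out / f"{iid}.png")
    anno.write_voc(out / f"{iid}.xml", iid,
                   (rec.image.width, rec.image.height), rec.boxes)


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> dict[str, Any]:
    """Execute every stage in order and return the run manifest.

    The manifest is a JSON-serialisable dict; when ``config.out_dir`` is set
    it is also written there as ``manifest.json`` together with the
    evaluation tables (and, when ``write_images`` is on, the composite
    images plus VOC annotations).
    """
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    out = None
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)

    # 1. normal backgrounds ------------------------------------------------
    backgrounds = generate_backgrounds(
        config.n_backgrounds, config.phantom, seed=config.seed
    )
    backgrounds = [(auto_contrast(img, config.normalize), tis)
                   for img, tis in backgrounds]
    manifest["stages"]["backgrounds"] = {"count": len(backgrounds)}

    # 2. source cases and lesion extraction --------------------------------
    lesion_slices = []
    injected = extracted = 0
    for c, (total, n_slices) in enumerate(
        zip(config.case_lesion_counts, config.case_slice_counts)
    ):
        case = generate_source_case(
            f"case{c}", total, n_slices, config.phantom, config.lesions,
            seed=config.seed,
        )
        for sl in case:
            norm = auto_contrast(sl.image, config.normalize)
            norm.image_id = sl.slice_id
            patches = extract_lesions(
                norm, sl.tissue, config.extraction, source_id=sl.slice_id
            )
            injected += len(sl.records)
            extracted += len(patches)
            if len(patches) != len(sl.records):
                logger.warning(
                    "slice %s: extracted %d of %d injected lesions",
                    sl.slice_id, len(patches), len(sl.records),
                )
            lesion_slices.append((sl.slice_id, patches))
    manifest["stages"]["lesion_bank"] = {
        "n_lesion_slices": len(lesion_slices),
        "n_injected": injected,
        "n_extracted": extracted,
    }

    # 3. compositing (full cross-product) ----------------------------------
    composites = build_composites(
        lesion_slices, backgrounds, config.constraints, seed=config.seed
    )
    manifest["stages"]["composites"] = {
        "count": len(composites),
        "expected": len(lesion_slices) * len(backgrounds),
    }

    # 4. subsets -> augmentation -> split ----------------------------------
    subsets = subsample_sets(composites, config.set_sizes, seed=config.seed)
    sets_info: dict[str, Any] = {}
    for size, subset in subsets.items():
        augmented = augment_set(
            [_strip_tissue(r) for r in subset], config.augmentation
        )
        ids = [r.image_id for r in augmented]
        split = anno.split_dataset(ids, config.train_frac, seed=config.seed)
        if out is not None and config.write_images:
            set_dir = out / f"set_{size}"
            set_dir.mkdir(exist_ok=True)
            for rec in augmented:
                _write_record(rec, set_dir)
        sets_info[str(size)] = {
            "subset": len(subset),
            "augmented": len(augmented),
            "n_boxes": sum(len(r.boxes) for r in augmented),
            "train": len(split.train_ids),
            "val": len(split.val_ids),
        }
    manifest["stages"]["sets"] = sets_info

    # 5. detection + evaluation on the composite validation split ----------
    comp_ids = [r.image_id for r in composites]
    comp_split = anno.split_dataset(comp_ids, config.train_frac, seed=config.seed)
    val_ids = set(comp_split.val_ids)
    val_records = [r for r in composites if r.image_id in val_ids]
    dets_by_image = {}
    truths_by_image = {}
    tissue_by_image = {}
    for rec in val_records:
        img = rec.image.copy()
        img.image_id = rec.image_id
        dets_by_image[rec.image_id] = detect(img, config.detector)
        truths_by_image[rec.image_id] = rec.boxes
        tissue_by_image[rec.image_id] = rec.tissue

    table = sweep_thresholds(dets_by_image, truths_by_image,
                             config.match, config.thresholds)
    fp_by_threshold = {}
    for t in config.thresholds:
        _, fps = fp_detections_at(dets_by_image, truths_by_image,
                                  config.match, threshold=t)
        fp_by_threshold[t] = classify_fp_locations(fps, tissue_by_image)
    tps, fps = fp_detections_at(dets_by_image, truths_by_image,
                                config.match, threshold=min(config.thresholds))
    prob_cmp = None
    if tps and fps:
        prob_cmp = compare_probabilities(
            [d.probability_percent for d in tps],
            [d.probability_percent for d in fps],
        )
    ap = average_precision(dets_by_image, truths_by_image, config.match)

    report = summarize(table, fp_by_threshold, prob_cmp)
    manifest["stages"]["evaluation"] = {
        "n_val_images": len(val_records),
        "n_truth": sum(len(v) for v in truths_by_image.values()),
        "average_precision": round(ap, 4),
        "detection_table": table.to_dict(orient="records"),
        "fp_location": report["fp_location"].to_dict(orient="records"),
    }
    if prob_cmp is not None:
        manifest["stages"]["evaluation"]["probability_comparison"] = {
            "tp_median": prob_cmp.tp_median,
            "tp_iqr": list(prob_cmp.tp_iqr),
            "fp_median": prob_cmp.fp_median,
            "fp_iqr": list(prob_cmp.fp_iqr),
            "u_statistic": prob_cmp.u_statistic,
            "p_value": prob_cmp.p_value,
        }

    if out is not None:
        report["detection"].to_csv(out / "table1.csv", index=False)
        report["fp_location"].to_csv(out / "table2.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=_json_default)
        )
    return manifest


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
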