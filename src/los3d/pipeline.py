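"""End-to-end segmentation pipeline and feature export.

Orchestrates binarization → connected components → divisible-part counting →
LoS decomposition of multi-part clumps → reassembly into a global component
matrix → volume filtering → per-nucleus feature extraction.  One fixed
configuration drives every stage; two runs with the same configuration and
seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from skimage.measure import regionprops

from .clumps import (
    Clump,
    ClumpConfig,
    count_divisible_parts,
    distance_transform,
    extract_components,
)
from .errors import ValidationError
from .image import IntensityImage, Spacing, as_voxels
from .los import SamplingPolicy, decompose_clump
from .preprocess import PreprocessConfig, binarize

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    los: SamplingPolicy = field(default_factory=SamplingPolicy)
    seed: int = 0
    min_volume_voxels: int = 50
    spacing: Spacing = (1.0, 1.0, 1.0)

    # flat key-value file representation, e.g. "preprocess.otsu_radius: 18"
    def to_flat(self) -> dict:
        flat = {}
        for section in ("preprocess", "clump", "los"):
            obj = getattr(self, section)
            for f in dataclasses.fields(obj):
                flat[f"{section}.{f.name}"] = getattr(obj, f.name)
        flat["seed"] = self.seed
        flat["min_volume_voxels"] = self.min_volume_voxels
        flat["spacing"] = list(self.spacing)
        return flat

    @classmethod
    def from_flat(cls, flat: dict) -> "PipelineConfig":
        sections = {"preprocess": {}, "clump": {}, "los": {}}
        top = {}
        for key, value in flat.items():
            if "." in key:
                section, name = key.split(".", 1)
                if section not in sections:
                    raise ValidationError(f"unknown config section {section!r}")
                sections[section][name] = value
            else:
                top[key] = value
        spacing = tuple(top.get("spacing", (1.0, 1.0, 1.0)))
        return cls(
            preprocess=PreprocessConfig(**sections["preprocess"]),
            clump=ClumpConfig(**sections["clump"]),
            los=SamplingPolicy(**sections["los"]),
            seed=int(top.get("seed", 0)),
            min_volume_voxels=int(top.get("min_volume_voxels", 50)),
            spacing=spacing,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        return cls.from_flat(flat)


@dataclass
class NucleusRecord:
    """Per-nucleus features: centroid (voxel and μm), volume, mean intensity."""

    id: int
    centroid: tuple[float, float, float]  # (z, y, x) voxels
    centroid_um: tuple[float, float, float]
    volume_voxels: int
    volume_um3: float
    mean_intensity: float


@dataclass
class SegmentationResult:
    components: np.ndarray  # global component matrix, 0 = background
    records: list[NucleusRecord]
    binary: np.ndarray | None = None  # binarization intermediate
    seeds: list[tuple[int, int, int]] | None = None  # EDT maxima, global coords


def _clump_seed(global_seed: int, offset: tuple[int, int, int]) -> int:
    """Stable per-clump seed so results are independent of processing order."""
    ss = np.random.SeedSequence([int(global_seed), *map(int, offset)])
    return int(ss.generate_state(1)[0]) % (2**31)


def compute_features(
    cm: np.ndarray, img: IntensityImage | np.ndarray, spacing: Spacing = (1.0, 1.0, 1.0)
) -> list[NucleusRecord]:
    """Centroid, voxel/μm³ volume and mean intensity for every positive label."""
    vox = as_voxels(img)
    if isinstance(img, IntensityImage):
        spacing = img.spacing
    if cm.shape != vox.shape:
        raise ValidationError(f"label grid {cm.shape} and image {vox.shape} differ in shape")
    dz, dy, dx = spacing
    voxel_um3 = dz * dy * dx
    records = []
    for prop in regionprops(np.asarray(cm), intensity_image=vox):
        cz, cy, cx = prop.centroid
        records.append(
            NucleusRecord(
                id=int(prop.label),
                centroid=(cz, cy, cx),
                centroid_um=(cz * dz, cy * dy, cx * dx),
                volume_voxels=int(prop.area),
                volume_um3=float(prop.area) * voxel_um3,
                mean_intensity=float(prop.intensity_mean),
            )
        )
    records.sort(key=lambda r: r.id)
    return records


def filter_by_volume(
    records: list[NucleusRecord], cm: np.ndarray, min_volume_voxels: int
) -> tuple[list[NucleusRecord], np.ndarray]:
    """Drop objects below the volume threshold; compact the surviving labels."""
    if min_volume_voxels <= 0:
        return records, cm
    survivors = [r for r in records if r.volume_voxels >= min_volume_voxels]
    remap = np.zeros(int(cm.max()) + 1, dtype=cm.dtype if cm.size else int)
    new_records = []
    for new_id, rec in enumerate(survivors, start=1):
        remap[rec.id] = new_id
        new_records.append(dataclasses.replace(rec, id=new_id))
    return new_records, remap[cm]


def _size_gate_ok(cfg: ClumpConfig, voxel_count: int) -> bool:
    if cfg.min_clump_voxels is not None and voxel_count < cfg.min_clump_voxels:
        return False
    if cfg.max_clump_voxels is not None and voxel_count >= cfg.max_clump_voxels:
        return False
    return True


def segment_binary(
    binary: np.ndarray, cfg: PipelineConfig
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Components + part counting + LoS decomposition on a precomputed mask.

    Returns the global component matrix (before volume filtering) and the EDT
    maxima in global coordinates.
    """
    labels = np.zeros(binary.shape, int)
    seeds: list[tuple[int, int, int]] = []
    next_label = 1
    for clump in extract_components(binary, cfg.clump.connectivity):
        dist = distance_transform(clump)
        parts = count_divisible_parts(dist, cfg.clump.min_prominence)
        off = clump.offset
        seeds.extend((off[0] + m[0], off[1] + m[1], off[2] + m[2]) for m in parts.maxima)
        if parts.k >= 2 and _size_gate_ok(cfg.clump, clump.voxel_count):
            local = decompose_clump(
                clump, parts.k, cfg.los, rng_seed=_clump_seed(cfg.seed, off)
            )
        else:
            local = clump.mask.astype(int)
        n_parts = int(local.max())
        logger.info(
            "clump offset=%s voxels=%d k=%d parts=%d", off, clump.voxel_count, parts.k, n_parts
        )
        sl = tuple(slice(o, o + s) for o, s in zip(off, clump.mask.shape))
        region = labels[sl]
        region[local > 0] = local[local > 0] + (next_label - 1)
        next_label += n_parts
    return labels, seeds


def run_pipeline(img: IntensityImage | np.ndarray, cfg: PipelineConfig | None = None) -> SegmentationResult:
    """Full segmentation: binarize, split clumps, filter, measure."""
    cfg = cfg or PipelineConfig()
    if isinstance(img, np.ndarray):
        img = IntensityImage(img, cfg.spacing)
    binary = binarize(img, cfg.preprocess)
    labels, seeds = segment_binary(binary, cfg)
    records = compute_features(labels, img)
    records, labels = filter_by_volume(records, labels, cfg.min_volume_voxels)
    return SegmentationResult(components=labels, records=records, binary=binary, seeds=seeds)
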