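"""End-to-end skeletonization workflow and configuration.

Ties the stages together: load likelihood image -> optional min-max
normalization -> Gaussian smoothing -> persistence-guided Morse graph ->
likelihood mask intersection -> per-component maximal spanning trees ->
haircut pruning -> fragment decomposition -> GeoJSON vectorization.  A run
manifest (config hash, package version, per-stage node/edge/fragment counts)
is written alongside the outputs so regressions are diffable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from . import __version__
from .morse import DensityField, extract_morse_graph, smooth_density
from .postprocess import (
    BinaryMask,
    FragmentSet,
    extract_fragments,
    haircut,
    mask_graph,
    max_spanning_forest,
    otsu_mask,
    skeleton_graph_from_morse,
    to_vector_document,
)

__all__ = ["PipelineConfig", "load_likelihood", "run_pipeline", "skeletonize_field"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the skeletonization workflow.

    ``delta`` is the persistence threshold (run low and rely on masking +
    spanning trees + haircut for cleanup); ``floor`` a minimum saddle value;
    ``mask_mode`` one of "otsu", "none" or a path to a binary mask image.
    """

    pixel_size_um: float = 1.0
    delta: float = 0.02
    floor: float = 0.0
    smooth_sigma_px: float = 1.0
    haircut_len_px: int = 10
    mask_mode: str = "otsu"
    normalize: bool = True
    optical_thickness_um: float = 2.5
    section_spacing_um: float = 40.0
    voxel_um: float = 100.0
    dr_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "optical_thickness_um", "section_spacing_um", "voxel_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.delta < 0 or self.floor < 0 or self.haircut_len_px < 0:
            raise ValueError("delta, floor and haircut_len_px must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def load_likelihood(path: str | Path, config: PipelineConfig) -> DensityField:
    """Read a single-channel 8/16-bit TIFF or PNG as a likelihood field.

    With ``config.normalize`` the values are min-max scaled to [0, 1] (16-bit
    inputs especially; persistence is shift-invariant but delta/floor are
    specified on likelihoods).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[-1] not in (1, 3, 4):
            raise ValueError(f"cannot interpret image of shape {arr.shape} as single-channel")
        arr = arr[..., 0] if arr.shape[-1] != 3 else arr.mean(axis=-1)
    if config.normalize:
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    return DensityField(arr, config.pixel_size_um)


def _resolve_mask(field: DensityField, config: PipelineConfig) -> BinaryMask | None:
    mode = config.mask_mode
    if mode == "none":
        return None
    if mode == "otsu":
        return otsu_mask(field)
    arr = iio.imread(mode) if not str(mode).endswith((".tif", ".tiff")) else tifffile.imread(mode)
    return BinaryMask(np.asarray(arr) > 0)


def skeletonize_field(field: DensityField, config: PipelineConfig):
    """Run smoothing through fragment extraction on an in-memory field.

    Returns (fragments, stage_counts) where stage_counts records per-stage
    node/edge/fragment numbers for the manifest.
    """
    counts: dict[str, dict[str, int]] = {}
    if field.values.max() == field.values.min():
        # flat image (e.g. all zero): nothing to skeletonize
        warnings.warn("input field is constant; producing empty fragment set")
        empty = FragmentSet(fragments=[], pixel_size_um=field.pixel_size_um)
        counts["empty_input"] = {"nodes": 0, "edges": 0}
        return empty, counts

    smoothed = smooth_density(field, config.smooth_sigma_px)
    counts["smooth"] = {"nodes": int(smoothed.values.size), "edges": 0}

    morse = extract_morse_graph(smoothed, delta=config.delta, floor=config.floor)
    counts["morse"] = {"nodes": len(morse.nodes), "edges": len(morse.edges)}

    mask = _resolve_mask(smoothed, config)
    if mask is None:
        graph = skeleton_graph_from_morse(morse)
    else:
        graph = mask_graph(morse, mask)
    counts["mask"] = {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges()}

    forest = max_spanning_forest(graph)
    counts["spanning_forest"] = {
        "nodes": forest.number_of_nodes(),
        "edges": forest.number_of_edges(),
    }

    trimmed = haircut(forest, config.haircut_len_px)
    counts["haircut"] = {"nodes": trimmed.number_of_nodes(), "edges": trimmed.number_of_edges()}

    frags = extract_fragments(trimmed, pixel_size_um=field.pixel_size_um)
    counts["fragments"] = {"fragments": len(frags), "edges": sum(f.n_edges for f in frags)}
    return frags, counts


def run_pipeline(config: PipelineConfig, image_paths, out_dir: str | Path) -> dict:
    """Run the full workflow on image files, writing GeoJSON and a manifest.

    One ``<stem>.geojson`` per input image plus ``manifest.json`` in
    ``out_dir``.  Any stage error aborts with a stage-tagged message and
    removes partial outputs of the failing image.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(image_paths, (str, Path)):
        image_paths = [image_paths]
    manifest = {
        "dmskel_version": __version__,
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "images": {},
    }
    for path in image_paths:
        path = Path(path)
        out_path = out_dir / f"{path.stem}.geojson"
        try:
            field = load_likelihood(path, config)
            frags, counts = skeletonize_field(field, config)
            doc = to_vector_document(frags)
            with open(out_path, "w") as fh:
                json.dump(doc, fh, separators=(",", ":"), sort_keys=True)
        except Exception as exc:
            out_path.unlink(missing_ok=True)
            raise RuntimeError(f"[{path.name}] pipeline failed: {exc}") from exc
        manifest["images"][path.name] = {
            "output": out_path.name,
            "stages": counts,
            "n_fragments": len(frags),
            "total_length_um": frags.total_length_um,
        }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
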