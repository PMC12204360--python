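"""Line-density summarization of skeleton fragments.

Skeleton fragments are 2D polylines of axon centrelines detected in optical
sections.  Biology cares about *length*: this module converts fragments into
an areal line density (length per unit area, um/um^2), divides by the optical
section thickness to obtain a volumetric density (length per unit volume,
um/um^3), interpolates across the unimaged gap between consecutive sections,
and integrates densities over labelled brain compartments to obtain total
cable length per compartment.

The optical thickness is the effective axial slab one 2D image represents:
the point-spread-function FWHM plus an average axonal diameter.  Defaults
follow the two modalities handled here: 2.5 um for whole-slide fluorescent
imaging (1.5 um FWHM + 0.5 um axon diameter geometry, sections every 40 um)
and 3 um for serial two-photon tomography (2 um FWHM + 0.5 um, sections every
50 um).  No stereological angular correction is applied (detected in-plane
lengths are a lower bound on true 3D cable length); a configurable scalar
multiplier is exposed instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .postprocess import Fragment, FragmentSet, polyline_length_um

__all__ = [
    "ArealDensityImage",
    "VolumetricDensityVolume",
    "CoordinateTransform",
    "WSI_OPTICAL_THICKNESS_UM",
    "STP_OPTICAL_THICKNESS_UM",
    "WSI_SECTION_SPACING_UM",
    "STP_SECTION_SPACING_UM",
    "n_intermediate_sections",
    "rasterize_density",
    "to_volumetric",
    "interpolate_sections",
    "map_fragments",
    "integrate_compartments",
    "read_swc",
    "voxelize_swc",
]

# modality constants (micrometres)
WSI_OPTICAL_THICKNESS_UM = 2.5
STP_OPTICAL_THICKNESS_UM = 3.0
WSI_SECTION_SPACING_UM = 40.0
STP_SECTION_SPACING_UM = 50.0


@dataclass(frozen=True)
class ArealDensityImage:
    """2D line-density raster, units um of length per um^2 of area."""

    values: np.ndarray
    pixel_size_um: float

    @property
    def total_length_um(self) -> float:
        return float(self.values.sum() * self.pixel_size_um**2)


@dataclass(frozen=True)
class VolumetricDensityVolume:
    """3D line-density raster (plane, row, col), units um per um^3.

    Each plane represents a slab of ``plane_thickness_um`` along the section
    axis; in-plane pixels are ``pixel_size_um`` squares.
    """

    values: np.ndarray
    pixel_size_um: float
    plane_thickness_um: float

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.pixel_size_um**2 * self.plane_thickness_um)

    @property
    def total_length_um(self) -> float:
        return float(self.values.sum() * self.voxel_volume_um3)


class CoordinateTransform:
    """Dense displacement-field lookup mapping pixel coordinates to atlas
    coordinates.

    The displacement grid gives, at each sample point of a regular grid over
    the source image, the (row, col) offset to add to the coordinate.
    Lookups interpolate the grid (order 0 = nearest, order 1 = linear).
    Transform *estimation* (diffeomorphic registration) is out of scope; this
    class only applies supplied transforms.
    """

    def __init__(
        self,
        displacement: np.ndarray,
        grid_rows: np.ndarray | None = None,
        grid_cols: np.ndarray | None = None,
        order: int = 1,
        target_pixel_size_um: float | None = None,
    ) -> None:
        displacement = np.asarray(displacement, dtype=np.float64)
        if displacement.ndim != 3 or displacement.shape[0] != 2:
            raise ValueError("displacement must have shape (2, n_rows, n_cols)")
        _, nr, nc = displacement.shape
        self.grid_rows = np.arange(nr, dtype=float) if grid_rows is None else np.asarray(grid_rows, float)
        self.grid_cols = np.arange(nc, dtype=float) if grid_cols is None else np.asarray(grid_cols, float)
        method = {0: "nearest", 1: "linear"}.get(order)
        if method is None:
            raise ValueError("interpolation order must be 0 (nearest) or 1 (linear)")
        self.target_pixel_size_um = target_pixel_size_um
        self._interp = [
            RegularGridInterpolator(
                (self.grid_rows, self.grid_cols), displacement[i], method=method, bounds_error=True
            )
            for i in range(2)
        ]

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "CoordinateTransform":
        return cls(np.zeros((2,) + tuple(shape)))

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=np.float64)
        try:
            dr = self._interp[0](coords)
            dc = self._interp[1](coords)
        except ValueError as exc:
            raise ValueError(f"vertex outside the transform domain: {exc}") from exc
        out = coords.copy()
        out[..., 0] += dr
        out[..., 1] += dc
        return out


def rasterize_density(
    frags: FragmentSet, shape: tuple[int, int], pixel_size_um: float | None = None
) -> ArealDensityImage:
    """Centre-pixel rasterization of fragment lengths into an areal density.

    Each unit segment (consecutive vertex pair) contributes its length
    divided by the pixel area to the pixel containing its midpoint.
    Midpoints exactly on a pixel border go to the pixel of lower index.
    Total length is conserved exactly: sum(density * pixel area) equals the
    summed fragment lengths.
    """
    if pixel_size_um is None:
        pixel_size_um = frags.pixel_size_um
    values = np.zeros(shape, dtype=np.float64)
    area = pixel_size_um**2
    bad = []
    for i, frag in enumerate(frags):
        v = np.asarray(frag.vertices, dtype=np.float64)
        if len(v) < 2:
            continue
        steps = np.diff(v, axis=0)
        seg_len = np.hypot(steps[:, 0], steps[:, 1]) * pixel_size_um
        mid = 0.5 * (v[:-1] + v[1:])
        # pixel (r, c) covers [r-0.5, r+0.5); ties at +0.5 go to the lower pixel
        idx = np.ceil(mid - 0.5).astype(np.int64)
        if (
            idx.min() < 0
            or idx[:, 0].max() >= shape[0]
            or idx[:, 1].max() >= shape[1]
        ):
            bad.append(i)
            continue
        np.add.at(values, (idx[:, 0], idx[:, 1]), seg_len / area)
    if bad:
        raise ValueError(f"fragments with vertices outside the image bounds: {bad}")
    return ArealDensityImage(values, pixel_size_um)


def to_volumetric(areal: ArealDensityImage, optical_thickness_um: float) -> np.ndarray:
    """Divide an areal density (um/um^2) by the optical slab thickness,
    yielding an in-plane volumetric density slab (um/um^3)."""
    if not optical_thickness_um > 0:
        raise ValueError(f"optical thickness must be > 0, got {optical_thickness_um}")
    return areal.values / optical_thickness_um


def n_intermediate_sections(spacing_um: float, thickness_um: float) -> int:
    """Number of unimaged optical planes between consecutive imaged sections:
    round(spacing / thickness) - 1 (e.g. spacing 40, thickness 2.5 -> 15)."""
    if spacing_um < thickness_um:
        raise ValueError("section spacing must be >= optical thickness")
    return int(round(spacing_um / thickness_um)) - 1


def interpolate_sections(
    slabs,
    spacing_um: float,
    thickness_um: float,
    pixel_size_um: float = 1.0,
) -> VolumetricDensityVolume:
    """Linearly interpolate volumetric-density slabs across unimaged planes.

    Inserts ``round(spacing/thickness) - 1`` intermediate planes between each
    pair of consecutive imaged slabs by linear interpolation along the
    section axis.  For identical slabs this amounts to multiplying the total
    integrated length by the ratio spacing/thickness (per imaged gap).
    """
    slabs = [np.asarray(s, dtype=np.float64) for s in slabs]
    if len(slabs) < 2:
        raise ValueError("need at least 2 slabs to interpolate between")
    if any(s.shape != slabs[0].shape for s in slabs):
        raise ValueError("all slabs must share one shape")
    n_insert = n_intermediate_sections(spacing_um, thickness_um)
    planes = [slabs[0]]
    for a, b in zip(slabs, slabs[1:]):
        for k in range(1, n_insert + 1):
            t = k / (n_insert + 1)
            planes.append((1.0 - t) * a + t * b)
        planes.append(b)
    return VolumetricDensityVolume(
        values=np.stack(planes), pixel_size_um=pixel_size_um, plane_thickness_um=thickness_um
    )


def map_fragments(frags: FragmentSet, transform: CoordinateTransform) -> FragmentSet:
    """Apply a coordinate transform to every fragment vertex, leaving the
    connectivity unchanged and recomputing lengths in the target space."""
    pixel_size = (
        transform.target_pixel_size_um
        if transform.target_pixel_size_um is not None
        else frags.pixel_size_um
    )
    out = []
    for frag in frags:
        coords = transform(np.asarray(frag.vertices, dtype=np.float64))
        vertices = tuple(map(tuple, coords))
        out.append(
            Fragment(
                vertices=vertices,
                length_um=polyline_length_um(vertices, pixel_size),
                kind=frag.kind,
            )
        )
    return FragmentSet(fragments=out, pixel_size_um=pixel_size)


def integrate_compartments(
    vol: VolumetricDensityVolume,
    labels: np.ndarray,
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Total cable length per labelled compartment.

    For each integer label, length = sum(density * voxel volume) over voxels
    carrying that label, reported in metres together with log10(metres).
    Label 0 is treated as background and skipped.
    """
    labels = np.asarray(labels)
    if labels.shape != vol.values.shape:
        raise ValueError(f"label volume shape {labels.shape} != density shape {vol.values.shape}")
    flat_labels = labels.ravel()
    sums = np.bincount(flat_labels, weights=vol.values.ravel())
    rows = []
    for label in np.unique(flat_labels):
        if label == 0:
            continue
        length_um = sums[label] * vol.voxel_volume_um3
        length_m = length_um * 1e-6
        rows.append(
            {
                "label": int(label),
                "name": (names or {}).get(int(label), str(int(label))),
                "length_m": length_m,
                "log10_length_m": np.log10(length_m) if length_m > 0 else -np.inf,
            }
        )
    return pd.DataFrame(rows, columns=["label", "name", "length_m", "log10_length_m"])


# --------------------------------------------------------------------------
# single-neuron morphologies (SWC)

def read_swc(path_or_lines) -> pd.DataFrame:
    """Read a standard 7-column SWC morphology (id type x y z radius parent).

    Coordinates are in micrometres.  Raises on orphaned parents or cycles.
    """
    if isinstance(path_or_lines, (list, tuple)):
        import io

        source = io.StringIO("\n".join(path_or_lines))
    else:
        source = path_or_lines
    df = pd.read_csv(
        source,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["id", "type", "x", "y", "z", "radius", "parent"],
    )
    df = df.astype({"id": int, "type": int, "parent": int})
    ids = set(df["id"])
    if len(ids) != len(df):
        raise ValueError("duplicate SWC node ids")
    for pid in df["parent"]:
        if pid != -1 and pid not in ids:
            raise ValueError(f"SWC parent {pid} does not exist (orphaned record)")
    # cycle check: walking parents from every node must reach a root
    parent = dict(zip(df["id"], df["parent"]))
    state: dict[int, int] = {}
    for start in parent:
        chain = []
        node = start
        while node != -1 and state.get(node) is None:
            state[node] = 1
            chain.append(node)
            node = parent[node]
        if node != -1 and state.get(node) == 1 and node in chain:
            raise ValueError("SWC parent pointers contain a cycle")
        for n in chain:
            state[n] = 2
    return df


def voxelize_swc(
    neuron: pd.DataFrame,
    voxel_size_um: float,
    origin=(0.0, 0.0, 0.0),
    shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Voxelized per-voxel cable length of a single neuron (um per voxel).

    Each child-parent segment is subdivided into sub-segments no longer than
    voxel_size/4; each sub-segment's full length accrues to the voxel
    containing its midpoint, so total cable length is conserved exactly.
    Voxel index along each axis is floor((coord - origin)/voxel_size) in
    (x, y, z) order.
    """
    if not voxel_size_um > 0:
        raise ValueError("voxel_size_um must be > 0")
    coords = {row.id: np.array([row.x, row.y, row.z]) for row in neuron.itertuples()}
    origin = np.asarray(origin, dtype=np.float64)
    entries: list[tuple[np.ndarray, float]] = []
    max_idx = np.zeros(3, dtype=np.int64)
    for row in neuron.itertuples():
        if row.parent == -1:
            continue
        a = coords[row.parent]
        b = coords[row.id]
        seg = b - a
        length = float(np.linalg.norm(seg))
        if length == 0:
            continue
        n_sub = max(1, int(np.ceil(length / (voxel_size_um / 4.0))))
        ts = (np.arange(n_sub) + 0.5) / n_sub
        mids = a[None, :] + ts[:, None] * seg[None, :]
        idx = np.floor((mids - origin) / voxel_size_um).astype(np.int64)
        if idx.min() < 0:
            raise ValueError("neuron extends below the raster origin")
        entries.append((idx, length / n_sub))
        max_idx = np.maximum(max_idx, idx.max(axis=0))
    if shape is None:
        shape = tuple(int(m) + 1 for m in max_idx)
    raster = np.zeros(shape, dtype=np.float64)
    for idx, sub_len in entries:
        if np.any(idx.max(axis=0) >= np.asarray(shape)):
            raise ValueError("neuron extends beyond the requested raster shape")
        np.add.at(raster, (idx[:, 0], idx[:, 1], idx[:, 2]), sub_len)
    return raster
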