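"""Single-cell morphometry and cell-cell contacts from 3D labeled volumes.

A labeled volume assigns every voxel inside the embryonic region the integer
label of exactly one cell (0 = exterior). Volumes are voxel counts times the
physical voxel volume; surface areas come from a marching-cubes isosurface on
the anisotropic grid; contacts are face-adjacent (6-connectivity) label pairs
with the contact area summed over shared voxel faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure


class AbsentCellError(KeyError):
    """Raised when a requested label is not present in a labeled volume."""


class UnannotatedCellError(ValueError):
    """Raised when labels in a volume have no lineage name."""


@dataclass
class LabeledVolume:
    """3D integer label grid with physical voxel spacing.

    ``grid`` has shape (nx, ny, nz); ``spacing`` is (dx, dy, dz) in microns.
    ``names`` optionally maps labels to cell names.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    frame: int = 0
    time_min: float = 0.0
    names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if np.issubdtype(self.grid.dtype, np.floating):
            raise ValueError("label grid must be integer-typed")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the grid."""
        lab = np.unique(self.grid)
        return lab[lab > 0]


@dataclass
class FeatureTrack:
    """Per-cell time series of morphological features.

    ``features`` maps a feature name to a 1D array over ``frames``
    (``centroid`` is (n, 3), microns). Units: volume in µm³, surface area in
    µm², sphericity dimensionless in (0, 1].
    """

    cell: str
    frames: np.ndarray
    times_min: np.ndarray
    features: dict[str, np.ndarray] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times_min = np.asarray(self.times_min, dtype=float)
        n = len(self.frames)
        for k, v in self.features.items():
            v = np.asarray(v, dtype=float)
            if v.shape[0] != n:
                raise ValueError(f"feature {k!r} length {v.shape[0]} != {n} frames")
            self.features[k] = v

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def volume(self) -> np.ndarray:
        return self.features["volume"]

    @property
    def sphericity(self) -> np.ndarray:
        return self.features["sphericity"]


@dataclass
class ContactTrack:
    """Per cell-pair time series of contact area (µm²); pair is unordered."""

    pair: tuple[str, str]
    frames: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("contact pair members must be distinct")
        self.pair = (min(a, b), max(a, b))
        self.frames = np.asarray(self.frames)
        self.areas = np.asarray(self.areas, dtype=float)
        if np.any(self.areas < 0):
            raise ValueError("contact areas must be non-negative")

    @property
    def integral_area(self) -> float:
        """Sum of the per-frame contact areas across the contact's lifetime."""
        return float(self.areas.sum())

    @property
    def contact_frames(self) -> int:
        return int(np.count_nonzero(self.areas > 0))

    @property
    def first_frame(self) -> int | None:
        idx = np.nonzero(self.areas > 0)[0]
        return int(self.frames[idx[0]]) if idx.size else None

    @property
    def last_frame(self) -> int | None:
        idx = np.nonzero(self.areas > 0)[0]
        return int(self.frames[idx[-1]]) if idx.size else None


def cell_volume(vol: LabeledVolume, label: int) -> float:
    """Cell volume in µm³: voxel count times the physical voxel volume."""
    n = int(np.count_nonzero(vol.grid == label))
    if n == 0:
        raise AbsentCellError(f"label {label} absent from volume at frame {vol.frame}")
    return n * vol.voxel_volume


def cell_surface_area(vol: LabeledVolume, label: int, smooth_sigma: float = 0.7) -> float:
    """Cell surface area in µm² from a marching-cubes isosurface.

    The binary mask is lightly Gaussian-smoothed before meshing, which
    removes the voxelization staircase and brings the estimate within ~1% of
    the true surface for compact cells down to ~10 voxel radii. The
    smoothing scale is ``smooth_sigma`` times the smallest voxel edge,
    applied isotropically in physical space (so the estimate is exactly
    covariant under uniform rescaling of the spacing). Cells thinner than
    ~4 voxels in any direction are meshed from the raw mask. Faces exposed
    at the exterior count toward the area.
    """
    mask = vol.grid == label
    if not mask.any():
        raise AbsentCellError(f"label {label} absent from volume at frame {vol.frame}")
    # crop to the cell's bounding box (plus a closing pad) for speed
    sl = ndimage.find_objects(mask.astype(np.uint8))[0]
    mask = np.pad(mask[sl], 2)
    extent = min(s - 4 for s in mask.shape)
    f = mask.astype(float)
    if smooth_sigma > 0 and extent >= 4:
        sig_um = smooth_sigma * min(vol.spacing)
        f = ndimage.gaussian_filter(f, [sig_um / s for s in vol.spacing])
        if f.max() <= 0.5:  # smoothing flattened the cell; fall back
            f = mask.astype(float)
    verts, faces, _, _ = measure.marching_cubes(f, level=0.5, spacing=vol.spacing)
    return float(measure.mesh_surface_area(verts, faces))


def voxel_face_area(vol: LabeledVolume, label: int) -> float:
    """Exposed-voxel-face surface area (µm²); cross-check for the mesh estimator.

    Counts faces between the cell and anything else (other cells or exterior),
    weighting each by its physical face area. Overestimates smooth surfaces
    (staircase effect) by up to a factor 1.5 on spheres.
    """
    mask = np.pad(vol.grid == label, 1)
    dx, dy, dz = vol.spacing
    area = 0.0
    for axis, fa in ((0, dy * dz), (1, dx * dz), (2, dx * dy)):
        d = np.diff(mask.astype(np.int8), axis=axis)
        area += np.count_nonzero(d) * fa
    return float(area)


def sphericity(volume: float, area: float) -> float:
    """Wadell sphericity π^(1/3) (6V)^(2/3) / A; equals 1 for a perfect sphere."""
    if volume <= 0 or area <= 0:
        raise ValueError("sphericity requires positive volume and area")
    return float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)


def _centroids(grid: np.ndarray, spacing: tuple[float, float, float]) -> dict[int, np.ndarray]:
    labels = np.unique(grid)
    labels = labels[labels > 0]
    coms = ndimage.center_of_mass(grid > 0, grid, labels)
    sp = np.asarray(spacing)
    return {int(l): (np.asarray(c) + 0.5) * sp for l, c in zip(labels, coms)}


def extract_features(
    frames: list[LabeledVolume],
    tree=None,
    feature_list: tuple[str, ...] = ("volume", "surface_area", "sphericity", "centroid"),
) -> dict[str, FeatureTrack]:
    """Extract per-cell feature tracks from a sequence of labeled volumes.

    Every nonzero label must map to a cell name via each volume's ``names``
    (or be consistent with ``tree`` if given). Returns one track per cell
    spanning exactly the frames where it exists.

    Optional extras beyond the default set: ``axis_lengths`` (principal axis
    lengths from the inertia tensor, µm), ``elongation`` and ``flatness``
    (axis-length ratios).
    """
    per_cell: dict[str, list] = {}
    for vol in frames:
        if vol.names is None:
            raise UnannotatedCellError("labeled volume has no label-to-name mapping")
        labels = vol.labels()
        unnamed = [int(l) for l in labels if int(l) not in vol.names]
        if unnamed:
            raise UnannotatedCellError(f"labels without names at frame {vol.frame}: {unnamed}")
        cents = _centroids(vol.grid, vol.spacing) if "centroid" in feature_list else {}
        for lab in labels:
            lab = int(lab)
            name = vol.names[lab]
            row: dict[str, object] = {"frame": vol.frame, "time_min": vol.time_min}
            if {"volume", "sphericity"} & set(feature_list):
                row["volume"] = cell_volume(vol, lab)
            if {"surface_area", "sphericity"} & set(feature_list):
                row["surface_area"] = cell_surface_area(vol, lab)
            if "sphericity" in feature_list:
                row["sphericity"] = sphericity(row["volume"], row["surface_area"])
            if "centroid" in feature_list:
                row["centroid"] = cents[lab]
            if {"axis_lengths", "elongation", "flatness"} & set(feature_list):
                row.update(_inertia_features(vol, lab))
            if "boundary_layer" in feature_list:
                row["boundary_layer"] = boundary_layer_count(vol, lab) * vol.voxel_volume
            per_cell.setdefault(name, []).append(row)

    tracks: dict[str, FeatureTrack] = {}
    for name, rows in per_cell.items():
        rows.sort(key=lambda r: r["frame"])
        fr = np.array([r["frame"] for r in rows])
        if np.any(np.diff(fr) != 1):
            raise ValueError(f"cell {name} has non-contiguous frames")
        feats = {
            k: np.stack([r[k] for r in rows]) if k == "centroid" else np.array([r[k] for r in rows])
            for k in rows[0]
            if k not in ("frame", "time_min")
        }
        tracks[name] = FeatureTrack(
            cell=name,
            frames=fr,
            times_min=np.array([r["time_min"] for r in rows]),
            features=feats,
        )
    return tracks


def _inertia_features(vol: LabeledVolume, label: int) -> dict[str, float | np.ndarray]:
    mask = vol.grid == label
    coords = np.argwhere(mask) * np.asarray(vol.spacing)
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / len(c)
    ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
    ev = np.maximum(ev, 1e-12)
    lengths = 4.0 * np.sqrt(ev)  # full axis lengths of the equivalent ellipsoid
    return {
        "axis_lengths": lengths,
        "elongation": float(np.sqrt(ev[1] / ev[0])),
        "flatness": float(np.sqrt(ev[2] / ev[1])),
    }


def boundary_layer_count(vol: LabeledVolume, label: int) -> int:
    """Voxels of the cell with at least one 6-neighbor outside the cell.

    This one-voxel surface layer is the segmentation-uncertainty volume used
    in the division-asymmetry analysis.
    """
    mask = vol.grid == label
    if not mask.any():
        raise AbsentCellError(f"label {label} absent from volume at frame {vol.frame}")
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return int(mask.sum() - eroded.sum())


def contact_areas(vol: LabeledVolume) -> dict[tuple[int, int], float]:
    """Contact areas (µm²) between all face-adjacent label pairs in one frame.

    Two cells are in contact iff at least one 6-connected voxel-face pair
    carries the two labels; the area is the number of shared faces times the
    physical face area (faces normal to x count dy·dz, etc.).
    """
    g = vol.grid
    dx, dy, dz = vol.spacing
    out: dict[tuple[int, int], float] = {}
    for axis, fa in ((0, dy * dz), (1, dx * dz), (2, dx * dy)):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        a = g[tuple(lo)].ravel()
        b = g[tuple(hi)].ravel()
        sel = (a > 0) & (b > 0) & (a != b)
        if not sel.any():
            continue
        pa, pb = a[sel], b[sel]
        lo_l = np.minimum(pa, pb).astype(np.int64)
        hi_l = np.maximum(pa, pb).astype(np.int64)
        codes, counts = np.unique(lo_l * (g.max() + 1) + hi_l, return_counts=True)
        for code, cnt in zip(codes, counts):
            key = (int(code // (g.max() + 1)), int(code % (g.max() + 1)))
            out[key] = out.get(key, 0.0) + float(cnt) * fa
    return out


def extract_contacts(frames: list[LabeledVolume], tree=None) -> dict[tuple[str, str], ContactTrack]:
    """Extract per-pair contact-area tracks from a sequence of labeled volumes."""
    per_pair: dict[tuple[str, str], dict[int, float]] = {}
    all_frames: list[int] = []
    for vol in frames:
        if vol.names is None:
            raise UnannotatedCellError("labeled volume has no label-to-name mapping")
        all_frames.append(vol.frame)
        for (la, lb), area in contact_areas(vol).items():
            na, nb = vol.names[la], vol.names[lb]
            key = (min(na, nb), max(na, nb))
            per_pair.setdefault(key, {})[vol.frame] = area
    tracks = {}
    for pair, areas in per_pair.items():
        frs = np.array(sorted(areas))
        tracks[pair] = ContactTrack(pair=pair, frames=frs, areas=np.array([areas[f] for f in frs]))
    return tracks


def adjacent_frame_volume_deviation(track: FeatureTrack) -> float:
    """Mean relative volume change between consecutive frames.

    mean over t of |V(t+1) − V(t)| / mean(V(t), V(t+1)); a segmentation
    quality indicator when the frame interval is short enough that the true
    volume is nearly constant between adjacent frames.
    """
    v = track.volume
    if len(v) < 2:
        raise ValueError("volume deviation needs a track of length >= 2")
    num = np.abs(np.diff(v))
    den = (v[:-1] + v[1:]) / 2.0
    return float(np.mean(num / den))
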