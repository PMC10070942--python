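"""Inter-embryo size and cell-cycle-length normalization.

Embryo sizes vary between individuals (up to ~1.4x in volume under identical
conditions), as do developmental rates. Before cross-embryo comparisons, each
embryo is linearly rescaled so its volume matches the cohort mean (features
are scaled by dimensional analysis: lengths by f, areas by f², volumes by f³,
sphericity untouched), and each cell's feature dynamics are resampled by
cubic spline to a common cycle of 25 minutes / 50 time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from morphodyn.morphometry import FeatureTrack, LabeledVolume


class TrackTooShortError(ValueError):
    """Track too short for cubic-spline resampling (needs >= 4 samples)."""


@dataclass
class EmbryoScale:
    """Linear scale factor bringing one embryo to the cohort mean volume."""

    embryo_id: str
    median_volume: float
    cohort_mean_volume: float

    def __post_init__(self) -> None:
        if self.median_volume <= 0 or self.cohort_mean_volume <= 0:
            raise ValueError("volumes must be positive")

    @property
    def factor(self) -> float:
        return (self.cohort_mean_volume / self.median_volume) ** (1.0 / 3.0)


def embryo_volume(frames: list[LabeledVolume]) -> float:
    """Embryo volume in µm³: median over frames of the labeled-region volume."""
    if not frames:
        raise ValueError("need at least one frame")
    vols = []
    for vol in frames:
        n = int(np.count_nonzero(vol.grid))
        if n == 0:
            raise ValueError(f"frame {vol.frame} has an empty labeling")
        vols.append(n * vol.voxel_volume)
    return float(np.median(vols))


#: Physical dimension (length exponent) of each feature; sphericity and the
#: shape ratios are dimensionless.
FEATURE_DIMENSION = {
    "volume": 3,
    "surface_area": 2,
    "centroid": 1,
    "axis_lengths": 1,
    "boundary_layer": 3,
    "sphericity": 0,
    "elongation": 0,
    "flatness": 0,
}


def scale_features(
    tracks: dict[str, FeatureTrack], scale: EmbryoScale
) -> dict[str, FeatureTrack]:
    """Rescale all tracks of one embryo by its linear factor (exactly invertible)."""
    f = scale.factor
    out = {}
    for name, tr in tracks.items():
        feats = {}
        for k, v in tr.features.items():
            dim = FEATURE_DIMENSION.get(k, 0)
            feats[k] = v * f**dim
        out[name] = FeatureTrack(
            cell=tr.cell,
            frames=tr.frames.copy(),
            times_min=tr.times_min.copy(),
            features=feats,
            normalized=tr.normalized,
        )
    return out


def normalize_time(
    track: FeatureTrack, n_out: int = 50, duration_min: float = 25.0
) -> FeatureTrack:
    """Resample a track's cell cycle to ``n_out`` points spanning ``duration_min``.

    Natural cubic splines through the original samples, evaluated on a
    uniform grid over the cycle. Exact for constant and linear dynamics.
    """
    n = len(track)
    if n < 4:
        raise TrackTooShortError(f"cell {track.cell}: {n} frames < 4 needed for a cubic spline")
    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, n_out)
    feats = {}
    for k, v in track.features.items():
        cs = CubicSpline(x_old, v, axis=0, bc_type="natural")
        feats[k] = cs(x_new)
    return FeatureTrack(
        cell=track.cell,
        frames=np.arange(n_out),
        times_min=np.linspace(0.0, duration_min, n_out),
        features=feats,
        normalized=True,
    )


def normalize_cohort_tracks(
    per_embryo_tracks: dict[str, dict[str, FeatureTrack]],
    per_embryo_volume: dict[str, float],
    n_out: int = 50,
) -> tuple[dict[str, dict[str, FeatureTrack]], list[tuple[str, str]]]:
    """Size- and time-normalize a cohort's feature tracks.

    Returns the normalized tracks plus a log of (embryo, cell) pairs excluded
    because the track was too short for spline resampling.
    """
    mean_v = float(np.mean(list(per_embryo_volume.values())))
    out: dict[str, dict[str, FeatureTrack]] = {}
    excluded: list[tuple[str, str]] = []
    for emb, tracks in per_embryo_tracks.items():
        scale = EmbryoScale(emb, per_embryo_volume[emb], mean_v)
        scaled = scale_features(tracks, scale)
        out[emb] = {}
        for name, tr in scaled.items():
            try:
                out[emb][name] = normalize_time(tr, n_out=n_out)
            except TrackTooShortError:
                excluded.append((emb, name))
    return out, excluded
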