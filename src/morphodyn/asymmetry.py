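"""Daughter-volume asymmetry of cell divisions with a segmentation-uncertainty band.

Each daughter's volume is its median over the whole cell cycle; the division
ratio is larger/smaller (>= 1). The uncertainty band reflects segmentation
error: a one-voxel surface layer around each daughter, expressed as a
relative-volume fraction, bounds how far a measured ratio can drift from 1
for truly equal daughters. A division is significantly asymmetric when the
ratio exceeds 1 by more than the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from morphodyn.lineage import LineageTree
from morphodyn.morphometry import FeatureTrack

# re-exported here because the uncertainty band is built on it
from morphodyn.morphometry import boundary_layer_count  # noqa: F401


@dataclass
class DivisionAsymmetry:
    """Asymmetry of one division (one embryo, or cohort-aggregated)."""

    mother: str
    daughters: tuple[str, str]
    median_volumes: tuple[float, float]
    ratio: float
    uncertainty: float
    significant: bool
    per_embryo_ratios: np.ndarray | None = None
    cohort_median_ratio: float | None = None
    cohort_sd: float | None = None
    n_embryos: int = 1


def _median_volume(track: FeatureTrack) -> float:
    v = float(np.median(track.volume))
    if v <= 0:
        raise ValueError(f"cell {track.cell} has non-positive median volume")
    return v


def _layer_fraction(track: FeatureTrack, median_volume: float, voxel_volume: float) -> float:
    """Relative volume of the one-voxel surface layer of a daughter.

    Uses the track's ``boundary_layer`` feature (µm³ per frame) when
    extracted from label images; otherwise estimated as median surface area
    times one voxel linear size.
    """
    if "boundary_layer" in track.features:
        layer = float(np.median(track.features["boundary_layer"]))
    else:
        layer = float(np.median(track.features["surface_area"])) * voxel_volume ** (1.0 / 3.0)
    return layer / median_volume


def division_ratio(
    daughter_a: FeatureTrack,
    daughter_b: FeatureTrack,
    mother: str = "",
    voxel_volume: float = 0.125,
    combine: str = "mean",
) -> DivisionAsymmetry:
    """Volume ratio and uncertainty band for one division in one embryo.

    ``combine`` sets how the two daughters' relative layer fractions form the
    band: ``"mean"`` (default) or ``"sum"``. Significant iff ratio − 1
    exceeds the band.
    """
    va, vb = _median_volume(daughter_a), _median_volume(daughter_b)
    ratio = max(va, vb) / min(va, vb)
    fa = _layer_fraction(daughter_a, va, voxel_volume)
    fb = _layer_fraction(daughter_b, vb, voxel_volume)
    if combine == "mean":
        u = 0.5 * (fa + fb)
    elif combine == "sum":
        u = fa + fb
    else:
        raise ValueError("combine must be 'mean' or 'sum'")
    return DivisionAsymmetry(
        mother=mother,
        daughters=(daughter_a.cell, daughter_b.cell),
        median_volumes=(va, vb),
        ratio=float(ratio),
        uncertainty=float(u),
        significant=bool(ratio - 1.0 > u),
    )


def cohort_asymmetry_table(
    per_embryo_tracks: dict[str, dict[str, FeatureTrack]],
    trees: dict[str, LineageTree],
    voxel_volume: float = 0.125,
    combine: str = "mean",
    min_embryos: int = 3,
) -> list[DivisionAsymmetry]:
    """Cohort-level asymmetry per division: median ratio, sd, significance.

    A division enters the table when both daughters have tracks in at least
    ``min_embryos`` embryos. Significance compares the cohort-median ratio
    against the cohort-median uncertainty band.
    """
    per_div: dict[str, list[DivisionAsymmetry]] = {}
    for emb, tracks in per_embryo_tracks.items():
        tree = trees[emb]
        for name in tree.cells:
            ds = tree.daughters(name)
            if len(ds) != 2 or ds[0] not in tracks or ds[1] not in tracks:
                continue
            res = division_ratio(
                tracks[ds[0]], tracks[ds[1]], mother=name,
                voxel_volume=voxel_volume, combine=combine,
            )
            per_div.setdefault(name, []).append(res)

    table = []
    for mother, results in sorted(per_div.items()):
        if len(results) < min_embryos:
            continue
        ratios = np.array([r.ratio for r in results])
        us = np.array([r.uncertainty for r in results])
        med_r = float(np.median(ratios))
        med_u = float(np.median(us))
        table.append(
            DivisionAsymmetry(
                mother=mother,
                daughters=results[0].daughters,
                median_volumes=(
                    float(np.median([r.median_volumes[0] for r in results])),
                    float(np.median([r.median_volumes[1] for r in results])),
                ),
                ratio=med_r,
                uncertainty=med_u,
                significant=bool(med_r - 1.0 > med_u),
                per_embryo_ratios=ratios,
                cohort_median_ratio=med_r,
                cohort_sd=float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
                n_embryos=len(results),
            )
        )
    return table
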