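"""Lineage annotation of nucleus point clouds by alignment and matching.

An unannotated embryo (a set of nucleus centroids at its final time point) is
named by aligning it to annotated reference embryos with the same nucleus
count: both clouds are mapped to their principal-component frames, the target
is swept through candidate rotations (a full revolution about PC1 in 2° steps
crossed with small swings about PC2/PC3 and the four proper axis-sign flips),
rescaled per axis to the reference's positional variance, and matched by
minimum-cost bipartite assignment with Euclidean distance as cost. The
lowest-cost combination over all references and rotations supplies the names,
which are then traced backward frame by frame through the tracked lineage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from morphodyn.lineage import LineageTree, daughter_names


class DegenerateGeometryError(ValueError):
    """Point cloud has no well-defined 3D principal frame."""


class SizeMismatchError(ValueError):
    """Target and reference have different nucleus counts."""


class NoReferenceError(ValueError):
    """No reference with a matching nucleus count."""


class AnnotationFailure(RuntimeError):
    """Backward tracing failed from every available starting frame."""


@dataclass
class NucleusSet:
    """Point cloud of nucleus centroids (µm) at one time point."""

    points: np.ndarray
    frame: int = 0
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("a nucleus set needs at least 2 points")
        if self.names is not None:
            if len(self.names) != len(self.points):
                raise ValueError("names must align with points")
            if len(set(self.names)) != len(self.names):
                raise ValueError("names must be unique")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MatchResult:
    """Outcome of matching a target cloud against a reference.

    ``mapping[i]`` is the reference index matched to target point ``i``;
    ``cost`` is the summed matched Euclidean distance (µm).
    """

    mapping: np.ndarray
    cost: float
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    signs: tuple[int, int, int] = (1, 1, 1)
    scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    reference_index: int = 0


def pca_align(nset: NucleusSet) -> NucleusSet:
    """Map a cloud to its principal-component frame.

    Output is centered at the origin with axes ordered by decreasing
    positional variance. Axis signs are fixed so the component of largest
    absolute skewness is positive on each axis (an arbitrary but
    deterministic convention; sign ambiguity is re-explored during matching).
    """
    pts = nset.points - nset.points.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] < 1e-9 * max(evals[0], 1.0) or len(pts) < 3:
        raise DegenerateGeometryError("point cloud is rank-deficient; PCA frame undefined")
    if np.linalg.det(evecs) < 0:  # keep the eigenbasis right-handed
        evecs[:, 2] = -evecs[:, 2]
    proj = pts @ evecs
    skew = (proj**3).mean(axis=0)
    flip = np.where(skew < 0, -1.0, 1.0)
    if np.prod(flip) < 0:  # keep the frame right-handed
        flip[np.argmin(np.abs(skew))] *= -1
    proj = proj * flip
    return NucleusSet(points=proj, frame=nset.frame, names=nset.names)


def candidate_transforms(
    swing_deg: float = 4.0, swing_step: float = 2.0, pc1_step: float = 2.0
) -> list[tuple[float, float, float]]:
    """Euler-angle triples (deg) of the rotation sweep in the PC frame.

    A full revolution about PC1 in ``pc1_step`` increments, crossed with
    swings of ±``swing_deg`` in ``swing_step`` increments about PC2 and PC3.
    The identity (0, 0, 0) is always included.
    """
    if swing_step <= 0 or pc1_step <= 0:
        raise ValueError("angle steps must be positive")
    theta = np.arange(0.0, 360.0, pc1_step)
    if swing_deg > 0:
        sw = np.arange(-swing_deg, swing_deg + 1e-9, swing_step)
    else:
        sw = np.array([0.0])
    return [(float(t), float(p2), float(p3)) for t in theta for p2 in sw for p3 in sw]


PROPER_SIGN_FLIPS: tuple[tuple[int, int, int], ...] = (
    (1, 1, 1),
    (1, -1, -1),
    (-1, 1, -1),
    (-1, -1, 1),
)


def scale_to_reference(target: NucleusSet, reference: NucleusSet) -> NucleusSet:
    """Rescale a PC-frame target so its per-axis sd equals the reference's."""
    scaled, _ = _scaled_points(target.points, reference.points)
    return NucleusSet(points=scaled, frame=target.frame, names=target.names)


def _scaled_points(pts: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd_t = pts.std(axis=0)
    sd_r = ref.std(axis=0)
    if np.any(sd_t < 1e-12):
        raise DegenerateGeometryError("zero positional variance on an axis")
    s = sd_r / sd_t
    return pts * s, s


def match_hungarian(target: NucleusSet, reference: NucleusSet) -> MatchResult:
    """Minimum-total-Euclidean-distance bijection between equal-size clouds."""
    if len(target) != len(reference):
        raise SizeMismatchError(f"target has {len(target)} nuclei, reference {len(reference)}")
    diff = target.points[:, None, :] - reference.points[None, :, :]
    cost = np.sqrt((diff**2).sum(-1))
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(len(target), dtype=int)
    mapping[rows] = cols
    return MatchResult(mapping=mapping, cost=float(cost[rows, cols].sum()))


def annotate(
    target: NucleusSet,
    references: list[NucleusSet],
    swing_deg: float = 4.0,
    swing_step: float = 2.0,
) -> tuple[NucleusSet, MatchResult]:
    """Name a target cloud from the best (reference × rotation) combination.

    Ties in total cost are broken by the first combination encountered in the
    deterministic order: references as given, then sign flips as listed, then
    rotations in sweep order.
    """
    usable = [(i, r) for i, r in enumerate(references) if len(r) == len(target)]
    if not usable:
        raise NoReferenceError(f"no reference with {len(target)} nuclei")
    t_pc = pca_align(target)
    angles = candidate_transforms(swing_deg=swing_deg, swing_step=swing_step)
    rots = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()  # (M,3,3)

    best: MatchResult | None = None
    for ref_i, ref in usable:
        r_pc = pca_align(ref)
        rp = r_pc.points
        sd_r = rp.std(axis=0)
        for signs in PROPER_SIGN_FLIPS:
            base = t_pc.points * np.asarray(signs, dtype=float)
            cand = np.einsum("mij,nj->mni", rots, base)  # (M, n, 3)
            sd_t = cand.std(axis=1)  # (M, 3)
            scales = sd_r[None, :] / np.maximum(sd_t, 1e-12)
            cand = cand * scales[:, None, :]
            d = cand[:, :, None, :] - rp[None, None, :, :]
            costs = np.sqrt((d**2).sum(-1))  # (M, n, n)
            for m in range(costs.shape[0]):
                rows, cols = linear_sum_assignment(costs[m])
                c = float(costs[m][rows, cols].sum())
                if best is None or c < best.cost - 1e-12:
                    mapping = np.empty(len(target), dtype=int)
                    mapping[rows] = cols
                    best = MatchResult(
                        mapping=mapping,
                        cost=c,
                        rotation=angles[m],
                        signs=signs,
                        scales=tuple(scales[m]),
                        reference_index=ref_i,
                    )
    assert best is not None
    ref = references[best.reference_index]
    if ref.names is None:
        raise ValueError("winning reference carries no names")
    names = [ref.names[j] for j in best.mapping]
    out = NucleusSet(points=target.points, frame=target.frame, names=names)
    return out, best


@dataclass
class TraceResult:
    """Names per frame from backward lineage tracing."""

    names: list[list[str]]
    n_restarts: int
    anchor_frame: int


def _trace_from(
    anchor: int,
    anchor_names: list[str],
    nuclei: list[NucleusSet],
    links: list[np.ndarray],
    tree: LineageTree,
) -> list[list[str]] | None:
    """Trace names backward from an anchor frame; None on inconsistency.

    ``links[t][j]`` is the index in frame ``t`` of the nucleus that nucleus
    ``j`` of frame ``t + 1`` descends from (its own earlier position, or its
    mother at a division).
    """
    names: list[list[str] | None] = [None] * len(nuclei)
    names[anchor] = list(anchor_names)
    for t in range(anchor - 1, -1, -1):
        child_names: dict[int, list[str]] = {}
        for j, i in enumerate(links[t]):
            child_names.setdefault(int(i), []).append(names[t + 1][j])
        row: list[str] = []
        for i in range(len(nuclei[t])):
            kids = child_names.get(i)
            if not kids:
                return None  # a nucleus with no descendant link: tracking hole
            if len(kids) == 1:
                row.append(kids[0])
            elif len(kids) == 2:
                pa = tree[kids[0]].parent if kids[0] in tree else None
                pb = tree[kids[1]].parent if kids[1] in tree else None
                if pa is None or pa != pb:
                    return None  # daughters disagree on the mother: bad annotation
                row.append(pa)
            else:
                return None
        if len(set(row)) != len(row):
            return None
        names[t] = row
    # forward fill any frames after the anchor (restart case)
    for t in range(anchor, len(nuclei) - 1):
        child_names = {}
        for j, i in enumerate(links[t]):
            child_names.setdefault(int(i), []).append(j)
        nxt: list[str | None] = [None] * len(nuclei[t + 1])
        for i, kids in child_names.items():
            mother = names[t][i]
            if len(kids) == 1:
                nxt[kids[0]] = mother
            else:
                # daughter identity at a division is ambiguous forward in time;
                # assign deterministically by nucleus index order
                for k, dname in zip(sorted(kids), sorted(daughter_names(mother))):
                    nxt[k] = dname
        if any(n is None for n in nxt):
            return None
        names[t + 1] = nxt  # type: ignore[assignment]
    return names  # type: ignore[return-value]


def trace_back(
    annotated_final: NucleusSet,
    nuclei: list[NucleusSet],
    links: list[np.ndarray],
    tree: LineageTree,
    annotate_fn=None,
) -> TraceResult:
    """Name every nucleus in every frame by backward lineage tracing.

    Starts from the annotated final frame. If tracing hits an inconsistency
    (a traced division contradicts the lineage tree), the annotation is
    redone one frame earlier via ``annotate_fn(nucleus_set) -> names`` and
    tracing restarts; this repeats until it succeeds or frames are exhausted.
    """
    if len(links) != len(nuclei) - 1:
        raise ValueError("need one link array per consecutive frame pair")
    if annotated_final.names is None:
        raise ValueError("final frame must be annotated")
    anchor = len(nuclei) - 1
    names = list(annotated_final.names)
    restarts = 0
    while anchor >= 0:
        traced = _trace_from(anchor, names, nuclei, links, tree)
        if traced is not None:
            return TraceResult(names=traced, n_restarts=restarts, anchor_frame=anchor)
        anchor -= 1
        if anchor < 0:
            break
        if annotate_fn is None:
            raise AnnotationFailure(
                "tracing from the final frame failed and no re-annotation callback was given"
            )
        restarts += 1
        names = list(annotate_fn(nuclei[anchor]))
    raise AnnotationFailure("annotation failed from every frame")
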