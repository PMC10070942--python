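"""Synthetic 4D embryos with known ground truth.

Cohorts of virtual C. elegans-like embryos are generated from an invariant
lineage program (Sulston-style names, mean division frames, per-division
timing jitter, daughter volume ratios) together with per-cell mitotic
programs (a sphericity rise and a volume rise over the last minutes before
anaphase). Two tiers are produced from the same program:

* analytic ground-truth feature and contact tracks (cheap; cohort-scale
  recovery and calibration studies run on these), and
* rendered 3D label images, in which live cells partition the interior of an
  ellipsoidal eggshell as a power diagram (additively weighted Voronoi) over
  moving seed points, with the weights solved by fixed-point iteration to
  realize the programmed per-cell volume fractions.

Every random draw flows from one master seed via spawned child seeds, so an
entire cohort is reproducible from (program, spec, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from morphodyn.lineage import Cell, LineageTree, daughter_names
from morphodyn.match import NucleusSet
from morphodyn.morphometry import ContactTrack, FeatureTrack, LabeledVolume


class RenderError(RuntimeError):
    """Raised when a frame cannot be rendered (e.g. more cells than voxels)."""


@dataclass(frozen=True)
class EmbryoSpec:
    """Acquisition-like geometry and timing of one synthetic embryo.

    Defaults are desk-scale: a (23, 15, 15) µm semi-axis eggshell rasterized
    at 0.5 µm isotropic voxels, 30 s frame interval. ``rate_factor``
    multiplies all division times (an embryo-specific developmental rate;
    the fastest/slowest ratio across a cohort stays within ``rate_band``).
    """

    eggshell_semi_axes: tuple[float, float, float] = (23.0, 15.0, 15.0)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    frame_interval_s: float = 30.0
    n_frames: int = 140
    rate_factor: float = 1.0
    rate_band: tuple[float, float] = (1 / 1.1, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.eggshell_semi_axes):
            raise ValueError("eggshell semi-axes must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        lo, hi = self.rate_band
        if not (lo - 1e-9 <= self.rate_factor <= hi + 1e-9):
            raise ValueError(f"rate_factor {self.rate_factor} outside band [{lo:.4f}, {hi:.4f}]")

    @property
    def dt_min(self) -> float:
        return self.frame_interval_s / 60.0

    @property
    def eggshell_volume(self) -> float:
        a, b, c = self.eggshell_semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Raster just large enough to hold the eggshell plus a 2-voxel pad."""
        return tuple(
            int(np.ceil(2 * ax / sp)) + 4
            for ax, sp in zip(self.eggshell_semi_axes, self.voxel_spacing)
        )


@dataclass
class DivisionProgram:
    mother: str
    daughters: tuple[str, str]
    mean_frame: float
    jitter_sd: float = 1.0
    volume_ratio: float = 1.0  # first daughter / second daughter, >= 1

    def __post_init__(self) -> None:
        if self.volume_ratio < 1:
            raise ValueError("volume ratio is larger/smaller, must be >= 1")


@dataclass
class MitoticProgram:
    """Programmed mitotic rounding and swelling of one cell.

    Over the last ``onset_min`` minutes before anaphase the sphericity rises
    by ``sphericity_amp`` (fractional) and the volume by ``volume_amp``,
    linearly. With ``plateau_min`` set (the ABa/ABp-like early-plateau
    phenotype) the rise saturates that many minutes before anaphase and then
    droops (by ``plateau_droop`` of the rise at anaphase), so the dynamics
    peak at the plateau onset, minutes before the end of metaphase. Baselines decline gently from birth to
    onset so the pre-mitotic minimum sits at the onset.
    """

    onset_min: float = 7.0
    sphericity_amp: float = 0.12
    volume_amp: float = 0.096
    plateau_min: float | None = None
    baseline_decline: float = 0.03
    plateau_droop: float = 0.15

    def __post_init__(self) -> None:
        if self.onset_min < 0:
            raise ValueError("onset offset must be >= 0")

    def ramp(self, minutes_before_anaphase: np.ndarray) -> np.ndarray:
        """Programmed rise fraction in [0, 1]; argument is >= 0, 0 at anaphase."""
        m = np.asarray(minutes_before_anaphase, dtype=float)
        if self.onset_min == 0:
            return np.where(m <= 0, 1.0, 0.0)
        end = self.plateau_min if self.plateau_min is not None else 0.0
        span = max(self.onset_min - end, 1e-9)
        r = np.clip((self.onset_min - m) / span, 0.0, 1.0)
        if self.plateau_min is not None:
            droop = self.plateau_droop * np.clip(
                (self.plateau_min - m) / max(self.plateau_min, 1e-9), 0.0, 1.0
            )
            r = np.where(m < self.plateau_min, 1.0 - droop, r)
        return r


@dataclass
class LineageProgram:
    """Full specification of a synthetic cohort's invariant development."""

    divisions: list[DivisionProgram]
    mitosis: dict[str, MitoticProgram] = field(default_factory=dict)
    default_mitosis: MitoticProgram = field(default_factory=MitoticProgram)
    karyo_cyto_lag: int = 2  # frames between anaphase onset and cytokinesis

    def mitosis_for(self, name: str) -> MitoticProgram:
        return self.mitosis.get(name, self.default_mitosis)

    def division_for(self, mother: str) -> DivisionProgram | None:
        for d in self.divisions:
            if d.mother == mother:
                return d
        return None

    def with_ratio(self, mother: str, ratio: float) -> "LineageProgram":
        divs = [replace(d, volume_ratio=ratio) if d.mother == mother else d for d in self.divisions]
        return replace(self, divisions=divs)


#: (mother, division time in minutes from the 2-cell stage, daughter ratio)
_DEFAULT_TABLE: list[tuple[str, float, float]] = [
    ("P0", 0.0, 1.35),
    ("AB", 15.0, 1.0),
    ("P1", 17.0, 1.18),
    ("ABa", 30.0, 1.0),
    ("ABp", 30.5, 1.0),
    ("EMS", 33.0, 1.28),
    ("P2", 35.0, 1.47),
    ("ABal", 44.0, 1.05),
    ("ABar", 44.5, 1.05),
    ("ABpl", 45.0, 1.05),
    ("ABpr", 45.5, 1.05),
    ("MS", 49.0, 1.0),
    ("C", 52.0, 1.1),
    ("E", 53.0, 1.0),
    ("P3", 54.0, 1.35),
    ("ABala", 58.0, 1.0),
    ("ABalp", 58.5, 1.0),
    ("ABara", 59.0, 1.0),
    ("ABarp", 59.5, 1.0),
    ("ABpla", 60.0, 1.0),
    ("ABplp", 60.5, 1.0),
    ("ABpra", 61.0, 1.0),
    ("ABprp", 61.5, 1.0),
    ("MSa", 63.0, 1.0),
    ("MSp", 63.5, 1.0),
    ("Ca", 65.0, 1.2),
    ("Cp", 65.5, 1.0),
    ("Ea", 68.0, 1.0),
    ("Ep", 68.5, 1.0),
    ("D", 69.0, 1.0),
]


def default_program(jitter_sd: float = 1.0, frame_interval_s: float = 30.0) -> LineageProgram:
    """Invariant early-lineage program from the 2-cell to the ~32-cell stage.

    Division times follow the stereotyped early C. elegans order (AB-lineage
    rounds roughly every 15 min, the P line budding off EMS, C, D, P4);
    daughter ratios encode the known asymmetric divisions of the P line.
    ABa and ABp carry the early-plateau sphericity phenotype (saturating
    about 4.5 min before anaphase).
    """
    fpm = 60.0 / frame_interval_s
    divisions = [
        DivisionProgram(
            mother=m,
            daughters=daughter_names(m),
            mean_frame=t * fpm,
            jitter_sd=0.0 if m == "P0" else jitter_sd,
            volume_ratio=r,
        )
        for m, t, r in _DEFAULT_TABLE
    ]
    mitosis = {
        "ABa": MitoticProgram(plateau_min=4.5),
        "ABp": MitoticProgram(plateau_min=4.5),
    }
    return LineageProgram(divisions=divisions, mitosis=mitosis)


def _stable_hash(*parts: object) -> int:
    h = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(h[:4], "little")


def generate_lineage(program: LineageProgram, spec: EmbryoSpec, seed: int) -> LineageTree:
    """Instantiate the lineage program as a frame-indexed tree.

    Division frames are the programmed means times ``rate_factor`` plus
    Gaussian jitter, rounded to the frame grid. A division landing beyond the
    recording leaves the mother cycle-incomplete (no error). Daughters appear
    ``karyo_cyto_lag`` frames after anaphase onset (cytokinesis completion).
    """
    rng = np.random.default_rng(seed)
    divisions = sorted(program.divisions, key=lambda d: (d.mean_frame, d.mother))
    jitters = {d.mother: rng.normal(0.0, d.jitter_sd) if d.jitter_sd > 0 else 0.0 for d in divisions}
    cells: dict[str, Cell] = {"P0": Cell("P0", None, 0)}
    for d in divisions:
        mother = cells.get(d.mother)
        if mother is None:
            continue
        ana = int(round(d.mean_frame * spec.rate_factor + jitters[d.mother]))
        ana = max(ana, mother.birth_frame)
        if d.mother != "P0" and ana >= spec.n_frames:
            continue  # cycle incomplete
        lag = 0 if d.mother == "P0" else program.karyo_cyto_lag
        div = ana + lag
        mother.anaphase_frame = ana
        if div >= spec.n_frames and d.mother != "P0":
            continue  # cytokinesis never completes on-screen
        mother.division_frame = div
        for name in d.daughters:
            cells[name] = Cell(name, d.mother, div)
    return LineageTree(cells, n_frames=spec.n_frames, frame_interval_s=spec.frame_interval_s)


def volume_fractions(program: LineageProgram) -> dict[str, float]:
    """Baseline volume fraction of the eggshell interior per cell."""
    frac = {"P0": 1.0}
    for d in sorted(program.divisions, key=lambda x: (x.mean_frame, x.mother)):
        if d.mother not in frac:
            continue
        r = d.volume_ratio
        frac[d.daughters[0]] = frac[d.mother] * r / (1 + r)
        frac[d.daughters[1]] = frac[d.mother] / (1 + r)
    return frac


def _division_axis(mother: str, wobble_rng: np.random.Generator | None = None,
                   wobble_sd: float = 0.0) -> np.ndarray:
    if mother == "P0":
        u = np.array([1.0, 0.0, 0.0])  # anterior-posterior
    else:
        r = np.random.default_rng(_stable_hash("axis", mother))
        u = r.normal(size=3)
        u /= np.linalg.norm(u)
    if wobble_rng is not None and wobble_sd > 0:
        u = u + wobble_rng.normal(0.0, wobble_sd, size=3)
        u /= np.linalg.norm(u)
    return u


def home_positions(
    tree: LineageTree,
    program: LineageProgram,
    spec: EmbryoSpec,
    wobble_rng: np.random.Generator | None = None,
    wobble_sd: float = 0.0,
    swap: tuple[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Stereotyped resting position of each cell's center (µm, eggshell frame).

    Daughters are displaced from the mother along a per-division axis (fixed
    across embryos, optionally wobbled per embryo), the larger daughter
    staying closer to the mother's center so volume-weighted centers are
    conserved. Positions are clamped inside 82% of the eggshell semi-axes.
    ``swap`` exchanges the home positions of two named cells (an
    arrangement-variant embryo).
    """
    fracs = volume_fractions(program)
    semi = np.asarray(spec.eggshell_semi_axes)
    pos = {"P0": np.zeros(3)}
    for d in sorted(program.divisions, key=lambda x: (x.mean_frame, x.mother)):
        if d.mother not in pos or d.daughters[0] not in tree.cells:
            continue
        u = _division_axis(d.mother, wobble_rng, wobble_sd)
        v_m = fracs[d.mother] * spec.eggshell_volume
        r_m = (3.0 * v_m / (4.0 * np.pi)) ** (1.0 / 3.0)
        share = d.volume_ratio / (1 + d.volume_ratio)  # larger daughter's share
        dstep = 0.55 * r_m
        for name, sgn, s in (
            (d.daughters[0], +1.0, 1.0 - share),
            (d.daughters[1], -1.0, share),
        ):
            p = pos[d.mother] + sgn * dstep * s * 2.0 * u
            rho = np.sqrt(np.sum((p / (0.82 * semi)) ** 2))
            if rho > 1.0:
                p = p * (0.95 / rho)
            pos[name] = p
    if swap is not None:
        a, b = swap
        pos[a], pos[b] = pos[b].copy(), pos[a].copy()
    return pos


def seed_positions(
    tree: LineageTree,
    homes: dict[str, np.ndarray],
    frame: int,
    settle_frames: int = 4,
) -> dict[str, np.ndarray]:
    """Cell center positions at one frame, with newborns settling smoothly.

    For the first ``settle_frames`` frames after birth a daughter
    interpolates from its mother's home toward its own.
    """
    out = {}
    for name in tree.alive_at(frame):
        c = tree[name]
        p = homes[name]
        if c.parent is not None and c.parent in homes:
            age = frame - c.birth_frame
            if age < settle_frames:
                t = (age + 1) / (settle_frames + 1)
                p = (1 - t) * homes[c.parent] + t * p
        out[name] = p
    return out


def target_fractions(
    tree: LineageTree, program: LineageProgram, spec: EmbryoSpec, frame: int
) -> dict[str, float]:
    """Per-cell eggshell volume fractions at a frame, swelling included.

    Fractions are renormalized to sum to one: the eggshell confines total
    volume, so a swelling cell compresses its neighbors.
    """
    base = volume_fractions(program)
    live = tree.alive_at(frame)
    out = {}
    for name in live:
        c = tree[name]
        f = base[name]
        if c.anaphase_frame is not None:
            m_before = (c.anaphase_frame - frame) * spec.dt_min
            mp = program.mitosis_for(name)
            f *= 1.0 + mp.volume_amp * float(mp.ramp(np.array([max(m_before, 0.0)]))[0])
        out[name] = f
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def label_map(tree: LineageTree) -> dict[str, int]:
    """Stable name -> integer label mapping (labels fixed over the movie)."""
    return {name: i + 1 for i, name in enumerate(sorted(tree.cells))}


def render_labels(
    tree: LineageTree,
    program: LineageProgram,
    spec: EmbryoSpec,
    frame: int,
    homes: dict[str, np.ndarray] | None = None,
    max_iter: int = 120,
    tol: float = 0.045,
) -> LabeledVolume:
    """Rasterize one frame as a power-diagram partition of the eggshell.

    Every voxel whose center lies inside the eggshell ellipsoid gets the
    label of the live cell minimizing ``|x - s_i|^2 - w_i``; the weights are
    iterated until each cell large enough to resolve (>= 500 expected voxels)
    realizes its programmed volume fraction within ``tol`` relative error.
    """
    if not 0 <= frame < spec.n_frames:
        raise ValueError(f"frame {frame} outside recording of {spec.n_frames} frames")
    if homes is None:
        homes = home_positions(tree, program, spec)
    live = tree.alive_at(frame)
    if not live:
        raise RenderError(f"no live cells at frame {frame}")
    seeds = seed_positions(tree, homes, frame)
    fracs = target_fractions(tree, program, spec, frame)

    shape = spec.grid_shape
    sp = np.asarray(spec.voxel_spacing)
    axes = [
        (np.arange(n) + 0.5) * s - n * s / 2.0 for n, s in zip(shape, sp)
    ]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    semi = np.asarray(spec.eggshell_semi_axes)
    inside = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2 <= 1.0
    pts = np.stack([X[inside], Y[inside], Z[inside]], axis=1)
    m = len(pts)
    k = len(live)
    if k > m:
        raise RenderError(f"frame {frame}: {k} cells but only {m} interior voxels")

    S = np.stack([seeds[n] for n in live])
    t = np.array([fracs[n] for n in live])
    d2 = ((pts[:, None, :].astype(np.float32) - S[None, :, :].astype(np.float32)) ** 2).sum(-1)
    r2 = (3.0 * t * spec.eggshell_volume / (4.0 * np.pi)) ** (2.0 / 3.0)
    # Weights solve the concave semi-discrete transport dual:
    #   maximize  sum_i t_i w_i + (1/m) sum_p min_i (|p - s_i|^2 - w_i)
    # whose gradient is t_i - f_i (target minus realized fraction).
    from scipy.optimize import minimize

    def neg_dual(w):
        val = d2 - w[None, :].astype(np.float32)
        lab = np.argmin(val, axis=1)
        f = np.bincount(lab, minlength=k) / m
        g = float(np.dot(t, w) + val[np.arange(m), lab].mean())
        return -g, -(t - f)

    res = minimize(neg_dual, r2.copy(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7})
    lab = np.argmin(d2 - res.x[None, :], axis=1)
    counts = np.bincount(lab, minlength=k)
    if counts.min() == 0:
        empty = [live[i] for i in np.nonzero(counts == 0)[0]]
        raise RenderError(f"frame {frame}: could not place cells {empty}")
    big = t * m >= 500
    rel = np.abs(counts / m - t) / t
    if big.any() and rel[big].max() > tol:
        worst = live[int(np.nonzero(big)[0][np.argmax(rel[big])])]
        raise RenderError(
            f"frame {frame}: volume fraction of {worst} off by {rel[big].max():.1%}"
        )

    grid = np.zeros(shape, dtype=np.int32)
    lmap = label_map(tree)
    grid_flat = np.zeros(m, dtype=np.int32)
    for i, name in enumerate(live):
        grid_flat[lab == i] = lmap[name]
    grid[inside] = grid_flat
    return LabeledVolume(
        grid=grid,
        spacing=tuple(sp),
        frame=frame,
        time_min=frame * spec.dt_min,
        names={v: k_ for k_, v in lmap.items()},
    )


def render_movie(
    tree: LineageTree, program: LineageProgram, spec: EmbryoSpec, frames: list[int] | None = None
) -> list[LabeledVolume]:
    """Render a sequence of frames with shared home positions and labels."""
    homes = home_positions(tree, program, spec)
    if frames is None:
        frames = list(range(spec.n_frames))
    return [render_labels(tree, program, spec, f, homes=homes) for f in frames]


def emit_nucleus_sets(
    tree: LineageTree,
    program: LineageProgram,
    spec: EmbryoSpec,
    rigid_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    jitter_sd: float = 0.0,
    seed: int = 0,
    frames: list[int] | None = None,
) -> list[NucleusSet]:
    """Nucleus centroids per frame: cell centers rigidly rotated plus jitter.

    ``rigid_rotation`` is an xyz Euler-angle triple in degrees applied about
    the eggshell center; jitter is isotropic Gaussian (µm). True cell names
    ride along as ``names`` (hidden ground truth for annotation experiments;
    strip them to build an unannotated target).
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    R = Rotation.from_euler("xyz", rigid_rotation, degrees=True).as_matrix()
    homes = home_positions(tree, program, spec)
    if frames is None:
        frames = list(range(spec.n_frames))
    out = []
    for f in frames:
        pos = seed_positions(tree, homes, f)
        names = sorted(pos)
        pts = np.stack([pos[n] for n in names]) @ R.T
        if jitter_sd > 0:
            pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
        out.append(NucleusSet(points=pts, frame=f, names=names))
    return out


# ---------------------------------------------------------------------------
# Analytic cohort tier: ground-truth feature and contact tracks
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Noise-free programmed dynamics of one synthetic embryo."""

    tracks: dict[str, FeatureTrack]
    contacts: dict[tuple[str, str], ContactTrack]
    volume_fractions: dict[str, float]
    rate_factor: float
    size_factor: float


@dataclass
class SyntheticEmbryo:
    """One cohort member: lineage, observed (noisy) tracks, ground truth."""

    embryo_id: str
    spec: EmbryoSpec
    tree: LineageTree
    tracks: dict[str, FeatureTrack]
    contacts: dict[tuple[str, str], ContactTrack]
    truth: GroundTruth


@dataclass
class CohortConfig:
    """Study conditions of a synthetic cohort.

    Defaults mirror the imaging cohort the analyses were designed around:
    32 embryos, 30 s frames, division jitter sd 1 frame, embryo-to-embryo
    volume spread up to 1.42x, developmental-rate spread up to 1.2x,
    1% per-frame multiplicative measurement noise, and a 2% sd embryo-level
    offset on each cell's dynamics (the inter-embryo biological variability
    the variability metrics measure). ``lineage_noise`` multiplies the
    offset sd per founder lineage; ``generation_noise_slope`` adds a
    per-generation increment; ``contact_coupling`` correlates the offsets of
    contacting cells (0 = independent).
    """

    n_embryos: int = 32
    program: LineageProgram = field(default_factory=default_program)
    n_frames: int = 140
    frame_interval_s: float = 30.0
    noise_sd: float = 0.01
    track_offset_sd: float = 0.02
    size_ratio: float = 1.42
    lineage_noise: dict[str, float] = field(default_factory=dict)
    generation_noise_slope: float = 0.0
    time_noise_slope: float = 0.0
    contact_coupling: float = 0.0
    baseline_sphericity: tuple[float, float] = (0.78, 0.84)
    arrangement_wobble_sd: float = 0.0


def _cell_baseline_sphericity(name: str, band: tuple[float, float]) -> float:
    u = _stable_hash("sph0", name) / 2**32
    return band[0] + u * (band[1] - band[0])


def _truth_dynamics(
    tree: LineageTree,
    program: LineageProgram,
    spec: EmbryoSpec,
    size_factor: float,
    sph_band: tuple[float, float],
    homes: dict[str, np.ndarray],
) -> tuple[dict[str, FeatureTrack], dict[str, float]]:
    """Noise-free per-cell volume/sphericity/surface-area/centroid tracks."""
    fracs = volume_fractions(program)
    v_embryo = spec.eggshell_volume * size_factor
    tracks: dict[str, FeatureTrack] = {}
    for name in sorted(tree.cells):
        c = tree[name]
        last = tree.last_frame(name)
        if name == "P0" and last < c.birth_frame:
            continue
        frames = np.arange(c.birth_frame, last + 1)
        if len(frames) == 0:
            continue
        mp = program.mitosis_for(name)
        if c.anaphase_frame is not None:
            m_before = np.maximum((c.anaphase_frame - frames) * spec.dt_min, 0.0)
            ramp = mp.ramp(m_before)
            onset_frame = c.anaphase_frame - mp.onset_min / spec.dt_min
            span = max(onset_frame - c.birth_frame, 1.0)
            u = np.clip((frames - c.birth_frame) / span, 0.0, 1.0)
        else:
            ramp = np.zeros(len(frames))
            u = np.zeros(len(frames))
        decline = mp.baseline_decline
        vol = fracs[name] * v_embryo * (1 - decline * u) * (1 + mp.volume_amp * ramp)
        s0 = _cell_baseline_sphericity(name, sph_band)
        sph = np.clip(s0 * (1 - decline * u) * (1 + mp.sphericity_amp * ramp), 0.01, 0.999)
        area = np.pi ** (1 / 3) * (6.0 * vol) ** (2 / 3) / sph
        cent = np.stack([seed_positions(tree, homes, int(f)).get(name, homes[name]) for f in frames])
        tracks[name] = FeatureTrack(
            cell=name,
            frames=frames,
            times_min=frames * spec.dt_min,
            features={"volume": vol, "surface_area": area, "sphericity": sph, "centroid": cent},
        )
    return tracks, fracs


def _truth_contacts(
    tree: LineageTree,
    tracks: dict[str, FeatureTrack],
    homes: dict[str, np.ndarray],
    spec: EmbryoSpec,
    reach: float = 1.25,
) -> dict[tuple[str, str], ContactTrack]:
    """Geometric ground-truth contacts from cell centers and equivalent radii.

    Two live cells contact at a frame when their center distance is below
    ``reach`` times the sum of their volume-equivalent radii; the contact
    area scales with the smaller cell's cross-section and the normalized
    overlap depth. Stable neighborhoods give long-lived contacts; cells
    whose co-existence straddles a jittered division give brief ones.
    """
    per_pair: dict[tuple[str, str], dict[int, float]] = {}
    for f in range(spec.n_frames):
        live = [n for n in tree.alive_at(f) if n in tracks]
        if len(live) < 2:
            continue
        radii = {}
        for n in live:
            tr = tracks[n]
            idx = f - int(tr.frames[0])
            radii[n] = (3.0 * tr.volume[idx] / (4 * np.pi)) ** (1 / 3)
        pos = seed_positions(tree, homes, f)
        for i, a in enumerate(live):
            for b in live[i + 1 :]:
                d = float(np.linalg.norm(pos[a] - pos[b]))
                rsum = radii[a] + radii[b]
                if d >= reach * rsum:
                    continue
                depth = (reach * rsum - d) / (reach * rsum)
                area = np.pi * min(radii[a], radii[b]) ** 2 * min(1.0, 1.6 * depth)
                key = (min(a, b), max(a, b))
                per_pair.setdefault(key, {})[f] = area
    out = {}
    for pair, d in per_pair.items():
        frs = np.array(sorted(d))
        out[pair] = ContactTrack(pair=pair, frames=frs, areas=np.array([d[f] for f in frs]))
    return out


def _noise_multipliers(
    tree: LineageTree,
    contacts: dict[tuple[str, str], ContactTrack],
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Per-embryo multiplicative offset for each cell's whole track.

    Offsets model embryo-level biological variability; the sd is modulated
    per founder lineage and generation, and offsets of contacting cells are
    correlated through shared edge latents when ``contact_coupling`` > 0.
    """
    from morphodyn.lineage import founder_lineage

    names = sorted(tree.cells)
    sds = {}
    for n in names:
        mult = cfg.lineage_noise.get(founder_lineage(n), 1.0)
        gen = tree.generation(n)
        mult *= 1.0 + cfg.generation_noise_slope * max(gen - 1, 0)
        sds[n] = cfg.track_offset_sd * mult
    xi = {n: rng.normal(0.0, 1.0) for n in names}
    rho = cfg.contact_coupling
    if rho > 0 and contacts:
        # regional coupling: a cell's shared component is the mean latent of
        # its contact neighborhood (incl. itself). Contacting cells share
        # most of their neighborhood, so their offsets correlate strongly;
        # spatially distant cells do not.
        zeta = {n: rng.normal(0.0, 1.0) for n in names}
        nbrs: dict[str, set[str]] = {n: {n} for n in names}
        for (a, b) in contacts:
            if a in nbrs and b in nbrs:
                nbrs[a].add(b)
                nbrs[b].add(a)
        out = {}
        for n in names:
            hood = sorted(nbrs[n])
            shared = sum(zeta[m] for m in hood) / np.sqrt(len(hood))
            out[n] = 1.0 + sds[n] * (np.sqrt(1 - rho) * xi[n] + np.sqrt(rho) * shared)
        return out
    return {n: 1.0 + sds[n] * xi[n] for n in names}


def simulate_embryo(
    embryo_id: str,
    cfg: CohortConfig,
    seed: int,
    rate_factor: float,
    size_factor: float,
) -> SyntheticEmbryo:
    """One synthetic embryo: lineage, ground truth, and noisy observations."""
    spec = EmbryoSpec(
        n_frames=cfg.n_frames,
        frame_interval_s=cfg.frame_interval_s,
        rate_factor=rate_factor,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    tree = generate_lineage(cfg.program, spec, seed=int(rng.integers(2**31)))
    wobble_rng = rng if cfg.arrangement_wobble_sd > 0 else None
    homes = home_positions(
        tree, cfg.program, spec, wobble_rng=wobble_rng, wobble_sd=cfg.arrangement_wobble_sd
    )
    truth_tracks, fracs = _truth_dynamics(
        tree, cfg.program, spec, size_factor, cfg.baseline_sphericity, homes
    )
    truth_contacts = _truth_contacts(tree, truth_tracks, homes, spec)
    offsets = _noise_multipliers(tree, truth_contacts, cfg, rng)

    tracks = {}
    for name, tt in truth_tracks.items():
        n_fr = len(tt.frames)
        # noise sd may grow along the cell cycle (developmental-time effect)
        cycle_pos = np.linspace(0.0, 1.0, n_fr) if n_fr > 1 else np.zeros(1)
        sd_t = cfg.noise_sd * (1.0 + cfg.time_noise_slope * cycle_pos)
        feats = {}
        for k, v in tt.features.items():
            if k == "centroid":
                feats[k] = v.copy()
            else:
                noise = 1.0 + rng.normal(0.0, 1.0, size=len(v)) * sd_t
                feats[k] = v * offsets[name] * noise
        feats["sphericity"] = np.clip(feats["sphericity"], 0.01, 0.999)
        tracks[name] = FeatureTrack(
            cell=name, frames=tt.frames.copy(), times_min=tt.times_min.copy(), features=feats
        )
    contacts = {}
    for pair, ct in truth_contacts.items():
        noise = np.abs(1.0 + rng.normal(0.0, cfg.noise_sd, size=len(ct.areas)))
        contacts[pair] = ContactTrack(pair=pair, frames=ct.frames.copy(), areas=ct.areas * noise)

    truth = GroundTruth(
        tracks=truth_tracks,
        contacts=truth_contacts,
        volume_fractions=fracs,
        rate_factor=rate_factor,
        size_factor=size_factor,
    )
    return SyntheticEmbryo(
        embryo_id=embryo_id, spec=spec, tree=tree, tracks=tracks, contacts=contacts, truth=truth
    )


def simulate_cohort(cfg: CohortConfig, seed: int) -> list[SyntheticEmbryo]:
    """A reproducible cohort: all randomness flows from the master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(cfg.n_embryos + 1)
    head = np.random.default_rng(children[0])
    lo, hi = 1 / 1.1, 1.1
    rates = head.uniform(lo, hi, size=cfg.n_embryos)
    sqrt_ratio = np.sqrt(cfg.size_ratio)
    sizes = head.uniform(1 / sqrt_ratio, sqrt_ratio, size=cfg.n_embryos)
    return [
        simulate_embryo(
            embryo_id=f"emb{i:03d}",
            cfg=cfg,
            seed=int(np.random.default_rng(children[i + 1]).integers(2**31)),
            rate_factor=float(rates[i]),
            size_factor=float(sizes[i]),
        )
        for i in range(cfg.n_embryos)
    ]
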