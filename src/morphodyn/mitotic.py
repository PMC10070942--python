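"""Mitotic rounding and swelling detection.

Feature dynamics of each cell type are registered across embryos at the end
of metaphase (t = 0, the last frame at or before anaphase onset) and
averaged per time offset. The mitotic-event window is estimated as the
offset where the all-cell-type average is minimal; the rise is then tested
per cell type by a paired t-test between a begin window (−7.5 to −6.5 min)
and an end window (−1.0 to 0 min), with per-embryo window means as the
paired samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from morphodyn.lineage import LineageTree
from morphodyn.morphometry import FeatureTrack


@dataclass
class RegisteredDynamics:
    """Per-embryo feature values of one cell type on a common offset grid.

    ``offsets_min`` ascend to 0 (= end of metaphase); ``matrix`` is
    (n_embryos, n_offsets) with NaN where an embryo's track does not reach
    an offset. Registration copies original track values (no interpolation).
    """

    cell_type: str
    feature: str
    offsets_min: np.ndarray
    matrix: np.ndarray
    embryo_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.offsets_min = np.asarray(self.offsets_min, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.offsets_min):
            raise ValueError("matrix columns must match offsets")
        if len(self.offsets_min) and self.offsets_min[-1] != 0.0:
            raise ValueError("offset grid must end at t = 0")

    @property
    def mean(self) -> np.ndarray:
        """Across-embryo mean at each offset (ignoring missing embryos)."""
        return np.nanmean(self.matrix, axis=0)

    @property
    def n_embryos(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MitoticTestResult:
    """Begin-vs-end window comparison for one cell type."""

    cell_type: str
    feature: str
    begin_mean: float
    end_mean: float
    percent_increase: float
    p_value: float
    significant: bool
    n_embryos: int
    underpowered: bool = False
    begin_truncated: bool = False


def register_at_metaphase_end(
    per_embryo_tracks: dict[str, dict[str, FeatureTrack]],
    trees: dict[str, LineageTree],
    feature: str = "sphericity",
    normalize_at_zero: bool | None = None,
) -> dict[str, RegisteredDynamics]:
    """Register one feature's dynamics at the end of metaphase per cell type.

    t = 0 is the last frame at or before the anaphase-onset frame; offsets
    count backward on the acquisition grid. Volume dynamics are normalized
    by the value at t = 0 (``normalize_at_zero`` defaults to True for the
    volume feature). Cells without a known anaphase frame are skipped.
    """
    if normalize_at_zero is None:
        normalize_at_zero = feature == "volume"
    rows: dict[str, list[tuple[str, np.ndarray, np.ndarray]]] = {}
    for emb, tracks in per_embryo_tracks.items():
        tree = trees[emb]
        dt = tree.dt_min
        for name, tr in tracks.items():
            if name not in tree or tree[name].anaphase_frame is None:
                continue
            ana = tree[name].anaphase_frame
            sel = tr.frames <= ana
            if not sel.any():
                continue
            frames = tr.frames[sel]
            vals = tr.features[feature][sel].astype(float)
            offs = (frames - frames[-1]) * dt
            if normalize_at_zero:
                vals = vals / vals[-1]
            rows.setdefault(name, []).append((emb, offs, vals))

    out = {}
    for name, entries in rows.items():
        all_offs = sorted({float(o) for _, offs, _ in entries for o in offs})
        grid = np.array(all_offs)
        mat = np.full((len(entries), len(grid)), np.nan)
        idx = {o: j for j, o in enumerate(grid)}
        ids = []
        for i, (emb, offs, vals) in enumerate(entries):
            ids.append(emb)
            for o, v in zip(offs, vals):
                mat[i, idx[float(o)]] = v
        out[name] = RegisteredDynamics(
            cell_type=name, feature=feature, offsets_min=grid, matrix=mat, embryo_ids=ids
        )
    return out


def average_over_types(
    registered: dict[str, RegisteredDynamics]
) -> tuple[np.ndarray, np.ndarray]:
    """All-cell-type average dynamics on the union offset grid.

    Each cell type contributes its across-embryo mean; types are averaged
    with equal weight at each offset where they have data.
    """
    grid = sorted({float(o) for r in registered.values() for o in r.offsets_min})
    grid_arr = np.array(grid)
    acc = np.zeros(len(grid))
    cnt = np.zeros(len(grid))
    for r in registered.values():
        m = r.mean
        for o, v in zip(r.offsets_min, m):
            if np.isnan(v):
                continue
            j = grid.index(float(o))
            acc[j] += v
            cnt[j] += 1
    mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return grid_arr, mean


def estimate_rounding_window(
    offsets_min: np.ndarray, mean_dynamics: np.ndarray, search: tuple[float, float] = (-10.0, 0.0)
) -> float:
    """Onset of the mitotic event: offset of the minimum of the averaged dynamics.

    The search is restricted to ``search`` (default the last 10 minutes);
    ties go to the earliest offset.
    """
    offsets_min = np.asarray(offsets_min, dtype=float)
    mean_dynamics = np.asarray(mean_dynamics, dtype=float)
    sel = (offsets_min >= search[0]) & (offsets_min <= search[1]) & ~np.isnan(mean_dynamics)
    if not sel.any():
        raise ValueError("averaged dynamics do not cover the search window")
    offs = offsets_min[sel]
    vals = mean_dynamics[sel]
    return float(offs[np.argmin(vals)])  # argmin returns the first (earliest) tie


def _window_means(reg: RegisteredDynamics, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    sel = (reg.offsets_min >= lo - 1e-9) & (reg.offsets_min <= hi + 1e-9)
    if not sel.any():
        return np.full(reg.n_embryos, np.nan)
    return np.nanmean(reg.matrix[:, sel], axis=1)


def test_window_increase(
    reg: RegisteredDynamics,
    begin: tuple[float, float] = (-7.5, -6.5),
    end: tuple[float, float] = (-1.0, 0.0),
    alpha: float = 0.05,
) -> MitoticTestResult:
    """Paired one-sided t-test of a feature increase between two offset windows.

    Per embryo the window values are averaged first; embryos missing either
    window are dropped. Fewer than 3 contributing embryos marks the result
    underpowered (no significance claim). A fully degenerate test (all
    paired differences zero) is non-significant with p = 1.
    """
    b = _window_means(reg, begin)
    e = _window_means(reg, end)
    ok = ~np.isnan(b) & ~np.isnan(e)
    b, e = b[ok], e[ok]
    n = int(ok.sum())
    truncated = bool(np.isnan(_window_means(reg, begin)).any())
    begin_mean = float(np.mean(b)) if n else np.nan
    end_mean = float(np.mean(e)) if n else np.nan
    pct = 100.0 * (end_mean - begin_mean) / begin_mean if n else np.nan
    if n < 3:
        return MitoticTestResult(
            reg.cell_type, reg.feature, begin_mean, end_mean, pct,
            p_value=np.nan, significant=False, n_embryos=n,
            underpowered=True, begin_truncated=truncated,
        )
    diffs = e - b
    if np.allclose(diffs, 0.0):
        p = 1.0
    else:
        p = float(stats.ttest_rel(e, b, alternative="greater").pvalue)
    return MitoticTestResult(
        reg.cell_type, reg.feature, begin_mean, end_mean, pct,
        p_value=p, significant=p < alpha, n_embryos=n, begin_truncated=truncated,
    )


def peak_offset(reg: RegisteredDynamics) -> float:
    """Offset (min) of the maximum of the across-embryo mean; ties go latest."""
    m = reg.mean
    ok = ~np.isnan(m)
    offs = reg.offsets_min[ok]
    vals = m[ok]
    best = np.max(vals)
    return float(offs[np.nonzero(vals == best)[0][-1]])
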