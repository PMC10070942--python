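"""Inter-embryo variability metrics and cell-type similarity.

The core variability metric for two length-n feature dynamics f_a, f_b
(strictly positive, cycle-normalized to a common length) is

    v = (1/n) Σ_t |f_a(t) − f_b(t)| / (f_a(t) + f_b(t)),

bounded in [0, 1), zero exactly for identical dynamics. Its scalar special
case for two median cell-cycle volumes is M_v = |V_A − V_B| / (V_A + V_B).
Cell-type similarity uses an integral RMSD: per feature the RMSE between two
cells' normalized dynamics divided by the mean of the pooled dynamics,
summed over features.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from morphodyn.lineage import founder_lineage
from morphodyn.morphometry import FeatureTrack

DEFAULT_FEATURES = ("volume", "surface_area", "sphericity")


def variability_v(fa: np.ndarray, fb: np.ndarray) -> float:
    """Variability of two equal-length, strictly positive feature dynamics."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if fa.shape != fb.shape or fa.ndim != 1:
        raise ValueError("dynamics must be 1D arrays of equal length")
    if np.any(fa <= 0) or np.any(fb <= 0):
        raise ValueError("variability metric requires strictly positive dynamics")
    return float(np.mean(np.abs(fa - fb) / (fa + fb)))


def variability_summand(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Per-time-point term |fa − fb| / (fa + fb) (for time-resolved analyses)."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if np.any(fa <= 0) or np.any(fb <= 0):
        raise ValueError("variability metric requires strictly positive dynamics")
    return np.abs(fa - fb) / (fa + fb)


def mv(va: float, vb: float) -> float:
    """Volume-variability |V_A − V_B| / (V_A + V_B) of two median volumes."""
    if va <= 0 or vb <= 0:
        raise ValueError("volumes must be positive")
    return abs(va - vb) / (va + vb)


def integral_rmsd(
    track_a: FeatureTrack,
    track_b: FeatureTrack,
    features: tuple[str, ...] = DEFAULT_FEATURES,
    denominator: str = "pooled",
) -> float:
    """Summed normalized RMSE between two cells' normalized feature dynamics.

    Per feature: RMSE over the common time grid divided by the mean of the
    two cells' pooled values of that feature (``denominator="per-cell"``
    divides by the mean of the two per-cell means instead — identical for
    equal-length tracks), summed over ``features``. Invariant to a common
    positive rescaling of both inputs.
    """
    total = 0.0
    for feat in features:
        if feat not in track_a.features or feat not in track_b.features:
            raise KeyError(f"feature {feat!r} missing from a track")
        a = track_a.features[feat]
        b = track_b.features[feat]
        if a.shape != b.shape:
            raise ValueError("tracks must be time-normalized to equal length")
        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
        if denominator == "pooled":
            den = float(np.mean(np.concatenate([a, b])))
        elif denominator == "per-cell":
            den = 0.5 * (float(np.mean(a)) + float(np.mean(b)))
        else:
            raise ValueError("denominator must be 'pooled' or 'per-cell'")
        if den <= 0:
            raise ValueError(f"feature {feat!r} has non-positive mean; cannot normalize")
        total += rmse / den
    return total


@dataclass
class DistinguishabilityResult:
    per_type_fraction: dict[str, float]
    fraction_types_above: float  # share of types distinguished from >= threshold of others
    mean_fraction: float
    threshold: float
    excluded_singletons: list[str]


def distinguishability(
    per_embryo_tracks: dict[str, dict[str, FeatureTrack]],
    features: tuple[str, ...] = DEFAULT_FEATURES,
    alpha: float = 0.05,
    threshold: float = 0.95,
) -> DistinguishabilityResult:
    """Fraction of other cell types each type can be told apart from.

    Type X is distinguished from type Y when X's intra-type integral-RMSD
    distribution (across embryo pairs) is significantly smaller than the
    X-vs-Y inter-type distribution (one-sided Welch test at ``alpha``).
    Reported per type, as the cohort mean, and as the share of types
    distinguished from at least ``threshold`` of the others.
    """
    types = sorted({c for tracks in per_embryo_tracks.values() for c in tracks})
    instances: dict[str, list[FeatureTrack]] = {t: [] for t in types}
    for tracks in per_embryo_tracks.values():
        for c, tr in tracks.items():
            instances[c].append(tr)
    excluded = [t for t in types if len(instances[t]) < 2]
    usable = [t for t in types if len(instances[t]) >= 2]

    intra: dict[str, np.ndarray] = {}
    for t in usable:
        ds = [integral_rmsd(a, b, features) for a, b in combinations(instances[t], 2)]
        intra[t] = np.array(ds)

    frac: dict[str, float] = {}
    for x in usable:
        n_dist = 0
        others = [y for y in usable if y != x]
        for y in others:
            inter = np.array(
                [integral_rmsd(a, b, features) for a in instances[x] for b in instances[y]]
            )
            if len(intra[x]) >= 2 and len(inter) >= 2:
                p = stats.ttest_ind(
                    intra[x], inter, equal_var=False, alternative="less"
                ).pvalue
                if p < alpha:
                    n_dist += 1
            elif intra[x].max() < inter.min():
                n_dist += 1
        frac[x] = n_dist / len(others) if others else np.nan
    vals = np.array([frac[t] for t in usable])
    return DistinguishabilityResult(
        per_type_fraction=frac,
        fraction_types_above=float(np.mean(vals >= threshold)) if len(vals) else np.nan,
        mean_fraction=float(np.mean(vals)) if len(vals) else np.nan,
        threshold=threshold,
        excluded_singletons=excluded,
    )


def distance_matrix(
    per_embryo_tracks: dict[str, dict[str, FeatureTrack]],
    features: tuple[str, ...] = DEFAULT_FEATURES,
) -> tuple[np.ndarray, list[str], int]:
    """Symmetric zero-diagonal integral-RMSD matrix over all cell instances.

    Returns (matrix, labels "embryo/cell", triangle-inequality violation
    count — the score is not guaranteed metric, violations are reported,
    not fixed). Intended for export to external embedding tools.
    """
    items: list[tuple[str, FeatureTrack]] = []
    for emb in sorted(per_embryo_tracks):
        for c in sorted(per_embryo_tracks[emb]):
            items.append((f"{emb}/{c}", per_embryo_tracks[emb][c]))
    n = len(items)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = integral_rmsd(items[i][1], items[j][1], features)
            mat[i, j] = mat[j, i] = d
    violations = 0
    for i, j in combinations(range(n), 2):
        if np.any(mat[i, j] > mat[i, :] + mat[:, j] + 1e-12):
            violations += 1
    return mat, [k for k, _ in items], violations


def pairwise_scores(
    per_embryo_tracks: dict[str, dict[str, FeatureTrack]],
    feature: str = "volume",
) -> dict[str, dict[tuple[str, str], float]]:
    """Variability v per cell for every embryo pair (cell -> pair -> v)."""
    embs = sorted(per_embryo_tracks)
    cells = sorted({c for e in embs for c in per_embryo_tracks[e]})
    out: dict[str, dict[tuple[str, str], float]] = {}
    for c in cells:
        have = [e for e in embs if c in per_embryo_tracks[e]]
        if len(have) < 2:
            continue
        d = {}
        for ea, eb in combinations(have, 2):
            d[(ea, eb)] = variability_v(
                per_embryo_tracks[ea][c].features[feature],
                per_embryo_tracks[eb][c].features[feature],
            )
        out[c] = d
    return out


@dataclass
class GroupedVariability:
    grouping: str
    group_stats: dict  # group -> (median, q1, q3, n)
    pairwise_p: dict  # (group_a, group_b) -> Welch p-value (two-sided)


def variability_by_group(
    scores: dict[str, dict[tuple[str, str], float]],
    generations: dict[str, int],
    grouping: str = "lineage",
) -> GroupedVariability:
    """Group per-cell variability scores by lineage, generation or cell.

    Pairwise comparisons between groups use Welch's two-sample t-test;
    groups with fewer than 2 scores are excluded.
    """
    def key(cell: str):
        if grouping == "lineage":
            return founder_lineage(cell)
        if grouping == "generation":
            return generations[cell]
        if grouping == "cell":
            return cell
        raise ValueError("grouping must be 'lineage', 'generation' or 'cell'")

    groups: dict[object, list[float]] = {}
    for cell, d in scores.items():
        groups.setdefault(key(cell), []).extend(d.values())
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    stats_d = {}
    for g, v in groups.items():
        arr = np.array(v)
        stats_d[g] = (
            float(np.median(arr)),
            float(np.percentile(arr, 25)),
            float(np.percentile(arr, 75)),
            len(arr),
        )
    pvals = {}
    for ga, gb in combinations(sorted(groups, key=str), 2):
        pvals[(ga, gb)] = float(
            stats.ttest_ind(groups[ga], groups[gb], equal_var=False).pvalue
        )
    return GroupedVariability(grouping=grouping, group_stats=stats_d, pairwise_p=pvals)


def variability_over_time(
    per_embryo_tracks: dict[str, dict[str, FeatureTrack]],
    feature: str = "volume",
    alpha: float = 0.01,
) -> dict:
    """Per-normalized-time variability and an initial-vs-final Welch test.

    At each time point of the normalized cycle the Eq.-style summand is
    averaged over embryo pairs per cell; the all-cell average dynamics and
    the Welch two-sample test between the initial and final time points'
    per-cell values are returned.
    """
    embs = sorted(per_embryo_tracks)
    cells = sorted({c for e in embs for c in per_embryo_tracks[e]})
    per_cell_series = {}
    for c in cells:
        have = [e for e in embs if c in per_embryo_tracks[e]]
        if len(have) < 2:
            continue
        terms = [
            variability_summand(
                per_embryo_tracks[ea][c].features[feature],
                per_embryo_tracks[eb][c].features[feature],
            )
            for ea, eb in combinations(have, 2)
        ]
        per_cell_series[c] = np.mean(terms, axis=0)
    series = np.array(list(per_cell_series.values()))
    initial = series[:, 0]
    final = series[:, -1]
    res = stats.ttest_ind(final, initial, equal_var=False)
    return {
        "mean_dynamics": series.mean(axis=0),
        "sd_dynamics": series.std(axis=0),
        "initial": initial,
        "final": final,
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < alpha and final.mean() > initial.mean()),
    }


def contact_dependence(
    scores: dict[str, dict[tuple[str, str], float]],
    embryos: list,
    seed: int = 0,
) -> dict:
    """Correlation of variability between contacting vs mock cell pairs.

    Contacting same-generation cell pairs contribute the points
    (v_cellA(embryo pair), v_cellB(embryo pair)); the Pearson correlation
    over all such points is compared with mock pairs — same-generation cells
    never contacting in any embryo, sampled to matching count with a fixed
    seed.
    """
    gen = {}
    for c in scores:
        for e in embryos:
            if c in e.tree:
                gen[c] = e.tree.generation(c)
                break
    contact_pairs = set()
    for e in embryos:
        for (a, b) in e.contacts:
            if a in scores and b in scores and gen[a] == gen[b]:
                contact_pairs.add((min(a, b), max(a, b)))
    all_same_gen = {
        (a, b)
        for a, b in combinations(sorted(scores), 2)
        if gen[a] == gen[b]
    }
    mock_pool = sorted(all_same_gen - contact_pairs)
    contact_pairs = sorted(contact_pairs)

    def _points(pairs):
        xs, ys = [], []
        for a, b in pairs:
            common = sorted(set(scores[a]) & set(scores[b]))
            xs.extend(scores[a][p] for p in common)
            ys.extend(scores[b][p] for p in common)
        return np.array(xs), np.array(ys)

    rng = np.random.default_rng(seed)
    n_mock = min(len(contact_pairs), len(mock_pool))
    mock = [mock_pool[i] for i in rng.choice(len(mock_pool), size=n_mock, replace=False)]
    x_c, y_c = _points(contact_pairs)
    x_m, y_m = _points(mock)
    r_contact = float(stats.pearsonr(x_c, y_c).statistic) if len(x_c) > 2 else np.nan
    r_mock = float(stats.pearsonr(x_m, y_m).statistic) if len(x_m) > 2 else np.nan
    return {
        "r_contact": r_contact,
        "r_mock": r_mock,
        "n_contact_pairs": len(contact_pairs),
        "n_mock_pairs": n_mock,
        "reduced_mock_pool": n_mock < len(contact_pairs),
    }
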