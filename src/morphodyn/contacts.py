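"""Cross-embryo reproducibility of cell-cell contacts.

A contact's reproducibility is the fraction of embryos forming it among the
embryos where both cells completed their cycles. Together with the integral
contact area (per-frame areas summed over the cell cycle) this separates
large, perfectly reproducible contacts from brief variable ones, which are
further classified as timing-variable (explainable by shifting division
times a few frames) or arrangement-variable. The neighbor-reproducibility
score compares one cell's filtered neighbor sets between two embryos over
normalized time (Jaccard overlap, maximum over the cycle).

Embryo records passed to these functions need ``tree`` (LineageTree),
``contacts`` (dict pair -> ContactTrack) and ``tracks`` (dict name ->
FeatureTrack) attributes; the synthetic generator's ``SyntheticEmbryo`` and
the IO module's loaded records both qualify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from morphodyn.morphometry import ContactTrack

CATEGORIES = ("timing-variable", "arrangement-variable", "perfectly-reproducible")


@dataclass
class ContactSummary:
    """Cohort-level summary of one cell-name pair's contact."""

    pair: tuple[str, str]
    reproducibility: float
    mean_integral_area: float
    n_cocomplete: int
    n_contact: int
    category: str
    false_detection_candidate: bool = False


@dataclass
class NeighborScore:
    """Neighbor-set reproducibility of one cell between two embryos."""

    cell: str
    embryo_a: str
    embryo_b: str
    score: float


def _cocomplete(pair: tuple[str, str], embryo) -> bool:
    a, b = pair
    t = embryo.tree
    return a in t and b in t and t[a].complete and t[b].complete


def _has_contact(pair: tuple[str, str], embryo) -> bool:
    key = (min(pair), max(pair))
    ct = embryo.contacts.get(key)
    return ct is not None and bool(np.any(ct.areas > 0))


def contact_reproducibility(pair: tuple[str, str], embryos: list) -> float | None:
    """Fraction of co-complete embryos where the pair is in contact.

    The denominator is restricted to embryos where both cells completed
    their cell cycles; ``None`` when that denominator is empty.
    """
    denom = [e for e in embryos if _cocomplete(pair, e)]
    if not denom:
        return None
    num = sum(1 for e in denom if _has_contact(pair, e))
    return num / len(denom)


def integral_area(track: ContactTrack) -> float:
    """Integral contact area in µm²: plain sum of per-frame areas."""
    return track.integral_area


def _relative_contact_window(pair: tuple[str, str], embryo) -> tuple[int, int] | None:
    """Contact window in frames relative to the pair's co-alive start."""
    key = (min(pair), max(pair))
    ct = embryo.contacts.get(key)
    if ct is None or not np.any(ct.areas > 0):
        return None
    start = max(embryo.tree[pair[0]].birth_frame, embryo.tree[pair[1]].birth_frame)
    return ct.first_frame - start, ct.last_frame - start


def _lifespan(embryo, name: str) -> tuple[int, int]:
    c = embryo.tree[name]
    return c.birth_frame, embryo.tree.last_frame(name)


def detect_timing_variability(pair: tuple[str, str], embryos: list, max_shift: int = 2) -> bool:
    """Whether a variable contact's losses are attributable to division timing.

    For every co-complete embryo lacking the contact, one cell's lifespan is
    virtually shifted by up to ``max_shift`` frames in either direction; the
    loss is timing-attributable if some shift creates co-alive overlap that
    reaches the contact window observed (relative to co-alive start) in the
    embryos that do form the contact. The pair is flagged timing-variable
    only if every non-contact embryo is explainable this way.
    """
    windows = [w for e in embryos if _cocomplete(pair, e) and (w := _relative_contact_window(pair, e))]
    if not windows:
        return False
    win_lo = min(w[0] for w in windows)
    non_contact = [e for e in embryos if _cocomplete(pair, e) and not _has_contact(pair, e)]
    if not non_contact:
        return False
    a, b = pair
    for e in non_contact:
        lo_a, hi_a = _lifespan(e, a)
        lo_b, hi_b = _lifespan(e, b)

        def _reaches(shift: int) -> bool:
            co_lo = max(lo_a + shift, lo_b)
            co_hi = min(hi_a + shift, hi_b)
            return co_hi >= co_lo and co_hi - co_lo >= win_lo

        if _reaches(0):
            # the cells already coexist through the contact window and still
            # do not touch: timing cannot explain this embryo's loss
            return False
        if not any(_reaches(s) for s in range(-max_shift, max_shift + 1) if s != 0):
            return False
    return True


def summarize_contacts(
    embryos: list,
    max_shift: int = 2,
    false_area_floor: float = 1.0,
) -> list[ContactSummary]:
    """Reproducibility, integral area and category per cell-name pair.

    Categories: perfectly-reproducible (reproducibility 1), timing-variable,
    arrangement-variable. Contacts whose mean integral area is below
    ``false_area_floor`` µm² and whose duration is a single frame in every
    embryo are additionally flagged as false-detection candidates (reported,
    never deleted).
    """
    pairs = sorted({p for e in embryos for p in e.contacts})
    out = []
    for pair in pairs:
        rep = contact_reproducibility(pair, embryos)
        if rep is None:
            continue
        denom = [e for e in embryos if _cocomplete(pair, e)]
        with_c = [e for e in denom if _has_contact(pair, e)]
        areas = [e.contacts[pair].integral_area for e in with_c]
        mean_area = float(np.mean(areas)) if areas else 0.0
        if rep >= 1.0:
            cat = "perfectly-reproducible"
        elif detect_timing_variability(pair, embryos, max_shift=max_shift):
            cat = "timing-variable"
        else:
            cat = "arrangement-variable"
        single_frame = all(e.contacts[pair].contact_frames <= 1 for e in with_c) if with_c else False
        out.append(
            ContactSummary(
                pair=pair,
                reproducibility=rep,
                mean_integral_area=mean_area,
                n_cocomplete=len(denom),
                n_contact=len(with_c),
                category=cat,
                false_detection_candidate=bool(single_frame and mean_area < false_area_floor),
            )
        )
    return out


def categorize_contacts(
    summaries: list[ContactSummary], area_threshold: float = 1000.0
) -> dict:
    """Category shares by count and by integral area, plus the biphasic split.

    Shares each sum to 100%. The biphasic split reports, above and below
    ``area_threshold`` µm² of integral area, the fraction of contacts that
    are perfectly reproducible.
    """
    if not summaries:
        raise ValueError("no contact summaries")
    total_n = len(summaries)
    total_area = sum(s.mean_integral_area for s in summaries)
    by_count = {}
    by_area = {}
    for cat in CATEGORIES:
        sel = [s for s in summaries if s.category == cat]
        by_count[cat] = 100.0 * len(sel) / total_n
        by_area[cat] = (
            100.0 * sum(s.mean_integral_area for s in sel) / total_area if total_area > 0 else 0.0
        )
    above = [s for s in summaries if s.mean_integral_area > area_threshold]
    below = [s for s in summaries if s.mean_integral_area <= area_threshold]

    def _frac_perfect(group):
        if not group:
            return None
        return sum(1 for s in group if s.category == "perfectly-reproducible") / len(group)

    return {
        "by_count": by_count,
        "by_area": by_area,
        "above_threshold_perfect_fraction": _frac_perfect(above),
        "below_threshold_perfect_fraction": _frac_perfect(below),
        "n_false_detection_candidates": sum(s.false_detection_candidate for s in summaries),
    }


def neighbor_sets_over_cycle(
    cell: str, embryo, n_points: int = 50, area_filter: float = 0.05
) -> list[frozenset]:
    """Filtered neighbor sets of a cell at each normalized-time point.

    At each of ``n_points`` uniformly spaced points of the cell cycle,
    neighbors are the partners whose contact area is at least
    ``area_filter`` times the cell's surface area at that time (noise
    removal).
    """
    tree = embryo.tree
    c = tree[cell]
    if not c.complete:
        raise ValueError(f"cell {cell} did not complete its cycle")
    tr = embryo.tracks[cell]
    first, last = int(tr.frames[0]), int(tr.frames[-1])
    sample_frames = np.round(np.linspace(first, last, n_points)).astype(int)
    partners = [
        (pair, ct) for pair, ct in embryo.contacts.items() if cell in pair
    ]
    sets = []
    for f in sample_frames:
        area_cell = tr.features["surface_area"][f - first]
        s = set()
        for pair, ct in partners:
            other = pair[0] if pair[1] == cell else pair[1]
            idx = np.nonzero(ct.frames == f)[0]
            if idx.size and ct.areas[idx[0]] >= area_filter * area_cell:
                s.add(other)
        sets.append(frozenset(s))
    return sets


def neighbor_reproducibility(
    cell: str, embryo_a, embryo_b, n_points: int = 50,
    area_filter: float = 0.05, denominator: str = "union",
) -> NeighborScore:
    """Neighbor-set reproducibility of one cell between two embryos.

    Per normalized-time point the two filtered neighbor sets are compared as
    |intersection| / |union| (``denominator="min"`` divides by the smaller
    set instead); the score is the maximum of this fraction over the cycle.
    1 means identical neighbor sets at some (and, if constant, every) time;
    0 means no common neighbor throughout.
    """
    sets_a = neighbor_sets_over_cycle(cell, embryo_a, n_points, area_filter)
    sets_b = neighbor_sets_over_cycle(cell, embryo_b, n_points, area_filter)
    best = 0.0
    for sa, sb in zip(sets_a, sets_b):
        if not sa and not sb:
            continue
        inter = len(sa & sb)
        if denominator == "union":
            den = len(sa | sb)
        elif denominator == "min":
            den = min(len(sa), len(sb)) or 1
        else:
            raise ValueError("denominator must be 'union' or 'min'")
        if den:
            best = max(best, inter / den)
    ea = getattr(embryo_a, "embryo_id", "A")
    eb = getattr(embryo_b, "embryo_id", "B")
    return NeighborScore(cell=cell, embryo_a=ea, embryo_b=eb, score=best)


def contact_duration_fraction(track: ContactTrack, cycle_a: int, cycle_b: int) -> float:
    """Contacting period as a fraction of the shorter cell cycle, capped at 1."""
    if cycle_a <= 0 or cycle_b <= 0:
        raise ValueError("cell cycle lengths must be positive")
    return min(1.0, track.contact_frames / min(cycle_a, cycle_b))


def conservation_summary(
    scores: list[NeighborScore],
    generations: dict[str, int],
    thresholds: tuple[float, ...] = (0.5, 0.8),
) -> dict[int, dict[float, float]]:
    """Percentage of cells whose neighbor score reaches each threshold, per generation.

    A cell's score is its mean over embryo pairs; generations with no scored
    cells are absent from the result.
    """
    per_cell: dict[str, list[float]] = {}
    for s in scores:
        per_cell.setdefault(s.cell, []).append(s.score)
    cell_scores = {c: float(np.mean(v)) for c, v in per_cell.items()}
    out: dict[int, dict[float, float]] = {}
    gens = sorted({generations[c] for c in cell_scores})
    for g in gens:
        cells = [c for c in cell_scores if generations[c] == g]
        out[g] = {
            th: 100.0 * sum(1 for c in cells if cell_scores[c] >= th) / len(cells)
            for th in thresholds
        }
    return out
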