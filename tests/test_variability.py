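"""Variability metrics, integral RMSD, distinguishability, group analyses."""

from itertools import combinations

import numpy as np
import pytest

from morphodyn import synthetic as sy
from morphodyn.morphometry import FeatureTrack
from morphodyn.normalize import normalize_cohort_tracks
from morphodyn.variability import (
    contact_dependence,
    distance_matrix,
    distinguishability,
    integral_rmsd,
    mv,
    pairwise_scores,
    variability_by_group,
    variability_over_time,
    variability_v,
)


def _track(values: dict, cell="ABa"):
    n = len(next(iter(values.values())))
    return FeatureTrack(cell, np.arange(n), np.arange(n) * 0.5,
                        {k: np.asarray(v, float) for k, v in values.items()})


class TestVariabilityMetric:
    def test_zero_on_identical_dynamics(self, rng):
        f = rng.uniform(0.5, 2.0, size=50)
        assert variability_v(f, f.copy()) == 0.0

    def test_constant_one_vs_three(self):
        assert variability_v(np.ones(50), np.full(50, 3.0)) == pytest.approx(0.5)

    def test_approaches_one_for_very_different_dynamics(self):
        assert variability_v(np.ones(10), np.full(10, 1e9)) > 0.999

    def test_bounded_and_symmetric(self, rng):
        for _ in range(20):
            a = rng.uniform(0.1, 10, size=30)
            b = rng.uniform(0.1, 10, size=30)
            v = variability_v(a, b)
            assert 0.0 <= v < 1.0
            assert v == variability_v(b, a)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            variability_v(np.zeros(5), np.ones(5))
        with pytest.raises(ValueError):
            variability_v(np.ones(5), np.ones(6))


class TestMv:
    def test_equal_volumes_zero(self):
        assert mv(100.0, 100.0) == 0.0

    def test_three_to_one(self):
        assert mv(3.0, 1.0) == pytest.approx(0.5)

    def test_limit_toward_one(self):
        assert mv(1.0, 1e12) == pytest.approx(1.0, abs=1e-6)

    def test_positive_volumes_required(self):
        with pytest.raises(ValueError):
            mv(0.0, 1.0)


class TestIntegralRmsd:
    def test_identical_tracks_zero(self):
        a = _track({"volume": np.linspace(10, 20, 50)})
        assert integral_rmsd(a, a, features=("volume",)) == 0.0

    def test_constant_two_vs_four(self):
        a = _track({"volume": np.full(50, 2.0)})
        b = _track({"volume": np.full(50, 4.0)})
        assert integral_rmsd(a, b, features=("volume",)) == pytest.approx(2 / 3)

    def test_common_rescaling_invariance(self, rng):
        va = rng.uniform(1, 2, 50)
        vb = rng.uniform(1, 2, 50)
        a, b = _track({"volume": va}), _track({"volume": vb})
        a2, b2 = _track({"volume": 7.3 * va}), _track({"volume": 7.3 * vb})
        assert integral_rmsd(a, b, ("volume",)) == pytest.approx(
            integral_rmsd(a2, b2, ("volume",)), rel=1e-12
        )

    def test_missing_feature_signalled(self):
        a = _track({"volume": np.ones(10)})
        b = _track({"sphericity": np.ones(10)})
        with pytest.raises(KeyError):
            integral_rmsd(a, b, features=("volume",))

    def test_sums_over_features(self):
        a = _track({"volume": np.full(10, 2.0), "sphericity": np.full(10, 0.8)})
        b = _track({"volume": np.full(10, 4.0), "sphericity": np.full(10, 0.8)})
        both = integral_rmsd(a, b, features=("volume", "sphericity"))
        assert both == pytest.approx(2 / 3)  # sphericity contributes zero


class TestDistinguishability:
    def test_well_separated_types_fully_distinguished(self, rng):
        per = {}
        for e in range(4):
            per[f"e{e}"] = {}
            for i, (name, base) in enumerate([("ABa", 100.0), ("ABp", 200.0), ("EMS", 400.0)]):
                noise = 1 + rng.normal(0, 0.01, size=50)
                per[f"e{e}"][name] = _track({"volume": base * noise}, cell=name)
        res = distinguishability(per, features=("volume",))
        assert res.mean_fraction == 1.0
        assert res.fraction_types_above == 1.0

    def test_two_identical_embryos_distinguish_via_zero_intra(self):
        per = {
            "e0": {"ABa": _track({"volume": np.full(50, 100.0)}),
                   "ABp": _track({"volume": np.full(50, 150.0)}, cell="ABp")},
            "e1": {"ABa": _track({"volume": np.full(50, 100.0)}),
                   "ABp": _track({"volume": np.full(50, 150.0)}, cell="ABp")},
        }
        res = distinguishability(per, features=("volume",))
        assert res.per_type_fraction["ABa"] == 1.0

    def test_singletons_excluded(self):
        per = {
            "e0": {"ABa": _track({"volume": np.full(50, 100.0)})},
            "e1": {"ABa": _track({"volume": np.full(50, 101.0)}),
                   "P4": _track({"volume": np.full(50, 10.0)}, cell="P4")},
        }
        res = distinguishability(per, features=("volume",))
        assert res.excluded_singletons == ["P4"]


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, small_cohort):
        per = {e.embryo_id: e.tracks for e in small_cohort[:2]}
        norm, _ = normalize_cohort_tracks(
            per, {e.embryo_id: 30000.0 for e in small_cohort[:2]}
        )
        # trim to a handful of cells for speed
        norm = {e: {c: t for c, t in list(cells.items())[:5]} for e, cells in norm.items()}
        mat, labels, violations = distance_matrix(norm)
        np.testing.assert_array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0)
        assert len(labels) == mat.shape[0]
        assert violations >= 0


@pytest.fixture(scope="module")
def lineage_noise_cohort():
    cfg = sy.CohortConfig(n_embryos=16, lineage_noise={"AB": 3.0})
    return sy.simulate_cohort(cfg, seed=31)


def _normalized(cohort):
    per = {e.embryo_id: e.tracks for e in cohort}
    vols = {e.embryo_id: e.spec.eggshell_volume * e.truth.size_factor for e in cohort}
    norm, _ = normalize_cohort_tracks(per, vols)
    return norm


class TestGroupedVariability:
    def test_lineage_specific_noise_recovered(self, lineage_noise_cohort):
        norm = _normalized(lineage_noise_cohort)
        scores = pairwise_scores(norm, feature="volume")
        tree = lineage_noise_cohort[0].tree
        gens = {c: tree.generation(c) for c in scores if c in tree}
        res = variability_by_group(scores, gens, grouping="lineage")
        assert res.group_stats["AB"][0] > res.group_stats["P"][0]
        key = ("AB", "P") if ("AB", "P") in res.pairwise_p else ("P", "AB")
        assert res.pairwise_p[key] < 0.01

    def test_group_medians_invariant_under_embryo_relabeling(self, lineage_noise_cohort):
        norm = _normalized(lineage_noise_cohort)
        scores = pairwise_scores(norm, feature="volume")
        tree = lineage_noise_cohort[0].tree
        gens = {c: tree.generation(c) for c in scores if c in tree}
        res1 = variability_by_group(scores, gens, grouping="lineage")
        relabeled = {
            c: {(eb + "_x", ea + "_x"): v for (ea, eb), v in d.items()}
            for c, d in scores.items()
        }
        res2 = variability_by_group(relabeled, gens, grouping="lineage")
        for g in res1.group_stats:
            assert res1.group_stats[g][0] == pytest.approx(res2.group_stats[g][0])

    def test_generation_increasing_noise_gives_monotone_medians(self):
        cfg = sy.CohortConfig(n_embryos=12, generation_noise_slope=0.8)
        cohort = sy.simulate_cohort(cfg, seed=41)
        norm = _normalized(cohort)
        scores = pairwise_scores(norm, feature="volume")
        tree = cohort[0].tree
        gens = {c: tree.generation(c) for c in scores if c in tree}
        res = variability_by_group(scores, gens, grouping="generation")
        meds = [res.group_stats[g][0] for g in sorted(res.group_stats) if g >= 2]
        assert all(a < b for a, b in zip(meds, meds[1:]))


class TestTimeAndContactDependence:
    def test_variability_increases_along_cycle(self):
        cfg = sy.CohortConfig(n_embryos=12, time_noise_slope=2.0, track_offset_sd=0.005)
        cohort = sy.simulate_cohort(cfg, seed=51)
        norm = _normalized(cohort)
        res = variability_over_time(norm, feature="volume")
        assert res["significant"]
        assert res["final"].mean() > res["initial"].mean()

    def test_contact_coupling_raises_contact_correlation(self):
        cfg = sy.CohortConfig(n_embryos=16, contact_coupling=0.9)
        cohort = sy.simulate_cohort(cfg, seed=61)
        norm = _normalized(cohort)
        scores = pairwise_scores(norm, feature="volume")
        res = contact_dependence(scores, cohort, seed=0)
        assert res["r_contact"] > res["r_mock"]
        assert res["r_contact"] > 0.15

    def test_independent_noise_gives_similar_small_correlations(self):
        cfg = sy.CohortConfig(n_embryos=16, contact_coupling=0.0)
        cohort = sy.simulate_cohort(cfg, seed=71)
        norm = _normalized(cohort)
        scores = pairwise_scores(norm, feature="volume")
        res = contact_dependence(scores, cohort, seed=0)
        assert abs(res["r_contact"]) < 0.25
        assert abs(res["r_mock"]) < 0.25


class TestBruteForceAgreement:
    def test_full_pipeline_matches_independent_recomputation(self, small_cohort):
        cohort = small_cohort[:4]
        norm = _normalized(cohort)
        scores = pairwise_scores(norm, feature="volume")
        embs = sorted(norm)
        for cell in list(scores)[:6]:
            for ea, eb in combinations([e for e in embs if cell in norm[e]], 2):
                fa = norm[ea][cell].features["volume"]
                fb = norm[eb][cell].features["volume"]
                manual = sum(
                    abs(x - y) / (x + y) for x, y in zip(fa, fb)
                ) / len(fa)
                assert scores[cell][(ea, eb)] == pytest.approx(manual, abs=1e-12)
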