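"""Stem-crown alignment: offset correction, allometry, normalized cost,
exact assignment, and parameter recovery on synthetic plots."""

from __future__ import annotations

import math

import numpy as np
import pytest

from crownpipe.alignment import (
    AlignmentNormalization,
    AllometricModel,
    alignment_accuracy,
    cluster_stems_to_plots,
    compute_normalization,
    correct_offset,
    diameter_from_area,
    fit_allometry,
    optimal_pairing,
    pair_cost,
)
from crownpipe.io_core import CrownRecord, StemRecord
from crownpipe.synthetic_scene import generate_scene

from conftest import light_scene_config
from oracles import min_cost_matching_by_enumeration


def stem(sid, x, y, h=10.0, d=30.0, **kw):
    return StemRecord(sid, x, y, h, d, **kw)


def crown(cid, x, y, area=20.0, plot="P1"):
    return CrownRecord(cid, x, y, area, plot)


class TestClusterStems:
    def test_dominant_separation(self):
        crowns = [crown("A1", 0, 0, plot="A"), crown("B1", 200, 0, plot="B")]
        stems = [stem("S1", 1, 0)]
        assert cluster_stems_to_plots(stems, crowns)[0].plot_id == "A"

    def test_tie_within_plot_is_irrelevant(self):
        crowns = [crown("A1", -5, 0, plot="A"), crown("A2", 5, 0, plot="A")]
        assert cluster_stems_to_plots([stem("S1", 0, 0)], crowns)[0].plot_id == "A"

    def test_brute_force_nearest_neighbour(self):
        rng = np.random.default_rng(0)
        crowns = [
            crown(f"A{i}", *rng.uniform(0, 40, 2), plot="A") for i in range(5)
        ] + [
            crown(f"B{i}", *(rng.uniform(0, 40, 2) + 300), plot="B") for i in range(5)
        ]
        stems = [stem(f"S{i}", *(rng.uniform(0, 40, 2) + 300 - 10)) for i in range(10)]
        out = cluster_stems_to_plots(stems, crowns)
        for s_in, s_out in zip(stems, out):
            dists = {
                c.crown_id: math.hypot(c.x_pos - s_in.x_pos, c.y_pos - s_in.y_pos)
                for c in crowns
            }
            nearest = min(sorted(dists), key=lambda k: (dists[k], k))
            expected_plot = next(c.plot_id for c in crowns if c.crown_id == nearest)
            assert s_out.plot_id == expected_plot

    def test_empty_crowns_rejected(self):
        with pytest.raises(ValueError):
            cluster_stems_to_plots([stem("S1", 0, 0)], [])


class TestCorrectOffset:
    def test_zero_shift(self):
        stems = [stem("S1", 0, 0), stem("S2", 2, 2)]
        crowns = [crown("C1", 0, 2), crown("C2", 2, 0)]
        out = correct_offset(stems, crowns)
        assert [(s.x_pos, s.y_pos) for s in out] == [(0, 0), (2, 2)]

    def test_constant_offset_recovered(self):
        truth = [(3.0, 4.0), (10.0, 2.0), (7.0, 9.0)]
        crowns = [crown(f"C{i}", x, y) for i, (x, y) in enumerate(truth)]
        stems = [
            stem(f"S{i}", x + 3.2, y - 1.7) for i, (x, y) in enumerate(truth)
        ]
        out = correct_offset(stems, crowns)
        for s, (x, y) in zip(out, truth):
            assert s.x_pos == pytest.approx(x, abs=1e-9)
            assert s.y_pos == pytest.approx(y, abs=1e-9)

    def test_single_pair_moves_onto_crown(self):
        out = correct_offset([stem("S1", 5, 5)], [crown("C1", 8, 1)])
        assert (out[0].x_pos, out[0].y_pos) == (8, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            correct_offset([], [crown("C1", 0, 0)])


class TestDiameterFromArea:
    @pytest.mark.parametrize(
        "area, expected",
        [(math.pi, 2.0), (0.0, 0.0), (100.0, 2.0 * math.sqrt(100.0 / math.pi))],
    )
    def test_values(self, area, expected):
        assert diameter_from_area(area) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            diameter_from_area(-1.0)


class TestFitAllometry:
    def test_noiseless_line(self):
        pts = [(x, 2.0 * x + 1.0) for x in (1.0, 2.0, 5.0, 9.0)]
        model = fit_allometry(pts)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)
        assert model.r_squared == pytest.approx(1.0)

    def test_flat_response(self):
        model = fit_allometry([(1.0, 3.0), (2.0, 3.0), (5.0, 3.0)])
        assert model.slope == pytest.approx(0.0)
        assert model.r_squared == pytest.approx(0.0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_allometry([(1.0, 1.0), (2.0, 2.0)])
        with pytest.raises(ValueError, match="constant"):
            fit_allometry([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])

    def test_slope_recovery_within_analytic_error(self):
        """Simulating D_crown = 0.114 D_stem + 0.882 + N(0,1): the OLS slope
        lands within 3 analytic standard errors of the simulated truth."""
        rng = np.random.default_rng(42)
        x = rng.uniform(5.0, 60.0, 200)
        y = 0.114 * x + 0.882 + rng.normal(0.0, 1.0, 200)
        model = fit_allometry(list(zip(x, y)))
        se = 1.0 / math.sqrt(((x - x.mean()) ** 2).sum())
        assert abs(model.slope - 0.114) <= 3.0 * se
        assert 3.0 * se < 0.02  # the fixture's x spread keeps 3 sigma tight

    def test_predict_uses_declared_predictor(self):
        model = AllometricModel(slope=0.127, intercept=2.152, r_squared=0.092,
                                predictor="stem_height_m")
        s = stem("S1", 0, 0, h=10.0, d=99.0)
        assert model.predict(s) == pytest.approx(0.127 * 10.0 + 2.152)


class TestNormalization:
    def test_equal_residuals(self):
        stems_ = [stem("S1", 2, 0), stem("S2", -2, 0)]
        crowns_ = [crown("C1", 0, 2), crown("C2", 0, -2)]
        model = AllometricModel(slope=0.0, intercept=diameter_from_area(20.0) - 2.0,
                                r_squared=0.0)
        norm = compute_normalization(list(zip(stems_, crowns_)), model)
        assert norm.d_rms == pytest.approx(2.0)
        assert norm.x_rms == pytest.approx(2.0)
        assert norm.y_rms == pytest.approx(2.0)

    def test_rms_hand_value(self):
        # coordinate residuals {3, 4} -> sqrt((9+16)/2)
        stems_ = [stem("S1", 0, 3), stem("S2", 0, -4)]
        crowns_ = [crown("C1", 3, 0), crown("C2", 4, 0)]
        model = AllometricModel(slope=0.0, intercept=diameter_from_area(20.0) - 5.0,
                                r_squared=0.0)
        norm = compute_normalization(list(zip(stems_, crowns_)), model)
        assert norm.x_rms == pytest.approx(math.sqrt(12.5))
        assert norm.y_rms == pytest.approx(math.sqrt(12.5))

    def test_degenerate_rms_instructs_floor(self):
        stems_ = [stem("S1", 0, 0), stem("S2", 1, 1)]
        crowns_ = [crown("C1", 0, 0), crown("C2", 1, 1)]
        model = AllometricModel(slope=0.0, intercept=0.0, r_squared=0.0)
        with pytest.raises(ValueError, match="floor"):
            compute_normalization(list(zip(stems_, crowns_)), model)


class TestPairCost:
    def unit_norm(self):
        return AlignmentNormalization(d_rms=1.0, x_rms=1.0, y_rms=1.0)

    def test_perfect_pair(self):
        model = AllometricModel(slope=0.0, intercept=diameter_from_area(20.0),
                                r_squared=0.0)
        assert pair_cost(stem("S", 3, 4), crown("C", 3, 4), model, self.unit_norm()) == 0.0

    def test_unit_residuals_cost_three(self):
        model = AllometricModel(slope=0.0, intercept=diameter_from_area(20.0) - 1.0,
                                r_squared=0.0)
        c = pair_cost(stem("S", 0, 0), crown("C", 1, 1), model, self.unit_norm())
        assert c == pytest.approx(3.0, abs=1e-12)

    def test_hand_value(self):
        # D residual 2 with d_rms 2, X residual 3 with x_rms 3, Y residual 0
        model = AllometricModel(slope=0.0, intercept=diameter_from_area(20.0) - 2.0,
                                r_squared=0.0)
        norm = AlignmentNormalization(d_rms=2.0, x_rms=3.0, y_rms=1.0)
        c = pair_cost(stem("S", 0, 5), crown("C", 3, 5), model, norm)
        assert c == pytest.approx(2.0, abs=1e-12)

    def test_position_only_drops_diameter_term(self):
        model = AllometricModel(slope=0.0, intercept=0.0, r_squared=0.0)
        c = pair_cost(stem("S", 0, 0), crown("C", 1, 0), model, self.unit_norm(),
                      position_only=True)
        assert c == pytest.approx(1.0)


class TestOptimalPairing:
    def setup_model(self):
        model = AllometricModel(slope=0.05, intercept=1.0, r_squared=0.5)
        norm = AlignmentNormalization(d_rms=1.0, x_rms=2.0, y_rms=2.0)
        return model, norm

    def test_single_pair(self):
        model, norm = self.setup_model()
        res = optimal_pairing([stem("S1", 0, 0)], [crown("C1", 1, 1)], model, norm)
        assert res.pairs == [("S1", "C1")]
        assert res.total_cost == pytest.approx(res.per_pair_cost[("S1", "C1")])

    def test_obvious_diagonal(self):
        model, norm = self.setup_model()
        stems_ = [stem("S1", 0, 0), stem("S2", 100, 0)]
        crowns_ = [crown("C1", 0, 0), crown("C2", 100, 0)]
        res = optimal_pairing(stems_, crowns_, model, norm)
        assert set(res.pairs) == {("S1", "C1"), ("S2", "C2")}

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_enumeration(self, n):
        """scipy's assignment equals exhaustive permutation enumeration."""
        model, norm = self.setup_model()
        for seed in range(34):
            rng = np.random.default_rng(1000 * n + seed)
            stems_ = [
                stem(f"S{i}", *rng.uniform(0, 30, 2), d=rng.uniform(10, 60))
                for i in range(n)
            ]
            crowns_ = [
                crown(f"C{j}", *rng.uniform(0, 30, 2), area=rng.uniform(5, 80))
                for j in range(n)
            ]
            res = optimal_pairing(stems_, crowns_, model, norm)
            cost = np.array(
                [[pair_cost(s, c, model, norm) for c in crowns_] for s in stems_]
            )
            assert res.total_cost == pytest.approx(
                min_cost_matching_by_enumeration(cost), abs=1e-9
            )

    def test_unequal_counts_reports_surplus(self):
        model, norm = self.setup_model()
        stems_ = [stem("S1", 0, 0), stem("S2", 50, 0), stem("S3", 100, 0)]
        crowns_ = [crown("C1", 0, 0), crown("C2", 50, 0)]
        res = optimal_pairing(stems_, crowns_, model, norm)
        assert len(res.pairs) == 2
        assert res.unmatched_stems == ["S3"]
        assert res.unmatched_crowns == []

    def test_translation_invariance(self):
        model, norm = self.setup_model()
        rng = np.random.default_rng(5)
        stems_ = [stem(f"S{i}", *rng.uniform(0, 30, 2)) for i in range(5)]
        crowns_ = [crown(f"C{j}", *rng.uniform(0, 30, 2)) for j in range(5)]
        base = optimal_pairing(stems_, crowns_, model, norm)
        shifted = optimal_pairing(
            [stem(s.stem_id, s.x_pos + 123.4, s.y_pos - 56.7) for s in stems_],
            [crown(c.crown_id, c.x_pos + 123.4, c.y_pos - 56.7) for c in crowns_],
            model, norm,
        )
        assert base.pairs == shifted.pairs
        assert base.total_cost == pytest.approx(shifted.total_cost, abs=1e-9)


class TestAccuracy:
    def make_result(self, pairs):
        return type(
            "R", (), {"pairs": pairs}
        )()

    def test_counting(self):
        from crownpipe.alignment import AlignmentResult

        res = AlignmentResult(
            pairs=[("S1", "C1"), ("S2", "C3"), ("S3", "C2"), ("S4", "C4")],
            total_cost=0.0,
            per_pair_cost={},
        )
        truth = [("S1", "C1"), ("S2", "C2"), ("S3", "C3"), ("S4", "C4")]
        assert alignment_accuracy(res, truth) == 0.5
        assert alignment_accuracy(res, res.pairs) == 1.0
        assert alignment_accuracy(res, [("S9", "C9")]) == 0.0

    def test_empty_truth_rejected(self):
        from crownpipe.alignment import AlignmentResult

        res = AlignmentResult(pairs=[], total_cost=0.0, per_pair_cost={})
        with pytest.raises(ValueError):
            alignment_accuracy(res, [])


def _align_scene(scene, position_only=False):
    """Fit allometry + normalizers on the scene's true pairings, then match."""
    stems = cluster_stems_to_plots(scene.stems, scene.crowns)
    stems = correct_offset(stems, scene.crowns)
    stem_by_id = {s.stem_id: s for s in stems}
    crown_by_id = {c.crown_id: c for c in scene.crowns}
    pairs = [(stem_by_id[s], crown_by_id[c]) for s, c in scene.truth.pairs]
    model = fit_allometry(
        [(s.stem_diameter_cm, diameter_from_area(c.area_m2)) for s, c in pairs]
    )
    norm = compute_normalization(pairs, model)
    return optimal_pairing(stems, scene.crowns, model, norm, position_only)


class TestParameterRecovery:
    def test_recovery_at_one_metre_jitter(self):
        """With 1 m stem jitter and >= 8 m spacing, at least 95% of the
        true stem-crown pairs are recovered across 20 seeded plots."""
        correct = total = 0
        for seed in range(20):
            scene = generate_scene(
                light_scene_config(seed=seed, n_trees=10, min_spacing_m=8.0)
            )
            res = _align_scene(scene)
            correct += sum(1 for p in scene.truth.pairs if p in set(res.pairs))
            total += len(scene.truth.pairs)
        assert correct / total >= 0.95

    def test_accuracy_degrades_with_jitter(self):
        """Accuracy is non-increasing in stem positional jitter (0.5, 2, 8 m),
        up to 0.05 sampling slack."""
        acc = []
        for sigma in (0.5, 2.0, 8.0):
            correct = total = 0
            for seed in range(20):
                scene = generate_scene(
                    light_scene_config(
                        seed=300 + seed, n_trees=10, min_spacing_m=8.0,
                        stem_jitter_sigma_m=sigma,
                    )
                )
                res = _align_scene(scene)
                correct += sum(1 for p in scene.truth.pairs if p in set(res.pairs))
                total += len(scene.truth.pairs)
            acc.append(correct / total)
        assert acc[1] <= acc[0] + 0.05
        assert acc[2] <= acc[1] + 0.05
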