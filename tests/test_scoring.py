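"""Normalization, enrichment, background correction, and MCC calibration."""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from bfgscreen.design import ReferenceSet, canonical_pair
from bfgscreen.scoring import (
    FrequencyMatrix,
    ScoringConfig,
    background_level,
    combine_scores,
    compute_s,
    correct_autoactivation,
    filter_covered_strains,
    infer_nonselective,
    mcc,
    normalize,
    optimize_threshold,
    score_screen,
    select_scoring_model,
)

from conftest import make_counts, make_design


def _freq(f, **kw):
    f = np.asarray(f, dtype=float)
    return FrequencyMatrix(
        axis_baits=[f"b{i}" for i in range(f.shape[0])],
        axis_preys=[f"p{j}" for j in range(f.shape[1])],
        f=f,
        **kw,
    )


class TestNormalize:
    def test_uniform_counts(self, design2x2):
        fm = normalize(make_counts(design2x2, [[2, 2], [2, 2]]), pseudocount=0)
        assert np.allclose(fm.f, 0.25)

    def test_pseudocount_arithmetic(self, design2x2):
        fm = normalize(make_counts(design2x2, [[3, 1], [0, 4]]), pseudocount=1)
        assert np.allclose(fm.f, np.array([[4, 2], [1, 5]]) / 12)

    def test_sums_to_one(self, design2x2):
        rng = np.random.default_rng(0)
        for _ in range(20):
            fm = normalize(make_counts(design2x2, rng.integers(0, 50, (2, 2)) + 1))
            assert abs(fm.f.sum() - 1.0) < 1e-12

    def test_all_zero_degenerate(self, design2x2):
        with pytest.raises(ValueError, match="degenerate"):
            normalize(make_counts(design2x2, np.zeros((2, 2), dtype=int)), 0)


class TestInferNonselective:
    def test_uniform_fixed_point(self):
        fm = _freq(np.full((3, 3), 1 / 9))
        assert np.allclose(infer_nonselective(fm).f, fm.f)

    def test_rank1_fixed_point(self):
        r = np.array([0.5, 0.3, 0.2])
        c = np.array([0.6, 0.4])
        fm = _freq(np.outer(r, c))
        assert np.allclose(infer_nonselective(fm).f, fm.f, atol=1e-12)

    def test_outer_product_example(self):
        fm = _freq([[0.5, 0.1], [0.2, 0.2]])
        assert np.allclose(infer_nonselective(fm).f, [[0.42, 0.18], [0.28, 0.12]])

    def test_marginal_conservation_random(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.random((6, 8))
            fm = _freq(x / x.sum())
            out = infer_nonselective(fm)
            assert np.abs(out.bait_marginals - fm.bait_marginals).max() < 1e-9
            assert np.abs(out.prey_marginals - fm.prey_marginals).max() < 1e-9
            assert abs(out.f.sum() - 1.0) < 1e-9


class TestComputeS:
    def test_identity_when_equal(self):
        fm = _freq(np.full((2, 2), 0.25))
        assert np.allclose(compute_s(fm, fm), 1.0)

    def test_direct_ratio(self):
        f_sel = _freq([[0.2, 0.3], [0.25, 0.25]])
        f_inf = _freq([[0.05, 0.45], [0.25, 0.25]])
        assert compute_s(f_sel, f_inf)[0, 0] == pytest.approx(4.0)

    def test_dropout_floored_finite(self):
        f_sel = _freq([[0.2, 0.8], [0.0, 0.0]])
        f_inf = _freq([[0.0, 1.0], [0.0, 0.0]])
        s = compute_s(f_sel, f_inf, floor=1e-6)
        assert np.isfinite(s).all() and s[0, 0] == pytest.approx(0.2 / 1e-6)

    def test_axis_mismatch_rejected(self):
        a = _freq(np.full((2, 2), 0.25))
        b = FrequencyMatrix(["x", "y"], ["p0", "p1"], np.full((2, 2), 0.25))
        with pytest.raises(ValueError, match="axis"):
            compute_s(a, b)


class TestCorrectAutoactivation:
    def test_constant_row_maps_to_one(self):
        s = np.array([[3.0, 3.0, 3.0, 3.0], [1.0, 1.0, 1.0, 9.0]])
        sp = correct_autoactivation(s, background_quantile=0.75)
        assert np.allclose(sp[0], 1.0)

    def test_quantile_example_row_unchanged(self):
        s = np.array([[1.0, 1.0, 1.0, 1.0, 8.0]])
        sp = correct_autoactivation(s, background_quantile=0.75)
        assert np.allclose(sp, s)  # q0.75 of the row is 1

    def test_zero_background_row_hits_floor(self):
        s = np.array([[0.0, 0.0, 0.0, 0.0, 5.0]])
        sp = correct_autoactivation(s, background_quantile=0.75, floor=1e-3)
        assert sp[0, -1] == pytest.approx(5.0 / 1e-3)


class TestBackgroundLevel:
    def test_constant_row_returns_constant(self):
        s = np.full((1, 10), 2.5)
        w = np.full((1, 10), 0.1)
        assert background_level(s, w)[0] == pytest.approx(2.5)

    def test_signal_excluded_from_background(self):
        # 2% background with two strong interactors in the row
        s = np.full((1, 50), 0.02)
        s[0, :2] = 40.0
        w = np.full((1, 50), 0.02)
        assert background_level(s, w)[0] == pytest.approx(0.02, rel=1e-6)

    def test_autoactivator_row_keeps_own_level(self):
        s = np.full((4, 50), 0.02)
        s[0] = 1.0  # 50x background bait
        w = np.full((4, 50), 0.005)
        bg = background_level(s, w)
        assert bg[0] == pytest.approx(1.0)
        assert np.allclose(bg[1:], 0.02)

    def test_undetected_row_floored_at_median_row_background(self):
        s = np.full((5, 50), 0.02)
        s[0] = 0.0
        w = np.full((5, 50), 0.004)
        bg = background_level(s, w)
        assert bg[0] == pytest.approx(0.02)

    def test_depth_invariant(self):
        rng = np.random.default_rng(3)
        s = rng.random((6, 30))
        w = rng.random((6, 30))
        w /= w.sum()
        assert np.allclose(background_level(s, w), background_level(s, w * 1.0))
        # s is a ratio of frequencies; scaling raw depth leaves it unchanged
        assert np.allclose(background_level(7 * s / 7, w), background_level(s, w))


class TestCombineScores:
    @pytest.mark.parametrize("method", ["mean", "median", "min", "max"])
    def test_identical_replicates(self, method):
        assert combine_scores([3, 3, 3, 3], method) == (3.0, 4)

    def test_mean_example(self):
        assert combine_scores([2, 4], "mean") == (3.0, 2)

    def test_order_statistics(self):
        vals = [1, 2, 3, 10]
        assert combine_scores(vals, "median")[0] == 2.5
        assert combine_scores(vals, "min")[0] == 1
        assert combine_scores(vals, "max")[0] == 10

    def test_missing_excluded_and_empty_unscored(self):
        score, n = combine_scores([np.nan, 2.0, 4.0], "mean")
        assert (score, n) == (3.0, 2)
        score, n = combine_scores([np.nan, np.nan], "mean")
        assert math.isnan(score) and n == 0


class TestMcc:
    def test_perfect_and_degenerate(self):
        assert mcc(5, 0, 0, 5) == 1.0
        assert mcc(0, 0, 5, 5) == 0.0  # zero-denominator convention
        assert mcc(3, 1, 2, 10) == pytest.approx(28 / math.sqrt(2640))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mcc(0, 0, 0, 0)

    def test_against_sklearn_on_random_tables(self):
        """Oracle: sklearn's MCC on label vectors rebuilt from each table."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, fn, tn = rng.integers(0, 30, size=4)
            if tp + fp + fn + tn == 0:
                continue
            y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
            expected = matthews_corrcoef(y_true, y_pred)
            assert mcc(int(tp), int(fp), int(fn), int(tn)) == pytest.approx(
                expected, abs=1e-12
            )


def _exhaustive_best_mcc(scores, reference, universe):
    """Independent oracle: try every distinct-score cutoff directly."""
    ref = {canonical_pair(*p) for p in reference} & universe
    best = -2.0
    for cut in {v for v in scores.values()} | {float("inf")}:
        positives = {p for p, v in scores.items() if v >= cut}
        tp = len(positives & ref)
        fp = len(positives) - tp
        fn = len(ref) - tp
        tn = len(universe) - len(ref) - fp
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        m = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
        best = max(best, m)
    return best


class TestOptimizeThreshold:
    def test_separable_scores_reach_mcc_one(self):
        scores = {("A", "X"): 9.0, ("B", "Y"): 8.0, ("C", "Z"): 1.0, ("D", "W"): 0.5}
        ref = ReferenceSet(pairs={("A", "X"), ("B", "Y")})
        res, _ = optimize_threshold(scores, ref, set(scores))
        assert res.mcc == 1.0 and res.rank_cutoff == 2

    def test_all_tied_scores_single_cutoff(self):
        scores = {("A", "X"): 1.0, ("B", "Y"): 1.0, ("C", "Z"): 1.0}
        ref = ReferenceSet(pairs={("A", "X")})
        res, profile = optimize_threshold(scores, ref, set(scores))
        assert set(profile.rank_cutoff) == {0, 3}  # all or none

    def test_empty_reference_overlap_rejected(self):
        scores = {("A", "X"): 1.0}
        ref = ReferenceSet(pairs={("Q", "R")})
        with pytest.raises(ValueError, match="overlap"):
            optimize_threshold(scores, ref, set(scores))

    def test_unscored_reference_pair_counts_as_miss(self):
        scores = {("A", "X"): 5.0, ("B", "Y"): float("nan")}
        ref = ReferenceSet(pairs={("A", "X"), ("B", "Y")})
        res, _ = optimize_threshold(scores, ref, set(scores))
        assert res.fn >= 1

    def test_matches_exhaustive_scan_with_ties(self):
        """Oracle: brute-force cutoff scan on random fixtures, ties included."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            pairs = [(f"L{i}", f"R{i}") for i in range(n)]
            # small integer scores force plenty of ties
            scores = {p: float(rng.integers(0, 6)) for p in pairs}
            ref_pairs = {p for p in pairs if rng.random() < 0.4}
            if not ref_pairs:
                ref_pairs = {pairs[0]}
            ref = ReferenceSet(pairs=ref_pairs)
            universe = {canonical_pair(*p) for p in pairs}
            res, _ = optimize_threshold(scores, ref, universe)
            assert res.mcc == pytest.approx(
                _exhaustive_best_mcc(
                    {canonical_pair(*p): v for p, v in scores.items()}, ref_pairs, universe
                ),
                abs=1e-12,
            )


class TestFilterCoveredStrains:
    def test_zero_threshold_masks_nothing(self):
        fm = _freq(np.full((3, 3), 1 / 9))
        bait_keep, prey_keep = filter_covered_strains(fm, min_marginal=0.0)
        assert bait_keep.all() and prey_keep.all()

    def test_absent_strain_masked(self):
        f = np.array([[0.5, 0.5, 0.0], [0.0, 0.0, 0.0]])
        fm = _freq(f / f.sum())
        bait_keep, prey_keep = filter_covered_strains(fm, min_marginal=1e-7)
        assert bait_keep.tolist() == [True, False]
        assert prey_keep.tolist() == [True, True, False]

    def test_all_masked_degenerate(self):
        fm = _freq(np.full((2, 2), 0.25))
        with pytest.raises(ValueError):
            filter_covered_strains(fm, min_marginal=2.0)


class TestScreenPipeline:
    def _counts(self, seed=0):
        from bfgscreen.simulator import SimulationParams, simulate_screen

        params = SimulationParams(
            n_bait_orfs=12, n_prey_orfs=12, mating_cells=200_000,
            plated_cells=500_000, extraction_molecules=100_000,
            pcr_template_molecules=50_000, read_depth=100_000,
            n_replicates=2, seed=seed,
        )
        return simulate_screen(params)

    def test_depth_invariance_of_scores(self):
        counts, ledger = self._counts(3)
        cfg = ScoringConfig(pseudocount=0.0)
        base = score_screen(ledger.design, counts, cfg).pair_scores
        scaled = dict(counts)
        key = ("-His", "BC1BC1", "r1")
        cm = counts[key]
        scaled[key] = make_counts(
            ledger.design, cm.counts * 10, cm.condition, cm.fusion_type, cm.replicate
        )
        rescored = score_screen(ledger.design, scaled, cfg).pair_scores
        assert np.allclose(
            base["score"].to_numpy(), rescored["score"].to_numpy(), equal_nan=True
        )

    def test_strain_permutation_equivariance(self):
        from bfgscreen.design import CountMatrix, ScreenDesign

        counts, ledger = self._counts(4)
        design = ledger.design
        rng = np.random.default_rng(0)
        bperm = rng.permutation(len(design.baits))
        pperm = rng.permutation(len(design.preys))
        design_p = ScreenDesign(
            baits=[design.baits[i] for i in bperm],
            preys=[design.preys[j] for j in pperm],
            conditions=design.conditions,
            replicates=design.replicates,
        )
        counts_p = {
            k: CountMatrix(
                axis_baits=design_p.bait_ids,
                axis_preys=design_p.prey_ids,
                counts=cm.counts[np.ix_(bperm, pperm)],
                condition=cm.condition,
                fusion_type=cm.fusion_type,
                replicate=cm.replicate,
            )
            for k, cm in counts.items()
        }
        a = score_screen(design, counts).pair_scores
        b = score_screen(design_p, counts_p).pair_scores
        key = ["bait_orf", "prey_orf"]
        a = a.sort_values(key).reset_index(drop=True)
        b = b.sort_values(key).reset_index(drop=True)
        assert np.allclose(a["score"], b["score"], equal_nan=True, rtol=1e-9)

    def test_select_scoring_model_prefers_selective_condition(self):
        """With selection only in condition A, A alone must beat A+B."""
        counts, ledger = self._counts(5)
        doctored = {}
        for (cond, ft, rep), cm in counts.items():
            if cond == "3-AT":
                # replace with a second non-selective sample: no signal here
                src = counts[("+His", ft, rep)]
                doctored[(cond, ft, rep)] = make_counts(
                    ledger.design, src.counts, "3-AT", ft, rep
                )
            else:
                doctored[(cond, ft, rep)] = cm
        ref = ReferenceSet(pairs=ledger.true_interactions)
        best, table = select_scoring_model(ledger.design, doctored, ref)
        assert best.conditions == ("-His",)

    def test_single_candidate_returned(self):
        counts, ledger = self._counts(6)
        ref = ReferenceSet(pairs=ledger.true_interactions)
        cfg = ScoringConfig(conditions=("-His",), combine="median")
        best, table = select_scoring_model(
            ledger.design, counts, ref, candidate_configs=[cfg]
        )
        assert best is cfg and len(table) == 1
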