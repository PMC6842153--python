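"""Synthetic panel generators: determinism, forced archetypes, noise response."""

import numpy as np
import pytest
from scipy import stats

from consensuskit import (
    ARCHETYPES,
    PanelDesign,
    PcmNoiseModel,
    PriorityVector,
    ValidationError,
    build_feedback,
    classify_consensus,
    derive_priorities,
    consistency,
    gen_likert,
    gen_pcms,
    gen_round3,
    gen_votes,
    run_round,
    summarize_item,
)
from consensuskit.simulate import snap_to_saaty


def _design(items, n_panelists=76, seed=0):
    return PanelDesign(items=tuple(items), n_panelists=n_panelists, seed=seed)


def _feedback_for(round2, result):
    fb = []
    for item_id in result.carried_forward:
        own = {pid: int(round2.scores[p, round2.item_ids.index(item_id)])
               for p, pid in enumerate(round2.panelist_ids)}
        fb.extend(build_feedback(item_id, result.summaries[item_id], "equivocal", own))
    return fb


class TestGenVotes:
    def test_strong_include_forces_inclusion(self):
        # all mass on 7-9 forces median >= 7, IQR <= 2, 100% agreement
        for seed in range(10):
            vm = gen_votes(_design([("a", "strong_include")], seed=seed))
            assert classify_consensus(summarize_item(vm.scores[:, 0])) == "include"

    def test_strong_exclude_forces_exclusion(self):
        for seed in range(10):
            vm = gen_votes(_design([("a", "strong_exclude")], seed=seed))
            assert classify_consensus(summarize_item(vm.scores[:, 0])) == "exclude"

    def test_same_seed_is_bit_identical(self):
        d = _design([("a", "equivocal"), ("b", "converging")], seed=123)
        assert np.array_equal(gen_votes(d).scores, gen_votes(d).scores)

    def test_different_seed_differs(self):
        a = gen_votes(_design([("a", "equivocal")], seed=1))
        b = gen_votes(_design([("a", "equivocal")], seed=2))
        assert not np.array_equal(a.scores, b.scores)

    def test_uniform_archetype_rarely_reaches_consensus(self):
        # with uniform votes the agree band is binomial(76, 1/3); the chance
        # of a 75% supermajority is astronomically small, so effectively
        # every simulated panel stays equivocal (spot-check 1000 panels)
        tail = stats.binom.sf(int(0.75 * 76) - 1, 76, 1 / 3)
        assert tail < 1e-12
        equivocal = 0
        for seed in range(1000):
            vm = gen_votes(_design([("a", "equivocal")], seed=seed))
            if classify_consensus(summarize_item(vm.scores[:, 0])) == "equivocal":
                equivocal += 1
        assert equivocal >= 999


class TestGenRound3:
    def test_zero_conformity_keeps_votes(self):
        design = PanelDesign(
            items=(("a", "frozen"),), seed=5,
            archetypes={"frozen": ARCHETYPES["equivocal"].__class__(
                "frozen", ARCHETYPES["equivocal"].round2_distribution, 0.0)},
        )
        r2 = gen_votes(design)
        result = run_round(r2)
        assert result.carried_forward == ("a",)
        r3 = gen_round3(r2, _feedback_for(r2, result), design)
        assert np.array_equal(r3.scores, r2.scores)

    def test_full_conformity_with_high_median_forces_inclusion(self):
        conv = ARCHETYPES["converging"]
        design = PanelDesign(
            items=(("a", "sure"),), seed=11,
            archetypes={"sure": conv.__class__("sure", conv.round2_distribution, 1.0)},
        )
        r2 = gen_votes(design)
        result = run_round(r2)
        if result.carried_forward:  # round-2 median is 7 for this archetype
            assert result.summaries["a"].median >= 7
            r3 = gen_round3(r2, _feedback_for(r2, result), design)
            assert r3.scores.min() >= 7
            assert run_round(r3).decisions["a"].label == "include"

    def test_conformity_inclusion_rate_matches_direct_monte_carlo(self):
        # the engine's round-3 inclusion frequency must match an independent
        # simulation of the same conformity mechanism
        p_conf, n_rep = 0.5, 400
        engine_inc = 0
        oracle_inc = 0
        oracle_rng = np.random.default_rng(998877)
        for seed in range(n_rep):
            design = _design([("a", "converging")], seed=seed)
            r2 = gen_votes(design)
            result = run_round(r2)
            if not result.carried_forward:
                engine_inc += 1  # already included in round 2
                col = r2.scores[:, 0]
            else:
                r3 = gen_round3(r2, _feedback_for(r2, result), design)
                if run_round(r3).decisions["a"].label == "include":
                    engine_inc += 1
                col = r2.scores[:, 0]
            # oracle: redo the move-to-median update with its own RNG
            if classify_consensus(summarize_item(col)) == "include":
                oracle_inc += 1
                continue
            med = int(round(np.percentile(col, 50)))
            new = col.copy()
            outside = (new < 7) | (new > 9)
            move = outside & (oracle_rng.random(new.size) < p_conf)
            new[move] = med
            if classify_consensus(summarize_item(new)) == "include":
                oracle_inc += 1
        rate_engine = engine_inc / n_rep
        rate_oracle = oracle_inc / n_rep
        # binomial sampling error at n=400 is ~2.5 points; allow 3 sigma
        se = np.sqrt(0.25 / n_rep) * 3 * 2
        assert abs(rate_engine - rate_oracle) < max(0.1, se)

    def test_feedback_for_decided_item_rejected(self):
        design = _design([("a", "strong_include"), ("b", "equivocal")], seed=3)
        r2 = gen_votes(design)
        result = run_round(r2)
        from consensuskit import FeedbackPackage
        bogus = [FeedbackPackage(item_id="a", panelist_id="p001", own_score=9,
                                 group_median=9.0, group_iqr=0.0)]
        with pytest.raises(ValidationError, match="equivocal"):
            gen_round3(r2, bogus, design)


class TestGenPcms:
    def _true(self):
        return PriorityVector(item_ids=("a", "b", "c", "d"),
                              weights=np.array([0.4, 0.3, 0.2, 0.1]))

    def test_noiseless_matrices_recover_weights_exactly(self):
        pcms = gen_pcms(PcmNoiseModel(true_weights=self._true(), sigma=0.0, seed=1))
        assert len(pcms) == 10
        for pcm in pcms:
            vec, lam = derive_priorities(pcm)
            assert np.allclose(vec.weights, self._true().weights, atol=1e-8)
            assert consistency(lam, pcm.n).cr == pytest.approx(0.0, abs=1e-8)

    def test_same_seed_is_bit_identical(self):
        model = PcmNoiseModel(true_weights=self._true(), sigma=0.25, seed=9)
        a, b = gen_pcms(model), gen_pcms(model)
        for x, y in zip(a, b):
            assert np.array_equal(x.matrix, y.matrix)

    def test_mean_cr_increases_with_sigma(self):
        mean_crs = []
        for sigma in (0.05, 0.15, 0.3):
            crs = []
            for seed in range(20):  # 20 models x 10 participants = 200 matrices
                model = PcmNoiseModel(true_weights=self._true(), sigma=sigma,
                                      n_participants=10, seed=seed)
                for pcm in gen_pcms(model):
                    _, lam = derive_priorities(pcm)
                    crs.append(consistency(lam, pcm.n).cr)
            mean_crs.append(np.mean(crs))
        assert mean_crs[0] < mean_crs[1] < mean_crs[2]

    def test_recovery_error_decreases_with_sigma(self):
        errors = []
        for sigma in (0.3, 0.15, 0.05, 0.0):
            errs = []
            for seed in range(10):
                model = PcmNoiseModel(true_weights=self._true(), sigma=sigma, seed=seed)
                for pcm in gen_pcms(model):
                    vec, _ = derive_priorities(pcm)
                    errs.append(np.abs(vec.weights - self._true().weights).mean())
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2] > errors[3]

    def test_discretized_entries_live_on_the_saaty_scale(self):
        from consensuskit.ahp import SAATY_SCALE
        pcms = gen_pcms(PcmNoiseModel(true_weights=self._true(), sigma=0.4,
                                      discretize=True, seed=2))
        for pcm in pcms:
            upper = pcm.matrix[np.triu_indices(pcm.n, 1)]
            for v in upper:
                assert np.min(np.abs(SAATY_SCALE - v)) < 1e-12

    def test_snap_ties_go_to_the_larger_value(self):
        # geometric midpoint between 1 and 2 is sqrt(2): equidistant in log
        assert snap_to_saaty(np.sqrt(2)) == 2.0
        assert snap_to_saaty(1.0) == 1.0
        assert snap_to_saaty(np.sqrt(1 / 2)) == 1.0


class TestGenLikert:
    def test_point_mass(self):
        item = gen_likert([1, 0, 0, 0, 0], n=50, seed=4)
        assert item.counts == (50, 0, 0, 0, 0)

    def test_same_seed_identical(self):
        a = gen_likert([0.5, 0.3, 0.1, 0.05, 0.05], 76, seed=6)
        b = gen_likert([0.5, 0.3, 0.1, 0.05, 0.05], 76, seed=6)
        assert a.counts == b.counts

    def test_frequencies_within_three_standard_errors(self):
        probs = np.array([0.6, 0.3, 0.1, 0.0, 0.0])
        n = 10_000
        item = gen_likert(probs, n, seed=8)
        freq = np.array(item.counts) / n
        se = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(freq - probs) <= 3 * se + 1e-12)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValidationError):
            gen_likert([0.5, 0.5, 0.5, 0, 0], 10, seed=0)


class TestEndToEndRecovery:
    def test_archetype_labels_recovered_across_seeds(self):
        # 40 forced-include, 40 forced-exclude, 42 equivocal items at n=76:
        # strong labels must always be recovered; equivocal >= 95% over seeds
        items = (
            [(f"inc{i}", "strong_include") for i in range(40)]
            + [(f"exc{i}", "strong_exclude") for i in range(40)]
            + [(f"eq{i}", "equivocal") for i in range(42)]
        )
        eq_total = eq_correct = 0
        for seed in range(100):
            vm = gen_votes(_design(items, seed=seed))
            rr = run_round(vm)
            for item_id, d in rr.decisions.items():
                if item_id.startswith("inc"):
                    assert d.label == "include"
                elif item_id.startswith("exc"):
                    assert d.label == "exclude"
                else:
                    eq_total += 1
                    eq_correct += d.label == "equivocal"
        assert eq_correct / eq_total >= 0.95
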