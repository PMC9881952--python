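import itertools

import numpy as np
import pandas as pd
import pytest

import permprior as pp


def brute_force_auroc(scores, labels):
    """Average over all positive-negative pairs, ties counting 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_and_tied_rankings(self):
        assert pp.auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert pp.auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_hand_computed_tie_case(self):
        assert pp.auroc([0.9, 0.7, 0.7, 0.1], [1, 1, 0, 0]) == 0.875

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            pp.auroc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(5, 200))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert pp.auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.random(300)
        labels = (scores + rng.normal(0, 0.4, 300) > 0.5).astype(int)
        assert pp.auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[0], labels[1] = 0, 1
        base = pp.auroc(scores, labels)
        for transform in (lambda s: 3 * s + 1, np.exp, lambda s: s**3):
            assert pp.auroc(transform(scores), labels) == pytest.approx(base, abs=1e-12)


class TestCalibration:
    def test_constant_prevalence_predictor(self):
        labels = np.array([1, 0, 0, 1, 0, 0, 0, 1, 0, 0])
        p = labels.mean()
        report = pp.calibration_report(np.full(10, p), labels)
        assert report.brier_calibration == 0.0
        assert report.brier_refinement == pytest.approx(p * (1 - p), abs=1e-15)

    def test_oracle_predictor_has_zero_components(self):
        labels = np.array([0, 1, 1, 0, 1])
        report = pp.calibration_report(labels.astype(float), labels)
        assert report.brier_calibration == 0.0
        assert report.brier_refinement == 0.0

    def test_two_bin_hand_computation(self):
        report = pp.calibration_report(
            [0.25, 0.25, 0.75, 0.75], [0, 1, 1, 1], n_bins=2
        )
        assert report.brier_calibration == pytest.approx(0.0625, abs=1e-12)
        assert report.brier_refinement == pytest.approx(0.125, abs=1e-12)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            pp.calibration_report([0.5, 1.2], [0, 1])

    def test_decomposition_identity(self):
        """calibration + refinement = mean squared error of binned scores."""
        rng = np.random.default_rng(3)
        scores = rng.random(500)
        labels = (rng.random(500) < scores).astype(int)
        report = pp.calibration_report(scores, labels, n_bins=20, binning="quantile")
        bins = report.calibration_bins
        binned_mse = float(
            np.sum(
                bins["count"]
                * (
                    (bins.mean_score - bins.event_rate) ** 2
                    + bins.event_rate * (1 - bins.event_rate)
                )
            )
            / bins["count"].sum()
        )
        assert report.brier_calibration + report.brier_refinement == pytest.approx(
            binned_mse, abs=1e-9
        )
        assert bins["count"].sum() == report.n_pos + report.n_neg


def indicator_predictor(network, positive_pairs):
    I, J = pp.candidate_pairs(network)
    hit = {network.canonical(*p) for p in positive_pairs}
    score = np.array([1.0 if (i, j) in hit else 0.0 for i, j in zip(I, J)])
    return pd.DataFrame({"source": I, "target": J, "score": score})


class TestTasks:
    def test_reconstruction_with_indicator_is_perfect(self, path4):
        report = pp.run_reconstruction_task(path4, indicator_predictor(path4, path4.edges))
        assert report.auroc == 1.0

    def test_reconstruction_with_constant_is_chance(self, path4):
        I, J = pp.candidate_pairs(path4)
        const = pd.DataFrame({"source": I, "target": J, "score": 0.5})
        assert pp.run_reconstruction_task(path4, const).auroc == 0.5

    def test_coverage_gap_is_an_error(self, path4):
        partial = pd.DataFrame({"source": [0], "target": [1], "score": [1.0]})
        with pytest.raises(ValueError, match="missing"):
            pp.run_reconstruction_task(path4, partial)

    def test_holdout_partition_arithmetic(self):
        net = pp.generate_network(pp.GeneratorConfig(n_source=20, m=10, seed=5))
        prior_fn = lambda sampled: pp.edge_prior(sampled, 20, pp.SwapParams(seed=0))
        report = pp.run_holdout_task(net, 0.7, seed=2, predictor_fn=prior_fn)
        assert report.n_pos == 3
        # sampled edges are excluded from scoring entirely
        sampled, heldout = pp.subsample_edges(net, 0.7, seed=2)
        I, J = pp.candidate_pairs(net)
        assert report.n_pos + report.n_neg == len(I) - sampled.m

    def test_holdout_is_deterministic_per_seed(self):
        net = pp.generate_network(pp.GeneratorConfig(n_source=30, m=40, seed=6))
        prior_fn = lambda s: pp.edge_prior(s, 10, pp.SwapParams(seed=1))
        r1 = pp.run_holdout_task(net, 0.7, seed=3, predictor_fn=prior_fn)
        r2 = pp.run_holdout_task(net, 0.7, seed=3, predictor_fn=prior_fn)
        assert r1.auroc == r2.auroc

    def test_holdout_requires_a_heldout_set(self, path4):
        with pytest.raises(ValueError):
            pp.run_holdout_task(path4, 0.99, seed=0,
                                predictor_fn=lambda s: pp.edge_prior(s, 5))

    def test_transfer_to_itself_reduces_to_reconstruction(self):
        net = pp.generate_network(pp.GeneratorConfig(n_source=40, m=80, seed=7))
        prior_fn = lambda s: pp.edge_prior(s, 30, pp.SwapParams(seed=2))
        transfer = pp.run_transfer_task(net, net, prior_fn)
        recon = pp.run_reconstruction_task(net, prior_fn(net))
        assert transfer.auroc == pytest.approx(recon.auroc, abs=1e-12)

    def test_transfer_requires_aligned_universe(self, path4):
        other = pp.Network(frozenset({(0, 1)}), 3, 3)
        with pytest.raises(ValueError, match="universe"):
            pp.run_transfer_task(path4, other, lambda s: pp.edge_prior(s, 5))


class TestPermutedFeatureBaseline:
    def test_preferential_attachment_is_a_point_mass(self):
        net = pp.generate_network(
            pp.GeneratorConfig(n_source=40, m=100, heterogeneity=1.0, seed=8)
        )
        baseline = pp.permuted_feature_baseline(
            net, "preferential_attachment", n_permutations=5,
            params=pp.SwapParams(seed=0),
        )
        assert (baseline.permuted_aurocs == baseline.feature_auroc).all()

    def test_single_permutation_plumbing(self, path4):
        baseline = pp.permuted_feature_baseline(
            path4, "jaccard", n_permutations=1, params=pp.SwapParams(seed=0)
        )
        assert len(baseline.permuted_aurocs) == 1
        assert 0.0 <= baseline.prior_auroc <= 1.0

    def test_unknown_feature_rejected(self, path4):
        with pytest.raises(ValueError):
            pp.permuted_feature_baseline(path4, "katz")
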