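import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intronevo import ancestral as anc
from intronevo.phylo import TreeIndex
from intronevo.synthetic_data import simulate_matrix

from conftest import matrix_from_frame, random_tree


def brute_force_min_losses(tree: TreeIndex, leaf_states: dict[str, int]) -> int:
    """Minimum losses over all single-gain node-state assignments.

    Enumerates presence/absence at every internal node, keeps assignments
    with at most one 0->1 edge (the gain; root presence counts as the
    origin), and returns the minimal number of 1->0 edges consistent with
    the leaves (-1 entries unconstrained).
    """
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf[i]]
    free_leaves = [
        i for i in tree.leaf_indices if leaf_states[tree.labels[i]] == -1
    ]
    best = None
    for internal_assign in itertools.product([0, 1], repeat=len(internal)):
        for free_assign in itertools.product([0, 1], repeat=len(free_leaves)):
            state = {}
            for i, v in zip(internal, internal_assign):
                state[i] = v
            for i, v in zip(free_leaves, free_assign):
                state[int(i)] = v
            ok = True
            for i in tree.leaf_indices:
                lab = tree.labels[i]
                if leaf_states[lab] != -1:
                    state[int(i)] = leaf_states[lab]
            gains = sum(
                1
                for i in range(tree.n_nodes)
                if tree.parent[i] >= 0 and state[tree.parent[i]] == 0 and state[i] == 1
            )
            gains += state[tree.root]  # root presence = root origin
            losses = sum(
                1
                for i in range(tree.n_nodes)
                if tree.parent[i] >= 0 and state[tree.parent[i]] == 1 and state[i] == 0
            )
            if gains != 1:
                continue
            if best is None or losses < best:
                best = losses
    return best


class TestDollo:
    def test_all_present_no_events(self, quartet_tree):
        df = pd.DataFrame({sp: [1] for sp in "ABCD"}, index=["s1"])
        ev = anc.dollo_events(matrix_from_frame(df), quartet_tree)
        assert ev.total_losses == 0 and ev.total_gains == 0
        assert ev.site_origin["s1"] == "root"

    def test_outgroup_absence_forces_gain_and_loss(self):
        tree = TreeIndex.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,O:3);")
        df = pd.DataFrame({"A": [1], "B": [1], "C": [1], "D": [0], "O": [0]}, index=["s1"])
        ev = anc.dollo_events(matrix_from_frame(df), tree)
        assert ev.site_losses["s1"] == ["D"]
        # origin on the stem of MRCA(A,B,C,D)
        origin = tree.index_of[ev.site_origin["s1"]]
        assert sorted(tree.labels[i] for i in tree.subtree_leaves(origin)) == list("ABCD")
        assert ev.site_gain["s1"] == ev.site_origin["s1"]

    def test_single_leaf_presence_is_terminal_gain(self, quartet_tree):
        df = pd.DataFrame({"A": [1], "B": [0], "C": [0], "D": [0]}, index=["s1"])
        ev = anc.dollo_events(matrix_from_frame(df), quartet_tree)
        assert ev.site_gain["s1"] == "A" and ev.total_losses == 0

    def test_ambiguous_cells_impose_no_constraint(self, quartet_tree):
        # B is ambiguous: no loss should be charged to it, while D's
        # confirmed absence still costs one loss
        df = pd.DataFrame({"A": [1], "B": ["?"], "C": [1], "D": [0]}, index=["s1"])
        ev = anc.dollo_events(matrix_from_frame(df), quartet_tree)
        assert ev.site_losses["s1"] == ["D"]
        assert ev.site_origin["s1"] == "root"

    def test_missing_species_rejected(self, quartet_tree):
        df = pd.DataFrame({"A": [1], "B": [1], "C": [1], "X": [1]}, index=["s1"])
        with pytest.raises(ValueError):
            anc.dollo_events(matrix_from_frame(df), quartet_tree)

    def test_matches_exhaustive_search_on_small_trees(self):
        """Dollo output equals brute-force minimal-loss search (spot check)."""
        rng = np.random.default_rng(42)
        for case in range(60):
            tree = TreeIndex.from_newick(random_tree(rng, int(rng.integers(3, 8))))
            labels = tree.leaf_labels
            states = {lab: int(rng.integers(0, 2)) for lab in labels}
            if rng.random() < 0.3:
                states[labels[int(rng.integers(len(labels)))]] = -1
            if not any(v == 1 for v in states.values()):
                states[labels[0]] = 1
            df = pd.DataFrame(
                {lab: [{1: "1", 0: "0", -1: "?"}[states[lab]]] for lab in labels},
                index=["s1"],
            )
            ev = anc.dollo_events(matrix_from_frame(df), tree)
            assert ev.total_losses == brute_force_min_losses(tree, states)


class TestLoglik:
    def test_two_leaf_closed_form(self):
        tree = TreeIndex.from_newick("(A:0.5,B:0.7);")
        df = pd.DataFrame({"A": [1], "B": [1]}, index=["s1"])
        model = anc.RateModel(loss_rate=0.4, gain_rate=0.2)
        ll = anc.loglik(matrix_from_frame(df), tree, model)

        def P(l, g, t):
            return np.array(
                [[np.exp(-g * t), 1 - np.exp(-g * t)], [1 - np.exp(-l * t), np.exp(-l * t)]]
            )

        pi = np.array([0.4 / 0.6, 0.2 / 0.6])
        Pa, Pb = P(0.4, 0.2, 0.5), P(0.4, 0.2, 0.7)
        num = pi[0] * Pa[0, 1] * Pb[0, 1] + pi[1] * Pa[1, 1] * Pb[1, 1]
        p_all0 = pi[0] * Pa[0, 0] * Pb[0, 0] + pi[1] * Pa[1, 0] * Pb[1, 0]
        assert ll == pytest.approx(np.log(num / (1 - p_all0)), abs=1e-12)

    def test_unit_multiplier_mixture_equals_constant(self, ten_taxon_tree):
        df = simulate_matrix(ten_taxon_tree, 0.5, 0.1, 200, seed=0)
        m = matrix_from_frame(df)
        const = anc.RateModel(loss_rate=0.5, gain_rate=0.1)
        mixed = anc.RateModel.rate_variation(0.5, 0.1, 1.0)
        assert anc.loglik(m, ten_taxon_tree, mixed) == pytest.approx(
            anc.loglik(m, ten_taxon_tree, const), abs=1e-9
        )

    def test_row_order_invariance(self, ten_taxon_tree):
        df = simulate_matrix(ten_taxon_tree, 0.5, 0.1, 100, seed=1)
        m1 = matrix_from_frame(df)
        m2 = matrix_from_frame(df.iloc[::-1])
        model = anc.RateModel(loss_rate=0.3, gain_rate=0.2)
        assert anc.loglik(m1, ten_taxon_tree, model) == pytest.approx(
            anc.loglik(m2, ten_taxon_tree, model), rel=1e-12
        )

    def test_likelihood_peaks_near_mle(self, ten_taxon_tree):
        df = simulate_matrix(ten_taxon_tree, 0.5, 0.1, 1000, seed=2)
        m = matrix_from_frame(df)
        fit = anc.fit_rates(m, ten_taxon_tree, "constant", seed=0)
        best = fit.loglik
        for factor in (0.7, 1.4):
            worse = anc.RateModel(
                loss_rate=fit.model.loss_rate * factor, gain_rate=fit.model.gain_rate
            )
            assert anc.loglik(m, ten_taxon_tree, worse) < best


class TestFitRates:
    def test_nested_model_never_fits_worse(self, ten_taxon_tree):
        df = simulate_matrix(ten_taxon_tree, 0.6, 0.1, 400, seed=3)
        m = matrix_from_frame(df)
        fit_c = anc.fit_rates(m, ten_taxon_tree, "constant", seed=0)
        fit_v = anc.fit_rates(m, ten_taxon_tree, "rate_variation", seed=0)
        assert fit_v.loglik >= fit_c.loglik - 1e-6

    def test_zero_losses_drives_loss_rate_to_floor(self, quartet_tree):
        df = pd.DataFrame({sp: [1] * 80 for sp in "ABCD"})
        m = matrix_from_frame(df.set_axis([f"s{i}" for i in range(80)]))
        fit = anc.fit_rates(m, quartet_tree, "constant", seed=0)
        assert fit.model.loss_rate <= 1e-6

    def test_small_matrix_warns(self, quartet_tree):
        df = pd.DataFrame({sp: [1, 0, 1] for sp in "ABCD"}, index=["a", "b", "c"])
        df.loc["a", "A"] = 1
        with pytest.warns(UserWarning, match="sites"):
            anc.fit_rates(matrix_from_frame(df), quartet_tree, "constant", seed=0)


class TestLRT:
    def test_published_loglik_pair_underflows(self):
        res = anc.lrt(-66_590.0, -65_107.0)
        assert res.delta == pytest.approx(2966.0)
        assert res.p_value == 0.0 and res.underflow

    def test_equal_likelihoods_give_p_one(self):
        res = anc.lrt(-100.0, -100.0)
        assert res.delta == 0.0 and res.p_value == 1.0

    def test_critical_value_quantile(self):
        res = anc.lrt(-100.0, -100.0 + 3.841 / 2)
        assert res.p_value == pytest.approx(0.05, abs=5e-4)

    def test_negative_delta_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            anc.lrt(-99.0, -100.0)


class TestPosteriorEvents:
    def test_all_present_sites_yield_no_events(self):
        tree = TreeIndex.from_newick("(A:0.5,B:0.5);")
        df = pd.DataFrame({"A": [1] * 5, "B": [1] * 5}).set_axis(list("abcde"))
        model = anc.RateModel(loss_rate=0.3, gain_rate=0.1)
        ev = anc.posterior_events(matrix_from_frame(df), tree, model, 0.99)
        assert ev.total_losses == 0 and ev.total_gains == 0

    def test_threshold_zero_keeps_every_positive_posterior(self, quartet_tree):
        df = pd.DataFrame({"A": [1], "B": [0], "C": [1], "D": [1]}, index=["s1"])
        model = anc.RateModel(loss_rate=0.3, gain_rate=0.1)
        ev0 = anc.posterior_events(matrix_from_frame(df), quartet_tree, model, 0.0)
        # every branch can carry a loss with positive posterior
        assert ev0.total_losses >= 1
        frame = ev0.event_posteriors
        assert (frame["posterior"] > 0).all()

    def test_invalid_threshold_rejected(self, quartet_tree):
        df = pd.DataFrame({sp: [1] for sp in "ABCD"}, index=["s1"])
        model = anc.RateModel()
        with pytest.raises(ValueError):
            anc.posterior_events(matrix_from_frame(df), quartet_tree, model, 1.5)

    def test_agrees_with_dollo_on_clear_signal(self, ten_taxon_tree):
        """Strong-signal sites: thresholded events are a subset of Dollo's."""
        df = simulate_matrix(ten_taxon_tree, 0.4, 0.02, 300, seed=5)
        m = matrix_from_frame(df)
        dollo = anc.dollo_events(m, ten_taxon_tree)
        model = anc.RateModel(loss_rate=0.4, gain_rate=0.02)
        post = anc.posterior_events(m, ten_taxon_tree, model, 0.99)
        dollo_losses = {
            (sid, b) for sid, brs in dollo.site_losses.items() for b in brs
        }
        post_losses = {
            (sid, b) for sid, brs in post.site_losses.items() for b in brs
        }
        assert post_losses, "expected confident losses at these rates"
        assert len(post_losses - dollo_losses) / len(post_losses) <= 0.05


class TestScaledDensity:
    @pytest.mark.parametrize("n, expected", [(373, 3.65), (0, 0.0), (746, 7.30)])
    def test_reference_scaling(self, n, expected):
        assert anc.scaled_density(n) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            anc.scaled_density(-1)


class TestBranchSummary:
    def test_zero_event_history_skips_test(self, quartet_tree):
        df = pd.DataFrame({sp: [1] for sp in "ABCD"}, index=["s1"])
        ev = anc.dollo_events(matrix_from_frame(df), quartet_tree)
        summary = anc.branch_summary(ev, quartet_tree)
        assert summary.p_value is None and "skipped" in summary.note
        assert (summary.table[["losses", "gains"]] == 0).all().all()

    def test_totals_conserved(self, ten_taxon_tree):
        df = simulate_matrix(ten_taxon_tree, 0.5, 0.1, 200, seed=6)
        ev = anc.dollo_events(matrix_from_frame(df), ten_taxon_tree)
        summary = anc.branch_summary(ev, ten_taxon_tree)
        assert summary.table["losses"].sum() == ev.total_losses
        assert summary.table["gains"].sum() == ev.total_gains
        per_site = sum(len(v) for v in ev.site_losses.values())
        assert per_site == ev.total_losses

    def test_balanced_event_counts_rarely_reject(self, ten_taxon_tree):
        """Exchangeable per-branch loss/gain counts: the signed-rank test is null."""
        rng = np.random.default_rng(0)
        branches = [
            ten_taxon_tree.labels[i]
            for i in range(ten_taxon_tree.n_nodes)
            if i != ten_taxon_tree.root
        ]
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            ev = anc.EventHistory(
                method="synthetic",
                site_origin={}, site_losses={}, site_gain={},
                branch_losses={b: int(rng.poisson(3)) for b in branches},
                branch_gains={b: int(rng.poisson(3)) for b in branches},
                node_counts={},
            )
            summary = anc.branch_summary(ev, ten_taxon_tree)
            if summary.p_value is not None and summary.p_value <= 0.05:
                rejections += 1
        assert rejections <= max(4, 0.1 * n_rep)
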