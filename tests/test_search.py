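"""Architecture search: space cardinality, costs, supernet, discretization."""

import itertools

import numpy as np
import pytest

from picocall.nn import ctc_loss
from picocall.search import (CostModel, SearchConfig, SearchSpace,
                             SupernetState, derive_architecture, expected_cost,
                             run_search, search_space_size, supernet_loss)
from picocall.training import TrainConfig


def small_space(**kw):
    defaults = dict(n_groups=2, repeats=1, kernel_options=(3, 9),
                    quant_options=((8, 8), (16, 16)), channel_options=(6, 8))
    defaults.update(kw)
    return SearchSpace(**defaults)


class TestSpaceSize:
    def test_full_scale_cardinality(self):
        space = SearchSpace()  # 10 kernels x 4 quants + identity over 5x4 layers
        assert search_space_size(space) == 41 ** 20
        assert search_space_size(space) == pytest.approx(1.80e32, rel=0.01)

    def test_op_only_space(self):
        space = SearchSpace(quant_options=((32, 32),))
        assert search_space_size(space) == 11 ** 20
        assert search_space_size(space) == pytest.approx(6.727e20, rel=0.01)

    def test_minimal_space(self):
        space = SearchSpace(n_groups=1, repeats=1, kernel_options=(3,),
                            quant_options=((8, 8),), channel_options=(4,))
        assert search_space_size(space) == 2

    def test_matches_brute_force_enumeration(self):
        space = small_space(repeats=1)  # 2 kernels x 2 quants + id, 2 layers
        cands = space.candidates()
        count = sum(1 for _ in itertools.product(cands, repeat=space.n_layers))
        assert search_space_size(space) == count == 25


class TestExpectedCost:
    def test_identity_everywhere_costs_nothing(self):
        space = small_space()
        cm = CostModel.analytic_bops(space)
        logits = np.full((space.n_layers, space.n_candidates), -50.0)
        logits[:, -1] = 50.0  # identity is last
        assert expected_cost(logits, cm) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_two_candidate_average(self):
        space = SearchSpace(n_groups=1, repeats=1, kernel_options=(3,),
                            quant_options=((8, 8),), channel_options=(4,))
        cm = CostModel.analytic_bops(space, ref_frames=10)
        c = cm.matrix[0, 0]
        logits = np.zeros((1, 2))
        assert expected_cost(logits, cm) * cm.normalizer == pytest.approx(c / 2)

    def test_matches_exhaustive_weighted_sum(self):
        rng = np.random.default_rng(0)
        space = small_space()
        cm = CostModel.analytic_bops(space)
        logits = rng.normal(size=(space.n_layers, space.n_candidates))
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        manual = sum(p[l, c] * cm.matrix[l, c]
                     for l in range(space.n_layers)
                     for c in range(space.n_candidates)) / cm.normalizer
        assert expected_cost(logits, cm) == pytest.approx(manual)

    def test_monotone_in_costlier_candidate_logit(self):
        rng = np.random.default_rng(1)
        space = small_space()
        cm = CostModel.analytic_bops(space)
        for _ in range(20):
            logits = rng.normal(size=(space.n_layers, space.n_candidates))
            l = int(rng.integers(space.n_layers))
            c = int(np.argmax(cm.matrix[l]))  # costliest candidate
            before = expected_cost(logits, cm)
            logits[l, c] += 0.5
            assert expected_cost(logits, cm) >= before - 1e-12


@pytest.fixture(scope="module")
def search_dataset(tiny_task):
    return tiny_task["dataset"].subset(np.arange(128))


class TestSupernetLoss:
    def test_lambda_zero_equals_mixture_ctc(self, search_dataset):
        space = small_space()
        state = SupernetState.initial(space, seed=0,
                                      cost_model=CostModel.analytic_bops(space))
        x = search_dataset.signals[:4].astype(float)
        targets = [search_dataset.labels_for(i).astype(np.int64) + 1
                   for i in range(4)]
        cfg0 = SearchConfig(lambda_hw=0.0, search_chunks=16)
        loss0 = supernet_loss((x, targets), state, cfg0)
        lp = state.supernet.forward(x, state.probs, train=True)
        ctc_only, _, _ = ctc_loss(lp, targets, want_grad=False)
        assert loss0 == pytest.approx(ctc_only)

    def test_lambda_term_scales_linearly(self, search_dataset):
        space = small_space()
        state = SupernetState.initial(space, seed=0,
                                      cost_model=CostModel.analytic_bops(space))
        x = search_dataset.signals[:4].astype(float)
        targets = [search_dataset.labels_for(i).astype(np.int64) + 1
                   for i in range(4)]
        losses = {}
        for lam in (0.0, 0.6, 1.2):
            losses[lam] = supernet_loss(
                (x, targets), state, SearchConfig(lambda_hw=lam,
                                                  search_chunks=16))
        gap1 = losses[0.6] - losses[0.0]
        gap2 = losses[1.2] - losses[0.0]
        assert gap2 == pytest.approx(2 * gap1)


class TestDeriveArchitecture:
    def test_one_hot_logits_recovered_exactly(self):
        space = small_space()
        cands = space.candidates()
        rng = np.random.default_rng(2)
        choice = [int(rng.integers(len(cands))) for _ in range(space.n_layers)]
        logits = np.full((space.n_layers, len(cands)), -10.0)
        for l, c in enumerate(choice):
            logits[l, c] = 10.0
        state = SupernetState(space=space, arch_logits=logits)
        spec = derive_architecture(state, space)
        derived = [(l.kernel, (l.quant.wbits, l.quant.abits))
                   for b in spec.blocks for l in b.layers
                   if b.skip and l.kind == "conv"]
        expected = [(cands[i][1], cands[i][2]) for i in choice
                    if cands[i][0] == "conv"]
        assert derived == expected

    def test_all_identity_minimal_network(self):
        space = small_space()
        logits = np.full((space.n_layers, space.n_candidates), -10.0)
        logits[:, -1] = 10.0
        spec = derive_architecture(
            SupernetState(space=space, arch_logits=logits), space)
        # only stem + channel transition remain; no searched layers, no skips
        assert spec.n_skips() == 0
        assert all(l.kernel in (1, space.stem_kernel)
                   for b in spec.blocks for l in b.layers)

    def test_argmax_matches_independent_recomputation(self):
        rng = np.random.default_rng(3)
        space = small_space()
        cm = CostModel.analytic_bops(space)
        logits = rng.normal(size=(space.n_layers, space.n_candidates))
        spec = derive_architecture(
            SupernetState(space=space, arch_logits=logits), space, cm)
        cands = space.candidates()
        picks = [cands[int(np.argmax(logits[l]))]
                 for l in range(space.n_layers)]
        derived = [(l.kernel, (l.quant.wbits, l.quant.abits))
                   for b in spec.blocks if b.skip for l in b.layers]
        expected = [(c[1], c[2]) for c in picks if c[0] == "conv"]
        assert derived == expected

    def test_derived_spec_is_space_member(self):
        rng = np.random.default_rng(4)
        space = small_space(repeats=2)
        for _ in range(10):
            logits = rng.normal(size=(space.n_layers, space.n_candidates))
            spec = derive_architecture(
                SupernetState(space=space, arch_logits=logits), space)
            spec.validate()
            for b in spec.blocks:
                for l in b.layers:
                    if b.skip:
                        assert l.kernel in space.kernel_options
                        assert (l.quant.wbits, l.quant.abits) in \
                            space.quant_options


class TestRunSearch:
    def test_zero_epochs_keeps_uniform_logits(self, search_dataset):
        space = small_space()
        res = run_search(search_dataset, space,
                         SearchConfig(search_chunks=32, epochs=0, seed=0))
        assert np.all(res.state.arch_logits == 0.0)

    def test_single_candidate_space_derivation_is_forced(self, search_dataset):
        space = SearchSpace(n_groups=1, repeats=1, kernel_options=(3,),
                            quant_options=((8, 8),), channel_options=(4,),
                            include_identity=False)
        res = run_search(search_dataset, space,
                         SearchConfig(search_chunks=32, epochs=1, seed=0,
                                      train=TrainConfig(batch_size=8)))
        spec = derive_architecture(res.state, space)
        convs = [l for b in spec.blocks if b.skip for l in b.layers]
        assert len(convs) == 1
        assert convs[0].kernel == 3
        assert (convs[0].quant.wbits, convs[0].quant.abits) == (8, 8)

    def test_large_lambda_drives_cost_down(self, search_dataset):
        """Paired-seed property: a heavy hardware penalty never yields a
        costlier derived architecture than no penalty."""
        space = small_space(repeats=2)
        cm = CostModel.analytic_bops(space, ref_frames=240)

        def derived_cost(lam, seed):
            cfg = SearchConfig(lambda_hw=lam, search_chunks=96, epochs=2,
                               seed=seed, train=TrainConfig(batch_size=16))
            res = run_search(search_dataset, space, cfg, cost_model=cm)
            one_hot = np.where(
                res.state.arch_logits ==
                res.state.arch_logits.max(axis=1, keepdims=True), 50.0, -50.0)
            return expected_cost(one_hot, cm)

        lam0 = [derived_cost(0.0, s) for s in range(3)]
        lam_hi = [derived_cost(1000.0, s) for s in range(3)]
        assert np.mean(lam_hi) <= np.mean(lam0) + 1e-9
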