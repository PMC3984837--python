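from types import SimpleNamespace

import numpy as np
import pytest

from p300select import fda
from p300select.datasets import (
    EpochDataset,
    ErpSpec,
    ProtocolSpec,
    generate_dataset,
)
from p300select.evaluation import (
    SplitSpec,
    averaged_trial_gm,
    build_master_list,
    jaccard,
    pareto_front,
    selection_frequency,
    stratified_split,
    train_final_and_test,
)
from p300select.preprocessing import PreprocSpec


@pytest.fixture(scope="module")
def full_protocol_split():
    """Default 1800-trial protocol on a 2-channel montage (split geometry
    depends only on the metadata)."""
    protocol = ProtocolSpec(n_channels=2)
    erp = ErpSpec(informative_channels=(0,), noise_sd=5.0)
    ds = generate_dataset(protocol, erp, seed=0)
    return ds, stratified_split(ds, SplitSpec(seed=1))


class TestStratifiedSplit:
    def test_default_protocol_gives_900_900(self, full_protocol_split):
        _, (train, test) = full_protocol_split
        assert train.n_trials == 900
        assert test.n_trials == 900

    def test_partition_is_disjoint_and_exhaustive(self, full_protocol_split):
        ds, (train, test) = full_protocol_split
        tr, te = set(train.trial_ids), set(test.trial_ids)
        assert tr.isdisjoint(te)
        assert tr | te == set(ds.trial_ids)

    def test_per_stratum_counts_balanced(self, full_protocol_split):
        _, (train, test) = full_protocol_split
        for side, n_expected in ((train, 15), (test, 15)):
            for d in range(1, 7):
                for s in (1, 2):
                    mask = (side.direction == d) & (side.session == s)
                    # 30 targets and 120 nontargets per session split evenly
                    assert (side.labels[mask] == 1).sum() == n_expected
                    assert (side.labels[mask] == -1).sum() == 60

    def test_odd_stratum_splits_13_12(self):
        n = 50
        labels = np.r_[np.ones(25), -np.ones(25)].astype(int)
        ds = EpochDataset(
            data=np.zeros((n, 2, 275)), labels=labels,
            direction=np.ones(n), session=np.ones(n),
            fs=250.0, t0_ms=-100.0, channel_names=("a", "b"),
        )
        train, test = stratified_split(ds, SplitSpec(seed=0))
        counts = sorted([(train.labels == 1).sum(), (test.labels == 1).sum()])
        assert counts == [12, 13]
        assert train.n_trials + test.n_trials == 50
        assert abs(train.n_trials - test.n_trials) == 0  # extras alternate

    def test_deterministic_under_seed(self, full_protocol_split):
        ds, (train, _) = full_protocol_split
        train2, _ = stratified_split(ds, SplitSpec(seed=1))
        assert np.array_equal(train.trial_ids, train2.trial_ids)


class TestFinalEvaluation:
    protocol = ProtocolSpec(n_channels=6, trials_per_session=50)
    pre = PreprocSpec()

    def _split(self, erp, seed):
        ds = generate_dataset(self.protocol, erp, seed)
        train, test = stratified_split(ds, SplitSpec(seed=seed))
        return train, test

    def test_high_snr_with_true_channels_is_accurate(self):
        erp = ErpSpec(informative_channels=(1, 4), amplitude=10.0, noise_sd=4.0)
        train, test = self._split(erp, 0)
        res = train_final_and_test(train, test, (10.0, (1, 4)), self.pre)
        assert res.gm >= 0.95
        assert res.scores_test.shape == (test.n_trials,)

    def test_null_data_stays_at_chance(self):
        erp = ErpSpec(informative_channels=(), amplitude=0.0, noise_sd=10.0)
        train, test = self._split(erp, 1)
        res = train_final_and_test(train, test, (10.0, (0, 1)), self.pre)
        assert 0.35 <= res.gm <= 0.65

    def test_resubstitution_not_worse_than_heldout_estimate(self):
        erp = ErpSpec(informative_channels=(1, 4), amplitude=6.0, noise_sd=6.0)
        train, test = self._split(erp, 2)
        heldout = train_final_and_test(train, test, (10.0, (1, 4)), self.pre).gm
        # diagnostic resubstitution: testing on a copy of the training half
        # is optimistic; fresh ids sidestep the leakage guard deliberately
        twin = EpochDataset(
            data=train.data, labels=train.labels, direction=train.direction,
            session=train.session, fs=train.fs, t0_ms=train.t0_ms,
            channel_names=train.channel_names,
            trial_ids=train.trial_ids + 100000,
        )
        resub = train_final_and_test(train, twin, (10.0, (1, 4)), self.pre).gm
        assert resub >= heldout - 0.05

    def test_leakage_guard_rejects_overlapping_sets(self):
        erp = ErpSpec(informative_channels=(1,), noise_sd=5.0)
        train, _ = self._split(erp, 3)
        with pytest.raises(ValueError, match="share"):
            train_final_and_test(train, train, (1.0, (1,)), self.pre)

    def test_empty_channels_rejected(self):
        erp = ErpSpec(informative_channels=(1,), noise_sd=5.0)
        train, test = self._split(erp, 4)
        with pytest.raises(ValueError, match="empty"):
            train_final_and_test(train, test, (1.0, ()), self.pre)


class TestMasterList:
    labels = np.resize([1, -1, -1, -1, -1], 100)

    def test_counts_and_class_ratio(self):
        master = build_master_list(self.labels, range(2, 11), seed=0)
        assert master.m_values == tuple(range(2, 11))
        for m in master.m_values:
            idx = master.entries[m]
            assert idx.shape == (100, m)
            assert np.array_equal(master.labels[m], self.labels)

    def test_every_tuple_is_single_class(self):
        master = build_master_list(self.labels, (3, 5), seed=1)
        for m in (3, 5):
            for row, lab in zip(master.entries[m], master.labels[m]):
                assert set(self.labels[row]) == {lab}

    def test_same_seed_reproduces_list(self):
        a = build_master_list(self.labels, (2, 4), seed=7)
        b = build_master_list(self.labels, (2, 4), seed=7)
        for m in (2, 4):
            assert np.array_equal(a.entries[m], b.entries[m])

    def test_single_class_test_set_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            build_master_list(np.ones(10), (2,), seed=0)


class TestAveragedTrials:
    def _model(self):
        return fda.FDAModel(w=np.ones(1), lam=0.0, mu_pos=1.0, mu_neg=-1.0,
                            var_pos=1.0, var_neg=1.0,
                            m_pos=np.ones(1), m_neg=-np.ones(1))

    def test_identical_members_reduce_to_single_trial(self):
        from p300select.evaluation import MasterList
        labels = np.resize([1, -1], 20)
        rng = np.random.default_rng(0)
        scores = labels + rng.normal(0, 0.5, 20)
        idx = np.tile(np.arange(20)[:, None], (1, 3))  # (i, i, i) tuples
        master = MasterList(entries={3: idx}, labels={3: labels})
        model = self._model()
        gm_avg = averaged_trial_gm(scores, labels, model, master, 3)
        pred = fda.predict_scores(model, scores)
        tp = np.sum((pred == 1) & (labels == 1)) / (labels == 1).sum()
        tn = np.sum((pred == -1) & (labels == -1)) / (labels == -1).sum()
        assert gm_avg == pytest.approx(np.sqrt(tp * tn))

    def test_m_outside_list_raises(self):
        labels = np.resize([1, -1], 10)
        master = build_master_list(labels, (2,), seed=0)
        with pytest.raises(ValueError, match="not in master list"):
            averaged_trial_gm(np.zeros(10), labels, self._model(), master, 5)

    def test_averaging_improves_on_noisy_signal(self):
        # score averaging reduces variance; accuracy should not degrade
        protocol = ProtocolSpec(n_channels=4, trials_per_session=50)
        pre = PreprocSpec()
        ok = 0
        for seed in range(5):
            erp = ErpSpec(informative_channels=(1,), amplitude=4.0,
                          noise_sd=8.0)
            ds = generate_dataset(protocol, erp, seed)
            train, test = stratified_split(ds, SplitSpec(seed=seed))
            res = train_final_and_test(train, test, (10.0, (1,)), pre)
            master = build_master_list(test.labels, (10,), seed=seed)
            gm10 = averaged_trial_gm(res.scores_test, test.labels, res.model,
                                     master, 10)
            if gm10 >= res.gm - 0.02:
                ok += 1
        assert ok == 5

    def test_null_data_stays_at_chance_for_all_m(self):
        protocol = ProtocolSpec(n_channels=3, trials_per_session=50)
        erp = ErpSpec(informative_channels=(), amplitude=0.0, noise_sd=10.0)
        ds = generate_dataset(protocol, erp, 5)
        pre = PreprocSpec()
        train, test = stratified_split(ds, SplitSpec(seed=5))
        res = train_final_and_test(train, test, (10.0, (0, 1)), pre)
        master = build_master_list(test.labels, range(2, 11), seed=5)
        for m in master.m_values:
            gm = averaged_trial_gm(res.scores_test, test.labels, res.model,
                                   master, m)
            assert 0.35 <= gm <= 0.65


class TestPareto:
    def test_dominated_on_channels_is_removed(self):
        assert pareto_front([(3, 0.8), (5, 0.8)]) == [(3, 0.8)]

    def test_single_point_survives(self):
        assert pareto_front([(4, 0.5)]) == [(4, 0.5)]

    def test_front_accuracy_increases_with_channels(self):
        front = pareto_front([(1, 0.6), (2, 0.9), (3, 0.7), (2, 0.5)])
        assert front == [(1, 0.6), (2, 0.9)]

    def test_matches_brute_force_dominance_oracle(self):
        rng = np.random.default_rng(0)
        pts = [(int(n), float(a)) for n, a in
               zip(rng.integers(1, 65, 200), rng.uniform(0.3, 1.0, 200))]

        def dominated(p, q):
            return (q[1] >= p[1] and q[0] <= p[0]
                    and (q[1] > p[1] or q[0] < p[0]))

        unique = set(pts)
        expected = sorted(
            p for p in unique if not any(dominated(p, q) for q in unique)
        )
        assert pareto_front(pts) == expected

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no points"):
            pareto_front([])


class TestSelectionFrequency:
    def _result(self, channels):
        return SimpleNamespace(decoded=(1.0, tuple(channels)))

    def test_counting(self):
        results = [self._result(c) for c in
                   [(0, 2), (0, 1), (0, 2), (2, 3)]]
        freq = selection_frequency(results, 4)
        assert freq.tolist() == [0.75, 0.25, 0.75, 0.25]

    def test_always_and_never_selected(self):
        results = [self._result((1,)) for _ in range(3)]
        freq = selection_frequency(results, 3)
        assert freq[1] == 1.0 and freq[0] == 0.0 and freq[2] == 0.0


class TestJaccard:
    def test_values(self):
        assert jaccard((1, 2), (1, 2)) == 1.0
        assert jaccard((1, 2), (3, 4)) == 0.0
        assert jaccard((1, 2, 3), (2, 3, 4)) == pytest.approx(0.5)
        assert jaccard((), ()) == 1.0
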