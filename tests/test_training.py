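"""Loss, fold assignment, training loop contracts, and grid search."""

import numpy as np
import pytest

import icipred as ip
from icipred.core_data import ValidationError
from icipred.training import (TrainingConfig, bce_loss, grid_search,
                              scaled_config, stratified_folds, train_model)


class TestBceLoss:
    def test_perfect_fit_limit(self):
        y = np.array([1, 0, 1])
        assert bce_loss(y, y.astype(float)) <= -np.log(1 - 1e-7) + 1e-12

    def test_uniform_half_is_ln_two(self):
        y = np.array([1, 0, 1, 0])
        assert bce_loss(y, np.full(4, 0.5)) == pytest.approx(np.log(2),
                                                             abs=1e-12)

    def test_hand_value(self):
        got = bce_loss(np.array([1, 0]), np.array([0.9, 0.2]))
        assert got == pytest.approx(-(np.log(0.9) + np.log(0.8)) / 2)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            bce_loss(np.array([]), np.array([]))

    def test_permutation_invariant_and_mean_of_per_sample(self, rng):
        y = rng.integers(0, 2, 20)
        p = rng.uniform(0.01, 0.99, 20)
        perm = rng.permutation(20)
        assert bce_loss(y, p) == pytest.approx(bce_loss(y[perm], p[perm]))
        per = [-np.log(pi) if yi else -np.log(1 - pi)
               for yi, pi in zip(y, p)]
        assert bce_loss(y, p) == pytest.approx(np.mean(per))


class TestStratifiedFolds:
    def test_balanced_cohort_exact_split(self):
        labels = {f"s{i}": int(i < 5) for i in range(10)}
        folds = stratified_folds(labels, 5, seed=0)
        counts = folds.responder_counts(labels)
        assert counts == [1, 1, 1, 1, 1]

    def test_same_seed_identical(self):
        labels = {f"s{i}": int(i % 3 == 0) for i in range(30)}
        a = stratified_folds(labels, 5, seed=4).assignment
        b = stratified_folds(labels, 5, seed=4).assignment
        assert a == b

    def test_uneven_cohort_counts_within_one(self):
        labels = {f"s{i}": int(i < 11) for i in range(37)}
        folds = stratified_folds(labels, 5, seed=1)
        counts = folds.responder_counts(labels)
        assert set(counts) <= {2, 3}
        sizes = [len(folds.test_samples(f)) for f in range(5)]
        assert sum(sizes) == 37

    def test_k_exceeding_minority_errors(self):
        labels = {f"s{i}": int(i < 3) for i in range(20)}
        with pytest.raises(ValidationError):
            stratified_folds(labels, 5)

    def test_folds_partition_cohort(self):
        labels = {f"s{i}": int(i % 2) for i in range(23)}
        folds = stratified_folds(labels, 5, seed=9)
        all_test = [s for f in range(5) for s in folds.test_samples(f)]
        assert sorted(all_test) == sorted(labels)

    def test_strata_spread_across_folds(self):
        labels = {f"s{i}": int(i % 2) for i in range(40)}
        strata = {f"s{i}": f"cancer{i % 4}" for i in range(40)}
        folds = stratified_folds(labels, 5, strata=strata, seed=2)
        counts = folds.responder_counts(labels)
        assert max(counts) - min(counts) <= 1
        # every stratum appears in several folds
        for g in set(strata.values()):
            in_folds = {folds.fold_of(s) for s in labels if strata[s] == g}
            assert len(in_folds) >= 3


def _tiny_bulk(rng, n=40, genes=12, sets=3):
    x_exp = rng.standard_normal((n, genes))
    labels = (rng.random(n) < 0.5).astype(np.int64)
    x_exp[:, 0] += 2.0 * labels  # separable signal
    from icipred.training import BulkDataset
    return BulkDataset([f"s{i}" for i in range(n)], x_exp,
                       rng.standard_normal((n, sets)),
                       rng.standard_normal((n, 8)), labels,
                       [f"g{i}" for i in range(genes)],
                       [f"p{i}" for i in range(sets)])


def _tiny_config(**kw):
    base = dict(hidden=8, latent=4, joint_dim=6, head_hidden=(8,),
                epochs=15, patience=30, batch_size=16, chain_width=4,
                val_fraction=0.0, gat_head_dim=4)
    base.update(kw)
    return TrainingConfig(**base)


class TestTrainModel:
    def test_constant_labels_drive_predictions_up(self, rng):
        data = _tiny_bulk(rng)
        data.labels[:] = 1
        cfg = _tiny_config(epochs=40, dropout=0.0, batch_size=64,
                           learning_rate=1e-2)
        model, history = train_model("bulk", data, cfg)
        train_losses = [h[1] for h in history]
        drops = sum(b <= a + 1e-9 for a, b in zip(train_losses,
                                                  train_losses[1:]))
        assert drops >= 0.9 * (len(train_losses) - 1)
        assert model.predict(data).mean() > 0.8

    def test_same_seed_bit_identical(self, rng):
        data = _tiny_bulk(rng)
        cfg = _tiny_config(dropout=0.0, seed=5)
        m1, h1 = train_model("bulk", data, cfg)
        m2, h2 = train_model("bulk", data, cfg)
        assert h1 == h2
        np.testing.assert_array_equal(m1.predict(data), m2.predict(data))

    def test_different_seeds_differ(self, rng):
        data = _tiny_bulk(rng)
        m1, _ = train_model("bulk", data, _tiny_config(seed=1))
        m2, _ = train_model("bulk", data, _tiny_config(seed=2))
        assert not np.array_equal(m1.predict(data), m2.predict(data))

    def test_learns_above_permuted_control(self, rng):
        data = _tiny_bulk(rng, n=60)
        cfg = _tiny_config(epochs=40, seed=0)
        model, _ = train_model("bulk", data, cfg)
        auroc = ip.classification_metrics(data.labels,
                                          model.predict(data)).auroc
        perm = data.labels.copy()
        np.random.default_rng(3).shuffle(perm)
        import dataclasses
        pdata = dataclasses.replace(data, labels=perm)
        pmodel, _ = train_model("bulk", pdata, cfg)
        p_auroc = ip.classification_metrics(
            data.labels, pmodel.predict(data)).auroc
        assert auroc > p_auroc

    def test_unknown_branch_errors(self, rng):
        with pytest.raises(ValidationError):
            train_model("nope", _tiny_bulk(rng), _tiny_config())


class TestGridSearch:
    def test_phase_tables_have_grid_products(self, rng):
        data = _tiny_bulk(rng)
        cfg = _tiny_config()
        calls = []

        def scorer(branch, d, c):
            calls.append((c.learning_rate, c.batch_size, c.n_heads,
                          c.dropout))
            return 0.5

        best, p1, p2 = grid_search(data, cfg, scorer=scorer)
        assert len(p1) == 16  # 4 learning rates × 4 batch sizes
        assert len(p2) == 20  # 4 head counts × 5 dropout rates
        assert len(calls) == 36

    def test_tie_break_smaller_lr_then_smaller_dropout(self, rng):
        data = _tiny_bulk(rng)
        cfg = _tiny_config()
        best, p1, p2 = grid_search(data, cfg, scorer=lambda *a: 0.7)
        assert best.learning_rate == min(cfg.lr_grid)
        assert best.dropout == min(cfg.dropout_grid)

    def test_singleton_grids_single_evaluation(self, rng):
        data = _tiny_bulk(rng)
        cfg = _tiny_config(lr_grid=(1e-3,), batch_grid=(16,),
                           heads_grid=(2,), dropout_grid=(0.2,))
        n = [0]

        def scorer(branch, d, c):
            n[0] += 1
            return 0.9

        best, p1, p2 = grid_search(data, cfg, scorer=scorer)
        assert (len(p1), len(p2), n[0]) == (1, 1, 2)
        assert (best.learning_rate, best.n_heads) == (1e-3, 2)

    def test_phase_two_fixes_phase_one_winner(self, rng):
        data = _tiny_bulk(rng)
        cfg = _tiny_config()
        seen = []

        def scorer(branch, d, c):
            seen.append(c)
            return c.learning_rate  # largest lr wins phase 1
        best, p1, p2 = grid_search(data, cfg, scorer=scorer)
        phase2_cfgs = seen[16:]
        assert all(c.learning_rate == max(cfg.lr_grid) for c in phase2_cfgs)


class TestArchitectureDefaults:
    def test_head_sizes_follow_published_widths(self):
        cfg = TrainingConfig()
        assert cfg.head_sizes() == (512, 128)
        assert TrainingConfig(extra_head_layer=True).head_sizes() == \
            (512, 128, 32)

    def test_grids_match_published_search_space(self):
        cfg = TrainingConfig()
        assert cfg.lr_grid == (1e-2, 1e-3, 1e-4, 1e-5)
        assert cfg.batch_grid == (32, 64, 128, 256)
        assert cfg.heads_grid == (1, 2, 3, 4)
        assert cfg.dropout_grid == (0.1, 0.2, 0.3, 0.4, 0.5)

    def test_joint_dim_divisible_by_stride(self):
        with pytest.raises(ValidationError):
            TrainingConfig(joint_dim=100)

    def test_scaled_config_keeps_stride_rule(self):
        cfg = scaled_config()
        assert cfg.joint_dim % cfg.sum_pool_stride == 0


class TestCheckpoints:
    def test_bulk_round_trip_predictions_identical(self, rng, tmp_path):
        from icipred.training import load_model, save_model
        data = _tiny_bulk(rng)
        model, _ = train_model("bulk", data, _tiny_config(seed=4))
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        np.testing.assert_array_equal(model.predict(data),
                                      back.predict(data))

    def test_config_round_trips_through_serialization(self):
        import dataclasses
        cfg = _tiny_config(n_heads=3, dropout=0.25)
        d = dataclasses.asdict(cfg)
        for key in ("head_hidden", "lr_grid", "batch_grid", "heads_grid",
                    "dropout_grid"):
            d[key] = tuple(d[key])
        assert TrainingConfig(**d) == cfg


class TestSCModelForward:
    def test_sc_training_runs_and_predicts(self, small_sc_prep):
        ds = small_sc_prep.dataset
        cfg = _tiny_config(epochs=5, batch_size=16, chain_width=480)
        model, history = train_model("single_cell", ds, cfg)
        scores = model.predict(ds)
        assert scores.shape == (len(ds),)
        assert np.all((scores > 0) & (scores < 1))

    def test_sc_same_seed_reproducible(self, small_sc_prep):
        ds = small_sc_prep.dataset
        cfg = _tiny_config(epochs=3, dropout=0.0, seed=8, chain_width=480)
        m1, _ = train_model("single_cell", ds, cfg)
        m2, _ = train_model("single_cell", ds, cfg)
        np.testing.assert_array_equal(m1.predict(ds), m2.predict(ds))
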