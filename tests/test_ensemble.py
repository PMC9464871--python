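"""Member training, checkpointing, vote aggregation, persistence."""

import itertools

import numpy as np
import pytest

from noisyensemble import (
    TrainConfig,
    VoteMatrix,
    group_accuracy,
    load_ensemble,
    majority_vote,
    make_member_splits,
    make_site_splits,
    inject_label_noise,
    predict_members,
    save_ensemble,
    select_single_class,
    train_ensemble,
    train_member,
)
from noisyensemble.backends import BACKENDS
from noisyensemble.simulate import default_sites, generate_cohort


# ---------------------------------------------------------------------------
# scripted backend: emits prescribed validation accuracies per epoch


class ScriptedBackend:
    """Test double whose validation predictions follow a script.

    Epoch t predicts the first ``round(acc*n)`` validation samples correctly;
    used to pin down checkpoint selection without real training.
    """

    script = (0.6, 0.8, 0.75, 0.8, 0.7, 0.6, 0.6, 0.6, 0.6, 0.6)

    def __init__(self):
        self.epoch = 0
        self._y = None

    def setup(self, input_shape, seed):
        pass

    def train_epoch(self, X, y):
        self.epoch += 1
        return 0.0

    def predict_proba(self, X):
        # correctness is arranged by the test via the `_truth` class attribute
        n = len(X)
        acc = self.script[min(self.epoch, len(self.script)) - 1]
        k = int(round(acc * n))
        out = np.where(np.arange(n) < k, self._truth[:n], 1 - self._truth[:n])
        return out.astype(float)

    def get_state(self):
        return {"epoch": np.asarray(self.epoch)}

    def set_state(self, state):
        self.epoch = int(state["epoch"])


class TestTrainMemberCheckpoint:
    def test_best_epoch_is_earliest_of_tied_maxima(self, monkeypatch):
        """Validation accuracies [.6,.8,.75,.8,.7,...] checkpoint epoch 2."""
        monkeypatch.setitem(BACKENDS, "scripted", ScriptedBackend)
        y_val = np.array([0, 1] * 10)
        ScriptedBackend._truth = y_val
        cfg = TrainConfig(n_members=3, epochs=10, backend_name="scripted")
        member = train_member(
            np.zeros((4, 2)), np.array([0, 1, 0, 1]),
            np.zeros((20, 2)), y_val, cfg, member_seed=0,
        )
        assert member.best_epoch == 2
        assert member.best_val_accuracy == pytest.approx(0.8)
        # restored state is the epoch-2 checkpoint
        assert member.backend.epoch == 2

    def test_single_epoch_returns_that_checkpoint(self, monkeypatch):
        monkeypatch.setitem(BACKENDS, "scripted", ScriptedBackend)
        y_val = np.array([0, 1] * 5)
        ScriptedBackend._truth = y_val
        cfg = TrainConfig(n_members=3, epochs=1, backend_name="scripted")
        member = train_member(
            np.zeros((4, 2)), np.array([0, 1, 0, 1]),
            np.zeros((10, 2)), y_val, cfg, member_seed=0,
        )
        assert member.best_epoch == 1

    def test_single_class_training_set_rejected(self):
        cfg = TrainConfig(n_members=3, epochs=1, backend_name="linear")
        with pytest.raises(ValueError, match="single-class training set"):
            train_member(
                np.zeros((4, 2)), np.array([1, 1, 1, 1]),
                np.zeros((2, 2)), np.array([0, 1]), cfg, member_seed=0,
            )

    def test_separable_solid_colors_reach_perfect_validation(self):
        """Two solid-colour tile populations are separable by mean channel
        value; the default CNN reaches validation accuracy 1.0 in 10 epochs."""
        rng = np.random.default_rng(0)
        dark = np.full((20, 32, 32, 3), 0.25) + rng.normal(0, 0.01, (20, 32, 32, 3))
        light = np.full((20, 32, 32, 3), 0.75) + rng.normal(0, 0.01, (20, 32, 32, 3))
        X = np.concatenate([dark, light]).astype(np.float32).clip(0, 1)
        y = np.repeat([0, 1], 20)
        idx = rng.permutation(40)
        cfg = TrainConfig(n_members=3, epochs=10)
        member = train_member(X[idx[:28]], y[idx[:28]], X[idx[28:]], y[idx[28:]],
                              cfg, member_seed=1)
        assert member.best_val_accuracy == 1.0


# ---------------------------------------------------------------------------
# vote aggregation


def brute_force_vote(row):
    """Independent tally oracle for a single vote row."""
    ones = sum(int(v) for v in row)
    zeros = len(row) - ones
    label = 1 if ones > zeros else 0
    return label, max(ones, zeros)


class TestVotes:
    def test_unanimous_row(self):
        vm = VoteMatrix(("t",), np.ones((1, 15)))
        labels, agreement = majority_vote(vm)
        assert labels[0] == 1 and agreement[0] == 15

    def test_eight_to_seven(self):
        vm = VoteMatrix(("t",), np.array([[0] * 8 + [1] * 7]))
        labels, agreement = majority_vote(vm)
        assert labels[0] == 0 and agreement[0] == 8

    def test_all_patterns_n7_match_brute_force(self):
        rows = np.array(list(itertools.product([0, 1], repeat=7)))
        vm = VoteMatrix(tuple(map(str, range(len(rows)))), rows)
        labels, agreement = majority_vote(vm)
        for i, row in enumerate(rows):
            lab, agr = brute_force_vote(row)
            assert labels[i] == lab
            assert agreement[i] == agr
            assert row.sum() + (7 - row.sum()) == 7
            assert 4 <= agr <= 7

    def test_even_member_count_rejected(self):
        vm = VoteMatrix(("t",), np.array([[0, 1]]))
        with pytest.raises(ValueError, match="odd"):
            majority_vote(vm)

    def test_group_accuracy_mean_of_member_accuracies(self):
        truth = {"a": 1, "b": 0}
        vm = VoteMatrix(("a", "b"), np.array([[1, 0], [0, 0]]))
        # member 0: both correct (1.0); member 1: one correct (0.5)
        assert group_accuracy(vm, truth) == pytest.approx(0.75)

    def test_group_accuracy_random_matrix_recount(self):
        rng = np.random.default_rng(3)
        votes = rng.integers(0, 2, (5, 3))
        truth = {str(i): int(v) for i, v in enumerate(rng.integers(0, 2, 5))}
        vm = VoteMatrix(tuple(map(str, range(5))), votes)
        y = np.array([truth[str(i)] for i in range(5)])
        expected = np.mean([np.mean(votes[:, j] == y) for j in range(3)])
        assert group_accuracy(vm, truth) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# full ensembles on a small rendered cohort


@pytest.fixture(scope="module")
def small_trained_ensemble():
    cohort, images = generate_cohort(default_sites((8, 8, 8)), 4, 64, seed=21)
    plan = make_site_splits(cohort, "A", 2, 1, seed=1)[0]
    retained, choice = select_single_class(cohort, plan.pool_patients, seed=2)
    plan = make_member_splits(plan, 3, 0.34, seed=3)
    noise_plan = inject_label_noise(retained, 0.15, seed=4, patient_class_choice=choice)
    cfg = TrainConfig(n_members=3, epochs=3, seed=5)
    ens = train_ensemble(cohort, plan, noise_plan, cfg, images)
    return cohort, images, plan, noise_plan, ens


class TestTrainEnsemble:
    def test_member_count_and_partitions(self, small_trained_ensemble):
        _, _, plan, _, ens = small_trained_ensemble
        assert ens.n_members == 3 == len(plan.member_partitions)
        assert ens.noise_plan is not None and ens.split_plan is not None

    def test_partition_mismatch_rejected(self, small_trained_ensemble):
        cohort, images, plan, noise_plan, _ = small_trained_ensemble
        cfg = TrainConfig(n_members=5, epochs=1)
        with pytest.raises(ValueError, match="member partitions"):
            train_ensemble(cohort, plan, noise_plan, cfg, images)

    def test_noise_levels_share_partitions(self, small_trained_ensemble):
        """rho=0 and rho=0.15 plans differ only in flipped labels."""
        cohort, _, plan, noise_plan, _ = small_trained_ensemble
        clean = inject_label_noise(
            noise_plan.retained_tiles, 0.0, seed=noise_plan.seed,
            patient_class_choice=noise_plan.patient_class_choice,
        )
        assert clean.retained_tiles == noise_plan.retained_tiles
        assert clean.patient_class_choice == noise_plan.patient_class_choice
        assert clean.flipped_tiles == frozenset()
        assert len(noise_plan.flipped_tiles) > 0

    def test_predict_members_aligned_and_binary(self, small_trained_ensemble):
        cohort, images, plan, _, ens = small_trained_ensemble
        tiles = cohort.tiles_of_patients(plan.test_patients)
        votes = predict_members(ens, tiles, images)
        assert votes.votes.shape == (len(tiles), 3)
        assert votes.tile_ids == tuple(t.tile_id for t in tiles)
        assert set(np.unique(votes.votes)) <= {0, 1}

    def test_missing_image_named(self, small_trained_ensemble):
        cohort, images, plan, _, ens = small_trained_ensemble
        tiles = cohort.tiles_of_patients(plan.test_patients)
        broken = {k: v for k, v in images.items() if k != tiles[0].tile_id}
        with pytest.raises(ValueError, match=tiles[0].tile_id):
            predict_members(ens, tiles, broken)

    def test_save_load_round_trip(self, small_trained_ensemble, tmp_path):
        cohort, images, plan, _, ens = small_trained_ensemble
        tiles = cohort.tiles_of_patients(plan.test_patients)
        save_ensemble(ens, tmp_path / "ens")
        back = load_ensemble(tmp_path / "ens")
        v1 = predict_members(ens, tiles, images)
        v2 = predict_members(back, tiles, images)
        assert np.array_equal(v1.votes, v2.votes)
        assert back.split_plan == ens.split_plan
        assert back.noise_plan == ens.noise_plan


def test_vote_threshold_is_inclusive_at_half():
    """A member probability of exactly 0.5 votes for class 1."""

    class Fixed:
        def __init__(self, p):
            self.p = p

        def predict_proba(self, X):
            return np.full(len(X), self.p)

    from noisyensemble.ensemble import MemberModel

    m = MemberModel(backend=Fixed(0.5), best_val_accuracy=1.0, best_epoch=1,
                    val_accuracy_history=(1.0,))
    assert m.predict(np.zeros((3, 2))).tolist() == [1, 1, 1]


def test_train_config_validation():
    with pytest.raises(ValueError, match="odd"):
        TrainConfig(n_members=4)
    with pytest.raises(ValueError, match="epochs"):
        TrainConfig(n_members=3, epochs=0)
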