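"""Scikit-learn-style estimator wrapping the noisy-ensemble procedure.

``NoisyEnsembleClassifier`` composes the full mechanism — per-patient
single-class tile selection, exact-fraction label flipping, member-specific
patient-level train/validation partitions, best-epoch checkpointing and
majority voting — behind a fit/predict surface, so it can be dropped into
sklearn pipelines and model selection.  Patient identities are passed to
``fit`` via ``groups``; without them every sample is treated as its own
patient (plain bagging with label noise).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._util import derive_rng, derive_seed, round_half_up
from .cohort import _distinct_validation_sets
from .ensemble import TrainConfig, VoteMatrix, train_member

__all__ = ["NoisyEnsembleClassifier"]


class NoisyEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Bagging ensemble trained with deliberate label-flip noise.

    Parameters
    ----------
    n_members : odd number of ensemble members.
    noise_rate : fraction rho in [0, 0.5) of retained training tiles whose
        labels are flipped (exactly ⌊rho·N⌉ tiles, drawn uniformly).
    epochs : training epochs per member; the checkpoint with the best
        validation accuracy is kept (earliest epoch on ties).
    val_fraction : fraction of training patients held out per member for
        validation (distinct validation sets across members).
    single_class_per_patient : when True (the defining constraint of the
        method) only one class of tiles per patient is used for training.
    balance_classes : balance retained tile counts across the two classes
        when choosing each patient's retained class.
    backend : backend registry name ("small_cnn" or "linear").
    backend_params : constructor parameters forwarded to the backend.
    random_state : seed for all randomness (splits, flips, initialisation).

    Attributes
    ----------
    classes_ : the two class labels seen in ``y`` (sorted).
    members_ : list of trained MemberModel objects.
    member_partitions_ : per-member (train, validation) sample-index tuples.
    flipped_indices_ : indices of training samples whose labels were flipped.
    retained_indices_ : indices of samples kept by single-class selection.
    class_choice_ : group -> retained class (as indices into ``classes_``).
    """

    def __init__(
        self,
        n_members: int = 15,
        noise_rate: float = 0.0,
        epochs: int = 10,
        val_fraction: float = 0.2,
        single_class_per_patient: bool = True,
        balance_classes: bool = True,
        backend: str = "small_cnn",
        backend_params: dict | None = None,
        random_state: int | None = None,
    ):
        self.n_members = n_members
        self.noise_rate = noise_rate
        self.epochs = epochs
        self.val_fraction = val_fraction
        self.single_class_per_patient = single_class_per_patient
        self.balance_classes = balance_classes
        self.backend = backend
        self.backend_params = backend_params
        self.random_state = random_state

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y, groups=None):
        X = np.asarray(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y have inconsistent lengths")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("NoisyEnsembleClassifier is a binary classifier")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must satisfy 0 <= rho < 0.5")
        y01 = (y == self.classes_[1]).astype(int)
        seed = 0 if self.random_state is None else int(self.random_state)
        if groups is None:
            groups = np.arange(len(X))
        groups = np.asarray(groups)

        # --- single-class selection per group
        group_ids = sorted({str(g) for g in groups}, key=str)
        idx_of_group = {g: np.flatnonzero(groups.astype(str) == g) for g in group_ids}
        rng = derive_rng(seed, "estimator-single-class")
        order = list(group_ids)
        rng.shuffle(order)
        counts = [0, 0]
        class_choice: dict[str, int] = {}
        retained: list[int] = []
        for g in order:
            idx = idx_of_group[g]
            present = set(y01[idx])
            if not self.single_class_per_patient:
                retained.extend(idx)
                continue
            if len(present) == 1:
                c = present.pop()
            elif self.balance_classes:
                c = (
                    0 if counts[0] < counts[1]
                    else 1 if counts[1] < counts[0]
                    else int(rng.integers(2))
                )
            else:
                c = int(rng.integers(2))
            class_choice[g] = c
            kept = idx[y01[idx] == c]
            counts[c] += len(kept)
            retained.extend(kept)
        retained = np.array(sorted(retained))
        self.retained_indices_ = retained
        self.class_choice_ = class_choice

        # --- exact-fraction label flips over the retained set
        n_flip = round_half_up(self.noise_rate * len(retained))
        flip_rng = derive_rng(seed, "estimator-noise")
        flipped = (
            np.sort(flip_rng.choice(retained, size=n_flip, replace=False))
            if n_flip
            else np.array([], dtype=int)
        )
        self.flipped_indices_ = flipped
        y_train = y01.copy()
        y_train[flipped] = 1 - y_train[flipped]

        # --- member partitions at the group level
        retained_groups = sorted({str(groups[i]) for i in retained})
        val_size = max(1, round_half_up(self.val_fraction * len(retained_groups)))
        if val_size >= len(retained_groups):
            raise ValueError("val_fraction leaves no training groups")
        part_rng = derive_rng(seed, "estimator-partitions")
        val_sets = _distinct_validation_sets(
            retained_groups, self.n_members, val_size, part_rng
        )
        retained_set = set(retained.tolist())
        config = TrainConfig(
            n_members=self.n_members,
            epochs=self.epochs,
            backend_name=self.backend,
            backend_params=self.backend_params,
            seed=seed,
        )
        members = []
        partitions = []
        for i, val_groups in enumerate(val_sets):
            val_g = set(val_groups)
            tr_idx = np.array(
                [
                    j
                    for g in retained_groups
                    if g not in val_g
                    for j in idx_of_group[g]
                    if j in retained_set
                ]
            )
            va_idx = np.array(
                [j for g in sorted(val_g) for j in idx_of_group[g] if j in retained_set]
            )
            partitions.append((tuple(tr_idx.tolist()), tuple(va_idx.tolist())))
            member_seed = derive_seed(seed, "estimator-member", i)
            members.append(
                train_member(
                    X[tr_idx], y_train[tr_idx], X[va_idx], y01[va_idx],
                    config, member_seed, member_index=i,
                )
            )
        self.members_ = members
        self.member_partitions_ = tuple(partitions)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else int(np.prod(X.shape[1:]))
        return self

    # -- prediction ----------------------------------------------------------

    def predict_votes(self, X) -> VoteMatrix:
        """Raw member votes as a VoteMatrix (tile ids are row indices)."""
        check_is_fitted(self, "members_")
        X = np.asarray(X)
        votes = np.stack([m.predict(X) for m in self.members_], axis=1)
        return VoteMatrix(tuple(str(i) for i in range(len(X))), votes)

    def predict(self, X):
        vm = self.predict_votes(X)
        return self.classes_[vm.ensemble_label]

    def predict_proba(self, X):
        """Fraction of member votes per class (the only score the vote-based
        design provides)."""
        frac = self.predict_votes(X).votes_for_1 / self.n_members
        return np.column_stack([1 - frac, frac])

    def agreement(self, X) -> np.ndarray:
        """Ensemble confidence: members matching the majority label per tile."""
        return self.predict_votes(X).agreement
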