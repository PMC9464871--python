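"""Bagging-ensemble training with best-epoch checkpointing and majority vote.

Each ensemble consists of an odd number of members (default 15) trained on
the same (possibly label-flipped) training labels but member-specific
patient-level train/validation partitions.  After every epoch, validation
accuracy is measured and the member keeps the weights of its best epoch
(earliest epoch on ties).  Predictions are binary votes (probability >= 0.5);
the ensemble label is the majority vote and the ensemble's confidence in a
tile is its agreement: the number of members matching the majority label.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import derive_seed
from .backends import get_backend
from .cohort import Cohort, SplitPlan
from .noise import NoisePlan, apply_noise

__all__ = [
    "TrainConfig",
    "MemberModel",
    "EnsembleModel",
    "VoteMatrix",
    "train_member",
    "train_ensemble",
    "predict_members",
    "majority_vote",
    "group_accuracy",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration shared by all members of an ensemble."""

    n_members: int = 15
    epochs: int = 10
    backend_name: str = "small_cnn"
    backend_params: Mapping | None = None
    optimizer_name: str = "adamax"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 3 or self.n_members % 2 == 0:
            raise ValueError("n_members must be odd and >= 3")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_members": self.n_members,
            "epochs": self.epochs,
            "backend_name": self.backend_name,
            "backend_params": dict(self.backend_params or {}),
            "optimizer_name": self.optimizer_name,
            "seed": self.seed,
        }


@dataclass
class MemberModel:
    """One trained member: a frozen backend plus its checkpoint metadata."""

    backend: object
    best_val_accuracy: float
    best_epoch: int
    val_accuracy_history: tuple[float, ...]
    member_index: int = 0
    repeat_index: int = 0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.backend.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.int8)


def train_member(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    member_seed: int,
    member_index: int = 0,
    repeat_index: int = 0,
) -> MemberModel:
    """Train one member, keeping the checkpoint with the best validation
    accuracy (ties resolved toward the earliest epoch)."""
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training set")
    backend = get_backend(config.backend_name, config.backend_params)
    backend.setup(tuple(np.asarray(X_train).shape[1:]), seed=member_seed)
    best_acc, best_epoch, best_state = -1.0, -1, None
    history = []
    for epoch in range(1, config.epochs + 1):
        backend.train_epoch(X_train, y_train)
        val_pred = (backend.predict_proba(X_val) >= 0.5).astype(int)
        acc = float(np.mean(val_pred == y_val))
        history.append(acc)
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_state = backend.get_state()
    backend.set_state(best_state)
    return MemberModel(
        backend=backend,
        best_val_accuracy=best_acc,
        best_epoch=best_epoch,
        val_accuracy_history=tuple(history),
        member_index=member_index,
        repeat_index=repeat_index,
    )


@dataclass
class VoteMatrix:
    """Per-tile binary votes of all members (rows: tiles, columns: members)."""

    tile_ids: tuple[str, ...]
    votes: np.ndarray  # (n_tiles, n_members) of {0, 1}

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=np.int8)
        if self.votes.ndim != 2 or len(self.tile_ids) != self.votes.shape[0]:
            raise ValueError("votes must be (n_tiles, n_members) aligned with tile_ids")
        if not np.isin(self.votes, (0, 1)).all():
            raise ValueError("votes must be binary")

    @property
    def n_members(self) -> int:
        return self.votes.shape[1]

    @property
    def votes_for_1(self) -> np.ndarray:
        return self.votes.sum(axis=1)

    @property
    def ensemble_label(self) -> np.ndarray:
        return (self.votes_for_1 * 2 > self.n_members).astype(np.int8)

    @property
    def agreement(self) -> np.ndarray:
        v1 = self.votes_for_1
        return np.maximum(v1, self.n_members - v1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.votes, columns=[f"member_{i}" for i in range(self.n_members)]
        )
        df.insert(0, "tile_id", list(self.tile_ids))
        df["ensemble_label"] = self.ensemble_label
        df["agreement"] = self.agreement
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VoteMatrix":
        member_cols = [c for c in df.columns if c.startswith("member_")]
        return cls(tuple(df["tile_id"].astype(str)), df[member_cols].to_numpy())


def majority_vote(matrix: VoteMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(ensemble labels, agreement counts); requires an odd member count."""
    if matrix.n_members % 2 == 0:
        raise ValueError("majority vote requires an odd number of members")
    return matrix.ensemble_label, matrix.agreement


def group_accuracy(matrix: VoteMatrix, truth: Mapping[str, int]) -> float:
    """Mean over members of per-member tile accuracy ("group" performance)."""
    y = np.array([truth[t] for t in matrix.tile_ids])
    return float((matrix.votes == y[:, None]).mean(axis=0).mean())


@dataclass
class EnsembleModel:
    """A trained ensemble with full provenance (split and noise plans)."""

    members: list[MemberModel]
    config: TrainConfig
    split_plan: SplitPlan | None = None
    noise_plan: NoisePlan | None = None
    input_shape: tuple[int, ...] = ()

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict_votes(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m.predict(X) for m in self.members], axis=1)


def _stack_images(
    tiles: Sequence, images: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, list[str]]:
    ids = [t.tile_id for t in tiles]
    missing = [t for t in ids if t not in images]
    if missing:
        raise ValueError(f"unreadable or missing image for tiles: {missing[:5]}")
    return np.stack([images[t] for t in ids]), ids


def train_ensemble(
    cohort: Cohort,
    plan: SplitPlan,
    noise_plan: NoisePlan,
    config: TrainConfig,
    images: Mapping[str, np.ndarray],
) -> EnsembleModel:
    """Train all members on noise-applied labels over the plan's partitions.

    Member i trains on the retained tiles of its train patients with flipped
    labels per the noise plan; validation uses the retained tiles of its
    validation patients with ground-truth labels (checkpoint selection must
    not be corrupted by the injected noise).
    """
    if len(plan.member_partitions) != config.n_members:
        raise ValueError(
            f"plan has {len(plan.member_partitions)} member partitions; "
            f"config.n_members = {config.n_members}"
        )
    retained = set(noise_plan.retained_tiles)
    train_labels = apply_noise(
        [cohort.tile(t) for t in noise_plan.retained_tiles], noise_plan
    )
    members = []
    for i, (train_pat, val_pat) in enumerate(plan.member_partitions):
        train_tiles = [
            cohort.tile(t)
            for p in train_pat
            for t in cohort.patients[p].tile_ids
            if t in retained
        ]
        val_tiles = [
            cohort.tile(t)
            for p in val_pat
            for t in cohort.patients[p].tile_ids
            if t in retained
        ]
        X_tr, ids_tr = _stack_images(train_tiles, images)
        X_va, _ = _stack_images(val_tiles, images)
        y_tr = np.array([train_labels[t] for t in ids_tr])
        y_va = np.array([t.class_label for t in val_tiles])
        member_seed = derive_seed(config.seed, "member", plan.repeat_index, i)
        try:
            member = train_member(
                X_tr, y_tr, X_va, y_va, config, member_seed,
                member_index=i, repeat_index=plan.repeat_index,
            )
        except ValueError as exc:
            raise ValueError(f"member {i}: {exc}") from exc
        members.append(member)
    return EnsembleModel(
        members=members,
        config=config,
        split_plan=plan,
        noise_plan=noise_plan,
        input_shape=tuple(np.asarray(X_tr).shape[1:]),
    )


def predict_members(
    ensemble: EnsembleModel,
    tiles: Sequence,
    images: Mapping[str, np.ndarray],
) -> VoteMatrix:
    """Vote matrix of all members over the given tiles (vote 1 iff p >= 0.5)."""
    X, ids = _stack_images(tiles, images)
    return VoteMatrix(tuple(ids), ensemble.predict_votes(X))


# ---------------------------------------------------------------------------
# persistence


def _plan_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def save_ensemble(ensemble: EnsembleModel, path: str | Path) -> None:
    """Persist as a directory: per-member .npz weights + a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": ensemble.config.to_dict(),
        "input_shape": list(ensemble.input_shape),
        "members": [],
    }
    for i, m in enumerate(ensemble.members):
        np.savez(path / f"member_{i:02d}.npz", **{
            k: v for k, v in _flatten_state(m.backend.get_state()).items()
        })
        manifest["members"].append(
            {
                "index": i,
                "best_val_accuracy": m.best_val_accuracy,
                "best_epoch": m.best_epoch,
                "val_accuracy_history": list(m.val_accuracy_history),
                "repeat_index": m.repeat_index,
            }
        )
    if ensemble.split_plan is not None:
        text = ensemble.split_plan.to_json()
        (path / "split_plan.json").write_text(text)
        manifest["split_plan_hash"] = _plan_hash(text)
    if ensemble.noise_plan is not None:
        text = ensemble.noise_plan.to_json()
        (path / "noise_plan.json").write_text(text)
        manifest["noise_plan_hash"] = _plan_hash(text)
    (path / "ensemble.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _flatten_state(state: Mapping) -> dict[str, np.ndarray]:
    flat = {}
    for k, v in state.items():
        if isinstance(v, Mapping):
            for k2, v2 in _flatten_state(v).items():
                flat[f"{k}.{k2}"] = v2
        elif v is None:
            continue
        else:
            flat[k] = np.asarray(v)
    return flat


def _unflatten_state(flat: Mapping[str, np.ndarray]) -> dict:
    out: dict = {}
    for k, v in flat.items():
        parts = k.split(".")
        d = out
        for p in parts[:-1]:
            d = d.setdefault(p, {})
        d[parts[-1]] = v
    return out


def load_ensemble(path: str | Path) -> EnsembleModel:
    path = Path(path)
    manifest = json.loads((path / "ensemble.json").read_text())
    config = TrainConfig(**manifest["config"])
    members = []
    for entry in manifest["members"]:
        i = entry["index"]
        with np.load(path / f"member_{i:02d}.npz") as data:
            flat = {k: data[k] for k in data.files}
        backend = get_backend(config.backend_name, config.backend_params)
        backend.setup(tuple(manifest["input_shape"]), seed=0)
        state = _unflatten_state(flat)
        if config.backend_name == "linear":
            state.setdefault("mu", None)
            state.setdefault("sd", None)
        backend.set_state(state)
        members.append(
            MemberModel(
                backend=backend,
                best_val_accuracy=entry["best_val_accuracy"],
                best_epoch=entry["best_epoch"],
                val_accuracy_history=tuple(entry["val_accuracy_history"]),
                member_index=i,
                repeat_index=entry.get("repeat_index", 0),
            )
        )
    split_plan = noise_plan = None
    if (path / "split_plan.json").exists():
        split_plan = SplitPlan.from_json((path / "split_plan.json").read_text())
    if (path / "noise_plan.json").exists():
        noise_plan = NoisePlan.from_json((path / "noise_plan.json").read_text())
    return EnsembleModel(
        members=members,
        config=config,
        split_plan=split_plan,
        noise_plan=noise_plan,
        input_shape=tuple(manifest["input_shape"]),
    )
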