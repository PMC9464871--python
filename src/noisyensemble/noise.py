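"""Deliberate label perturbation for noisy-ensemble training.

Two steps define the perturbation: (1) per training patient, keep only the
tiles of one class ("single-class constraint"); (2) flip the labels of an
exact fraction rho of the retained tiles, chosen uniformly at random across
patients and classes.  Ground-truth labels are never mutated — training label
maps are derived views.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

from ._util import derive_rng, round_half_up
from .cohort import Cohort, TileRecord

__all__ = [
    "NoisePlan",
    "DEFAULT_NOISE_LEVELS",
    "select_single_class",
    "inject_label_noise",
    "apply_noise",
]

DEFAULT_NOISE_LEVELS = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass(frozen=True)
class NoisePlan:
    """A replayable record of one noise draw.

    ``flipped_tiles`` always has exactly ⌊rho·N⌉ elements, N being the number
    of retained training tiles, and every flipped tile is a retained tile.
    """

    rho: float
    seed: int
    patient_class_choice: Mapping[str, int]
    retained_tiles: tuple[str, ...]
    flipped_tiles: frozenset[str]

    def __post_init__(self) -> None:
        if not set(self.flipped_tiles) <= set(self.retained_tiles):
            raise ValueError("flipped tiles must be a subset of retained tiles")
        expected = round_half_up(self.rho * len(self.retained_tiles))
        if len(self.flipped_tiles) != expected:
            raise ValueError(
                f"plan has {len(self.flipped_tiles)} flips; "
                f"⌊rho·N⌉ = {expected} required"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "rho": self.rho,
                "seed": self.seed,
                "patient_class_choice": dict(self.patient_class_choice),
                "retained_tiles": list(self.retained_tiles),
                "flipped_tiles": sorted(self.flipped_tiles),
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "NoisePlan":
        d = json.loads(text)
        return cls(
            rho=d["rho"],
            seed=d["seed"],
            patient_class_choice=d["patient_class_choice"],
            retained_tiles=tuple(d["retained_tiles"]),
            flipped_tiles=frozenset(d["flipped_tiles"]),
        )


def _tiles_by_patient(
    cohort: Cohort, training_patients: Iterable[str]
) -> dict[str, list[TileRecord]]:
    return {
        pid: [cohort.tile(tid) for tid in cohort.patients[pid].tile_ids]
        for pid in sorted(set(training_patients))
    }


def select_single_class(
    cohort: Cohort,
    training_patients: Iterable[str],
    seed: int,
    balance: bool = True,
) -> tuple[tuple[str, ...], dict[str, int]]:
    """Keep, per training patient, only the tiles of one class.

    Patients whose tiles all carry one class are forced to that class.  With
    ``balance=True`` (default) the remaining choices are made greedily in a
    seeded random patient order so the retained per-class tile counts stay
    within one patient's tile count of each other; with ``balance=False``
    each choice is a fair seeded coin.

    Returns (retained tile ids sorted, patient -> retained class).
    """
    by_patient = _tiles_by_patient(cohort, training_patients)
    if not by_patient:
        raise ValueError("empty training patient set")
    rng = derive_rng(seed, "single-class")
    order = list(by_patient)
    rng.shuffle(order)
    counts = [0, 0]  # retained tiles per class
    choice: dict[str, int] = {}
    retained: list[str] = []
    for pid in order:
        tiles = by_patient[pid]
        present = {t.class_label for t in tiles}
        if len(present) == 1:
            c = present.pop()
        elif balance:
            c = 0 if counts[0] < counts[1] else 1 if counts[1] < counts[0] else int(
                rng.integers(2)
            )
        else:
            c = int(rng.integers(2))
        choice[pid] = c
        kept = [t.tile_id for t in tiles if t.class_label == c]
        counts[c] += len(kept)
        retained.extend(kept)
    return tuple(sorted(retained)), choice


def inject_label_noise(
    retained_tiles: Iterable[str],
    rho: float,
    seed: int,
    patient_class_choice: Mapping[str, int] | None = None,
) -> NoisePlan:
    """Select exactly ⌊rho·N⌉ retained tiles, uniformly without replacement,
    for label flipping.  rho must satisfy 0 <= rho < 0.5."""
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if rho >= 0.5:
        raise ValueError("noise level would exceed label informativeness")
    retained = tuple(sorted(set(retained_tiles)))
    k = round_half_up(rho * len(retained))
    rng = derive_rng(seed, "label-noise")
    flipped = frozenset(rng.choice(retained, size=k, replace=False)) if k else frozenset()
    return NoisePlan(
        rho=rho,
        seed=seed,
        patient_class_choice=dict(patient_class_choice or {}),
        retained_tiles=retained,
        flipped_tiles=flipped,
    )


def apply_noise(
    tiles: Iterable[TileRecord] | Mapping[str, int], plan: NoisePlan
) -> dict[str, int]:
    """Training label map: flipped tiles get 1 - label, all others the label.

    ``tiles`` may be TileRecords (labels taken from ground truth) or an
    existing tile_id -> label mapping; applying the same plan twice restores
    the original labels (flipping is an involution).
    """
    if isinstance(tiles, Mapping):
        labels = dict(tiles)
    else:
        labels = {t.tile_id: t.class_label for t in tiles}
    unknown = set(plan.flipped_tiles) - set(labels)
    if unknown:
        raise ValueError(f"plan references unknown tiles: {sorted(unknown)[:5]}")
    for tid in plan.flipped_tiles:
        labels[tid] = 1 - labels[tid]
    return labels
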