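"""Tile/patient data model and all patient-level splitting logic.

Splits are always drawn at the patient level: tiles of one patient never
appear on both sides of any train/validation/test boundary.  A repeat's
train+validation pool is subdivided into one (train, validation) partition
per ensemble member, with validation sets required to be pairwise distinct
as patient sets (bagging-style overlap between train sets is allowed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import derive_rng, round_half_up

__all__ = [
    "TileRecord",
    "Cohort",
    "SplitPlan",
    "read_manifest",
    "write_manifest",
    "make_repeat_splits",
    "make_member_splits",
    "make_site_splits",
    "check_split_plan",
]

MANIFEST_COLUMNS = [
    "tile_id",
    "patient_id",
    "site_id",
    "quality_grade",
    "class_label",
    "image_path",
]


@dataclass(frozen=True)
class TileRecord:
    """One image tile: identity, provenance and ground-truth label."""

    tile_id: str
    patient_id: str
    site_id: str
    quality_grade: int
    class_label: int
    image_path: str = ""

    def __post_init__(self) -> None:
        if self.class_label not in (0, 1):
            raise ValueError(
                f"tile {self.tile_id!r}: class_label must be 0 or 1, "
                f"got {self.class_label!r}"
            )
        if self.quality_grade not in (1, 2, 3):
            raise ValueError(
                f"tile {self.tile_id!r}: quality_grade must be 1, 2 or 3, "
                f"got {self.quality_grade!r}"
            )


@dataclass(frozen=True)
class PatientInfo:
    site_id: str
    quality_grade: int
    tile_ids: tuple[str, ...]


class Cohort:
    """An immutable collection of tiles with a derived patient index.

    Each patient belongs to exactly one site; a patient's quality grade is
    the modal grade of its tiles (grades are assigned per case, so normally
    all tiles of a patient share one grade).
    """

    def __init__(self, tiles: Iterable[TileRecord], root: Path | None = None):
        self.tiles: tuple[TileRecord, ...] = tuple(tiles)
        self.root = Path(root) if root is not None else None
        seen: dict[str, int] = {}
        patients: dict[str, list[TileRecord]] = {}
        for i, t in enumerate(self.tiles):
            if t.tile_id in seen:
                raise ValueError(
                    f"duplicate tile_id {t.tile_id!r} (rows {seen[t.tile_id]} and {i})"
                )
            seen[t.tile_id] = i
            patients.setdefault(t.patient_id, []).append(t)
        self._by_id = {t.tile_id: t for t in self.tiles}
        index: dict[str, PatientInfo] = {}
        for pid, recs in patients.items():
            sites = {r.site_id for r in recs}
            if len(sites) > 1:
                raise ValueError(
                    f"patient {pid!r} is mapped to multiple sites: {sorted(sites)}"
                )
            grades = [r.quality_grade for r in recs]
            grade = max(set(grades), key=grades.count)
            index[pid] = PatientInfo(
                site_id=recs[0].site_id,
                quality_grade=grade,
                tile_ids=tuple(r.tile_id for r in recs),
            )
        self.patients: dict[str, PatientInfo] = index

    # -- basic access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.patients))

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(sorted({t.site_id for t in self.tiles}))

    def tile(self, tile_id: str) -> TileRecord:
        return self._by_id[tile_id]

    def tiles_of_patients(self, patients: Iterable[str]) -> list[TileRecord]:
        out: list[TileRecord] = []
        for pid in sorted(set(patients)):
            out.extend(self._by_id[tid] for tid in self.patients[pid].tile_ids)
        return out

    def patients_of_site(self, site_id: str) -> tuple[str, ...]:
        return tuple(
            sorted(p for p, info in self.patients.items() if info.site_id == site_id)
        )

    def truth(self) -> dict[str, int]:
        """tile_id -> ground-truth class label."""
        return {t.tile_id: t.class_label for t in self.tiles}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.tiles], columns=MANIFEST_COLUMNS)


# ---------------------------------------------------------------------------
# manifest I/O


def write_manifest(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort as a comma-separated manifest with a header row."""
    cohort.to_frame().to_csv(path, index=False)


def read_manifest(path: str | Path) -> Cohort:
    """Read a manifest written by :func:`write_manifest` (or hand-built).

    Raises with the offending row on duplicate tile ids, invalid labels or a
    patient mapped to two sites.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"tile_id": str, "patient_id": str, "site_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                TileRecord(
                    tile_id=str(row.tile_id),
                    patient_id=str(row.patient_id),
                    site_id=str(row.site_id),
                    quality_grade=int(row.quality_grade),
                    class_label=int(row.class_label),
                    image_path="" if pd.isna(row.image_path) else str(row.image_path),
                )
            )
        except ValueError as exc:
            raise ValueError(f"manifest row {i}: {exc}") from exc
    return Cohort(records, root=path.parent)


# ---------------------------------------------------------------------------
# split plans


@dataclass(frozen=True)
class SplitPlan:
    """One repeat: a held-out patient test set, the train+validation pool,
    and (once filled) one (train, validation) patient partition per member."""

    repeat_index: int
    test_patients: tuple[str, ...]
    pool_patients: tuple[str, ...]
    member_partitions: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "repeat_index": self.repeat_index,
                "test_patients": list(self.test_patients),
                "pool_patients": list(self.pool_patients),
                "member_partitions": [
                    {"train": list(tr), "validation": list(va)}
                    for tr, va in self.member_partitions
                ],
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            repeat_index=d["repeat_index"],
            test_patients=tuple(d["test_patients"]),
            pool_patients=tuple(d["pool_patients"]),
            member_partitions=tuple(
                (tuple(m["train"]), tuple(m["validation"]))
                for m in d["member_partitions"]
            ),
        )


def check_split_plan(plan: SplitPlan) -> None:
    """Assert patient-level disjointness and validation distinctness."""
    test = set(plan.test_patients)
    pool = set(plan.pool_patients)
    if test & pool:
        raise AssertionError(f"test/pool overlap: {sorted(test & pool)}")
    val_sets = []
    for i, (train, val) in enumerate(plan.member_partitions):
        tr, va = set(train), set(val)
        if tr & test or va & test:
            raise AssertionError(f"member {i}: test patients leak into train/val")
        if tr & va:
            raise AssertionError(f"member {i}: train/validation overlap")
        if (tr | va) != pool:
            raise AssertionError(f"member {i}: train ∪ validation != pool")
        val_sets.append(frozenset(va))
    if len(set(val_sets)) != len(val_sets):
        raise AssertionError("member validation sets are not pairwise distinct")


def make_repeat_splits(
    cohort: Cohort, n_repeats: int, test_fraction: float, seed: int
) -> list[SplitPlan]:
    """Draw ``n_repeats`` patient-level test sets of ⌊test_fraction·n⌉ patients.

    Assignment is balanced greedily: each repeat holds out the patients with
    the fewest test appearances so far (seeded random tie-breaks), so counts
    across patients never differ by more than one while each repeat's test
    set remains an exact-size patient sample.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    patients = cohort.patient_ids
    n = len(patients)
    if n < 4:
        raise ValueError("too few patients to split")
    k = max(1, round_half_up(test_fraction * n))
    if k >= n:
        raise ValueError("test_fraction leaves no training patients")
    rng = derive_rng(seed, "repeat-splits")
    counts = {p: 0 for p in patients}
    plans = []
    for r in range(n_repeats):
        priority = rng.permutation(n)
        order = sorted(range(n), key=lambda i: (counts[patients[i]], priority[i]))
        test = tuple(sorted(patients[i] for i in order[:k]))
        for p in test:
            counts[p] += 1
        pool = tuple(sorted(set(patients) - set(test)))
        plans.append(SplitPlan(repeat_index=r, test_patients=test, pool_patients=pool))
    return plans


def _distinct_validation_sets(
    pool: Sequence[str], n_members: int, val_size: int, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """n_members pairwise-distinct validation subsets of the pool.

    When the pool is large enough to hold disjoint subsets, a shuffled pool is
    dealt out in consecutive blocks (covers the leave-one-patient-out case
    exactly); otherwise subsets are resampled until distinct.
    """
    pool = list(pool)
    n = len(pool)
    if comb(n, val_size) < n_members:
        raise ValueError(
            f"pool of {n} patients cannot provide {n_members} distinct "
            f"validation sets of size {val_size}; need a pool with "
            f"C(pool, {val_size}) >= {n_members}"
        )
    if n_members * val_size <= n:
        shuffled = list(rng.permutation(pool))
        return [
            tuple(sorted(shuffled[i * val_size : (i + 1) * val_size]))
            for i in range(n_members)
        ]
    seen: set[tuple[str, ...]] = set()
    out: list[tuple[str, ...]] = []
    attempts = 0
    while len(out) < n_members:
        cand = tuple(sorted(rng.choice(pool, size=val_size, replace=False)))
        attempts += 1
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
        if attempts > 10000 * n_members:  # pragma: no cover - guarded by comb()
            raise RuntimeError("failed to sample distinct validation sets")
    return out


def make_member_splits(
    plan: SplitPlan, n_members: int, val_fraction: float, seed: int
) -> SplitPlan:
    """Fill a plan's member partitions: per member, a validation patient set
    of ⌊val_fraction·pool⌉ (>= 1) and the remaining pool as training set."""
    if n_members < 3 or n_members % 2 == 0:
        raise ValueError("n_members must be odd and >= 3")
    pool = list(plan.pool_patients)
    n = len(pool)
    val_size = round_half_up(val_fraction * n)
    if val_size < 1:
        raise ValueError(
            f"val_fraction {val_fraction} gives an empty validation set for a "
            f"pool of {n} patients; need val_fraction >= {0.5 / n:.4f}"
        )
    if val_size >= n:
        raise ValueError("validation set would consume the whole pool")
    rng = derive_rng(seed, "member-splits", plan.repeat_index)
    val_sets = _distinct_validation_sets(pool, n_members, val_size, rng)
    partitions = tuple(
        (tuple(sorted(set(pool) - set(val))), val) for val in val_sets
    )
    filled = replace(plan, member_partitions=partitions)
    check_split_plan(filled)
    return filled


def make_site_splits(
    cohort: Cohort,
    train_site: str,
    n_test_per_site: int,
    n_repeats: int,
    seed: int,
) -> list[SplitPlan]:
    """Site-restricted designs with a shared test pool.

    Per repeat, ``n_test_per_site`` patients are held out from every site
    (forming one common test pool); the train+validation pool is drawn only
    from ``train_site`` (or the union of sites when ``train_site="all"``),
    minus its held-out patients.  The held-out pools depend only on
    (cohort, seed, repeat), never on ``train_site``, so test sets are
    identical across training designs.
    """
    sites = cohort.site_ids
    if train_site != "all" and train_site not in sites:
        raise ValueError(
            f"unknown site {train_site!r}; available sites: {list(sites)} or 'all'"
        )
    for s in sites:
        if len(cohort.patients_of_site(s)) <= n_test_per_site:
            raise ValueError(
                f"site {s!r} has {len(cohort.patients_of_site(s))} patients; "
                f"needs more than n_test_per_site={n_test_per_site}"
            )
    plans = []
    for r in range(n_repeats):
        test: list[str] = []
        for s in sites:
            rng = derive_rng(seed, "site-test", r, s)
            site_patients = list(cohort.patients_of_site(s))
            test.extend(rng.choice(site_patients, size=n_test_per_site, replace=False))
        test_t = tuple(sorted(test))
        if train_site == "all":
            pool_src = set(cohort.patient_ids)
        else:
            pool_src = set(cohort.patients_of_site(train_site))
        pool = tuple(sorted(pool_src - set(test_t)))
        plans.append(SplitPlan(repeat_index=r, test_patients=test_t, pool_patients=pool))
    return plans
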