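"""End-to-end synthetic benchmark: generate → split → noise → train → evaluate.

The benchmark reproduces, on synthetic cohorts, the qualitative study design:
site-restricted training with a shared multi-site test pool, a sweep over
label-noise levels, majority-vote evaluation, agreement curves, and
quality-grade statistics.  Desk-scale defaults (3 sites x 30 patients x 8
tiles at 64 px, 7 members, 3 repeats) complete on one CPU in a few minutes;
the study-scale values (15 members, 10 repeats, 40 tiles/patient) are plain
config settings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import derive_seed
from .cohort import make_member_splits, make_site_splits
from .ensemble import (
    TrainConfig,
    group_accuracy,
    predict_members,
    train_ensemble,
)
from .evaluation import accuracy_by_agreement, stratified_performance
from .noise import inject_label_noise, select_single_class
from .simulate import (
    DegradationProfile,
    SiteProfile,
    TextureParams,
    default_sites,
    default_textures,
    generate_cohort,
)
from .stats import PosthocResult, pairwise_t_holm

__all__ = [
    "ExperimentConfig",
    "BenchmarkResult",
    "run_benchmark",
    "mechanism_summary",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun a benchmark bit-exactly (given the seed)."""

    sites: tuple[SiteProfile, ...] = tuple(default_sites())
    textures: Mapping[int, TextureParams] = field(
        default_factory=default_textures
    )
    tiles_per_patient: int = 8
    tile_size: int = 64
    class_balance: float = 0.5
    n_repeats: int = 3
    n_test_per_site: int = 7
    val_fraction: float = 0.2
    train_sites: tuple[str, ...] = ("A", "B")
    noise_levels: tuple[float, ...] = (0.0, 0.15)
    n_members: int = 7
    epochs: int = 30
    backend: str = "small_cnn"
    backend_params: Mapping | None = field(
        default_factory=lambda: {"batch_size": 8}
    )
    seed: int = 0

    def validate(self) -> None:
        for rho in self.noise_levels:
            if not 0 <= rho < 0.5:
                raise ValueError(f"noise level {rho} outside [0, 0.5)")
        TrainConfig(n_members=self.n_members, epochs=self.epochs)
        site_ids = {s.site_id for s in self.sites}
        for ts in self.train_sites:
            if ts != "all" and ts not in site_ids:
                raise ValueError(f"train_site {ts!r} not among sites {sorted(site_ids)}")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sites"] = [asdict(s) for s in self.sites]
        for s in d["sites"]:
            s["quality_mix"] = {int(k): float(v) for k, v in s["quality_mix"].items()}
            s["degradation_by_grade"] = {
                int(k): v for k, v in s["degradation_by_grade"].items()
            }
        d["textures"] = {int(k): asdict(v) for k, v in self.textures.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        if "sites" in d:
            sites = []
            for s in d["sites"]:
                s = dict(s)
                s["quality_mix"] = {int(k): v for k, v in s["quality_mix"].items()}
                s["degradation_by_grade"] = {
                    int(k): DegradationProfile(**{
                        **p, "stain_gain": tuple(p.get("stain_gain", (1, 1, 1)))
                    })
                    for k, p in s["degradation_by_grade"].items()
                }
                sites.append(SiteProfile(**s))
            d["sites"] = tuple(sites)
        if "textures" in d:
            d["textures"] = {
                int(k): TextureParams(**{
                    **t,
                    "blob_eccentricity_range": tuple(t["blob_eccentricity_range"]),
                    "foreground_color": tuple(t["foreground_color"]),
                    "background_color": tuple(t["background_color"]),
                })
                for k, t in d["textures"].items()
            }
        for key in ("train_sites", "noise_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(text))


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML output."""
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class BenchmarkResult:
    """All benchmark tables plus the quality-grade post-hoc statistics."""

    config: ExperimentConfig
    site_accuracy: pd.DataFrame
    grade_accuracy: pd.DataFrame
    patient_accuracy: pd.DataFrame
    agreement_curves: pd.DataFrame
    agreement_stats: pd.DataFrame
    quality_posthoc: PosthocResult | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(self.config.to_yaml())
        self.site_accuracy.to_csv(out / "site_accuracy.csv", index=False)
        self.grade_accuracy.to_csv(out / "grade_accuracy.csv", index=False)
        self.patient_accuracy.to_csv(out / "patient_accuracy.csv", index=False)
        self.agreement_curves.to_csv(out / "agreement_curves.csv", index=False)
        self.agreement_stats.to_csv(out / "agreement_stats.csv", index=False)
        if self.quality_posthoc is not None:
            self.quality_posthoc.to_frame().to_csv(
                out / "quality_posthoc.csv", index=False
            )
            (out / "quality_anova.json").write_text(
                json.dumps(
                    {
                        "anova_f": self.quality_posthoc.anova_f,
                        "anova_p": self.quality_posthoc.anova_p,
                        "alpha": self.quality_posthoc.alpha,
                    }
                )
            )


def _mean_agreement(votes, truth) -> tuple[float, float]:
    y = np.array([truth[t] for t in votes.tile_ids])
    correct = votes.ensemble_label == y
    agree = votes.agreement.astype(float)
    mc = float(agree[correct].mean()) if correct.any() else np.nan
    mi = float(agree[~correct].mean()) if (~correct).any() else np.nan
    return mc, mi


def run_benchmark(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    progress: bool = False,
    cells: Sequence[tuple[str, float]] | None = None,
) -> BenchmarkResult:
    """Run the full benchmark described by ``config``.

    Per repeat, a fresh cohort is generated from a repeat-derived seed and
    one site-restricted split is drawn per training design; the held-out test
    pools are identical across training designs within a repeat.  The noise
    sweep reuses the same member partitions and single-class selection so
    noise levels differ only in flipped labels (auditable via the plans
    saved under ``out_dir``).

    ``cells`` restricts the run to an explicit list of (train_site, rho)
    combinations instead of the full train_sites x noise_levels product.
    """
    config.validate()
    if cells is None:
        cells = [
            (ts, rho) for ts in config.train_sites for rho in config.noise_levels
        ]
    site_ids = {s.site_id for s in config.sites} | {"all"}
    by_site: dict[str, list[float]] = {}
    for ts, rho in cells:
        if ts not in site_ids:
            raise ValueError(f"unknown train site {ts!r} in cells")
        if not 0 <= rho < 0.5:
            raise ValueError(f"noise level {rho} outside [0, 0.5)")
        by_site.setdefault(ts, []).append(rho)
    seed = config.seed
    rows_site, rows_grade, rows_patient, rows_curve, rows_agree = [], [], [], [], []
    plans_dir = None
    if out_dir is not None:
        plans_dir = Path(out_dir) / "plans"
        plans_dir.mkdir(parents=True, exist_ok=True)

    for r in range(config.n_repeats):
        cohort, images = generate_cohort(
            config.sites,
            tiles_per_patient=config.tiles_per_patient,
            tile_size=config.tile_size,
            class_balance=config.class_balance,
            seed=derive_seed(seed, "cohort", r),
            textures=config.textures,
        )
        truth = cohort.truth()
        for train_site in by_site:
            base = make_site_splits(
                cohort,
                train_site,
                config.n_test_per_site,
                1,
                seed=derive_seed(seed, "site-split", r),
            )[0]
            base = replace(base, repeat_index=r)
            retained, choice = select_single_class(
                cohort,
                base.pool_patients,
                seed=derive_seed(seed, "select", r, train_site),
                balance=True,
            )
            plan = make_member_splits(
                base,
                config.n_members,
                config.val_fraction,
                seed=derive_seed(seed, "members", r, train_site),
            )
            test_tiles = cohort.tiles_of_patients(plan.test_patients)
            for rho in by_site[train_site]:
                if progress:
                    print(f"[repeat {r}] train_site={train_site} rho={rho}", flush=True)
                noise_plan = inject_label_noise(
                    retained,
                    rho,
                    seed=derive_seed(seed, "noise", r, train_site, float(rho)),
                    patient_class_choice=choice,
                )
                tcfg = TrainConfig(
                    n_members=config.n_members,
                    epochs=config.epochs,
                    backend_name=config.backend,
                    backend_params=config.backend_params,
                    seed=derive_seed(seed, "train", r, train_site, float(rho)),
                )
                ens = train_ensemble(cohort, plan, noise_plan, tcfg, images)
                votes = predict_members(ens, test_tiles, images)
                if plans_dir is not None:
                    tag = f"r{r}_{train_site}_rho{int(round(rho * 100)):02d}"
                    (plans_dir / f"split_{tag}.json").write_text(plan.to_json())
                    (plans_dir / f"noise_{tag}.json").write_text(noise_plan.to_json())

                key = {"repeat": r, "train_site": train_site, "rho": rho}
                # per test-site metrics
                for test_site in cohort.site_ids:
                    ids = [
                        t.tile_id for t in test_tiles if t.site_id == test_site
                    ]
                    idx = [votes.tile_ids.index(t) for t in ids]
                    sub = type(votes)(tuple(ids), votes.votes[idx])
                    y = np.array([truth[t] for t in ids])
                    mc, mi = _mean_agreement(sub, truth)
                    rows_site.append(
                        {
                            **key,
                            "test_site": test_site,
                            "n_tiles": len(ids),
                            "ensemble_accuracy": float(
                                (sub.ensemble_label == y).mean()
                            ),
                            "group_accuracy": group_accuracy(sub, truth),
                            "mean_agreement_correct": mc,
                            "mean_agreement_incorrect": mi,
                        }
                    )
                    curve = accuracy_by_agreement(sub, truth)
                    for row in curve.to_dict("records"):
                        rows_curve.append({**key, "test_site": test_site, **row})
                # grade- and patient-stratified metrics on the whole test pool
                for row in stratified_performance(
                    votes, cohort, by="quality"
                ).to_dict("records"):
                    rows_grade.append({**key, **row})
                for row in stratified_performance(
                    votes, cohort, by="patient"
                ).to_dict("records"):
                    info = cohort.patients[row["patient"]]
                    rows_patient.append(
                        {
                            **key,
                            **row,
                            "site": info.site_id,
                            "quality_grade": info.quality_grade,
                        }
                    )
                mc, mi = _mean_agreement(votes, truth)
                rows_agree.append(
                    {
                        **key,
                        "mean_agreement_correct": mc,
                        "mean_agreement_incorrect": mi,
                        "mean_member_val_accuracy": float(
                            np.mean([m.best_val_accuracy for m in ens.members])
                        ),
                    }
                )

    patient_df = pd.DataFrame(rows_patient)
    posthoc = _quality_posthoc(patient_df)
    result = BenchmarkResult(
        config=config,
        site_accuracy=pd.DataFrame(rows_site),
        grade_accuracy=pd.DataFrame(rows_grade),
        patient_accuracy=patient_df,
        agreement_curves=pd.DataFrame(rows_curve),
        agreement_stats=pd.DataFrame(rows_agree),
        quality_posthoc=posthoc,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def mechanism_summary(
    result: BenchmarkResult,
    clean_site: str = "A",
    degraded_site: str = "B",
    external_site: str = "C",
    rho_hi: float = 0.15,
) -> dict:
    """Condense a benchmark run into the mechanism-level quantities.

    Expects the run to contain at least the cells (clean_site, 0),
    (clean_site, rho_hi) and (degraded_site, 0).  All accuracies are on the
    common held-out test pool; "repeats" index independent splits/cohorts.
    """
    sa = result.site_accuracy

    def acc(train, rho, test):
        sub = sa[
            (sa["train_site"] == train) & (sa["rho"] == rho) & (sa["test_site"] == test)
        ].sort_values("repeat")
        return sub["ensemble_accuracy"].to_numpy()

    deg0 = acc(clean_site, 0.0, degraded_site)
    deg_hi = acc(clean_site, rho_hi, degraded_site)
    clean0 = acc(clean_site, 0.0, clean_site)
    clean_hi = acc(clean_site, rho_hi, clean_site)
    gains = deg_hi - deg0
    drops = clean0 - clean_hi

    grades = result.grade_accuracy
    g = grades[(grades["train_site"] == clean_site) & (grades["rho"] == 0.0)]
    grade_acc = {
        int(k): float(v)
        for k, v in g.groupby("quality")["accuracy"].mean().items()
    }

    ag = result.agreement_stats
    ag_a = ag[ag["train_site"] == clean_site]
    agreement = {
        float(rho): (
            float(sub["mean_agreement_correct"].mean()),
            float(sub["mean_agreement_incorrect"].mean()),
        )
        for rho, sub in ag_a.groupby("rho")
    }

    # pooled agreement curve (over test sites) for the noisy clean-site model
    cur = result.agreement_curves
    cur = cur[(cur["train_site"] == clean_site) & (cur["rho"] == rho_hi)]
    curve_stats = []
    for rep, sub in cur.groupby("repeat"):
        t_min, t_max = sub["threshold"].min(), sub["threshold"].max()
        lo = sub[sub["threshold"] == t_min].sum(numeric_only=True)
        hi = sub[sub["threshold"] == t_max].sum(numeric_only=True)
        n_all = lo["n_retained"]
        acc_lo = (lo["n_retained"] - lo["false_positives"] - lo["false_negatives"]) / n_all
        if hi["n_retained"] > 0:
            acc_hi = (
                hi["n_retained"] - hi["false_positives"] - hi["false_negatives"]
            ) / hi["n_retained"]
        else:
            acc_hi = np.nan
        incorrect_total = (
            hi["false_positives"] + hi["false_negatives"] + hi["n_discarded_incorrect"]
        )
        discarded = hi["n_discarded_correct"] + hi["n_discarded_incorrect"]
        if discarded > 0 and incorrect_total > 0:
            enrichment = (hi["n_discarded_incorrect"] / discarded) / (
                incorrect_total / n_all
            )
        else:
            enrichment = np.nan
        curve_stats.append(
            {
                "repeat": rep,
                "accuracy_min_threshold": float(acc_lo),
                "accuracy_full_agreement": float(acc_hi),
                "retained_fraction_full_agreement": float(hi["n_retained"] / n_all),
                "discard_incorrect_enrichment": float(enrichment),
            }
        )
    curve_df = pd.DataFrame(curve_stats)

    return {
        "n_repeats": len(deg0),
        "degraded_rho0": deg0,
        "degraded_rho_hi": deg_hi,
        "clean_rho0": clean0,
        "clean_rho_hi": clean_hi,
        "external_rho0": acc(clean_site, 0.0, external_site),
        "gains": gains,
        "n_gain_positive": int((gains > 0).sum()),
        "median_clean_drop": float(np.median(drops)),
        "transfer_clean_to_degraded": float(np.median(deg0)),
        "transfer_degraded_to_clean": float(np.median(acc(degraded_site, 0.0, clean_site))),
        "degraded_self": float(np.median(acc(degraded_site, 0.0, degraded_site))),
        "grade_accuracy": grade_acc,
        "agreement_by_rho": agreement,
        "curve_stats": curve_df,
    }


def _quality_posthoc(patient_df: pd.DataFrame) -> PosthocResult | None:
    """Per-patient accuracies of clean-trained runs, compared across grades."""
    clean = patient_df[patient_df["rho"] == 0.0]
    groups = {
        f"grade{g}": sub["accuracy"].to_numpy()
        for g, sub in clean.groupby("quality_grade")
    }
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        return None
    try:
        return pairwise_t_holm(groups, alpha=0.05)
    except ValueError:
        return None
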