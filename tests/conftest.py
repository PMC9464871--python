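"""Shared fixtures: small metadata-only cohorts and rendered tile sets."""

from __future__ import annotations

import numpy as np
import pytest

from noisyensemble import Cohort, TileRecord
from noisyensemble._util import derive_rng
from noisyensemble.simulate import default_textures, render_tile


def build_cohort(
    site_sizes: dict[str, int],
    tiles_per_patient: int = 8,
    grades: dict[str, int] | None = None,
    labels: str = "alternate",
) -> Cohort:
    """Metadata-only cohort: `site_sizes` maps site_id -> n_patients.

    ``labels='alternate'`` gives each patient half class-0, half class-1
    tiles; ``labels='by_patient'`` gives every patient a single class.
    """
    records = []
    for site, n in site_sizes.items():
        for p in range(n):
            pid = f"{site}-P{p:03d}"
            grade = (grades or {}).get(site, 1)
            for t in range(tiles_per_patient):
                if labels == "alternate":
                    lab = t % 2
                elif labels == "by_patient":
                    lab = p % 2
                else:
                    raise ValueError(labels)
                records.append(
                    TileRecord(
                        tile_id=f"{pid}-T{t:02d}",
                        patient_id=pid,
                        site_id=site,
                        quality_grade=grade,
                        class_label=lab,
                        image_path=f"images/{pid}-T{t:02d}.png",
                    )
                )
    return Cohort(records)


@pytest.fixture(scope="session")
def two_site_cohort() -> Cohort:
    return build_cohort({"A": 28, "B": 34})


@pytest.fixture(scope="session")
def rendered_tiles():
    """260 undegraded tiles (balanced classes, 64 px) with patient structure."""
    tex = default_textures()
    X, y, groups = [], [], []
    for i in range(260):
        lab = i % 2
        X.append(
            render_tile(tex[lab], patient_stain_seed=5000 + i // 8, tile_seed=i, size=64)
        )
        y.append(lab)
        groups.append(i // 8)
    return np.asarray(X, np.float32), np.asarray(y), np.asarray(groups)
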