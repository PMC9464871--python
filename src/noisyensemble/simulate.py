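"""Synthetic multi-site histology-tile simulator.

Generates two-class (cancer vs. non-cancer) tissue-like image tiles organised
into patients and tissue source sites, with per-site quality-grade mixtures
realised as image degradations (blur, contrast loss, brightness shift, stain
perturbation, JPEG compression).  The simulator stands in for restricted
clinical tile collections so that ensemble training, label-noise injection
and agreement-based rejection can be exercised end to end at desk scale.

Class morphology is a blob texture: the "cancer" class renders many small
dark nuclei-like blobs, the "non-cancer" class fewer, larger structures, on a
shared pale eosin-like background.  Both classes cover a similar (not equal)
area fraction so that the main discriminative signal is texture granularity —
a high-frequency cue that degradations genuinely erode — while total stain
mass carries a weaker, degradation-robust signal.  Each patient draws one
stain-colour offset shared by all of its tiles, emulating per-case staining
batch effects.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from ._util import derive_rng, derive_seed
from .cohort import Cohort, TileRecord, write_manifest

__all__ = [
    "load_images",
    "DegradationProfile",
    "TextureParams",
    "SiteProfile",
    "render_tile",
    "degrade",
    "jpeg_roundtrip",
    "generate_cohort",
    "default_textures",
    "default_grade_profiles",
    "default_sites",
    "IDENTITY_PROFILE",
]

MIN_TILE_SIZE = 32


# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class DegradationProfile:
    """One point in artifact space, applied tissue-first to acquisition-last.

    Operator order is fixed: stain gain -> brightness -> contrast -> blur ->
    JPEG.  Stain and illumination act on the tissue appearance, optics blur
    the field, and compression happens last in the acquisition chain.

    Parameters
    ----------
    blur_sigma : Gaussian blur standard deviation in pixels (>= 0).
    contrast_factor : scaling of deviations from the image mean, in (0, 1].
    brightness_shift : additive intensity shift on the unit scale, |s| <= 0.3.
    stain_gain : per-channel multiplicative factors, each in [0.6, 1.4].
    jpeg_quality : JPEG encoder quality 1-100, or None for no compression.
    """

    blur_sigma: float = 0.0
    contrast_factor: float = 1.0
    brightness_shift: float = 0.0
    stain_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    jpeg_quality: int | None = None

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0 < self.contrast_factor <= 1:
            raise ValueError("contrast_factor must be in (0, 1]")
        if abs(self.brightness_shift) > 0.3:
            raise ValueError("brightness_shift must be in [-0.3, 0.3]")
        if len(self.stain_gain) != 3 or any(
            not 0.6 <= g <= 1.4 for g in self.stain_gain
        ):
            raise ValueError("stain_gain must be three factors in [0.6, 1.4]")
        if self.jpeg_quality is not None and not (
            isinstance(self.jpeg_quality, (int, np.integer))
            and 1 <= self.jpeg_quality <= 100
        ):
            raise ValueError("jpeg_quality must be an integer in 1..100 or None")

    @property
    def is_identity(self) -> bool:
        return (
            self.blur_sigma == 0
            and self.contrast_factor == 1
            and self.brightness_shift == 0
            and tuple(self.stain_gain) == (1.0, 1.0, 1.0)
            and self.jpeg_quality is None
        )


IDENTITY_PROFILE = DegradationProfile()


@dataclass(frozen=True)
class TextureParams:
    """Blob-texture parameters for one class.

    blob_density is expressed per 1000 px² so tile size can change without
    changing the texture statistics.  Eccentricity e in [0, 1) stretches a
    blob of radius r into an ellipse with semi-axes r/sqrt(1-e), r*sqrt(1-e)
    (area preserved).
    """

    class_id: int
    blob_density: float
    blob_radius_mean: float
    blob_radius_sd: float
    blob_eccentricity_range: tuple[float, float] = (0.0, 0.5)
    foreground_color: tuple[float, float, float] = (0.38, 0.24, 0.50)
    background_color: tuple[float, float, float] = (0.91, 0.82, 0.88)
    color_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.class_id not in (0, 1):
            raise ValueError("class_id must be 0 or 1")
        if self.blob_density < 0:
            raise ValueError("blob_density must be >= 0")
        lo, hi = self.blob_eccentricity_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("blob_eccentricity_range must lie in [0, 1)")


@dataclass(frozen=True)
class SiteProfile:
    """A tissue source site: patient count, quality mixture, storage format.

    quality_mix maps grade (1 good, 2 medium, 3 poor) to the probability a
    patient of this site receives that grade; degradation_by_grade supplies
    the artifact profile realising each grade.  jpeg_quality, when set, is
    the site's slide-storage compression (tiles are saved as JPEG at that
    quality instead of PNG).
    """

    site_id: str
    n_patients: int
    quality_mix: Mapping[int, float]
    degradation_by_grade: Mapping[int, DegradationProfile] = field(
        default_factory=dict
    )
    jpeg_quality: int | None = None

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be a non-empty string")
        if self.n_patients <= 0:
            raise ValueError(f"site {self.site_id!r} must have >= 1 patient")
        probs = np.array([self.quality_mix.get(g, 0.0) for g in (1, 2, 3)])
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"site {self.site_id!r}: quality_mix must be non-negative and sum to 1"
            )
        for g in (1, 2, 3):
            if self.quality_mix.get(g, 0.0) > 0 and g not in self.degradation_by_grade:
                raise ValueError(
                    f"site {self.site_id!r}: grade {g} has probability > 0 "
                    "but no DegradationProfile"
                )
        if self.jpeg_quality is not None and not 1 <= int(self.jpeg_quality) <= 100:
            raise ValueError("site jpeg_quality must be in 1..100 or None")


# ---------------------------------------------------------------------------
# rendering


def _place_blobs(texture: TextureParams, rng: np.random.Generator, size: int):
    """Sample blob placements; returns a list of (cx, cy, radius, ecc, theta)."""
    lam = texture.blob_density * size * size / 1000.0
    n = int(rng.poisson(lam))
    blobs = []
    for _ in range(n):
        cx, cy = rng.uniform(0, size, 2)
        r = max(1.0, rng.normal(texture.blob_radius_mean, texture.blob_radius_sd))
        lo, hi = texture.blob_eccentricity_range
        e = rng.uniform(lo, hi)
        theta = rng.uniform(0, np.pi)
        blobs.append((cx, cy, r, e, theta))
    return blobs


def render_tile(
    texture: TextureParams,
    patient_stain_seed: int,
    tile_seed: int,
    size: int = 64,
    return_log: bool = False,
):
    """Render one tile as an (size, size, 3) float array on the unit scale.

    The per-patient stain offset is a function of ``patient_stain_seed`` only,
    so all tiles of a patient share one colour shift.  Everything else is a
    pure function of ``tile_seed``.  With ``return_log=True`` the blob
    placement log is returned alongside the image for auditing.
    """
    if size < MIN_TILE_SIZE:
        raise ValueError("tile too small for texture model")
    if patient_stain_seed < 0 or tile_seed < 0:
        raise ValueError("seeds must be non-negative integers")

    stain_rng = derive_rng("stain", int(patient_stain_seed))
    jitter = stain_rng.normal(0.0, texture.color_jitter_sd, size=3)
    fg = np.clip(np.asarray(texture.foreground_color) + jitter, 0.0, 1.0)
    bg = np.clip(np.asarray(texture.background_color) + jitter, 0.0, 1.0)

    rng = derive_rng("tile", int(tile_seed))
    blobs = _place_blobs(texture, rng, size)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    alpha = np.zeros((size, size))
    for cx, cy, r, e, theta in blobs:
        a = r / np.sqrt(1.0 - e)
        b = r * np.sqrt(1.0 - e)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        d = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        # soft elliptical disc with a ~1 px anti-aliased rim
        blob_alpha = np.clip((1.0 - d) * r + 0.5, 0.0, 1.0)
        np.maximum(alpha, blob_alpha, out=alpha)

    img = bg[None, None, :] * (1.0 - alpha[..., None]) + fg[None, None, :] * alpha[
        ..., None
    ]
    img = np.clip(img, 0.0, 1.0)
    if return_log:
        return img, blobs
    return img


# ---------------------------------------------------------------------------
# degradation


def jpeg_roundtrip(image: np.ndarray, quality: int) -> np.ndarray:
    """Encode to JPEG at the given quality and decode back to the unit scale."""
    if not 1 <= int(quality) <= 100:
        raise ValueError("jpeg_quality must be in 1..100")
    data = _encode(image, "JPEG", quality=int(quality))
    return _decode(data)


def _encode(image: np.ndarray, fmt: str, **kwargs) -> bytes:
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    u8 = np.round(arr * 255.0).astype(np.uint8)
    buf = io.BytesIO()
    Image.fromarray(u8, mode="RGB").save(buf, format=fmt, **kwargs)
    return buf.getvalue()


def _decode(data: bytes) -> np.ndarray:
    with Image.open(io.BytesIO(data)) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0


def degrade(
    image: np.ndarray, profile: DegradationProfile, seed: int = 0
) -> np.ndarray:
    """Apply a degradation profile to a unit-scale RGB image.

    Operators run in acquisition order (stain gain, brightness, contrast
    toward the image mean, reflect-padded Gaussian blur, JPEG round-trip);
    identity steps are skipped so the identity profile returns the input
    bit-exactly.  The seed argument is part of the operator contract for
    stochastic degradations; the five built-in operators are deterministic
    and ignore it.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("image must be on the unit scale [0, 1]")
    out = img.copy()
    if tuple(profile.stain_gain) != (1.0, 1.0, 1.0):
        out = out * np.asarray(profile.stain_gain)[None, None, :]
    if profile.brightness_shift != 0:
        out = out + profile.brightness_shift
    if profile.contrast_factor != 1:
        m = out.mean()
        out = m + profile.contrast_factor * (out - m)
    if profile.blur_sigma > 0:
        out = ndimage.gaussian_filter(
            out, sigma=(profile.blur_sigma, profile.blur_sigma, 0.0), mode="reflect"
        )
    out = np.clip(out, 0.0, 1.0)
    if profile.jpeg_quality is not None:
        out = jpeg_roundtrip(out, profile.jpeg_quality)
    return out


# ---------------------------------------------------------------------------
# defaults: textures, grade profiles, sites


def default_textures() -> dict[int, TextureParams]:
    """Default class textures: dense small nuclei (1) vs. sparse large blobs (0).

    Densities and radii are set so the classes differ both in granularity (a
    high-frequency cue that blur and compression erode) and, more mildly, in
    total stained area (~22% vs ~29%, a cue that survives blur); the
    per-patient stain jitter (sd 0.07) exceeds the residual mean-colour gap
    between classes, so colour alone cannot separate them.
    """
    common = dict(
        foreground_color=(0.38, 0.24, 0.50),
        background_color=(0.91, 0.82, 0.88),
        color_jitter_sd=0.07,
    )
    return {
        0: TextureParams(
            class_id=0,
            blob_density=2.0,
            blob_radius_mean=6.0,
            blob_radius_sd=1.2,
            blob_eccentricity_range=(0.2, 0.7),
            **common,
        ),
        1: TextureParams(
            class_id=1,
            blob_density=9.0,
            blob_radius_mean=3.5,
            blob_radius_sd=0.7,
            blob_eccentricity_range=(0.0, 0.4),
            **common,
        ),
    }


def default_grade_profiles() -> dict[int, DegradationProfile]:
    """Grade 1 is near-pristine; grade 3 combines noticeable blur, weak
    contrast, a brightness shift, a stain cast and re-compression.

    Magnitudes are calibrated so poor-quality data stays learnable (a model
    trained on the mixed-quality site still classifies that site well, as
    clinical experience with diagnostically usable poor-quality slides
    suggests) while clean-trained models lose measurable accuracy on it.
    """
    return {
        1: DegradationProfile(blur_sigma=0.3, contrast_factor=0.97),
        2: DegradationProfile(
            blur_sigma=0.8,
            contrast_factor=0.88,
            brightness_shift=0.02,
            stain_gain=(1.05, 0.96, 1.02),
            jpeg_quality=75,
        ),
        3: DegradationProfile(
            blur_sigma=1.4,
            contrast_factor=0.75,
            brightness_shift=0.05,
            stain_gain=(1.12, 0.88, 1.05),
            jpeg_quality=50,
        ),
    }


def default_sites(n_patients: tuple[int, int, int] = (30, 30, 30)) -> list[SiteProfile]:
    """Three sites mirroring the study layout: A high quality, B mixed/low
    quality, C an intermediate external site.  Sites A and B store tiles as
    JPEG (qualities 30 and 70 respectively); C stores PNG."""
    grades = default_grade_profiles()
    return [
        SiteProfile(
            site_id="A",
            n_patients=n_patients[0],
            quality_mix={1: 0.8, 2: 0.2, 3: 0.0},
            degradation_by_grade=grades,
            jpeg_quality=30,
        ),
        SiteProfile(
            site_id="B",
            n_patients=n_patients[1],
            quality_mix={1: 0.15, 2: 0.35, 3: 0.5},
            degradation_by_grade=grades,
            jpeg_quality=70,
        ),
        SiteProfile(
            site_id="C",
            n_patients=n_patients[2],
            quality_mix={1: 0.5, 2: 0.4, 3: 0.1},
            degradation_by_grade=grades,
            jpeg_quality=None,
        ),
    ]


def load_images(
    cohort: Cohort, tile_ids: Iterable[str] | None = None
) -> dict[str, np.ndarray]:
    """Read tile images referenced by a cohort manifest into a unit-scale store.

    Relative image paths resolve against the manifest's directory
    (``cohort.root``).
    """
    ids = list(tile_ids) if tile_ids is not None else [t.tile_id for t in cohort.tiles]
    images = {}
    for tid in ids:
        rec = cohort.tile(tid)
        p = Path(rec.image_path)
        if not p.is_absolute() and cohort.root is not None:
            p = cohort.root / p
        if not p.exists():
            raise FileNotFoundError(f"image for tile {tid!r} not found: {p}")
        images[tid] = _decode(p.read_bytes())
    return images


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    sites: Sequence[SiteProfile],
    tiles_per_patient: int = 8,
    tile_size: int = 64,
    class_balance: float = 0.5,
    seed: int = 0,
    textures: Mapping[int, TextureParams] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[Cohort, dict[str, np.ndarray]]:
    """Generate a full multi-site cohort of degraded tiles.

    Each patient receives one quality grade sampled from its site's mix (a
    per-case property, like a slide score), one stain offset, and exactly
    ``tiles_per_patient`` tiles whose classes are i.i.d. Bernoulli with
    P(class 1) = ``class_balance``.  Returns the cohort plus an in-memory
    image store {tile_id: array}; when ``out_dir`` is given, images are also
    written (JPEG at the site's storage quality when set, else PNG) together
    with ``manifest.csv``.  The whole cohort, pixels included, is a pure
    function of (sites, textures, sizes, seed).
    """
    if tiles_per_patient < 2:
        raise ValueError("tiles_per_patient must be >= 2")
    if not 0 < class_balance < 1:
        raise ValueError("class_balance must be in (0, 1)")
    site_ids = [s.site_id for s in sites]
    if len(set(site_ids)) != len(site_ids):
        raise ValueError("duplicate site_id in site list")
    if not sites:
        raise ValueError("at least one site is required")
    textures = dict(textures) if textures is not None else default_textures()

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)

    records: list[TileRecord] = []
    images: dict[str, np.ndarray] = {}
    for site in sites:
        grade_values = sorted(g for g, p in site.quality_mix.items() if p > 0)
        grade_probs = np.array([site.quality_mix[g] for g in grade_values])
        for p_idx in range(site.n_patients):
            patient_id = f"{site.site_id}-P{p_idx:03d}"
            p_rng = derive_rng(seed, "patient", site.site_id, p_idx)
            grade = int(p_rng.choice(grade_values, p=grade_probs))
            profile = site.degradation_by_grade[grade]
            stain_seed = derive_seed(seed, "stain", patient_id)
            for t_idx in range(tiles_per_patient):
                tile_id = f"{patient_id}-T{t_idx:02d}"
                t_rng = derive_rng(seed, "class", tile_id)
                label = int(t_rng.random() < class_balance)
                tile_seed = derive_seed(seed, "render", tile_id)
                img = render_tile(textures[label], stain_seed, tile_seed, tile_size)
                img = degrade(img, profile, seed=derive_seed(seed, "degrade", tile_id))
                if site.jpeg_quality is not None:
                    data = _encode(img, "JPEG", quality=int(site.jpeg_quality))
                    ext = "jpg"
                else:
                    data = _encode(img, "PNG")
                    ext = "png"
                rel_path = f"images/{tile_id}.{ext}"
                if out_path is not None:
                    (out_path / rel_path).write_bytes(data)
                # the stored image (after any storage compression) is what a
                # consumer of the files would see; keep the store consistent
                images[tile_id] = _decode(data)
                records.append(
                    TileRecord(
                        tile_id=tile_id,
                        patient_id=patient_id,
                        site_id=site.site_id,
                        quality_grade=grade,
                        class_label=label,
                        image_path=rel_path,
                    )
                )
    cohort = Cohort(records, root=out_path)
    if out_path is not None:
        write_manifest(cohort, out_path / "manifest.csv")
    return cohort, images
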