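"""Brain-like phantom images with Rician noise, for controlled experiments.

Each phantom is a set of concentric ellipses emulating the three main brain
tissues visible on a T2-weighted slice once skull and scalp are stripped:
an outer cerebrospinal-fluid (CSF) band, a gray-matter (GM) band and a
white-matter (WM) core, on a dark background.  Ellipse axes, orientation
and center are jittered per draw so no two phantoms are identical.
Malignancy is modeled as one or more hyperintense focal lesions (discs)
placed inside the brain parenchyma — a deliberately simplified stand-in
for real tumor appearance.

Noise follows the MRI magnitude model: the output pixel is
sqrt((I + n1)^2 + n2^2) with n1, n2 i.i.d. zero-mean Gaussian of standard
deviation sigma_n, where sigma_n = rms(clean) / 10^(SNR_dB / 20).  The
signal-to-noise ratio is therefore defined on the rms intensity of the
clean image against the per-channel Gaussian sigma.

Two presets mirror the study designs this generator stands in for: a
noise-sweep set (balanced benign/malignant at SNR 5/10/15/20 dB) and a
"90-image" clinical-style set of 18 subtypes x 5 replicates, 17 malignant
subtypes differing in lesion count, size and contrast plus 1 benign.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

BENIGN, MALIGNANT = -1, 1


@dataclass
class PhantomSpec:
    size: int = 128
    #: background / CSF / GM / WM intensities, normalized to [0, 1];
    #: T2-weighted contrast (CSF bright, WM dark, lesions hyperintense)
    tissue_intensities: tuple[float, float, float, float] = (0.0, 0.8, 0.55, 0.3)
    lesion_present: bool = False
    n_lesions: int = 1
    lesion_radius_range: tuple[float, float] = (10.0, 16.0)
    lesion_intensity: float = 1.0
    #: relative jitter of the ellipse semi-axes and of the center (as a
    #: fraction of the image side) applied per draw
    axis_jitter: float = 0.04
    center_jitter: float = 0.015
    snr_db: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not all(0 <= t <= 1 for t in self.tissue_intensities):
            raise ValueError("tissue intensities must lie in [0, 1]")
        if not 0 <= self.lesion_intensity <= 1:
            raise ValueError("lesion intensity must lie in [0, 1]")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ValueError("invalid lesion radius range")
        if hi > 0.25 * self.size:
            raise ValueError("lesion too large to fit inside the brain")


def _elliptical_radius(size: int, center, axes, theta) -> np.ndarray:
    """Normalized elliptical radius field: 1.0 on the ellipse boundary."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return np.sqrt((u / axes[1]) ** 2 + (v / axes[0]) ** 2)


def make_phantom(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """One clean phantom slice in [0, 1], shape (size, size)."""
    n = spec.size
    bg, csf, gm, wm = spec.tissue_intensities
    cj, aj = spec.center_jitter, spec.axis_jitter
    center = n / 2 + rng.uniform(-cj * n, cj * n, size=2)
    axes = (
        0.42 * n * (1 + rng.uniform(-aj, aj)),  # semi-axis along y
        0.34 * n * (1 + rng.uniform(-aj, aj)),  # semi-axis along x
    )
    theta = rng.uniform(0, np.pi)
    r = _elliptical_radius(n, center, axes, theta)
    img = np.full((n, n), bg, dtype=float)
    img[r <= 1.0] = csf
    img[r <= 0.88] = gm
    img[r <= 0.70] = wm
    if spec.lesion_present:
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        inner = np.argwhere(r <= 0.45)  # candidate lesion centers
        for _ in range(spec.n_lesions):
            placed = False
            for _attempt in range(200):
                radius = rng.uniform(*spec.lesion_radius_range)
                cy, cx = inner[rng.integers(0, len(inner))]
                # lesion disc must sit fully inside the parenchyma (r<=0.66)
                disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
                if disc.any() and r[disc].max() <= 0.66:
                    img[disc] = spec.lesion_intensity
                    placed = True
                    break
            if not placed:
                raise RuntimeError("could not place lesion inside the brain")
    return img


def add_rician_noise(
    img: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((I + n1)^2 + n2^2).

    ``snr_db >= 200`` is treated as the noiseless limit.  The per-channel
    Gaussian sigma is rms(img) / 10^(snr_db/20).
    """
    img = np.asarray(img, dtype=float)
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    rms = float(np.sqrt(np.mean(img**2)))
    if rms == 0:
        raise ValueError("all-zero image has no defined SNR")
    if snr_db >= 200:
        return np.abs(img)
    sigma_n = rms / 10 ** (snr_db / 20)
    n1 = rng.normal(0.0, sigma_n, img.shape)
    n2 = rng.normal(0.0, sigma_n, img.shape)
    return np.hypot(img + n1, n2)


def noise_sigma(img: np.ndarray, snr_db: float) -> float:
    """Per-channel Gaussian sigma implied by an image and an SNR in dB."""
    rms = float(np.sqrt(np.mean(np.asarray(img, dtype=float) ** 2)))
    return rms / 10 ** (snr_db / 20)


# ---------------------------------------------------------------------------
# datasets

#: 17 malignant subtypes: (n_lesions, radius_range, lesion_intensity)
_MALIGNANT_SUBTYPES = [
    (1, (8.0, 12.0), 1.0),
    (1, (12.0, 16.0), 1.0),
    (1, (16.0, 20.0), 1.0),
    (1, (8.0, 12.0), 0.97),
    (1, (12.0, 16.0), 0.97),
    (1, (16.0, 20.0), 0.97),
    (2, (7.0, 10.0), 1.0),
    (2, (10.0, 14.0), 1.0),
    (2, (7.0, 10.0), 0.97),
    (2, (10.0, 14.0), 0.97),
    (3, (6.0, 9.0), 1.0),
    (3, (8.0, 11.0), 1.0),
    (3, (6.0, 9.0), 0.97),
    (1, (18.0, 22.0), 1.0),
    (2, (12.0, 16.0), 1.0),
    (3, (9.0, 12.0), 1.0),
    (1, (12.0, 18.0), 0.95),
]


def _scaled(rr: tuple[float, float], size: int) -> tuple[float, float]:
    """Subtype radius ranges are stated at the default 128-px scale."""
    f = size / 128.0
    return (rr[0] * f, rr[1] * f)


def _generate(specs_with_meta, snr_db, seed):
    rng = np.random.default_rng(seed)
    images, rows = [], []
    for i, (spec, label, subtype) in enumerate(specs_with_meta):
        img = make_phantom(spec, rng)
        if snr_db is not None:
            img = add_rician_noise(img, snr_db, rng)
        images.append(img)
        rows.append(
            {
                "filename": f"img_{i:04d}.png",
                "label": label,
                "subtype": subtype,
                "snr_db": snr_db if snr_db is not None else "",
                "seed": seed,
            }
        )
    labels = np.array([r["label"] for r in rows])
    return images, labels, pd.DataFrame(rows)


def make_dataset(
    n_benign: int,
    n_malignant: int,
    snr_db: float | None,
    seed: int,
    size: int = 128,
):
    """Balanced-composition generator: lesion-free benign phantoms vs
    single/multi-lesion malignant phantoms cycling over the subtype table.

    Returns ``(images, labels, manifest)`` with labels in {-1, +1}.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("both classes need at least one image")
    entries = []
    for _ in range(n_benign):
        entries.append((PhantomSpec(size=size, lesion_present=False),
                        BENIGN, "benign"))
    for k in range(n_malignant):
        n_les, rr, inten = _MALIGNANT_SUBTYPES[k % len(_MALIGNANT_SUBTYPES)]
        entries.append(
            (
                PhantomSpec(size=size, lesion_present=True, n_lesions=n_les,
                            lesion_radius_range=_scaled(rr, size),
                            lesion_intensity=inten),
                MALIGNANT,
                f"malignant_{k % len(_MALIGNANT_SUBTYPES) + 1:02d}",
            )
        )
    return _generate(entries, snr_db, seed)


def aanlib_style_dataset(seed: int, snr_db: float | None = 20.0,
                         size: int = 128):
    """90 images in 18 subtypes x 5 replicates: 1 benign subtype (5 images)
    and 17 malignant subtypes (85 images) differing in lesion count, size
    and contrast."""
    entries = []
    for _rep in range(5):
        entries.append((PhantomSpec(size=size, lesion_present=False),
                        BENIGN, "benign"))
        for s, (n_les, rr, inten) in enumerate(_MALIGNANT_SUBTYPES, start=1):
            entries.append(
                (
                    PhantomSpec(size=size, lesion_present=True,
                                n_lesions=n_les,
                                lesion_radius_range=_scaled(rr, size),
                                lesion_intensity=inten),
                    MALIGNANT,
                    f"malignant_{s:02d}",
                )
            )
    return _generate(entries, snr_db, seed)


def snr_sweep_datasets(seed: int, snr_levels=(5.0, 10.0, 15.0, 20.0),
                       n_per_class: int = 45, size: int = 128):
    """One balanced 2x``n_per_class`` dataset per SNR level, same phantom
    seed so only the noise level differs across entries."""
    return {
        snr: make_dataset(n_per_class, n_per_class, snr, seed, size=size)
        for snr in snr_levels
    }


def write_dataset(images, manifest: pd.DataFrame, outdir: str) -> str:
    """Write 8-bit grayscale PNGs plus manifest.csv; returns manifest path."""
    os.makedirs(outdir, exist_ok=True)
    for img, fname in zip(images, manifest["filename"]):
        arr = np.clip(img, 0.0, 1.0)
        Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(
            os.path.join(outdir, fname)
        )
    path = os.path.join(outdir, "manifest.csv")
    manifest.to_csv(path, index=False)
    return path
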