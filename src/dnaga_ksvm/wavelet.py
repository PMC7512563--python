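"""Decimated multilevel 2-D Haar wavelet decomposition of grayscale images.

Images are decomposed with the orthonormal Haar filter pair — low-pass
(1/sqrt(2), 1/sqrt(2)), high-pass (1/sqrt(2), -1/sqrt(2)) — applied
separably along each axis, with symmetric (half-point) boundary extension
and decimation by two. One level of the 2-D transform splits an image into
four sub-bands: the approximation LL and three detail bands HL
(high-frequency along width), LH (high-frequency along height) and HH
(diagonal). The LL band of each level feeds the next level, producing a
pyramid whose deepest approximation is the coarse image summary used for
feature extraction: a 128x128 input decomposed over three levels leaves a
16x16 = 256-coefficient approximation.

The filtering itself is delegated to PyWavelets (`haar`, mode
``symmetric``); this module owns the pyramid container, the sub-band
naming and ordering used downstream, validation, and serialization.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pywt

WAVELET = "haar"
#: symmetric half-point boundary extension, used to avoid boundary distortion
MODE = "symmetric"

#: detail sub-band order within one level, as consumed by feature extraction
DETAIL_NAMES = ("HL", "LH", "HH")

# Count of forward multilevel transforms run since import.  The
# cross-validation pipeline caches one pyramid per image; this counter makes
# the "the transform runs once per image" contract observable in tests.
_transform_calls = 0


def transform_call_count() -> int:
    """Number of multilevel forward transforms executed so far."""
    return _transform_calls


def _validate_image(img: np.ndarray, min_size: int = 2) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={img.ndim}")
    h, w = img.shape
    if h < min_size or w < min_size:
        raise ValueError(f"image {h}x{w} is smaller than {min_size}x{min_size}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    return img


@dataclass
class WaveletPyramid:
    """Multilevel 2-D DWT coefficients.

    Attributes
    ----------
    approximation
        The LL band at the deepest level J.
    details
        ``details[j-1]`` holds the level-j detail bands as a dict with keys
        ``HL``, ``LH``, ``HH`` (level 1 = finest).
    input_shape
        Shape of the original image, needed for exact inversion when a
        dimension is odd at some level.
    """

    approximation: np.ndarray
    details: list[dict[str, np.ndarray]]
    input_shape: tuple[int, int] = field(default=(0, 0))

    @property
    def levels(self) -> int:
        return len(self.details)

    def subbands(self) -> list[tuple[str, np.ndarray]]:
        """Named sub-bands in feature order: LL_J, then (HL, LH, HH) for
        levels 1..J."""
        out = [(f"LL{self.levels}", self.approximation)]
        for j, det in enumerate(self.details, start=1):
            out.extend((f"{name}{j}", det[name]) for name in DETAIL_NAMES)
        return out

    def validate(self) -> None:
        """Check internal shape consistency (each level ceil-halves)."""
        if self.levels < 1:
            raise ValueError("pyramid must hold at least one level")
        h, w = self.input_shape
        for j, det in enumerate(self.details, start=1):
            expect = (math.ceil(h / 2**j), math.ceil(w / 2**j))
            for name in DETAIL_NAMES:
                if det[name].shape != expect:
                    raise ValueError(
                        f"{name}{j} has shape {det[name].shape}, expected {expect}"
                    )
        if self.approximation.shape != self.details[-1]["HH"].shape:
            raise ValueError("approximation shape does not match deepest details")

    def energy(self) -> float:
        return float(
            sum(np.sum(b * b) for _, b in self.subbands())
        )

    def save_csv(self, outdir: str) -> list[str]:
        """Dump each sub-band as a headerless CSV (debug aid)."""
        os.makedirs(outdir, exist_ok=True)
        paths = []
        for name, band in self.subbands():
            p = os.path.join(outdir, f"{name}.csv")
            np.savetxt(p, band, delimiter=",")
            paths.append(p)
        return paths


def dwt2d_single(img: np.ndarray) -> dict[str, np.ndarray]:
    """One level of the 2-D Haar DWT.

    Returns the four sub-bands ``{"LL", "HL", "LH", "HH"}``, each of shape
    ``(ceil(h/2), ceil(w/2))``.
    """
    img = _validate_image(img, min_size=2)
    cA, (cH, cV, cD) = pywt.dwt2(img, WAVELET, mode=MODE)
    # cV varies along the width (columns), cH along the height (rows)
    return {"LL": cA, "HL": cV, "LH": cH, "HH": cD}


def dwt2d_multilevel(img: np.ndarray, levels: int) -> WaveletPyramid:
    """Recursive decomposition: the LL band of each level feeds the next."""
    global _transform_calls
    img = _validate_image(img, min_size=2)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    d = min(img.shape)
    for _ in range(levels):
        if d < 2:
            raise ValueError(
                f"image {img.shape} is too small for a {levels}-level decomposition"
            )
        d = math.ceil(d / 2)
    details: list[dict[str, np.ndarray]] = []
    approx = img
    for _ in range(levels):
        bands = dwt2d_single(approx)
        approx = bands.pop("LL")
        details.append(bands)
    _transform_calls += 1
    return WaveletPyramid(approximation=approx, details=details,
                          input_shape=img.shape)


def idwt2d_multilevel(
    pyramid: WaveletPyramid, target_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Inverse transform back to an image.

    For dyadic input sizes the round trip ``idwt2d_multilevel(
    dwt2d_multilevel(x, J))`` recovers ``x`` to ~1e-12 (orthonormal
    filters); odd sizes are handled by cropping the one-sample overshoot at
    each level.
    """
    pyramid.validate()
    if target_shape is None:
        target_shape = pyramid.input_shape
    h, w = target_shape
    rec = pyramid.approximation
    for j in range(pyramid.levels, 0, -1):
        det = pyramid.details[j - 1]
        rec = pywt.idwt2((rec, (det["LH"], det["HL"], det["HH"])),
                         WAVELET, mode=MODE)
        hj = math.ceil(h / 2 ** (j - 1))
        wj = math.ceil(w / 2 ** (j - 1))
        rec = rec[:hj, :wj]
    return rec
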