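"""Synthetic speckle-phantom cohorts.

Generates seeded grayscale "ultrasound-like" images with class-dependent
texture and a single elliptical lesion mask, so the whole few-shot pipeline
is testable without private clinical data.  Speckle is emulated as
multiplicative gamma noise with unit mean — the standard surrogate for the
granular noise of coherent imaging; lower gamma shape means grainier
texture.  No acoustic physics is simulated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhantomClassSpec",
    "LabeledImage",
    "make_speckle",
    "make_lesion_mask",
    "render_phantom",
    "generate_cohort",
    "DEFAULT_PRESETS",
]

DEFAULT_IMAGE_SIZE = (256, 256)

#: sinusoidal grating wavelength in pixels, shared by all classes
GRATING_WAVELENGTH = 16.0

MIN_MASK_PIXELS = 32


@dataclasses.dataclass(frozen=True)
class PhantomClassSpec:
    """Texture recipe for one phantom class.

    Parameters
    ----------
    class_id : int
        Label in {0, 1, 2}.
    base_intensity : float
        Mean background brightness, in (0, 1).
    speckle_shape : float
        Gamma shape of the multiplicative speckle; lower is grainier.
    grating_amplitude : float
        Amplitude of an oriented sinusoidal grating added to the base field.
    grating_angle_deg : float
        Grating orientation in [0, 180) degrees.
    blob_count : int
        Number of Gaussian blobs placed inside the lesion.
    blob_contrast : float
        Peak amplitude of each blob (signed).
    """

    class_id: int
    base_intensity: float
    speckle_shape: float
    grating_amplitude: float = 0.0
    grating_angle_deg: float = 0.0
    blob_count: int = 0
    blob_contrast: float = 0.0

    def __post_init__(self) -> None:
        if self.class_id not in (0, 1, 2):
            raise ValueError(f"class_id must be in {{0,1,2}}, got {self.class_id}")
        if not 0.0 < self.base_intensity < 1.0:
            raise ValueError(f"base_intensity must lie in (0,1), got {self.base_intensity}")
        if self.speckle_shape <= 0:
            raise ValueError(f"speckle_shape must be positive, got {self.speckle_shape}")
        if self.grating_amplitude < 0:
            raise ValueError("grating_amplitude must be >= 0")
        if not 0.0 <= self.grating_angle_deg < 180.0:
            raise ValueError("grating_angle_deg must lie in [0,180)")
        if self.blob_count < 0:
            raise ValueError("blob_count must be >= 0")


@dataclasses.dataclass(frozen=True)
class LabeledImage:
    """A grayscale image with its binary lesion mask and class label."""

    pixels: np.ndarray
    mask: np.ndarray
    label: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"pixels {self.pixels.shape} and mask {self.mask.shape} differ for {self.sample_id}"
            )
        if int(self.mask.sum()) < MIN_MASK_PIXELS:
            raise ValueError(f"mask of {self.sample_id} has < {MIN_MASK_PIXELS} foreground pixels")
        if self.label not in (0, 1, 2):
            raise ValueError(f"label must be in {{0,1,2}}, got {self.label}")


#: three presets loosely mimicking a smooth, a directional and a
#: heterogeneous lesion texture; no clinical fidelity is claimed.
DEFAULT_PRESETS: dict[str, PhantomClassSpec] = {
    "homogeneous": PhantomClassSpec(
        class_id=0, base_intensity=0.55, speckle_shape=12.0
    ),
    "directional": PhantomClassSpec(
        class_id=1, base_intensity=0.50, speckle_shape=4.0,
        grating_amplitude=0.18, grating_angle_deg=30.0,
    ),
    "heterogeneous": PhantomClassSpec(
        class_id=2, base_intensity=0.50, speckle_shape=1.5,
        blob_count=6, blob_contrast=0.30,
    ),
}


def _unit_mean_gamma(shape: tuple[int, int], speckle_shape: float, rng: np.random.Generator) -> np.ndarray:
    # gamma(a, scale=1/a) has mean 1 and variance 1/a
    return rng.gamma(speckle_shape, 1.0 / speckle_shape, size=shape)


def make_speckle(shape: tuple[int, int], speckle_shape: float, seed: int) -> np.ndarray:
    """Multiplicative gamma speckle applied to a unit field, rescaled into [0, 1].

    The raw field is unit-mean gamma noise (variance 1/``speckle_shape``);
    it is clipped at zero and divided by its maximum so the output lies in
    [0, 1].  In the large-shape limit the noise vanishes and the field
    tends to a constant 1.  A degenerate (constant) field maps to ones.
    """
    if speckle_shape <= 0:
        raise ValueError(f"speckle_shape must be positive, got {speckle_shape}")
    rng = np.random.default_rng(seed)
    field = np.clip(_unit_mean_gamma(shape, speckle_shape, rng), 0.0, None)
    hi = field.max()
    if hi == 0.0:
        return np.ones(shape, dtype=float)
    return field / hi


def make_lesion_mask(shape: tuple[int, int], seed: int) -> np.ndarray:
    """A single filled ellipse covering 5–40 % of the image, seeded.

    Center, area fraction, aspect ratio and orientation are drawn from
    uniform ranges chosen so the ellipse always fits inside the frame.
    """
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError(f"image must be at least 64x64, got {h}x{w}")
    rng = np.random.default_rng(seed)
    # target area fraction kept inside (0.05, 0.40) with margin for
    # rasterization error
    frac = rng.uniform(0.08, 0.35)
    aspect = rng.uniform(0.55, 1.0)
    angle = rng.uniform(0.0, np.pi)
    area = frac * h * w
    # pi * a * b = area, b = aspect * a
    a = np.sqrt(area / (np.pi * aspect))
    b = aspect * a
    # bounding half-extent of the rotated ellipse along each axis
    ext_x = np.sqrt((a * np.cos(angle)) ** 2 + (b * np.sin(angle)) ** 2)
    ext_y = np.sqrt((a * np.sin(angle)) ** 2 + (b * np.cos(angle)) ** 2)
    cx = rng.uniform(ext_x + 1, w - ext_x - 1)
    cy = rng.uniform(ext_y + 1, h - ext_y - 1)
    yy, xx = np.mgrid[0:h, 0:w]
    xr = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    yr = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    return mask.astype(bool)


def render_phantom(
    spec: PhantomClassSpec,
    seed: int,
    size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
) -> LabeledImage:
    """Render one phantom: base + grating + lesion blobs, times speckle.

    The noise-free field is ``base_intensity`` plus an oriented sinusoidal
    grating plus ``blob_count`` Gaussian blobs confined to the lesion; the
    field is multiplied by unit-mean gamma speckle and clipped to [0, 1].
    """
    h, w = size
    ss = np.random.SeedSequence([int(seed), spec.class_id])
    mask_seed = int(ss.generate_state(1)[0] % (2**31))
    s_blob, s_speck = [np.random.default_rng(c) for c in ss.spawn(2)]

    mask = make_lesion_mask(size, seed=mask_seed)
    yy, xx = np.mgrid[0:h, 0:w]

    field = np.full(size, spec.base_intensity, dtype=float)
    if spec.grating_amplitude > 0:
        theta = np.deg2rad(spec.grating_angle_deg)
        # wavefronts perpendicular to (cos, sin)
        phase = 2.0 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / GRATING_WAVELENGTH
        field = field + spec.grating_amplitude * np.sin(phase)

    if spec.blob_count > 0:
        fg_rows, fg_cols = np.nonzero(mask)
        for _ in range(spec.blob_count):
            i = s_blob.integers(0, fg_rows.size)
            cy, cx = fg_rows[i], fg_cols[i]
            sigma = s_blob.uniform(4.0, 10.0)
            sign = s_blob.choice([-1.0, 1.0])
            field = field + sign * spec.blob_contrast * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
            )

    speckle = _unit_mean_gamma(size, spec.speckle_shape, s_speck)
    pixels = np.clip(field * speckle, 0.0, 1.0)
    return LabeledImage(pixels=pixels, mask=mask, label=spec.class_id, sample_id=f"c{spec.class_id}_s{seed}")


def _to_png(arr: np.ndarray, path: Path) -> None:
    img = Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L")
    img.save(path, format="PNG")


def generate_cohort(
    specs: list[PhantomClassSpec],
    n_per_class: int,
    out_dir: str | Path,
    seed: int,
    size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
) -> pd.DataFrame:
    """Write a class-balanced cohort of PNG image/mask pairs plus a manifest.

    Every sample's seed derives deterministically from (``seed``, class,
    index), so the cohort is byte-identical across reruns.  The manifest CSV
    has columns ``sample_id,image_path,mask_path,label`` with paths relative
    to the manifest location.

    Returns the manifest as a DataFrame.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in specs:
        for i in range(n_per_class):
            sample_seed = int(
                np.random.SeedSequence([int(seed), spec.class_id, i]).generate_state(1)[0] % (2**31)
            )
            img = render_phantom(spec, seed=sample_seed, size=size)
            sample_id = f"c{spec.class_id}_{i:04d}"
            image_path = f"{sample_id}.png"
            mask_path = f"{sample_id}_mask.png"
            _to_png(img.pixels, out_dir / image_path)
            _to_png(img.mask.astype(float), out_dir / mask_path)
            rows.append(
                {"sample_id": sample_id, "image_path": image_path, "mask_path": mask_path, "label": spec.class_id}
            )
    manifest = pd.DataFrame(rows, columns=["sample_id", "image_path", "mask_path", "label"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
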