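"""Seeded synthetic natural-image surrogates and sparse-synthesis fixtures.

Three generators stand in for photographic material so that the whole
pipeline can be exercised reproducibly without downloads:

* pink noise — random-phase images whose radially averaged amplitude
  spectrum falls off as omega^(-exponent) (exponent 1 by default), the
  canonical second-order statistic of natural scenes;
* dead leaves — occluding random discs with a power-law radius
  distribution, reproducing the sharp luminance edges and occlusion
  structure that natural images have and pink noise lacks;
* sparse synthesis — patches built as known sparse combinations of a
  ground-truth dictionary, providing exact codes for recovery experiments.

All generators are pure functions of their parameters (seed included).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .dictionary_init import Dictionary
from .exceptions import DomainError
from .image_prep import NaturalImage, PatchSet

DEFAULT_SIZE = 540


@dataclasses.dataclass
class SyntheticSpec:
    """Declarative recipe for one synthetic image."""

    kind: str  # pink_noise | dead_leaves
    size: int = DEFAULT_SIZE
    seed: int = 0
    exponent: float = 1.0  # pink noise spectral exponent
    r_min: float = 2.0  # dead-leaves disc radii (pixels)
    r_max: float = 100.0
    radius_power: float = 3.0

    def generate(self) -> NaturalImage:
        if self.kind == "pink_noise":
            return generate_pink_noise(self.size, self.exponent, self.seed)
        if self.kind == "dead_leaves":
            return generate_dead_leaves(
                self.size, self.seed, self.r_min, self.r_max, self.radius_power
            )
        raise DomainError(f"unknown synthetic image kind {self.kind!r}")


def _rescale_255(pixels: np.ndarray) -> np.ndarray:
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return np.zeros_like(pixels)
    return 255.0 * (pixels - lo) / (hi - lo)


def generate_pink_noise(
    size: int = DEFAULT_SIZE, exponent: float = 1.0, seed: int = 0
) -> NaturalImage:
    """Random image with a power-law (1/f^exponent) amplitude spectrum.

    White Gaussian noise is shaped in the frequency domain by
    omega^(-exponent) (DC removed), transformed back and rescaled to
    [0, 255].  ``exponent = 0`` gives spectrally flat white noise.
    """
    if size < 32:
        raise DomainError("size must be at least 32")
    if exponent < 0:
        raise DomainError("spectral exponent must be non-negative")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    wy = 2 * np.pi * np.fft.fftfreq(size)[:, None]
    wx = 2 * np.pi * np.fft.fftfreq(size)[None, :]
    radial = np.hypot(wy, wx)
    shaping = np.zeros_like(radial)
    nonzero = radial > 0
    shaping[nonzero] = radial[nonzero] ** (-exponent)
    pixels = np.real(np.fft.ifft2(np.fft.fft2(white) * shaping))
    return NaturalImage(_rescale_255(pixels))


def generate_dead_leaves(
    size: int = DEFAULT_SIZE,
    seed: int = 0,
    r_min: float = 2.0,
    r_max: float = 100.0,
    radius_power: float = 3.0,
    max_discs: int = 200_000,
) -> NaturalImage:
    """Occluding-disc ("dead leaves") image with power-law disc radii.

    Discs with radius density proportional to r^(-radius_power) on
    [r_min, r_max] and uniform random intensities are laid down front to
    back: each new disc paints only pixels not yet covered, and generation
    stops when the canvas is fully covered (or at ``max_discs``).
    """
    if size < 32:
        raise DomainError("size must be at least 32")
    if r_min <= 0 or r_max <= r_min or radius_power <= 1:
        raise DomainError("degenerate radius law")
    rng = np.random.default_rng(seed)
    pixels = np.full((size, size), 128.0)
    covered = np.zeros((size, size), dtype=bool)
    # Inverse-CDF sampling for p(r) ~ r^(-a): F^-1(u) with a != 1.
    a = radius_power
    lo, hi = r_min ** (1 - a), r_max ** (1 - a)
    remaining = size * size
    for _ in range(max_discs):
        u = rng.random()
        r = (lo + u * (hi - lo)) ** (1.0 / (1 - a))
        cy, cx = rng.random(2) * size
        intensity = rng.random() * 255.0
        y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 2, size)
        x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 2, size)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.ogrid[y0:y1, x0:x1]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        patch_cov = covered[y0:y1, x0:x1]
        new = disc & ~patch_cov
        n_new = int(new.sum())
        if n_new:
            pixels[y0:y1, x0:x1][new] = intensity
            patch_cov |= disc
            remaining -= n_new
            if remaining == 0:
                break
    return NaturalImage(pixels)


def generate_sparse_synthesis(
    dictionary: Dictionary,
    n_patches: int,
    k_active: int,
    noise_sd: float,
    seed: int = 0,
    amp_range: tuple[float, float] = (0.5, 1.5),
) -> tuple[PatchSet, np.ndarray]:
    """Patches synthesized as known sparse combinations of a dictionary.

    Each patch activates ``k_active`` distinct atoms with random signs and
    amplitudes uniform in ``amp_range``, plus i.i.d. Gaussian pixel noise.
    Returns the patch set and the true codes as an (n_patches, P) array.
    """
    P = dictionary.P
    if not 0 <= k_active <= P:
        raise DomainError(f"k_active must lie in [0, {P}]")
    rng = np.random.default_rng(seed)
    G = dictionary.as_matrix()
    codes = np.zeros((n_patches, P))
    for i in range(n_patches):
        support = rng.choice(P, size=k_active, replace=False)
        amps = rng.uniform(*amp_range, size=k_active)
        signs = rng.choice([-1.0, 1.0], size=k_active)
        codes[i, support] = signs * amps
    f = dictionary.frame_size
    patches = (codes @ G.T).reshape(n_patches, f, f)
    if noise_sd > 0:
        patches = patches + noise_sd * rng.standard_normal(patches.shape)
    return (
        PatchSet(patches=patches, frame_size=f, preprocessing="sparse_synthesis"),
        codes,
    )


def generate_fixture_corpus(
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_images: int = 10,
    size: int = DEFAULT_SIZE,
) -> tuple[list[NaturalImage], list[dict]]:
    """A seeded corpus of natural-image surrogates (half pink, half discs).

    Returns the images and a manifest of per-image specs; regenerating from
    the manifest reproduces the corpus bit-exactly.  When ``out_dir`` is
    given, images are written as 8-bit PNGs alongside ``manifest.json``.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_images)
    images, manifest = [], []
    for i in range(n_images):
        kind = "pink_noise" if i < (n_images + 1) // 2 else "dead_leaves"
        spec = SyntheticSpec(kind=kind, size=size, seed=int(child_seeds[i]))
        images.append(spec.generate())
        manifest.append(dataclasses.asdict(spec))
    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, (img, entry) in enumerate(zip(images, manifest)):
            name = f"synthetic_{i:02d}_{entry['kind']}.png"
            iio.imwrite(out / name, np.round(img.pixels).astype(np.uint8))
            entry["file"] = name
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return images, manifest
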