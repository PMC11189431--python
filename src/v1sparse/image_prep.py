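"""Image loading and preprocessing for patch-based sparse coding.

The coding pipeline mirrors the early visual pathway: a retina-like
element-wise logarithm compresses the dynamic range, a zero-phase radial
whitening/low-pass filter flattens the ~1/f amplitude spectrum of natural
scenes (so that a mean-square reconstruction error does not favour low
frequencies), and the filtered image is tiled into non-overlapping square
frames that become the units of sparse coding.

The whitening transfer profile is

    H(omega) = (omega / 2 pi) * exp(-(omega / 0.4 pi)^4),   omega in [0, pi],

applied radially in the 2D discrete-frequency plane with zero phase.  The
linear ramp compensates the 1/f spectral fall-off of natural images; the
quartic-exponential roll-off suppresses the highest frequencies, where
rectangular sampling artefacts live.  H(0) = 0, so whitening removes the DC
component exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from .exceptions import DomainError, ShapeError

DEFAULT_FRAME_SIZE = 12
DEFAULT_LOG_OFFSET = 1.0
#: Shape parameter of the quartic roll-off, in rad/pixel.
WHITENING_CUTOFF = 0.4 * np.pi


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class NaturalImage:
    """A 2D grayscale image with non-negative intensities.

    Multi-channel input is reduced to grayscale by a luminance average over
    channels at load time.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ShapeError(f"image must be 2D, got shape {self.pixels.shape}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_file(cls, path: str | Path) -> "NaturalImage":
        """Load a PNG/TIFF/PGM image; multi-channel data is channel-averaged."""
        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        return cls(arr)


@dataclasses.dataclass
class WhiteningFilter:
    """Zero-phase radial whitening/low-pass filter.

    ``cutoff`` is the shape parameter of the quartic exponential roll-off in
    rad/pixel.  The filter is real and radially symmetric in frequency, so it
    is applied with exactly zero phase.
    """

    cutoff: float = WHITENING_CUTOFF
    zero_phase: bool = True

    def profile(self, omega):
        return whitening_profile(omega, cutoff=self.cutoff)

    def response_grid(self, shape: tuple[int, int]) -> np.ndarray:
        """Transfer values on the DFT grid of ``shape``.

        Per-axis angular frequencies come from the discrete Fourier grid in
        [-pi, pi); the radial frequency is their Euclidean norm, clipped to
        pi at the grid corners.
        """
        wy = 2.0 * np.pi * np.fft.fftfreq(shape[0])
        wx = 2.0 * np.pi * np.fft.fftfreq(shape[1])
        radial = np.hypot(wy[:, None], wx[None, :])
        radial = np.minimum(radial, np.pi)
        return self.profile(radial)


@dataclasses.dataclass
class PatchSet:
    """Non-overlapping square patches cut from one or more images.

    ``offsets`` holds the (row, col) of each patch's top-left corner in its
    source image; offsets are multiples of ``frame_size`` (partial border
    frames are discarded).
    """

    patches: np.ndarray
    frame_size: int
    offsets: np.ndarray | None = None
    preprocessing: str = "raw"

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=float)
        if self.patches.ndim != 3:
            raise ShapeError("patches must be a (count, frame, frame) array")
        f = int(self.frame_size)
        if self.patches.shape[1:] != (f, f):
            raise ShapeError(
                f"every patch must be {f}x{f}, got {self.patches.shape[1:]}"
            )
        if self.offsets is None:
            self.offsets = np.zeros((len(self.patches), 2), dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=int)

    def __len__(self) -> int:
        return len(self.patches)

    def as_matrix(self) -> np.ndarray:
        """Patches flattened row-major to a (count, frame**2) matrix."""
        return self.patches.reshape(len(self.patches), -1)

    def reassemble(self) -> np.ndarray:
        """Place patches back at their offsets (single-image patch sets)."""
        rows = self.offsets[:, 0].max() + self.frame_size
        cols = self.offsets[:, 1].max() + self.frame_size
        out = np.zeros((rows, cols))
        for patch, (r, c) in zip(self.patches, self.offsets):
            out[r : r + self.frame_size, c : c + self.frame_size] = patch
        return out

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("patches", data=self.patches)
            f.create_dataset("offsets", data=self.offsets)
            f.attrs["frame_size"] = self.frame_size
            f.attrs["preprocessing"] = self.preprocessing

    @classmethod
    def load(cls, path: str | Path) -> "PatchSet":
        with h5py.File(path, "r") as f:
            return cls(
                patches=f["patches"][...],
                offsets=f["offsets"][...],
                frame_size=int(f.attrs["frame_size"]),
                preprocessing=str(f.attrs["preprocessing"]),
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def whitening_profile(omega, cutoff: float = WHITENING_CUTOFF):
    """Radial whitening/low-pass transfer value at ``omega`` (rad/pixel).

    H(omega) = (omega / 2 pi) * exp(-(omega / cutoff)^4) for omega in [0, pi].
    Accepts scalars or arrays; raises :class:`DomainError` outside [0, pi].
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0) or np.any(w > np.pi * (1 + 1e-12)):
        raise DomainError("omega must lie in [0, pi] rad/pixel")
    out = (w / (2.0 * np.pi)) * np.exp(-((w / cutoff) ** 4))
    return out if out.ndim else float(out)


def whiten_image(
    image: NaturalImage | np.ndarray, filt: WhiteningFilter | None = None
) -> np.ndarray:
    """Apply the zero-phase radial whitening filter to a whole image.

    The image spectrum is multiplied by H(radial omega) on the DFT grid and
    transformed back; periodic boundary conditions are implied by the FFT.
    Since H(0) = 0 the output has (numerically) zero mean, and the output is
    invariant to adding a constant to the input.
    """
    pixels = image.pixels if isinstance(image, NaturalImage) else np.asarray(image, float)
    if pixels.size == 0:
        raise DomainError("cannot whiten an empty image")
    if filt is None:
        filt = WhiteningFilter()
    spectrum = np.fft.fft2(pixels)
    out = np.fft.ifft2(spectrum * filt.response_grid(pixels.shape))
    return np.real(out)


def log_transform(
    image: NaturalImage | np.ndarray, offset: float = DEFAULT_LOG_OFFSET
) -> np.ndarray:
    """Retina-like element-wise logarithm: log(pixel + offset).

    ``offset`` (default 1.0 on raw 0-255 intensities) avoids log(0).  Two
    images differing by a multiplicative gain map to outputs differing by an
    additive constant, which the subsequent whitening removes.
    """
    pixels = image.pixels if isinstance(image, NaturalImage) else np.asarray(image, float)
    if offset <= 0:
        raise DomainError("log offset must be positive")
    if np.any(pixels < 0):
        raise DomainError("intensities must be non-negative before the log transform")
    return np.log(pixels + offset)


def segment_image(
    image: NaturalImage | np.ndarray, frame_size: int = DEFAULT_FRAME_SIZE
) -> PatchSet:
    """Tile an image into non-overlapping frame_size x frame_size patches.

    Patches are emitted in row-major order; partial border frames are
    discarded (floor division), so an H x W image yields
    floor(H/frame) * floor(W/frame) patches.
    """
    pixels = image.pixels if isinstance(image, NaturalImage) else np.asarray(image, float)
    if frame_size <= 0:
        raise DomainError("frame_size must be a positive integer")
    h, w = pixels.shape
    if h < frame_size or w < frame_size:
        raise DomainError("image smaller than one frame")
    nr, nc = h // frame_size, w // frame_size
    cropped = pixels[: nr * frame_size, : nc * frame_size]
    patches = (
        cropped.reshape(nr, frame_size, nc, frame_size)
        .swapaxes(1, 2)
        .reshape(nr * nc, frame_size, frame_size)
    )
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    offsets = np.stack([rr.ravel(), cc.ravel()], axis=1) * frame_size
    return PatchSet(patches=patches, frame_size=frame_size, offsets=offsets)


def preprocess_image(
    image: NaturalImage | np.ndarray,
    frame_size: int = DEFAULT_FRAME_SIZE,
    order: tuple[str, ...] = ("log", "whiten"),
    log_offset: float = DEFAULT_LOG_OFFSET,
    filt: WhiteningFilter | None = None,
) -> PatchSet:
    """Full pipeline: (log, whiten) in the configured order, then segment.

    Whitening is applied to the whole image rather than per patch, which
    avoids per-patch boundary artefacts; segmentation always comes last.
    """
    pixels = image.pixels if isinstance(image, NaturalImage) else np.asarray(image, float)
    for step in order:
        if step == "log":
            pixels = log_transform(pixels, offset=log_offset)
        elif step == "whiten":
            pixels = whiten_image(pixels, filt=filt)
        else:
            raise DomainError(f"unknown preprocessing step {step!r}")
    patch_set = segment_image(pixels, frame_size=frame_size)
    patch_set.preprocessing = "+".join(order) if order else "raw"
    return patch_set
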