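"""GUV image analysis: segmentation, recruitment, ratiometric lipid order,
condensate detection and the granulosity index.

The stages here mirror a standard confocal workflow on giant unilamellar
vesicles (GUVs): the membrane channel is Gaussian-blurred and thresholded to
build a mask; protein recruitment is the mean protein intensity over that
mask; the relative lipid order φ of a solvatochromic membrane probe is the
ratio of a blue/green to a red emission window over the mask; condensates
are connected components above an area cut; and the granulosity index is
the sd/mean of a Fourier high-pass-filtered image, a texture measure that
is 0 for a uniform field and grows with condensate content.

All coordinates are 0-based (row, col); areas are reported in µm² through
the channel's pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .errors import (
    DivisionByZeroError,
    EmptyMaskError,
    NoForegroundError,
    ParameterError,
    UndefinedIndexError,
)

__all__ = [
    "ImageChannel",
    "RegionMask",
    "RecruitmentMeasure",
    "PhiResult",
    "Condensate",
    "GranulosityResult",
    "segment_guv",
    "quantify_recruitment",
    "compute_phi",
    "compute_phi_live",
    "detect_condensates",
    "granulosity_index",
]


@dataclass
class ImageChannel:
    """A single 2-D fluorescence channel with physical pixel size.

    Parameters
    ----------
    intensities : ndarray, shape (rows, cols)
        Non-negative intensity grid.
    pixel_size_um : float
        Physical edge length of one pixel in µm (> 0).
    label : str
        Free-form channel name (e.g. ``"membrane"``, ``"protein"``).
    """

    intensities: np.ndarray
    pixel_size_um: float
    label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ParameterError("ImageChannel requires a 2-D intensity grid")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if np.any(self.intensities < 0):
            raise ParameterError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


@dataclass
class RegionMask:
    """Boolean pixel mask tied to the pixel size of its source channel."""

    flags: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ParameterError("RegionMask requires a 2-D boolean grid")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")

    @property
    def n_pixels(self) -> int:
        return int(self.flags.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size_um ** 2


@dataclass
class RecruitmentMeasure:
    """Protein recruitment over a membrane mask.

    ``intensity_per_area`` equals the mean masked protein intensity
    (integrated intensity normalised to the mask pixel count), the readout
    used to compare recruitment across conditions.
    """

    integrated_intensity: float
    area_um2: float
    intensity_per_area: float


@dataclass
class PhiResult:
    """Relative lipid order φ over a region.

    φ is the ratio of the summed blue/green-window intensity to the summed
    red-window intensity over the masked membrane pixels; higher φ means
    more ordered (tightly packed) lipids.
    """

    phi: float
    n_pixels: int
    valid: bool = True
    ratio_map: Optional[np.ndarray] = None
    region_id: Optional[int] = None


@dataclass
class Condensate:
    centroid: tuple[float, float]
    area_um2: float
    mean_intensity: float


@dataclass
class GranulosityResult:
    index: float
    highpass_radius: float


def _threshold(values: np.ndarray, method: str, fixed_value: Optional[float]) -> float:
    if method == "otsu":
        if np.ptp(values) == 0:
            raise NoForegroundError("constant image: Otsu threshold undefined")
        return float(filters.threshold_otsu(values))
    if method == "fixed":
        if fixed_value is None:
            raise ParameterError("fixed threshold requested without fixed_value")
        return float(fixed_value)
    raise ParameterError(f"unknown threshold method {method!r}")


def segment_guv(
    membrane: ImageChannel,
    blur_sigma_px: float = 1.5,
    threshold_method: str = "otsu",
    fixed_value: Optional[float] = None,
) -> RegionMask:
    """Segment GUV membranes: Gaussian blur then intensity threshold.

    The default blur sigma of 1.5 px suppresses detector noise before
    thresholding. Otsu thresholding is the parameter-free default; a fixed
    intensity can be supplied instead.

    Raises
    ------
    NoForegroundError
        If the image is constant or thresholding yields an empty mask.
    """
    img = membrane.intensities
    if img.size == 0:
        raise ParameterError("empty image")
    blurred = ndimage.gaussian_filter(img, sigma=blur_sigma_px)
    thr = _threshold(blurred, threshold_method, fixed_value)
    flags = blurred > thr
    if not flags.any():
        raise NoForegroundError("threshold yields an empty mask")
    return RegionMask(flags=flags, pixel_size_um=membrane.pixel_size_um)


def quantify_recruitment(protein: ImageChannel, mask: RegionMask) -> RecruitmentMeasure:
    """Integrated protein intensity within the GUV mask, normalised to area.

    Raises :class:`EmptyMaskError` for a mask with no pixels.
    """
    if protein.shape != mask.flags.shape:
        raise ParameterError("protein channel and mask shapes differ")
    if mask.n_pixels == 0:
        raise EmptyMaskError("mask contains no pixels")
    values = protein.intensities[mask.flags]
    integrated = float(values.sum())
    return RecruitmentMeasure(
        integrated_intensity=integrated,
        area_um2=mask.area_um2,
        intensity_per_area=float(values.mean()),
    )


def compute_phi(
    blue_green: ImageChannel,
    red: ImageChannel,
    mask: RegionMask,
    outside_to_zero: bool = True,
) -> PhiResult:
    """Relative lipid order φ = Σ(blue/green) / Σ(red) over the mask.

    The ratio of masked sums is robust to per-pixel division noise; the
    per-pixel ratio map is also returned for display, with out-of-mask
    pixels zeroed when ``outside_to_zero`` (mirroring how regions outside
    the GUV mask are set to grey value 0 before ratioing).
    """
    if blue_green.shape != red.shape or blue_green.shape != mask.flags.shape:
        raise ParameterError("channel and mask shapes differ")
    red_sum = float(red.intensities[mask.flags].sum())
    if red_sum <= 0:
        raise DivisionByZeroError("masked red-window sum is zero")
    bg_sum = float(blue_green.intensities[mask.flags].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(red.intensities > 0, blue_green.intensities / np.maximum(red.intensities, 1e-300), 0.0)
    if outside_to_zero:
        ratio = np.where(mask.flags, ratio, 0.0)
    return PhiResult(phi=bg_sum / red_sum, n_pixels=mask.n_pixels, ratio_map=ratio)


def compute_phi_live(
    blue_green: ImageChannel,
    red: ImageChannel,
    lysosome_regions: Sequence[RegionMask],
    background_region: RegionMask,
) -> list[PhiResult]:
    """Per-lysosome φ with scalar background subtraction (live-cell variant).

    A per-channel background level (mean over ``background_region``) is
    subtracted from both emission windows before ratioing; negative
    post-subtraction pixels are clipped to 0. A region whose
    background-subtracted red sum is non-positive is returned flagged
    invalid (``valid=False``, φ = nan) rather than silently dropped.
    """
    if background_region.n_pixels == 0:
        raise EmptyMaskError("background region is empty")
    for region in lysosome_regions:
        if np.any(region.flags & background_region.flags):
            raise ParameterError("background region overlaps a lysosome region")
    bg_blue = float(blue_green.intensities[background_region.flags].mean())
    bg_red = float(red.intensities[background_region.flags].mean())
    blue_sub = np.clip(blue_green.intensities - bg_blue, 0.0, None)
    red_sub = np.clip(red.intensities - bg_red, 0.0, None)
    results: list[PhiResult] = []
    for i, region in enumerate(lysosome_regions):
        red_sum = float(red_sub[region.flags].sum())
        if red_sum <= 0:
            results.append(PhiResult(phi=float("nan"), n_pixels=region.n_pixels,
                                     valid=False, region_id=i))
            continue
        phi = float(blue_sub[region.flags].sum()) / red_sum
        results.append(PhiResult(phi=phi, n_pixels=region.n_pixels, valid=True, region_id=i))
    return results


def detect_condensates(
    channel: ImageChannel,
    threshold_method: str = "otsu",
    fixed_value: Optional[float] = None,
    min_area_um2: float = 0.0,
) -> list[Condensate]:
    """Detect condensates as 8-connected components above an intensity
    threshold, dropping components smaller than ``min_area_um2``.

    A blank (constant) field returns an empty list.
    """
    img = channel.intensities
    if np.ptp(img) == 0 and threshold_method == "otsu":
        return []
    thr = _threshold(img, threshold_method, fixed_value)
    binary = img > thr
    if not binary.any():
        return []
    labels = measure.label(binary, connectivity=2)
    px_area = channel.pixel_area_um2
    out: list[Condensate] = []
    for region in measure.regionprops(labels, intensity_image=img):
        area = region.area * px_area
        if area <= min_area_um2:
            continue
        out.append(
            Condensate(
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                area_um2=float(area),
                mean_intensity=float(region.intensity_mean),
            )
        )
    return out


def highpass_filter(
    image: np.ndarray, highpass_radius: float, keep_dc: bool = True
) -> np.ndarray:
    """Circular Fourier high-pass: zero radial frequencies < highpass_radius.

    ``highpass_radius`` is in cycles per image dimension. The DC component
    is retained by default so that the filtered image keeps the original
    mean (see :func:`granulosity_index`).
    """
    rows, cols = image.shape
    fy = np.fft.fftfreq(rows) * rows
    fx = np.fft.fftfreq(cols) * cols
    radial = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    keep = radial >= highpass_radius
    if keep_dc:
        keep[0, 0] = True
    spectrum = np.fft.fft2(image) * keep
    return np.fft.ifft2(spectrum).real


def granulosity_index(
    image: ImageChannel,
    highpass_radius: float,
    background: float = 0.0,
) -> GranulosityResult:
    """Granulosity index G = sd/mean of the high-pass-filtered image.

    The image (after subtracting a homogeneous ``background``) is Fourier
    high-pass filtered with a circular mask of radius ``highpass_radius``
    (cycles per image dimension); the DC component is retained so the
    filtered mean equals the image mean and G is well defined — a constant
    image then gives exactly G = 0, and G is invariant to rescaling the
    image by any positive factor. The cutoff must be held fixed across any
    series being compared.

    Raises
    ------
    UndefinedIndexError
        If the filtered-image mean is non-positive.
    ParameterError
        If the cutoff wavelength does not fit the image at least twice.
    """
    img = image.intensities - background
    rows, cols = img.shape
    # cutoff wavelength (pixels) = min(shape)/radius must fit at least twice
    # into the image, i.e. radius must exceed 2 cycles per image dimension
    if highpass_radius <= 2:
        raise ParameterError("highpass_radius must exceed 2 cycles per image")
    filtered = highpass_filter(img, highpass_radius, keep_dc=True)
    mean = float(filtered.mean())
    if mean <= 0:
        raise UndefinedIndexError("filtered-image mean is non-positive")
    return GranulosityResult(index=float(filtered.std()) / mean, highpass_radius=highpass_radius)
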