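"""Mask-based fluorescence quantification for microscopy pulse-chase data.

Implements the quantification rules used for epitope tag-switch (RITE) and
drug-treatment timecourses: the DNA stain defines a nuclear mask, all GFP
(or epitope) fluorescence within the mask is integrated per cell, a
background level measured in a cell-free region of the dish is subtracted,
and signals are normalized to a reference condition (the day-0, no-switch
timepoint). A region-ratio helper compares integrated intensity between
two externally supplied masks (e.g. Golgi versus nuclear envelope).

Quantification operates on 2-D frames; z-stacks are reduced with
:func:`max_projection` first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as label_components

from .errors import ConfigurationError, DomainError


@dataclass(frozen=True)
class ImageFrame:
    """Named 2-D intensity channels of equal shape (e.g. ``dna``, ``gfp``)."""

    channels: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.channels:
            raise DomainError("ImageFrame needs at least one channel")
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1 or len(next(iter(shapes))) != 2:
            raise DomainError(
                f"channels must be 2-D arrays of one common shape, got {shapes}"
            )
        for name, chan in self.channels.items():
            arr = np.asarray(chan, dtype=float)
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise DomainError(f"channel {name!r} has negative or non-finite pixels")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise ConfigurationError(
                f"frame has no channel {name!r}; available: {sorted(self.channels)}"
            )
        return np.asarray(self.channels[name], dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class CellQuant:
    """Per-cell intensity quantification.

    ``corrected_intensity`` is the integrated signal minus background-per-
    pixel times mask area, floored at zero; ``intensity_per_area`` is the
    corrected signal per mask pixel.
    """

    cell_id: int
    mask_area: int
    integrated_intensity: float
    background_per_pixel: float
    corrected_intensity: float
    intensity_per_area: float
    normalized_intensity: float | None = None


def max_projection(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a z-stack (z, rows, cols) to 2-D."""
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise DomainError(f"expected a (z, rows, cols) stack, got shape {arr.shape}")
    return arr.max(axis=0)


def dna_mask(
    frame: ImageFrame,
    threshold: float | str = "auto",
    dna_channel: str = "dna",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Threshold the DNA channel into a nuclear mask and label cells.

    ``threshold="auto"`` picks the Otsu threshold (maximizing between-class
    variance of the intensity histogram); pixels strictly above the
    threshold form the mask and its connected components are labeled as
    cells. An empty mask is reported with a warning, not an error.

    Returns (mask, labels, n_cells).
    """
    dna = frame.channel(dna_channel)
    if threshold == "auto":
        if np.ptp(dna) == 0:
            mask = np.zeros_like(dna, dtype=bool)
            warnings.warn("uniform DNA channel: empty mask, 0 cells", stacklevel=2)
            return mask, np.zeros_like(dna, dtype=int), 0
        cut = threshold_otsu(dna)
    else:
        cut = float(threshold)
    mask = dna > cut
    if not mask.any():
        warnings.warn("DNA mask is empty: 0 cells", stacklevel=2)
        return mask, np.zeros_like(dna, dtype=int), 0
    labels = label_components(mask, connectivity=2)
    return mask, labels, int(labels.max())


def _region_slices(region: tuple[int, int, int, int], shape) -> tuple[slice, slice]:
    r0, c0, r1, c1 = region
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ConfigurationError(
            f"background region {region} does not fit image shape {shape}"
        )
    return slice(r0, r1), slice(c0, c1)


def quantify_cells(
    frame: ImageFrame,
    labels: np.ndarray,
    background_region: tuple[int, int, int, int],
    signal_channel: str = "gfp",
) -> list[CellQuant]:
    """Integrate the signal channel per labeled cell with background correction.

    ``background_region`` is a (row0, col0, row1, col1) half-open rectangle
    that must be cell-free (disjoint from all labels); its mean intensity
    defines the background per pixel subtracted from every cell.
    """
    signal = frame.channel(signal_channel)
    labels = np.asarray(labels)
    if labels.shape != signal.shape:
        raise ConfigurationError("labels and image shape differ")
    rows, cols = _region_slices(background_region, signal.shape)
    if np.any(labels[rows, cols] > 0):
        raise ConfigurationError(
            "background region overlaps a cell mask; pick a cell-free rectangle"
        )
    background = float(signal[rows, cols].mean())
    quants = []
    for cell_id in range(1, int(labels.max()) + 1):
        cell_mask = labels == cell_id
        area = int(cell_mask.sum())
        if area == 0:
            continue
        integrated = float(signal[cell_mask].sum())
        corrected = max(0.0, integrated - background * area)
        quants.append(
            CellQuant(
                cell_id=cell_id,
                mask_area=area,
                integrated_intensity=integrated,
                background_per_pixel=background,
                corrected_intensity=corrected,
                intensity_per_area=corrected / area,
            )
        )
    return quants


def normalize_to_reference(
    quants_by_condition: Mapping[str, Sequence[CellQuant]],
    reference_condition: str,
) -> dict[str, list[CellQuant]]:
    """Normalize corrected intensities to the reference condition's mean.

    Every cell's corrected intensity is divided by the mean corrected
    intensity of the reference condition (the no-switch day-0 timepoint in
    a tag-exchange timecourse), so the reference condition averages 1.
    """
    if reference_condition not in quants_by_condition:
        raise ConfigurationError(
            f"reference condition {reference_condition!r} not present; "
            f"have {sorted(quants_by_condition)}"
        )
    reference = quants_by_condition[reference_condition]
    if not reference:
        raise DomainError("reference condition has no cells")
    ref_mean = float(np.mean([q.corrected_intensity for q in reference]))
    if ref_mean <= 0:
        raise DomainError(
            f"reference mean corrected intensity must be positive, got {ref_mean}"
        )
    normalized: dict[str, list[CellQuant]] = {}
    for condition, quants in quants_by_condition.items():
        normalized[condition] = [
            CellQuant(
                cell_id=q.cell_id,
                mask_area=q.mask_area,
                integrated_intensity=q.integrated_intensity,
                background_per_pixel=q.background_per_pixel,
                corrected_intensity=q.corrected_intensity,
                intensity_per_area=q.intensity_per_area,
                normalized_intensity=q.corrected_intensity / ref_mean,
            )
            for q in quants
        ]
    return normalized


def region_ratio(
    frame: ImageFrame,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    background_per_pixel: float = 0.0,
    signal_channel: str = "gfp",
) -> float:
    """Ratio of background-corrected integrated intensity in mask A vs mask B.

    Used e.g. for the Golgi-to-nuclear-envelope abundance ratio of a
    GFP-tagged protein. Masks must be non-empty and disjoint; a
    non-positive denominator is a domain error rather than a silent
    infinity.
    """
    signal = frame.channel(signal_channel)
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != signal.shape or b.shape != signal.shape:
        raise ConfigurationError("masks must match the image shape")
    if not a.any() or not b.any():
        raise DomainError("region_ratio requires two non-empty masks")
    if np.any(a & b):
        raise DomainError("region masks overlap")
    corrected_a = float(signal[a].sum()) - background_per_pixel * int(a.sum())
    corrected_b = float(signal[b].sum()) - background_per_pixel * int(b.sum())
    if corrected_b <= 0:
        raise DomainError(
            f"denominator region has non-positive corrected intensity "
            f"({corrected_b:.3g})"
        )
    return corrected_a / corrected_b


def make_disc_fixture(
    shape: tuple[int, int] = (128, 128),
    discs: Sequence[tuple[int, int, int, float]] = ((32, 32, 10, 50.0), (90, 90, 12, 30.0)),
    background: float = 10.0,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[ImageFrame, dict]:
    """Generate a synthetic two-channel frame with disc-shaped nuclei.

    Each disc is (row, col, radius, gfp_intensity); the DNA channel is 100
    inside discs and 0 outside, the GFP channel is ``background`` plus the
    disc intensity inside each disc, with optional Gaussian noise (clipped
    at 0). Returns the frame and a ground-truth dict with per-disc areas
    and noise-free corrected intensities.
    """
    rng = rng or np.random.default_rng(0)
    dna = np.zeros(shape)
    gfp = np.full(shape, background, dtype=float)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    truth_discs = []
    for row, col, radius, intensity in discs:
        inside = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
        dna[inside] = 100.0
        gfp[inside] += intensity
        area = int(inside.sum())
        truth_discs.append(
            {
                "center": (row, col),
                "area": area,
                "gfp_intensity": intensity,
                "corrected_intensity": intensity * area,
            }
        )
    if noise_sigma > 0:
        gfp = np.clip(gfp + rng.normal(0.0, noise_sigma, size=shape), 0.0, None)
    frame = ImageFrame(channels={"dna": dna, "gfp": gfp})
    truth = {"background": background, "noise_sigma": noise_sigma, "discs": truth_discs}
    return frame, truth
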