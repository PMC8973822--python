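"""Cell segmentation on the tagged-protein channel.

Pipeline: circular median filter (noise reduction) -> Huang fuzzy-entropy
auto-threshold -> 8-connected components -> particle size filter, mirroring
the classic ImageJ particle-analysis workflow. Manual ROI correction is
replaced by a file-based label-mask override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationParams",
    "LabelMask",
    "median_filter",
    "huang_threshold",
    "extract_rois",
    "apply_mask_override",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structure


@dataclass(frozen=True)
class SegmentationParams:
    median_radius: int = 4
    min_area: int = 800
    max_area: Optional[int] = None
    histogram_bins: int = 256
    border_policy: str = "keep"  # or "drop"

    def __post_init__(self) -> None:
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.max_area is not None and self.max_area <= self.min_area:
            raise ValueError("max_area must exceed min_area")
        if self.border_policy not in ("keep", "drop"):
            raise ValueError("border_policy must be 'keep' or 'drop'")


@dataclass
class LabelMask:
    """Per-pixel cell assignment: 0 = background, k > 0 = cell k."""

    labels: np.ndarray
    provenance: str = "auto"  # or "override"
    touches_border: dict[int, bool] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def areas(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts) if v > 0}

    def pixels(self, label: int) -> np.ndarray:
        return self.labels == label


def _disk_offsets(radius: int) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy ** 2 + dx ** 2 <= radius ** 2
    return np.stack([dy[keep], dx[keep]], axis=1)


def median_filter(image: np.ndarray, radius: int) -> np.ndarray:
    """Median over a circular neighborhood of Euclidean radius ``radius``.

    At image edges the neighborhood is truncated to in-image pixels (no
    padding values enter the median).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if radius == 0:
        return image.copy()

    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    footprint = dy ** 2 + dx ** 2 <= radius ** 2
    # interior via the C implementation (any boundary mode agrees there)
    out = ndimage.median_filter(image, footprint=footprint, mode="nearest")

    # recompute the border band with true truncation
    h, w = image.shape
    band = np.zeros(image.shape, dtype=bool)
    band[:r, :] = band[-r:, :] = True
    band[:, :r] = band[:, -r:] = True
    offs = _disk_offsets(radius)
    for y, x in np.argwhere(band):
        yy = y + offs[:, 0]
        xx = x + offs[:, 1]
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        out[y, x] = np.median(image[yy[ok], xx[ok]])
    return out


def _fuzzy_entropy_curve(hist: np.ndarray) -> np.ndarray:
    """Huang–Wang fuzziness S(t) for every candidate threshold t.

    For threshold t, pixels with gray level g <= t belong to the background
    with membership 1/(1+|g-mu0(t)|/C), pixels above to the foreground with
    membership 1/(1+|g-mu1(t)|/C); C is the full gray range.  S(t) is the
    histogram-weighted Shannon entropy of those memberships.
    """
    n_bins = hist.size
    g = np.arange(n_bins, dtype=float)
    C = float(n_bins - 1)

    w = hist.astype(float)
    cw = np.cumsum(w)                # pixels with level <= t
    cwg = np.cumsum(w * g)
    total_w, total_wg = cw[-1], cwg[-1]

    S = np.full(n_bins, np.inf)
    for t in range(n_bins - 1):
        w0, w1 = cw[t], total_w - cw[t]
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cwg[t] / w0
        mu1 = (total_wg - cwg[t]) / w1
        mu = np.empty(n_bins)
        mu[: t + 1] = 1.0 / (1.0 + np.abs(g[: t + 1] - mu0) / C)
        mu[t + 1:] = 1.0 / (1.0 + np.abs(g[t + 1:] - mu1) / C)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -mu * np.log(mu) - (1.0 - mu) * np.log(1.0 - mu)
        ent[~np.isfinite(ent)] = 0.0  # mu in {0,1} contributes nothing
        S[t] = float(np.dot(w, ent))
    return S


def huang_threshold_bin(hist: np.ndarray) -> int:
    """Huang threshold as a bin index: argmin of fuzziness, ties to lowest t."""
    hist = np.asarray(hist)
    if (hist > 0).sum() < 2:
        raise ValueError("histogram needs >= 2 occupied bins")
    S = _fuzzy_entropy_curve(hist)
    return int(np.argmin(S))  # argmin returns the first (lowest) minimizer


def huang_threshold(image: np.ndarray, bins: int = 256) -> float:
    """Huang fuzzy-entropy threshold in original intensity units.

    The image is min–max scaled onto ``bins`` histogram bins; the returned
    threshold is the lower edge of the first above-threshold bin, so the
    foreground is ``image >= threshold``.
    """
    image = np.asarray(image, dtype=float)
    gmin, gmax = float(image.min()), float(image.max())
    if gmin == gmax:
        raise ValueError("constant image: no threshold exists")
    hist, edges = np.histogram(image, bins=bins, range=(gmin, gmax))
    t = huang_threshold_bin(hist)
    return float(edges[t + 1])


def _relabel_raster(labels: np.ndarray) -> np.ndarray:
    """Relabel components 1..n in raster order of their top-left pixel."""
    out = np.zeros_like(labels)
    ids = [int(v) for v in np.unique(labels) if v > 0]
    firsts = []
    flat = labels.ravel()
    for v in ids:
        first = int(np.argmax(flat == v))  # first pixel in raster order
        firsts.append((first, v))
    for new, (_, v) in enumerate(sorted(firsts), start=1):
        out[labels == v] = new
    return out


def extract_rois(image: np.ndarray, params: SegmentationParams) -> LabelMask:
    """Segment cells: median filter, Huang threshold, components, size filter."""
    filtered = median_filter(image, params.median_radius)
    t = huang_threshold(filtered, params.histogram_bins)
    binary = filtered >= t
    labels, _ = ndimage.label(binary, structure=_EIGHT)
    labels = _filter_components(labels, params)
    labels = _relabel_raster(labels)
    mask = LabelMask(labels=labels, provenance="auto")
    mask.touches_border = _border_flags(labels)
    return mask


def _border_flags(labels: np.ndarray) -> dict[int, bool]:
    border_vals = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :])) \
        | set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
    return {int(v): (int(v) in border_vals)
            for v in np.unique(labels) if v > 0}


def _filter_components(labels: np.ndarray, params: SegmentationParams) -> np.ndarray:
    labels = labels.copy()
    vals, counts = np.unique(labels, return_counts=True)
    for v, c in zip(vals, counts):
        if v == 0:
            continue
        too_small = c < params.min_area
        too_big = params.max_area is not None and c > params.max_area
        if too_small or too_big:
            labels[labels == v] = 0
    if params.border_policy == "drop":
        for v, touches in _border_flags(labels).items():
            if touches:
                labels[labels == v] = 0
    return labels


def apply_mask_override(auto: LabelMask, override: LabelMask,
                        params: SegmentationParams) -> LabelMask:
    """Replace an automatic mask wholesale with a curated one.

    Size and border filters are re-applied to the override so the LabelMask
    invariants hold regardless of the source; provenance is recorded.
    """
    if auto.labels.shape != override.labels.shape:
        raise ValueError(
            f"mask shape mismatch: {auto.labels.shape} vs {override.labels.shape}")
    labels = _filter_components(override.labels, params)
    labels = _relabel_raster(labels)
    mask = LabelMask(labels=labels, provenance="override")
    mask.touches_border = _border_flags(labels)
    return mask
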