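"""Focus counting, projected-area measurement, and pan-nuclear exclusion.

Works on maximal projections.  Within each nucleus region the focal channel
is binarized at a threshold defined on the in-nucleus dynamic range
(``threshold × (max − background) + background`` with the in-nucleus minimum
as background), 8-connected components become candidate foci, and components
smaller than 3 px are discarded as noise — at the 0.285 µm projection pixel
this floor corresponds to 0.24 µm², one pixel to 0.081 µm².  An absolute
threshold mode reproduces the fixed-threshold usage of interactive image
software.  Because the threshold is relative, focus counts are invariant
under multiplying the image by a positive gain.

Nuclei with homogeneous dense staining (apoptotic-type, "pan-nuclear") are
flagged and excluded from counting: a nucleus is flagged when the fraction
of its area above a threshold pooled over all nuclei exceeds a coverage
cutoff.  The pooled (rather than per-nucleus) dynamic range is essential
here — a uniformly stained nucleus has no internal contrast, so only a
scene-wide reference exposes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segmentation import NucleusMask

__all__ = [
    "FocusRecord",
    "NucleusFocusSummary",
    "PafHistogram",
    "FocusCountStats",
    "detect_foci",
    "flag_pan_nuclear",
    "paf_histogram",
    "mean_foci_per_nucleus",
]

MIN_FOCUS_AREA_PX = 3
_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class FocusRecord:
    """One segmented focus (records below the 3-px noise floor are dropped)."""

    nucleus_label: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]   # (row, col)
    mean_intensity: float


@dataclass
class NucleusFocusSummary:
    """Per-nucleus focus count and exclusion status."""

    nucleus_label: int
    focus_count: int
    focus_areas_um2: list[float]
    pan_nuclear: bool
    excluded: bool


def flag_pan_nuclear(
    channel: np.ndarray,
    mask: NucleusMask,
    coverage_cutoff: float = 0.5,
    threshold: float = 0.5,
) -> dict[int, bool]:
    """Flag homogeneously (densely) stained nuclei.

    The binarization threshold is placed at ``threshold`` of the dynamic
    range pooled over all in-mask pixels; a nucleus is flagged when more
    than ``coverage_cutoff`` of its area is suprathreshold.
    """
    if not 0.0 < coverage_cutoff < 1.0:
        raise ValueError("coverage_cutoff must lie in (0, 1)")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    img = np.asarray(channel, dtype=np.float64)
    if img.shape != mask.labels.shape:
        raise ValueError("channel and mask shapes differ")
    flags: dict[int, bool] = {}
    fg = mask.foreground
    if not fg.any():
        return flags
    vals = img[fg]
    background = vals.min()
    cut = background + threshold * (vals.max() - background)
    above = img > cut
    for lab, sl in mask.bounding_slices().items():
        region = mask.labels[sl] == lab
        coverage = above[sl][region].mean()
        flags[lab] = bool(coverage > coverage_cutoff)
    return flags


def detect_foci(
    channel: np.ndarray,
    mask: NucleusMask,
    pixel_size: float,
    threshold: float = 0.5,
    min_area_px: int = MIN_FOCUS_AREA_PX,
    absolute_threshold: float | None = None,
    pan_coverage_cutoff: float = 0.5,
    flag_pan: bool = True,
) -> tuple[list[FocusRecord], list[NucleusFocusSummary]]:
    """Detect foci per nucleus on a maximal projection.

    Per nucleus, pixels above ``background + threshold × (max − background)``
    (or above ``absolute_threshold`` when given, applied identically to every
    nucleus) are grouped into 8-connected components; components of at least
    ``min_area_px`` pixels become :class:`FocusRecord` entries with areas in
    px and µm² (``area_um2 = area_px × pixel_size²``).  Pan-nuclear nuclei
    are flagged and excluded: they receive a summary with ``excluded=True``
    and contribute no focus records.
    """
    img = np.asarray(channel, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("channel must be a 2-D maximal projection")
    if img.shape != mask.labels.shape:
        raise ValueError("channel and mask shapes differ")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    if absolute_threshold is None and not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    px_area = float(pixel_size) ** 2

    pan_flags = (flag_pan_nuclear(img, mask, pan_coverage_cutoff, threshold)
                 if flag_pan else {lab: False for lab in mask.present_labels})

    records: list[FocusRecord] = []
    summaries: list[NucleusFocusSummary] = []
    boxes = mask.bounding_slices()
    for lab in mask.present_labels:
        if pan_flags.get(lab, False):
            summaries.append(NucleusFocusSummary(lab, 0, [], True, True))
            continue
        sl = boxes[lab]
        region = mask.labels[sl] == lab
        sub = img[sl]
        vals = sub[region]
        if absolute_threshold is not None:
            cut = float(absolute_threshold)
        else:
            background = vals.min()
            cut = background + threshold * (vals.max() - background)
        binary = (sub > cut) & region
        labeled, n = ndi.label(binary, structure=_EIGHT_CONNECTED)
        areas_um2: list[float] = []
        if n > 0:
            comp_areas = np.bincount(labeled.ravel())
            centroids = ndi.center_of_mass(binary, labeled, range(1, n + 1))
            means = ndi.mean(sub, labeled, range(1, n + 1))
            r_off, c_off = sl[0].start, sl[1].start
            for comp in range(1, n + 1):
                area_px = int(comp_areas[comp])
                if area_px < min_area_px:
                    continue   # below the noise floor
                area_um2 = area_px * px_area
                areas_um2.append(area_um2)
                cr, cc = centroids[comp - 1]
                records.append(FocusRecord(
                    nucleus_label=lab,
                    area_px=area_px,
                    area_um2=area_um2,
                    centroid=(cr + r_off, cc + c_off),
                    mean_intensity=float(means[comp - 1]),
                ))
        summaries.append(NucleusFocusSummary(
            lab, len(areas_um2), areas_um2, False, False))
    return records, summaries


@dataclass
class PafHistogram:
    """Histogram of projected focus areas (PAF), µm².

    Half-open bins of ``bin_width`` starting at ``origin`` (0.2 µm² by
    default, so the 0.24 µm² minimum falls in the first bin), a final open
    bin collecting areas >= ``overflow_at``, and — only when records below
    the origin exist — a leading underflow bin.  ``peak_bin`` is the most
    occupied bin (lowest on ties); ``mean_um2`` is NaN for empty input.
    """

    bin_edges: np.ndarray          # finite lower edges + [overflow_at, inf]
    counts: np.ndarray
    fractions: np.ndarray
    peak_bin: tuple[float, float] | None
    mean_um2: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1],
            "bin_high": self.bin_edges[1:],
            "count": self.counts,
            "fraction": self.fractions,
        })


def paf_histogram(
    records,
    bin_width: float = 0.1,
    overflow_at: float = 5.0,
    origin: float = 0.2,
) -> PafHistogram:
    """Bin projected focus areas; accepts FocusRecords or raw areas in µm²."""
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    if not overflow_at > origin:
        raise ValueError("overflow_at must exceed the histogram origin")
    areas = np.asarray(
        [r.area_um2 if isinstance(r, FocusRecord) else float(r) for r in records],
        dtype=np.float64,
    )
    n_regular = int(np.ceil((overflow_at - origin) / bin_width - 1e-9))
    edges = origin + bin_width * np.arange(n_regular + 1)
    edges[-1] = overflow_at
    if areas.size and areas.min() < origin:
        edges = np.concatenate(([0.0], edges))
    full_edges = np.concatenate((edges, [np.inf]))
    counts, _ = np.histogram(areas, bins=full_edges)
    n = int(areas.size)
    fractions = counts / n if n > 0 else np.zeros_like(counts, dtype=float)
    if n > 0:
        peak_idx = int(np.argmax(counts))
        peak_bin = (float(full_edges[peak_idx]), float(full_edges[peak_idx + 1]))
        mean = float(areas.mean())
    else:
        peak_bin = None
        mean = float("nan")
    return PafHistogram(full_edges, counts, fractions, peak_bin, mean, n)


@dataclass(frozen=True)
class FocusCountStats:
    """Mean foci per nucleus with SE (and 3·SE, the plotting convention)."""

    mean: float
    se: float
    three_se: float
    n: int


def mean_foci_per_nucleus(
    summaries,
    exclude_flagged: bool = True,
) -> FocusCountStats:
    """Mean ± SE of focus counts over (non-excluded) nuclei.

    SE = sample SD / sqrt(n); NaN when fewer than 2 nuclei are included.
    """
    counts = np.asarray(
        [s.focus_count for s in summaries
         if not (exclude_flagged and s.excluded)],
        dtype=np.float64,
    )
    n = counts.size
    if n == 0:
        return FocusCountStats(float("nan"), float("nan"), float("nan"), 0)
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return FocusCountStats(mean, se, 3.0 * se, int(n))
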