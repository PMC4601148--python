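"""Per-nucleus Pearson and Manders colocalization coefficients.

Coefficients are computed over the pixel set of one nucleus, on the
DoG-enhanced (clipped, normalized) channel images — the same order of
operations as the imaging pipeline the package reproduces: enhance both
channels, zero everything outside the DAPI-derived nucleus mask, then
correlate.  A raw-intensity mode is available for comparison.

Definitions over in-mask pixels a_i, b_i:

* Pearson ``Rr = Σ(a−ā)(b−b̄) / sqrt(Σ(a−ā)² Σ(b−b̄)²)``, range [−1, 1];
  undefined when either channel is constant inside the mask.
* Manders overlap ``R = Σ a b / sqrt(Σa² Σb²)``, range [0, 1]; undefined
  when either channel has zero energy inside the mask.
* Manders split ``M1 = Σ_{b>0} a / Σ a`` and ``M2 = Σ_{a>0} b / Σ b``
  (zero intensity thresholds).

Undefined coefficients are reported as NaN with ``valid=False`` — never as
silent zeros — and are excluded from group summaries.  One coefficient per
cell is the unit of analysis; group statistics are means ± SE over nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import DoGParams, NucleusMask, dog_segment
from .stackio import ImageStack

__all__ = [
    "ColocResult",
    "pearson_rr",
    "manders_overlap",
    "manders_split",
    "coloc_per_nucleus",
    "results_to_frame",
    "summarize_coloc",
]


@dataclass(frozen=True)
class ColocResult:
    """Colocalization coefficients for one nucleus and one channel pair."""

    nucleus_label: int
    Rr: float
    R: float
    M1: float
    M2: float
    n_pixels: int
    valid: bool


def _masked(a, b, mask):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channels must have equal shapes")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape does not match channel shape")
        return a[mask], b[mask]
    return a.ravel(), b.ravel()


def pearson_rr(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of pixel intensities inside the mask.

    Returns NaN when fewer than 2 pixels are in the mask or either channel
    is constant there (zero variance).
    """
    av, bv = _masked(a, b, mask)
    if av.size < 2:
        return float("nan")
    da = av - av.mean()
    db = bv - bv.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0.0:
        return float("nan")
    return float((da * db).sum() / denom)


def manders_overlap(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Manders overlap coefficient R = Σab / sqrt(Σa² Σb²) inside the mask.

    Returns NaN when the mask is empty or either channel has zero energy.
    """
    av, bv = _masked(a, b, mask)
    if av.size < 1:
        return float("nan")
    denom = np.sqrt((av * av).sum() * (bv * bv).sum())
    if denom == 0.0:
        return float("nan")
    return float((av * bv).sum() / denom)


def manders_split(
    a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Manders split coefficients (M1, M2) with zero intensity thresholds."""
    av, bv = _masked(a, b, mask)
    sa = av.sum()
    sb = bv.sum()
    m1 = float(av[bv > 0].sum() / sa) if sa > 0 else float("nan")
    m2 = float(bv[av > 0].sum() / sb) if sb > 0 else float("nan")
    return m1, m2


def coloc_per_nucleus(
    stack: ImageStack,
    mask: NucleusMask,
    channels: tuple[str, str] = ("A", "B"),
    dog: DoGParams = DoGParams(),
    raw: bool = False,
) -> list[ColocResult]:
    """Compute one ColocResult per nucleus for a channel pair.

    Each channel is DoG-enhanced over the full mask (set ``raw=True`` to
    correlate raw intensities instead), then coefficients are computed over
    each nucleus region.  Nuclei with undefined coefficients are flagged
    ``valid=False``.
    """
    if stack.has_z:
        raise ValueError("coloc_per_nucleus expects a 2-D (projected) stack")
    ch_a = np.asarray(stack.channel(channels[0]), dtype=np.float64)
    ch_b = np.asarray(stack.channel(channels[1]), dtype=np.float64)
    if ch_a.shape != mask.labels.shape:
        raise ValueError("mask shape does not match image shape")
    if raw:
        ega, egb = ch_a, ch_b
    else:
        ega = dog_segment(ch_a, dog, mask)
        egb = dog_segment(ch_b, dog, mask)

    results: list[ColocResult] = []
    boxes = mask.bounding_slices()
    for lab in mask.present_labels:
        sl = boxes[lab]
        region = mask.labels[sl] == lab
        a = ega[sl]
        b = egb[sl]
        rr = pearson_rr(a, b, region)
        r = manders_overlap(a, b, region)
        m1, m2 = manders_split(a, b, region)
        valid = bool(np.isfinite(rr) and np.isfinite(r))
        results.append(ColocResult(lab, rr, r, m1, m2, int(region.sum()), valid))
    return results


def results_to_frame(results: Sequence[ColocResult], **labels) -> pd.DataFrame:
    """Flatten ColocResults to a table; extra keyword labels become columns."""
    df = pd.DataFrame([vars(r) if not hasattr(r, "__dataclass_fields__")
                       else {f: getattr(r, f) for f in r.__dataclass_fields__}
                       for r in results])
    for key, value in labels.items():
        df[key] = value
    return df


def summarize_coloc(
    df: pd.DataFrame,
    group_cols: Sequence[str] = ("group",),
    coefficients: Sequence[str] = ("Rr", "R"),
) -> pd.DataFrame:
    """Per-group mean ± SE of coefficients over valid nuclei.

    Input is a long table as produced by :func:`results_to_frame` with one
    row per nucleus.  Invalid rows (``valid == False``) are excluded from
    means and counted in the ``n_invalid`` QC column.  SE uses the sample
    standard deviation (ddof=1) and is NaN for groups of fewer than 2
    valid nuclei.
    """
    group_cols = list(group_cols)
    if "valid" in df.columns:
        valid_df = df[df["valid"].astype(bool)]
    else:
        valid_df = df
    rows = []
    for key, sub in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vsub = valid_df.loc[valid_df.index.intersection(sub.index)]
        n = len(vsub)
        row = dict(zip(group_cols, key))
        row["n"] = n
        row["n_invalid"] = len(sub) - n
        for coef in coefficients:
            vals = vsub[coef].to_numpy(dtype=float)
            row[f"{coef}_mean"] = vals.mean() if n > 0 else float("nan")
            row[f"{coef}_se"] = (
                vals.std(ddof=1) / np.sqrt(n) if n >= 2 else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
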