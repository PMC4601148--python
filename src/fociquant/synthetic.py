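"""Synthetic fluorescence-microscopy scenes with planted nuclei and foci.

Generates three-channel 2-D scenes — a DNA counterstain channel plus two
immunofluorescence channels ``A`` and ``B`` — together with the full ground
truth (nucleus geometry, focus positions, colocalized pairs, pan-nuclear
labels).  The scenes emulate confocal maximal projections of immunostained
fibroblast nuclei: bright convex (elliptical) nuclei on a dark background,
discrete isotropic 2-D Gaussian foci, a controllable fraction of channel-A
foci duplicated at identical positions in channel B, occasional pan-nuclear
("homogeneously stained", apoptotic-type) nuclei, additive Gaussian read
noise and optional Poisson shot noise.

Two factory functions encode the standard simulated acquisition geometries:

* :func:`default_counting_spec` — the focus-counting scale (0.285 µm
  projection pixels, nuclei 7–10 µm in radius), used for focus counts,
  projected-area histograms and repair kinetics.
* :func:`default_coloc_spec` — the colocalization scale (30 nm pixels,
  focal signals up to ~25–30 px across), used for the DoG + Pearson/Manders
  pipeline.

All randomness flows through one ``numpy.random.Generator`` seeded from the
spec (or an explicit seed), so identical spec + seed gives bit-identical
images and ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stackio import ImageStack

__all__ = [
    "SceneSpec",
    "Nucleus",
    "PlantedFocus",
    "GroundTruth",
    "SceneSpecError",
    "PlacementError",
    "generate_scene",
    "generate_timecourse",
    "default_counting_spec",
    "default_coloc_spec",
]


class SceneSpecError(ValueError):
    """A SceneSpec field is invalid; the message names the field."""


class PlacementError(RuntimeError):
    """Nuclei or foci could not be placed within the bounded attempt budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``foci_per_nucleus`` is either a fixed nonnegative int or a tuple
    ``("poisson", mean)`` for Poisson-distributed counts.  ``coloc_fraction``
    is the fraction of channel-A foci duplicated at identical positions in
    channel B (optionally jittered by ``coloc_jitter_px``);
    ``independent_foci_b`` additionally places that many unrelated foci per
    nucleus in channel B.  ``pan_nuclear_fraction`` of nuclei are rendered
    with uniform dense staining (1.5 × focus amplitude) across the whole
    nucleus in channel A instead of discrete foci.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.285            # µm per pixel, square pixels
    n_nuclei: int = 5
    nucleus_radius_range: tuple[float, float] = (25.0, 35.0)   # px semi-axes
    foci_per_nucleus: int | tuple = 10
    focus_sigma_range: tuple[float, float] = (1.2, 2.2)        # px
    focus_amplitude: float = 3000.0
    coloc_fraction: float = 0.0
    independent_foci_b: int = 0
    background_level: float = 500.0
    dna_level: float = 2500.0            # DNA-channel intensity above background
    noise_sigma: float = 0.0             # Gaussian read noise, intensity units
    shot_noise: bool = False             # Poisson resampling of the signal
    pan_nuclear_fraction: float = 0.0
    coloc_jitter_px: float = 0.0
    min_focus_separation_px: float = 0.0
    seed: int = 0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        r, c = self.image_shape
        if r < 8 or c < 8:
            raise SceneSpecError("image_shape: must be at least 8x8 pixels")
        if not self.pixel_size > 0:
            raise SceneSpecError("pixel_size: must be > 0")
        if self.n_nuclei < 0:
            raise SceneSpecError("n_nuclei: must be >= 0")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise SceneSpecError("nucleus_radius_range: need 0 < min <= max")
        if isinstance(self.foci_per_nucleus, tuple):
            kind = self.foci_per_nucleus[0]
            if kind != "poisson" or len(self.foci_per_nucleus) != 2:
                raise SceneSpecError(
                    "foci_per_nucleus: tuple form must be ('poisson', mean)")
            if not self.foci_per_nucleus[1] >= 0:
                raise SceneSpecError("foci_per_nucleus: Poisson mean must be >= 0")
        elif int(self.foci_per_nucleus) < 0:
            raise SceneSpecError("foci_per_nucleus: must be >= 0")
        slo, shi = self.focus_sigma_range
        if not (0 < slo <= shi):
            raise SceneSpecError("focus_sigma_range: need 0 < min <= max")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise SceneSpecError("coloc_fraction: must lie in [0, 1]")
        if self.independent_foci_b < 0:
            raise SceneSpecError("independent_foci_b: must be >= 0")
        if self.background_level < 0:
            raise SceneSpecError("background_level: must be >= 0")
        if self.noise_sigma < 0:
            raise SceneSpecError("noise_sigma: must be >= 0")
        if not 0.0 <= self.pan_nuclear_fraction <= 1.0:
            raise SceneSpecError("pan_nuclear_fraction: must lie in [0, 1]")
        if self.coloc_jitter_px < 0:
            raise SceneSpecError("coloc_jitter_px: must be >= 0")
        if self.min_focus_separation_px < 0:
            raise SceneSpecError("min_focus_separation_px: must be >= 0")
        if self.bit_depth not in (8, 16):
            raise SceneSpecError("bit_depth: must be 8 or 16")


@dataclass(frozen=True)
class Nucleus:
    """One elliptical nucleus: label, center (row, col), semi-axes, rotation."""

    label: int
    center: tuple[float, float]
    axes: tuple[float, float]      # semi-axes in px
    angle: float                   # rotation, radians

    def contains(self, row: float, col: float, scale: float = 1.0) -> bool:
        dr = row - self.center[0]
        dc = col - self.center[1]
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        u = dr * ca + dc * sa
        v = -dr * sa + dc * ca
        a, b = self.axes
        return (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 <= 1.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        u = dr * ca + dc * sa
        v = -dr * sa + dc * ca
        a, b = self.axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class PlantedFocus:
    """One planted Gaussian focus (center in px, isotropic sigma in px)."""

    nucleus_label: int
    row: float
    col: float
    sigma: float
    amplitude: float


@dataclass
class GroundTruth:
    """Complete ground truth for one scene."""

    nuclei: list[Nucleus]
    foci_a: list[PlantedFocus]
    foci_b: list[PlantedFocus]
    colocalized_pairs: list[tuple[int, int]]   # (index into foci_a, index into foci_b)
    pan_nuclear_labels: list[int]

    def foci_per_nucleus(self, channel: str = "A") -> dict[int, int]:
        foci = self.foci_a if channel.upper() == "A" else self.foci_b
        counts = {n.label: 0 for n in self.nuclei}
        for f in foci:
            counts[f.nucleus_label] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Sidecar table: one row per planted focus."""
        paired_a = {ia for ia, _ in self.colocalized_pairs}
        paired_b = {ib for _, ib in self.colocalized_pairs}
        rows = []
        for i, f in enumerate(self.foci_a):
            rows.append(("A", i, f.nucleus_label, f.row, f.col, f.sigma,
                         f.amplitude, i in paired_a))
        for i, f in enumerate(self.foci_b):
            rows.append(("B", i, f.nucleus_label, f.row, f.col, f.sigma,
                         f.amplitude, i in paired_b))
        return pd.DataFrame(
            rows,
            columns=["channel", "focus_id", "nucleus_label", "row", "col",
                     "sigma_px", "amplitude", "colocalized"],
        )


# ---------------------------------------------------------------------------
# sampling

_MAX_ATTEMPTS = 500


def _sample_nuclei(spec: SceneSpec, rng: np.random.Generator) -> list[Nucleus]:
    h, w = spec.image_shape
    lo, hi = spec.nucleus_radius_range
    placed: list[Nucleus] = []
    for label in range(1, spec.n_nuclei + 1):
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        angle = rng.uniform(0, math.pi)
        rmax = max(a, b)
        if 2 * (rmax + 2) >= min(h, w):
            raise PlacementError(
                f"nucleus radius {rmax:.1f} px does not fit image {spec.image_shape}")
        for _ in range(_MAX_ATTEMPTS):
            cr = rng.uniform(rmax + 2, h - rmax - 2)
            cc = rng.uniform(rmax + 2, w - rmax - 2)
            ok = all(
                math.hypot(cr - n.center[0], cc - n.center[1])
                > rmax + max(n.axes) + 4.0
                for n in placed
            )
            if ok:
                placed.append(Nucleus(label, (cr, cc), (a, b), angle))
                break
        else:
            raise PlacementError(
                f"could not place nucleus {label} without overlap "
                f"after {_MAX_ATTEMPTS} attempts")
    return placed


def _sample_point_in_nucleus(
    nucleus: Nucleus,
    margin: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    a = nucleus.axes[0] - margin
    b = nucleus.axes[1] - margin
    if a <= 1.0 or b <= 1.0:
        raise PlacementError(
            f"nucleus {nucleus.label}: focus margin {margin:.1f} px leaves no room "
            f"inside semi-axes {nucleus.axes}")
    r = math.sqrt(rng.uniform())
    theta = rng.uniform(0, 2 * math.pi)
    u = r * math.cos(theta) * a
    v = r * math.sin(theta) * b
    ca, sa = math.cos(nucleus.angle), math.sin(nucleus.angle)
    dr = u * ca - v * sa
    dc = u * sa + v * ca
    return nucleus.center[0] + dr, nucleus.center[1] + dc


def _sample_foci_for_nucleus(
    nucleus: Nucleus,
    n_foci: int,
    spec: SceneSpec,
    rng: np.random.Generator,
) -> list[PlantedFocus]:
    out: list[PlantedFocus] = []
    positions: list[tuple[float, float]] = []
    for _ in range(n_foci):
        sigma = rng.uniform(*spec.focus_sigma_range)
        margin = 2.0 * sigma + 1.0
        for _ in range(_MAX_ATTEMPTS):
            row, col = _sample_point_in_nucleus(nucleus, margin, rng)
            if all(
                math.hypot(row - r0, col - c0) >= spec.min_focus_separation_px
                for r0, c0 in positions
            ):
                break
        else:
            raise PlacementError(
                f"nucleus {nucleus.label}: could not place focus with separation "
                f">= {spec.min_focus_separation_px} px after {_MAX_ATTEMPTS} attempts")
        positions.append((row, col))
        out.append(PlantedFocus(nucleus.label, row, col, sigma, spec.focus_amplitude))
    return out


def _draw_focus_count(spec: SceneSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.foci_per_nucleus, tuple):
        return int(rng.poisson(spec.foci_per_nucleus[1]))
    return int(spec.foci_per_nucleus)


def _sample_truth(spec: SceneSpec, rng: np.random.Generator) -> GroundTruth:
    nuclei = _sample_nuclei(spec, rng)
    n_pan = int(round(spec.pan_nuclear_fraction * spec.n_nuclei))
    pan_labels: list[int] = []
    if n_pan > 0:
        pan_labels = sorted(
            int(x) for x in
            rng.choice([n.label for n in nuclei], size=n_pan, replace=False)
        )
    pan_set = set(pan_labels)

    foci_a: list[PlantedFocus] = []
    for nucleus in nuclei:
        if nucleus.label in pan_set:
            continue   # pan-nuclear nuclei carry dense staining, not discrete foci
        n_foci = _draw_focus_count(spec, rng)
        foci_a.extend(_sample_foci_for_nucleus(nucleus, n_foci, spec, rng))

    # colocalized pairs are sampled globally so that
    # |pairs| == round(coloc_fraction * |foci_a|) holds exactly
    n_pairs = int(round(spec.coloc_fraction * len(foci_a)))
    pair_idx = sorted(
        int(x) for x in rng.choice(len(foci_a), size=n_pairs, replace=False)
    ) if n_pairs > 0 else []

    foci_b: list[PlantedFocus] = []
    pairs: list[tuple[int, int]] = []
    for ia in pair_idx:
        f = foci_a[ia]
        row, col = f.row, f.col
        if spec.coloc_jitter_px > 0:
            row += rng.normal(0, spec.coloc_jitter_px)
            col += rng.normal(0, spec.coloc_jitter_px)
        foci_b.append(PlantedFocus(f.nucleus_label, row, col, f.sigma, f.amplitude))
        pairs.append((ia, len(foci_b) - 1))
    for nucleus in nuclei:
        if spec.independent_foci_b > 0:
            foci_b.extend(
                _sample_foci_for_nucleus(nucleus, spec.independent_foci_b, spec, rng))

    return GroundTruth(nuclei, foci_a, foci_b, pairs, pan_labels)


# ---------------------------------------------------------------------------
# rendering

def _add_gaussian(img: np.ndarray, focus: PlantedFocus) -> None:
    h, w = img.shape
    rad = int(math.ceil(4.0 * focus.sigma))
    r0 = max(0, int(math.floor(focus.row)) - rad)
    r1 = min(h, int(math.ceil(focus.row)) + rad + 1)
    c0 = max(0, int(math.floor(focus.col)) - rad)
    c1 = min(w, int(math.ceil(focus.col)) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - focus.row
    cc = np.arange(c0, c1)[None, :] - focus.col
    img[r0:r1, c0:c1] += focus.amplitude * np.exp(
        -(rr**2 + cc**2) / (2.0 * focus.sigma**2))


def _render(
    spec: SceneSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> ImageStack:
    shape = spec.image_shape
    masks = {n.label: n.mask(shape) for n in truth.nuclei}
    union = np.zeros(shape, dtype=bool)
    for m in masks.values():
        union |= m

    dna = np.zeros(shape, dtype=np.float64)
    dna[union] = spec.dna_level

    sig_a = np.zeros(shape, dtype=np.float64)
    for f in truth.foci_a:
        _add_gaussian(sig_a, f)
    sig_a[~union] = 0.0                       # foci clipped at nucleus borders
    for label in truth.pan_nuclear_labels:
        sig_a[masks[label]] = 1.5 * spec.focus_amplitude

    sig_b = np.zeros(shape, dtype=np.float64)
    for f in truth.foci_b:
        _add_gaussian(sig_b, f)
    sig_b[~union] = 0.0

    limit = float(2**spec.bit_depth - 1)
    channels = []
    for sig in (dna, sig_a, sig_b):
        img = spec.background_level + sig
        if spec.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
        channels.append(np.clip(np.rint(img), 0.0, limit))
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    data = np.stack(channels).astype(dtype)
    return ImageStack(
        data=data,
        channel_names=["dna", "A", "B"],
        pixel_size=spec.pixel_size,
        bit_depth=spec.bit_depth,
    )


def generate_scene(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one scene plus its ground truth from a validated spec.

    Deterministic: identical spec (including its seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _sample_truth(spec, rng)
    stack = _render(spec, truth, rng)
    return stack, truth


# ---------------------------------------------------------------------------
# timecourses

def _surviving_truth(
    truth: GroundTruth,
    retention: float,
    rng: np.random.Generator,
) -> GroundTruth:
    keep_a = rng.random(len(truth.foci_a)) < retention
    new_a: list[PlantedFocus] = []
    map_a: dict[int, int] = {}
    for i, f in enumerate(truth.foci_a):
        if keep_a[i]:
            map_a[i] = len(new_a)
            new_a.append(f)

    paired_b = {ib: ia for ia, ib in truth.colocalized_pairs}
    new_b: list[PlantedFocus] = []
    new_pairs: list[tuple[int, int]] = []
    indep_b = [i for i in range(len(truth.foci_b)) if i not in paired_b]
    keep_indep = rng.random(len(indep_b)) < retention
    keep_indep_map = dict(zip(indep_b, keep_indep))
    for ib, f in enumerate(truth.foci_b):
        if ib in paired_b:
            ia = paired_b[ib]
            if keep_a[ia]:                    # paired focus follows its partner
                new_pairs.append((map_a[ia], len(new_b)))
                new_b.append(f)
        elif keep_indep_map[ib]:
            new_b.append(f)
    return GroundTruth(truth.nuclei, new_a, new_b, new_pairs,
                       list(truth.pan_nuclear_labels))


def generate_timecourse(
    base_spec: SceneSpec,
    timepoints: Sequence[float],
    retention: Mapping[float, float],
    seed: int | None = None,
) -> list[tuple[float, ImageStack, GroundTruth]]:
    """Render a repair timecourse by binomial thinning of planted foci.

    The scene geometry (nuclei and the initial focus set) is sampled once;
    at each timepoint ``t`` every planted focus is kept independently with
    probability ``retention[t]`` and the surviving set is re-rendered with
    fresh noise.  Colocalized channel-B partners follow the survival of
    their channel-A focus; independent channel-B foci are thinned with the
    same probability.  Retention at the first timepoint must be 1 (the
    maximum-induction reference).
    """
    if not timepoints:
        raise SceneSpecError("timepoints: must be nonempty")
    for t in timepoints:
        if t not in retention:
            raise SceneSpecError(f"retention: no value for timepoint {t}")
        if not 0.0 <= retention[t] <= 1.0:
            raise SceneSpecError(f"retention: value at t={t} must lie in [0, 1]")
    if retention[timepoints[0]] != 1.0:
        raise SceneSpecError("retention: must equal 1.0 at the first timepoint")

    rng = np.random.default_rng(base_spec.seed if seed is None else seed)
    truth0 = _sample_truth(base_spec, rng)
    out: list[tuple[float, ImageStack, GroundTruth]] = []
    for i, t in enumerate(timepoints):
        if i == 0:
            truth_t = truth0
        else:
            truth_t = _surviving_truth(truth0, retention[t], rng)
        out.append((float(t), _render(base_spec, truth_t, rng), truth_t))
    return out


# ---------------------------------------------------------------------------
# standard acquisition geometries

def default_counting_spec(
    n_nuclei: int = 25,
    foci_per_nucleus: int | tuple = 10,
    seed: int = 0,
    noise_sigma: float = 0.0,
    pan_nuclear_fraction: float = 0.0,
    coloc_fraction: float = 0.0,
    independent_foci_b: int = 0,
    **overrides,
) -> SceneSpec:
    """Focus-counting geometry: 0.285 µm projection pixels, 7–10 µm nuclei.

    Focus widths (sigma 1.2–2.2 px) give half-maximum footprints of roughly
    0.4–2 µm², matching the observed projected-area range; the minimum
    inter-focus separation of 9 px keeps planted foci resolvable so the
    detector's output can be compared against the planted count.
    """
    params = dict(
        image_shape=(600, 600),
        pixel_size=0.285,
        n_nuclei=n_nuclei,
        nucleus_radius_range=(25.0, 35.0),
        foci_per_nucleus=foci_per_nucleus,
        focus_sigma_range=(1.2, 2.2),
        focus_amplitude=3000.0,
        coloc_fraction=coloc_fraction,
        independent_foci_b=independent_foci_b,
        background_level=500.0,
        dna_level=2500.0,
        noise_sigma=noise_sigma,
        pan_nuclear_fraction=pan_nuclear_fraction,
        min_focus_separation_px=9.0,
        seed=seed,
    )
    params.update(overrides)
    return SceneSpec(**params)


def default_coloc_spec(
    coloc_fraction: float,
    foci_per_nucleus: int = 10,
    seed: int = 0,
    noise_sigma: float = 300.0,
    independent_foci_b: int | None = None,
    **overrides,
) -> SceneSpec:
    """Colocalization geometry: 30 nm pixels, one nucleus per field.

    Focal signals of sigma 3.5–5 px span up to ~25–30 px, the scale the
    band-pass (DoG) segmentation with a 30 px outer Gaussian is tuned to.
    By default channel B carries ``round(coloc_fraction * n)`` duplicated
    foci plus enough independent foci to keep ~n foci per channel.  The
    default read noise of 300 (amplitude / 10) represents a moderately
    noisy confocal acquisition.
    """
    if independent_foci_b is None:
        if isinstance(foci_per_nucleus, tuple):
            raise SceneSpecError(
                "independent_foci_b: give explicitly with Poisson focus counts")
        independent_foci_b = (
            foci_per_nucleus - int(round(coloc_fraction * foci_per_nucleus)))
    params = dict(
        image_shape=(384, 384),
        pixel_size=0.030,
        n_nuclei=1,
        nucleus_radius_range=(120.0, 150.0),
        foci_per_nucleus=foci_per_nucleus,
        focus_sigma_range=(3.5, 5.0),
        focus_amplitude=3000.0,
        coloc_fraction=coloc_fraction,
        independent_foci_b=independent_foci_b,
        background_level=500.0,
        dna_level=2500.0,
        noise_sigma=noise_sigma,
        min_focus_separation_px=20.0,
        seed=seed,
    )
    params.update(overrides)
    return SceneSpec(**params)
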