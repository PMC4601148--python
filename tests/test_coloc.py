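"""Pearson/Manders coefficients against brute-force oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fociquant as fq
from fociquant.coloc import manders_split, results_to_frame, summarize_coloc


# --- independent double-loop oracles -------------------------------------

def pearson_bruteforce(a, b, mask):
    xs, ys = [], []
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if mask[i, j]:
                xs.append(float(a[i, j]))
                ys.append(float(b[i, j]))
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def manders_bruteforce(a, b, mask):
    num = sa = sb = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if mask[i, j]:
                num += float(a[i, j]) * float(b[i, j])
                sa += float(a[i, j]) ** 2
                sb += float(b[i, j]) ** 2
    return num / math.sqrt(sa * sb)


def test_coefficients_match_bruteforce_on_random_masked_images(rng):
    for _ in range(200):
        h = int(rng.integers(2, 9))
        w = int(rng.integers(2, 9))
        a = rng.uniform(0, 10, size=(h, w))
        b = rng.uniform(0.1, 10, size=(h, w))
        mask = rng.random((h, w)) < 0.7
        if mask.sum() < 3 or a[mask].std() == 0 or b[mask].std() == 0:
            continue
        assert fq.pearson_rr(a, b, mask) == pytest.approx(
            pearson_bruteforce(a, b, mask), abs=1e-12)
        assert fq.manders_overlap(a, b, mask) == pytest.approx(
            manders_bruteforce(a, b, mask), abs=1e-12)


# --- closed-form identities ----------------------------------------------

def test_pearson_identities():
    a = np.array([[1.0, 2.0], [3.0, 4.0]])
    mask = np.ones_like(a, dtype=bool)
    assert fq.pearson_rr(a, a, mask) == pytest.approx(1.0)
    assert fq.pearson_rr(a, 10.0 - a, mask) == pytest.approx(-1.0)
    b = np.array([[2.0, 1.0], [4.0, 3.0]])
    assert fq.pearson_rr(a, b, mask) == pytest.approx(
        pearson_bruteforce(a, b, mask), abs=1e-12)


def test_manders_identities():
    a = np.array([[1.0, 0.0, 2.0]])
    b = np.array([[2.0, 1.0, 0.0]])
    mask = np.ones_like(a, dtype=bool)
    assert fq.manders_overlap(a, b, mask) == pytest.approx(0.4)   # 2/sqrt(5*5)
    assert fq.manders_overlap(a, a, mask) == pytest.approx(1.0)
    disjoint_b = np.array([[0.0, 5.0, 0.0]])
    assert fq.manders_overlap(a, disjoint_b, mask) == pytest.approx(0.0)


def test_undefined_coefficients_are_nan_not_zero():
    const = np.full((3, 3), 4.0)
    varied = np.arange(9.0).reshape(3, 3)
    mask = np.ones((3, 3), dtype=bool)
    assert math.isnan(fq.pearson_rr(const, varied, mask))
    zeros = np.zeros((3, 3))
    assert math.isnan(fq.manders_overlap(zeros, varied, mask))
    assert math.isnan(fq.pearson_rr(varied, varied, np.zeros((3, 3), bool)))


# --- invariance properties -----------------------------------------------

@st.composite
def channel_pairs(draw):
    h = draw(st.integers(2, 8))
    w = draw(st.integers(2, 8))
    vals = st.floats(0.0, 100.0, allow_nan=False)
    a = np.array(draw(st.lists(vals, min_size=h * w, max_size=h * w))).reshape(h, w)
    b = np.array(draw(st.lists(vals, min_size=h * w, max_size=h * w))).reshape(h, w)
    return a, b


@settings(max_examples=40, derandomize=True, deadline=None)
@given(channel_pairs())
def test_channel_swap_symmetry(pair):
    a, b = pair
    mask = np.ones(a.shape, dtype=bool)
    rr_ab = fq.pearson_rr(a, b, mask)
    rr_ba = fq.pearson_rr(b, a, mask)
    if not math.isnan(rr_ab):
        assert rr_ab == pytest.approx(rr_ba, abs=1e-12)
    r_ab = fq.manders_overlap(a, b, mask)
    r_ba = fq.manders_overlap(b, a, mask)
    if not math.isnan(r_ab):
        assert r_ab == pytest.approx(r_ba, abs=1e-12)
    m1, m2 = manders_split(a, b, mask)
    m2s, m1s = manders_split(b, a, mask)
    if not math.isnan(m1):
        assert m1 == pytest.approx(m1s, abs=1e-12)
    if not math.isnan(m2):
        assert m2 == pytest.approx(m2s, abs=1e-12)


def test_affine_invariance_of_pearson_but_not_manders(rng):
    a = rng.uniform(1, 10, size=(6, 6))
    b = rng.uniform(1, 10, size=(6, 6))
    mask = np.ones(a.shape, dtype=bool)
    rr = fq.pearson_rr(a, b, mask)
    assert fq.pearson_rr(2.5 * a + 7.0, b, mask) == pytest.approx(rr, abs=1e-12)
    r = fq.manders_overlap(a, b, mask)
    assert fq.manders_overlap(2.5 * a, b, mask) == pytest.approx(r, abs=1e-12)
    # an offset changes the overlap coefficient
    assert fq.manders_overlap(a + 50.0, b, mask) != pytest.approx(r, abs=1e-6)


# --- per-nucleus pipeline ------------------------------------------------

def test_perfect_planted_overlap_gives_high_pearson():
    spec = fq.default_coloc_spec(coloc_fraction=1.0, seed=21, noise_sigma=0.0)
    stack, _ = fq.generate_scene(spec)
    mask = fq.segment_nuclei(stack.channel("dna"))
    results = fq.coloc_per_nucleus(stack, mask)
    assert results and all(r.valid for r in results)
    assert all(r.Rr > 0.9 for r in results)


def test_disjoint_planted_foci_give_low_overlap():
    values = []
    for seed in range(5):
        spec = fq.default_coloc_spec(coloc_fraction=0.0, seed=seed,
                                     noise_sigma=0.0)
        stack, _ = fq.generate_scene(spec)
        mask = fq.segment_nuclei(stack.channel("dna"))
        values += [r.R for r in fq.coloc_per_nucleus(stack, mask) if r.valid]
    assert values and float(np.mean(values)) < 0.2


def test_mean_pearson_monotone_in_planted_fraction_small_grid():
    means = []
    for fraction in (0.0, 0.5, 1.0):
        vals = []
        for seed in range(5):
            spec = fq.default_coloc_spec(coloc_fraction=fraction,
                                         seed=1000 + seed)
            stack, _ = fq.generate_scene(spec)
            mask = fq.segment_nuclei(stack.channel("dna"))
            vals += [r.Rr for r in fq.coloc_per_nucleus(stack, mask) if r.valid]
        means.append(float(np.mean(vals)))
    assert means[0] < means[1] < means[2]


def test_summarize_coloc_closed_form():
    results = [
        fq.ColocResult(1, 0.4, 0.5, 0.5, 0.5, 100, True),
        fq.ColocResult(2, 0.6, 0.5, 0.5, 0.5, 100, True),
        fq.ColocResult(3, float("nan"), float("nan"), float("nan"),
                       float("nan"), 100, False),
    ]
    df = results_to_frame(results, group="young", time_h=0.0)
    summary = summarize_coloc(df, group_cols=("group", "time_h"))
    row = summary.iloc[0]
    assert row["n"] == 2 and row["n_invalid"] == 1
    assert row["Rr_mean"] == pytest.approx(0.5)
    assert row["Rr_se"] == pytest.approx(0.1)
    assert row["R_se"] == pytest.approx(0.0)
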