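"""Tests of the synthetic scene generator against its stated contracts."""

import numpy as np
import pytest

import fociquant as fq
from fociquant.synthetic import PlacementError, SceneSpecError


def test_identical_seed_gives_bit_identical_scene():
    spec = fq.SceneSpec(n_nuclei=3, foci_per_nucleus=10, seed=7, noise_sigma=50.0,
                        shot_noise=True)
    stack1, truth1 = fq.generate_scene(spec)
    stack2, truth2 = fq.generate_scene(spec)
    assert np.array_equal(stack1.data, stack2.data)
    assert truth1.foci_a == truth2.foci_a
    assert truth1.foci_b == truth2.foci_b
    assert truth1.colocalized_pairs == truth2.colocalized_pairs


def test_no_foci_no_noise_gives_flat_focal_channel():
    spec = fq.SceneSpec(n_nuclei=1, foci_per_nucleus=0, noise_sigma=0.0,
                        background_level=0.0, seed=1)
    stack, _ = fq.generate_scene(spec)
    assert np.all(stack.channel("A") == 0)
    assert np.all(stack.channel("B") == 0)


def test_full_coloc_duplicates_every_center():
    spec = fq.SceneSpec(n_nuclei=3, foci_per_nucleus=8, coloc_fraction=1.0,
                        independent_foci_b=0, noise_sigma=0.0, seed=5)
    _, truth = fq.generate_scene(spec)
    assert len(truth.foci_b) == len(truth.foci_a)
    centers_a = {(f.row, f.col) for f in truth.foci_a}
    centers_b = {(f.row, f.col) for f in truth.foci_b}
    assert centers_a == centers_b


@pytest.mark.parametrize("fraction", [0.0, 0.25, 0.3, 0.5, 0.75, 1.0])
def test_pair_count_matches_rounded_fraction(fraction):
    spec = fq.SceneSpec(n_nuclei=4, foci_per_nucleus=10, coloc_fraction=fraction,
                        independent_foci_b=0, seed=2)
    _, truth = fq.generate_scene(spec)
    assert len(truth.colocalized_pairs) == round(fraction * len(truth.foci_a))


def test_every_focus_center_lies_inside_its_nucleus():
    spec = fq.SceneSpec(n_nuclei=5, foci_per_nucleus=12, independent_foci_b=3,
                        coloc_fraction=0.5, seed=9)
    _, truth = fq.generate_scene(spec)
    nuclei = {n.label: n for n in truth.nuclei}
    for f in truth.foci_a + truth.foci_b:
        assert nuclei[f.nucleus_label].contains(f.row, f.col)


def test_every_planted_focus_has_a_pixel_above_background():
    spec = fq.default_counting_spec(n_nuclei=5, seed=3)
    stack, truth = fq.generate_scene(spec)
    a = stack.channel("A").astype(float)
    for f in truth.foci_a:
        r, c = int(round(f.row)), int(round(f.col))
        patch = a[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
        assert patch.max() > spec.background_level


def test_pan_nuclear_nucleus_is_uniform_dense_staining():
    spec = fq.SceneSpec(n_nuclei=4, foci_per_nucleus=5, pan_nuclear_fraction=0.25,
                        noise_sigma=0.0, seed=4)
    stack, truth = fq.generate_scene(spec)
    assert len(truth.pan_nuclear_labels) == 1
    label = truth.pan_nuclear_labels[0]
    nucleus = next(n for n in truth.nuclei if n.label == label)
    region = nucleus.mask(spec.image_shape)
    a = stack.channel("A").astype(float)
    expected = spec.background_level + 1.5 * spec.focus_amplitude
    assert np.all(a[region] == expected)
    # and it carries no discrete planted foci
    assert all(f.nucleus_label != label for f in truth.foci_a)


def test_halfmax_footprint_grows_with_sigma():
    areas = []
    for sigma in (1.0, 1.5, 2.0, 3.0, 4.0):
        spec = fq.SceneSpec(
            image_shape=(256, 256), n_nuclei=1, foci_per_nucleus=1,
            nucleus_radius_range=(60.0, 60.0), focus_sigma_range=(sigma, sigma),
            noise_sigma=0.0, seed=8)
        stack, _ = fq.generate_scene(spec)
        a = stack.channel("A").astype(float) - spec.background_level
        areas.append(int((a > a.max() / 2).sum()))
    assert areas == sorted(areas) and len(set(areas)) == len(areas)


@pytest.mark.parametrize("kwargs, field", [
    (dict(coloc_fraction=1.5), "coloc_fraction"),
    (dict(pixel_size=0.0), "pixel_size"),
    (dict(n_nuclei=-1), "n_nuclei"),
    (dict(foci_per_nucleus=-2), "foci_per_nucleus"),
    (dict(noise_sigma=-1.0), "noise_sigma"),
    (dict(pan_nuclear_fraction=2.0), "pan_nuclear_fraction"),
    (dict(independent_foci_b=-1), "independent_foci_b"),
])
def test_invalid_spec_field_named_in_error(kwargs, field):
    with pytest.raises(SceneSpecError, match=field):
        fq.SceneSpec(**kwargs)


def test_unplaceable_nuclei_raise_placement_error():
    spec = fq.SceneSpec(image_shape=(128, 128), n_nuclei=20,
                        nucleus_radius_range=(30.0, 35.0), seed=0)
    with pytest.raises(PlacementError):
        fq.generate_scene(spec)


class TestTimecourse:
    def test_constant_retention_keeps_all_foci(self):
        spec = fq.SceneSpec(n_nuclei=3, foci_per_nucleus=10, seed=6)
        tc = fq.generate_timecourse(spec, [1.0, 4.0], {1.0: 1.0, 4.0: 1.0})
        assert len(tc[0][2].foci_a) == len(tc[1][2].foci_a) == 30

    def test_zero_retention_removes_all_foci(self):
        spec = fq.SceneSpec(n_nuclei=3, foci_per_nucleus=10, seed=6)
        tc = fq.generate_timecourse(spec, [1.0, 72.0], {1.0: 1.0, 72.0: 0.0})
        assert len(tc[1][2].foci_a) == 0

    def test_survival_fraction_matches_binomial_schedule(self):
        # 4 x 50 nuclei x 10 foci = 2000 trials at retention 0.37
        survived = total = 0
        for seed in range(4):
            spec = fq.SceneSpec(
                image_shape=(900, 900), n_nuclei=50, foci_per_nucleus=10,
                seed=seed)
            tc = fq.generate_timecourse(spec, [1.0, 48.0], {1.0: 1.0, 48.0: 0.37})
            total += len(tc[0][2].foci_a)
            survived += len(tc[1][2].foci_a)
        p = 0.37
        sd = np.sqrt(p * (1 - p) / total)
        assert abs(survived / total - p) < 3 * sd

    def test_paired_b_focus_follows_partner_survival(self):
        spec = fq.SceneSpec(n_nuclei=3, foci_per_nucleus=10, coloc_fraction=1.0,
                            independent_foci_b=0, seed=6)
        tc = fq.generate_timecourse(spec, [1.0, 48.0], {1.0: 1.0, 48.0: 0.4})
        _, _, truth48 = tc[1]
        assert len(truth48.foci_b) == len(truth48.foci_a)
        assert len(truth48.colocalized_pairs) == len(truth48.foci_a)

    def test_retention_validation(self):
        spec = fq.SceneSpec(n_nuclei=1, seed=0)
        with pytest.raises(SceneSpecError, match="retention"):
            fq.generate_timecourse(spec, [1.0, 4.0], {1.0: 1.0, 4.0: 1.2})
        with pytest.raises(SceneSpecError, match="first timepoint"):
            fq.generate_timecourse(spec, [1.0, 4.0], {1.0: 0.9, 4.0: 0.5})
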