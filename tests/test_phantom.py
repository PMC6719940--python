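import numpy as np
import pytest

from mwdetect.phantom import (DEFAULT_ANTHROPOMETRIC_TABLE, LABELS,
                              MAX_BLEEDING_ML, add_hair,
                              combine_gender_percentiles,
                              compute_scale_factors, draw_head_measures,
                              insert_bleeding, make_reference_phantom,
                              radius_from_volume_ml, randomize_subject,
                              rescale_phantom)


def test_reference_extents_match_design(reference_phantom):
    # 180 x 210 x 150 mm head, within one voxel per axis
    for axis, target in enumerate((180.0, 210.0, 150.0)):
        assert abs(reference_phantom.extent_mm(axis) - target) <= 2.0


def test_reference_contains_all_anatomy_labels(reference_phantom):
    present = set(np.unique(reference_phantom.labels))
    for name in ("background", "skin", "fat", "muscle", "skull", "csf",
                 "grey_matter", "white_matter"):
        assert LABELS[name] in present


def test_ventricles_inside_cavity(reference_phantom):
    # interior CSF (ventricles) is enclosed by the cranial cavity
    cavity = reference_phantom.cranial_cavity()
    grey = reference_phantom.labels == LABELS["grey_matter"]
    white = reference_phantom.labels == LABELS["white_matter"]
    assert cavity[grey].all() and cavity[white].all()
    assert cavity.sum() > (grey | white).sum()  # ventricles add volume


def test_combination_rule_rejects_unordered_triples():
    with pytest.raises(ValueError):
        combine_gender_percentiles((150, 140, 160), (130, 140, 150))


def test_combination_rule_spans_extremes():
    combined = combine_gender_percentiles((142, 155, 169), (132, 145, 159))
    assert combined[0] == 132 and combined[2] == 169


def test_head_measure_draws_within_truncation(rng):
    table = DEFAULT_ANTHROPOMETRIC_TABLE
    draws = np.array([draw_head_measures(table, rng) for _ in range(500)])
    for k, m in enumerate(table.measures):
        p1, p50, p99 = table.combined[m]
        assert draws[:, k].min() >= p1 - (p50 - p1)
        assert draws[:, k].max() <= p99 + (p99 - p50)
        # mean close to the combined median
        assert abs(draws[:, k].mean() - p50) < 3.0


def test_rescale_identity_is_exact(reference_phantom):
    out = rescale_phantom(reference_phantom, (1.0, 1.0, 1.0))
    assert np.array_equal(out.labels, reference_phantom.labels)


def test_rescale_by_two_repeats_voxels():
    from mwdetect.phantom import VoxelPhantom
    labels = np.arange(8, dtype=np.uint8).reshape(2, 2, 2) % 8
    p = VoxelPhantom(labels=labels, voxel_size=(1.0, 1.0, 1.0),
                     label_map={k: str(k) for k in range(8)})
    out = rescale_phantom(p, (2.0, 2.0, 2.0))
    assert out.labels.shape == (4, 4, 4)
    assert np.array_equal(out.labels, np.repeat(
        np.repeat(np.repeat(labels, 2, 0), 2, 1), 2, 2))


def test_scale_factors_are_ratios():
    assert compute_scale_factors((180, 210, 150), (90, 70, 50)) == \
        (2.0, 3.0, 3.0)


def test_add_hair_zero_thickness_is_identity(reference_phantom):
    out = add_hair(reference_phantom, thickness=0)
    assert np.array_equal(out.labels, reference_phantom.labels)


def test_add_hair_shell_adjacent_to_scalp(reference_phantom):
    from scipy import ndimage
    out = add_hair(reference_phantom, thickness=3)
    hair = out.labels == LABELS["hair"]
    assert hair.any()
    # hair voxels were background before and lie within 3 mm of the head
    assert (reference_phantom.labels[hair] == LABELS["background"]).all()
    head = reference_phantom.labels != LABELS["background"]
    dist = ndimage.distance_transform_edt(
        ~head, sampling=reference_phantom.voxel_size)
    assert dist[hair].max() <= 3.0


def test_add_hair_rejects_out_of_range():
    with pytest.raises(ValueError):
        add_hair(make_reference_phantom(), thickness=5)


def test_radius_volume_inverse():
    assert radius_from_volume_ml(4.0 / 3.0 * np.pi) == pytest.approx(10.0)


def test_insert_bleeding_respects_cavity_and_bound(reference_phantom, rng):
    cavity = reference_phantom.cranial_cavity()
    for _ in range(20):
        out, spec = insert_bleeding(reference_phantom, rng)
        blood = out.labels == LABELS["blood"]
        assert blood.sum() * out.voxel_volume_mm3 / 1000.0 == \
            pytest.approx(spec.volume_ml)
        assert spec.volume_ml <= MAX_BLEEDING_ML
        assert cavity[blood].all()
        # nothing but the lesion changed
        changed = out.labels != reference_phantom.labels
        assert np.array_equal(changed, blood &
                              (reference_phantom.labels != LABELS["blood"]))


def test_insert_bleeding_deterministic(reference_phantom):
    a = insert_bleeding(reference_phantom, np.random.default_rng(5))[1]
    b = insert_bleeding(reference_phantom, np.random.default_rng(5))[1]
    assert a == b


def test_randomize_subject_pipeline(reference_phantom):
    rng = np.random.default_rng(17)
    subject, spec = randomize_subject(reference_phantom, rng, bleeding=True)
    assert spec is not None and 0.0 <= spec.volume_ml <= MAX_BLEEDING_ML
    assert (subject.labels == LABELS["blood"]).any()
    ops = [p["op"] for p in subject.provenance if isinstance(p, dict)]
    assert ops[-3:] == ["insert_bleeding", "rescale_phantom", "add_hair"]

    healthy, spec_h = randomize_subject(reference_phantom, rng,
                                        bleeding=False)
    assert spec_h is None
    assert not (healthy.labels == LABELS["blood"]).any()
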