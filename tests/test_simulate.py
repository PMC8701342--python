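import json

import numpy as np
import pytest

from copyamp.coverage import genome_mean_depth
from copyamp.qpcr import quantify_plate, sample_quantities
from copyamp.regions import RegionMask
from copyamp.simulate import (
    EventSet,
    GenomeLayout,
    NoiseModel,
    nb_draw,
    simulate_depth,
    simulate_plasmid_depth,
    simulate_qpcr_plate,
    simulate_variant_calls,
    write_truth,
)


# ---------------------------------------------------------------------------
# layout / event validation


def test_layout_rejects_duplicate_names():
    with pytest.raises(ValueError, match="unique"):
        GenomeLayout([("chrI", 100), ("chrI", 200)])


def test_layout_rejects_zero_length():
    with pytest.raises(ValueError):
        GenomeLayout([("chrI", 0)])


def test_layout_excluded_must_lie_within():
    with pytest.raises(ValueError):
        GenomeLayout([("chrI", 100)], RegionMask([("chrI", 50, 200)]))


def test_eventset_rejects_bad_factor():
    with pytest.raises(ValueError):
        EventSet(segments=[("chrI", 0, 10, 0.0)])


def test_eventset_rejects_negative_plasmid_cn():
    with pytest.raises(ValueError):
        EventSet(plasmid_cn=-1.0)


def test_overlapping_events_multiply():
    events = EventSet(disomies={"chrI"}, segments=[("chrI", 10, 20, 3.0)])
    prof = events.factor_profile("chrI", 30)
    assert prof[5] == 2.0
    assert prof[15] == 6.0


# ---------------------------------------------------------------------------
# simulate_depth


def test_deterministic_no_event_genome_equals_mean(small_layout, det_noise):
    tracks, _ = simulate_depth(small_layout, EventSet(), det_noise, bin_size=1000)
    for track in tracks.values():
        np.testing.assert_allclose(track.means, 30.0)
    assert genome_mean_depth(tracks.values()) == pytest.approx(30.0)


def test_deterministic_disomy_doubles_chromosome(small_layout, det_noise):
    tracks, _ = simulate_depth(
        small_layout, EventSet(disomies={"chrII"}), det_noise, bin_size=1000
    )
    np.testing.assert_allclose(tracks["chrII"].means, 60.0)
    np.testing.assert_allclose(tracks["chrI"].means, 30.0)


def test_deterministic_segment_factor(small_layout, det_noise):
    tracks, _ = simulate_depth(
        small_layout,
        EventSet(segments=[("chrIV", 10_000, 20_000, 2.0)]),
        det_noise,
        bin_size=1000,
    )
    np.testing.assert_allclose(tracks["chrIV"].means[10:20], 60.0)
    np.testing.assert_allclose(tracks["chrIV"].means[:10], 30.0)


def test_nb_moments_match_formula():
    """Empirical mean within 1% of 30; variance within 15% of 30 + 30^2/10."""
    rng = np.random.default_rng(42)
    draws = nb_draw(rng, np.full(10_000, 30.0), 10.0)
    assert abs(draws.mean() - 30.0) / 30.0 < 0.01
    expected_var = 30.0 + 30.0**2 / 10.0  # 120
    assert abs(draws.var() - expected_var) / expected_var < 0.15


def test_simulate_depth_moments():
    layout = GenomeLayout([("chrI", 10_000_000)])
    tracks, _ = simulate_depth(
        layout, EventSet(), NoiseModel(30.0, 10.0, seed=7), bin_size=1000
    )
    means = tracks["chrI"].means
    assert means.size == 10_000
    assert abs(means.mean() - 30.0) / 30.0 < 0.01
    expected_var = 30.0 + 30.0**2 / 10.0
    assert abs(means.var() - expected_var) / expected_var < 0.15


def test_simulate_depth_deterministic_seed_reproducibility(small_layout):
    a, _ = simulate_depth(small_layout, EventSet(), NoiseModel(30, 10, seed=5), 1000)
    b, _ = simulate_depth(small_layout, EventSet(), NoiseModel(30, 10, seed=5), 1000)
    c, _ = simulate_depth(small_layout, EventSet(), NoiseModel(30, 10, seed=6), 1000)
    for name in a:
        np.testing.assert_array_equal(a[name].means, b[name].means)
    assert any(not np.array_equal(a[n].means, c[n].means) for n in a)


def test_simulate_depth_bin_size_guard(small_layout, det_noise):
    with pytest.raises(ValueError, match="bin_size"):
        simulate_depth(small_layout, EventSet(), det_noise, bin_size=16_000)


def test_truth_record_round_trip(small_layout, det_noise, tmp_path):
    events = EventSet(
        plasmid_cn=5.0, disomies={"chrII"}, segments=[("chrIV", 0, 1000, 2.0)]
    )
    _, truth = simulate_depth(small_layout, events, det_noise, 1000)
    path = tmp_path / "truth.json"
    write_truth(truth, path)
    back = json.loads(path.read_text())
    assert back["events"]["plasmid_cn"] == 5.0
    assert back["events"]["disomies"] == ["chrII"]
    assert back["events"]["segments"] == [["chrIV", 0, 1000, 2.0]]


# ---------------------------------------------------------------------------
# simulate_plasmid_depth


def test_plasmid_depth_cn_zero(plasmid_spec, det_noise):
    track = simulate_plasmid_depth(plasmid_spec, 0.0, 40.0, det_noise)
    dense = track.to_dense(plasmid_spec.length)
    specific = plasmid_spec.specific_membership()
    np.testing.assert_allclose(dense[specific], 0.0)
    np.testing.assert_allclose(dense[~specific], 40.0)


def test_plasmid_depth_cn_one_additive(plasmid_spec, det_noise):
    track = simulate_plasmid_depth(plasmid_spec, 1.0, 40.0, det_noise)
    dense = track.to_dense(plasmid_spec.length)
    specific = plasmid_spec.specific_membership()
    np.testing.assert_allclose(dense[specific], 40.0)
    np.testing.assert_allclose(dense[~specific], 80.0)


def test_plasmid_depth_cn_7_5(plasmid_spec, det_noise):
    # 40 x 7.5 = 300 on plasmid-specific bases
    track = simulate_plasmid_depth(plasmid_spec, 7.5, 40.0, det_noise)
    dense = track.to_dense(plasmid_spec.length)
    np.testing.assert_allclose(dense[plasmid_spec.specific_membership()], 300.0)


def test_plasmid_depth_rejects_negative_cn(plasmid_spec, det_noise):
    with pytest.raises(ValueError):
        simulate_plasmid_depth(plasmid_spec, -0.5, 40.0, det_noise)


def test_plasmid_depth_seed_reproducible(plasmid_spec):
    a = simulate_plasmid_depth(plasmid_spec, 5.0, 30.0, NoiseModel(30, 10, seed=3))
    b = simulate_plasmid_depth(plasmid_spec, 5.0, 30.0, NoiseModel(30, 10, seed=3))
    np.testing.assert_array_equal(a.depth, b.depth)


# ---------------------------------------------------------------------------
# simulate_variant_calls


def test_variant_calls_nothing_planted():
    calls, truth = simulate_variant_calls(
        5, RegionMask([("plasmid", 0, 100)]), 0.0, 0.0, seed=1
    )
    assert all(len(v) == 0 for v in calls.values())
    assert truth["artifact_keys"] == []


def test_variant_calls_empty_mask_with_artifacts_errors():
    with pytest.raises(ValueError, match="mask"):
        simulate_variant_calls(5, RegionMask(), 0.5, 0.0, seed=1)


def test_introduced_allele_recurrence_by_construction():
    introduced = [
        {
            "sequence": "chrIV",
            "position": 541,
            "ref": "G",
            "alt": "T",
            "samples": ["s01", "s02", "s03", "s04", "s05"],
        }
    ]
    calls, truth = simulate_variant_calls(
        10, RegionMask([("plasmid", 0, 100)]), 0.0, 0.0,
        introduced_alleles=introduced, seed=1,
    )
    carriers = [s for s, recs in calls.items() if recs]
    assert carriers == ["s01", "s02", "s03", "s04", "s05"]
    assert truth["introduced"][0]["key"] == ["chrIV", 541, "G", "T"]


def test_artifacts_are_het_inside_mask():
    mask = RegionMask([("plasmid", 100, 500)])
    calls, truth = simulate_variant_calls(
        20, mask, 0.5, 0.0, seed=2, n_artifact_sites=3
    )
    planted = {tuple(k) for k in truth["artifact_keys"]}
    assert len(planted) == 3
    for recs in calls.values():
        for r in recs:
            assert r.zygosity == "het"
            assert mask.contains(r.sequence, r.position - 1)
    # each artifact recurs in round(0.5 * 20) = 10 carriers
    from collections import Counter

    counts = Counter(r.key for recs in calls.values() for r in recs)
    assert all(counts[k] == 10 for k in planted)


def test_private_variants_are_hom_outside_mask():
    layout = GenomeLayout([("chrI", 10_000)])
    mask = RegionMask([("chrI", 0, 5000)])
    calls, truth = simulate_variant_calls(
        10, mask, 0.0, 0.3, seed=3, layout=layout
    )
    seen = set()
    for sid, recs in calls.items():
        for r in recs:
            assert r.zygosity == "hom"
            assert not mask.contains(r.sequence, r.position - 1)
            assert r.key not in seen  # sample-private
            seen.add(r.key)
        assert {tuple(k) for k in truth["private_keys"][sid]} == {r.key for r in recs}


def test_variant_calls_order_of_samples_deterministic():
    mask = RegionMask([("plasmid", 0, 1000)])
    a, _ = simulate_variant_calls(8, mask, 0.5, 0.0, seed=9)
    b, _ = simulate_variant_calls(8, mask, 0.5, 0.0, seed=9)
    assert {s: [r.key for r in recs] for s, recs in a.items()} == {
        s: [r.key for r in recs] for s, recs in b.items()
    }


# ---------------------------------------------------------------------------
# simulate_qpcr_plate


def test_qpcr_calibrator_identity():
    ms, _ = simulate_qpcr_plate({"cal": 1.0, "s": 1.0}, 20.0, 0.0, seed=0)
    df = quantify_plate(ms, "cal")
    assert set(df["quantity"].round(12)) == {1.0}
    target = [m for m in ms if m.sample == "s" and m.role == "target"][0]
    assert target.cts == [20.0, 20.0, 20.0]


def test_qpcr_quantity_8_gives_delta_ct_minus_3():
    ms, _ = simulate_qpcr_plate({"cal": 1.0, "s": 8.0}, 20.0, 0.0, seed=0)
    df = quantify_plate(ms, "cal")
    row = df[df["sample"] == "s"].iloc[0]
    assert row["delta_ct"] == pytest.approx(-3.0)
    assert row["quantity"] == pytest.approx(8.0)


def test_qpcr_rejects_nonpositive_quantity():
    with pytest.raises(ValueError):
        simulate_qpcr_plate({"s": 0.0}, 20.0, 0.0)


def test_qpcr_noisy_recovery_within_10pct():
    truth_q = {"cal": 1.0, "a": 1.0, "b": 2.0, "c": 4.0, "d": 2.0, "e": 4.0}
    ms, _ = simulate_qpcr_plate(
        truth_q, 20.0, 0.1, n_triplicates=3, n_bio_replicates=3, seed=11
    )
    df = quantify_plate(ms, "cal")
    recovered = sample_quantities(df)
    for sample, q in truth_q.items():
        assert abs(recovered[sample] - q) / q < 0.10


def test_qpcr_seed_reproducible():
    a, _ = simulate_qpcr_plate({"s": 2.0}, 20.0, 0.2, seed=4)
    b, _ = simulate_qpcr_plate({"s": 2.0}, 20.0, 0.2, seed=4)
    assert a[0].cts == b[0].cts
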