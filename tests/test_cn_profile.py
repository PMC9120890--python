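"""Profiles, SEG I/O, segmentation and tumor-fraction estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plasmacna.cn_profile import (
    BinnedProfile,
    SegmentProfile,
    SEGMENT_COLUMNS,
    ctdna_status,
    estimate_noise_sd,
    estimate_tf,
    expected_logr,
    read_seg,
    segment,
    segments_to_bins,
    write_seg,
)
from plasmacna.genome import make_bins
from plasmacna.synthetic_cohort import render_logR, simulate_tumor_profile


def _flat_profile(n_bins=200, value=0.0, chrom="chr1", bin_size=50_000):
    bins = make_bins([(chrom, n_bins * bin_size)], bin_size)
    bins["logr"] = value
    return BinnedProfile("s", bins)


def _seg_profile(rows, sample="s"):
    return SegmentProfile(sample, pd.DataFrame(rows, columns=SEGMENT_COLUMNS))


# ---------------------------------------------------------------------------
# containers and SEG I/O
# ---------------------------------------------------------------------------

def test_binned_profile_rejects_overlap():
    bins = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 40_000], "end": [50_000, 90_000],
         "logr": [0.0, 0.0]}
    )
    with pytest.raises(ValueError, match="overlap"):
        BinnedProfile("s", bins)


def test_seg_round_trip(tmp_path):
    prof = _seg_profile(
        [
            ("chr1", 0, 500_000, 10, 0.25, 3.0),
            ("chr1", 500_000, 1_000_000, 10, 0.0, 2.0),
            ("chr2", 0, 250_000, 5, -0.3, 1.0),
        ]
    )
    path = tmp_path / "a.seg"
    write_seg(prof, path)
    back = read_seg(path)
    assert back.sample_id == prof.sample_id
    pd.testing.assert_frame_equal(back.segments, prof.segments)


def test_seg_end_before_start_names_line(tmp_path):
    path = tmp_path / "bad.seg"
    path.write_text(
        "sample\tchrom\tstart\tend\tnum_bins\tlogR\n"
        "s\tchr1\t1\t500000\t10\t0.1\n"
        "s\tchr1\t900000\t600000\t5\t0.2\n"
    )
    with pytest.raises(ValueError, match="line 3"):
        read_seg(path)


def test_seg_hand_written_bin_count(tmp_path):
    path = tmp_path / "hand.seg"
    path.write_text(
        "sample\tchrom\tstart\tend\tnum_bins\tlogR\n"
        "s\tchr1\t1\t150000\t3\t0.0\n"
        "s\tchr1\t150001\t400000\t5\t0.4\n"
        "s\tchr2\t1\t100000\t2\t-0.2\n"
    )
    prof = read_seg(path)
    assert prof.segments["n_bins"].sum() == 10
    # SEG is 1-based inclusive; internal coordinates 0-based half-open
    assert prof.segments.loc[0, "start"] == 0
    assert prof.segments.loc[1, "start"] == 150_000


@settings(max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.integers(1, 40), st.floats(-2, 2)), min_size=1, max_size=8))
def test_seg_round_trip_property(tmp_path_factory, lengths):
    rows, pos = [], 0
    for n, logr in lengths:
        rows.append(("chr1", pos, pos + n * 50_000, n, float(np.round(logr, 6)), 2.0))
        pos += n * 50_000
    prof = _seg_profile(rows)
    path = tmp_path_factory.mktemp("seg") / "p.seg"
    write_seg(prof, path)
    back = read_seg(path)
    np.testing.assert_allclose(back.segments["logr"], prof.segments["logr"], atol=1e-9)
    assert (back.segments["start"] == prof.segments["start"]).all()


def test_segments_to_bins_inverts_averaging():
    prof = _seg_profile(
        [("chr1", 0, 500_000, 10, 0.3, 2.0), ("chr1", 500_000, 750_000, 5, -0.1, 2.0)]
    )
    bp = segments_to_bins(prof, 50_000)
    assert bp.n_bins == 15
    assert np.allclose(bp.bins["logr"][:10], 0.3)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_segment_constant_profile_single_segment():
    prof = _flat_profile(300, 0.13)
    seg = segment(prof)
    assert len(seg.segments) == 1
    assert seg.segments.loc[0, "n_bins"] == 300


def test_segment_noiseless_block_exact_boundaries():
    bins = make_bins([("chr1", 300 * 50_000)], 50_000)
    x = np.zeros(300)
    x[120:180] = np.log2(1.2)  # CN=3 block at tf=0.4
    bins["logr"] = x
    seg = segment(BinnedProfile("s", bins))
    assert len(seg.segments) == 3
    assert seg.segments.loc[1, "start"] == 120 * 50_000
    assert seg.segments.loc[1, "end"] == 180 * 50_000
    assert np.isclose(seg.segments.loc[1, "logr"], np.log2(1.2))


def test_segment_chromosome_order_invariance(rng):
    bins1 = make_bins([("chr1", 100 * 50_000), ("chr2", 80 * 50_000)], 50_000)
    x = rng.normal(0, 0.3, len(bins1))
    bins1["logr"] = x
    p1 = BinnedProfile("s", bins1)
    flipped = pd.concat(
        [bins1[bins1.chrom == "chr2"], bins1[bins1.chrom == "chr1"]]
    ).reset_index(drop=True)
    p2 = BinnedProfile("s", flipped)
    s1 = segment(p1).segments.sort_values(["chrom", "start"]).reset_index(drop=True)
    s2 = segment(p2).segments.sort_values(["chrom", "start"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(s1, s2)


def test_segment_empty_profile_errors():
    with pytest.raises(ValueError):
        BinnedProfile("s", pd.DataFrame(columns=["chrom", "start", "end", "logr"]))


# ---------------------------------------------------------------------------
# tumor fraction
# ---------------------------------------------------------------------------

def test_estimate_tf_all_diploid():
    prof = _seg_profile([("chr1", 0, 5_000_000, 100, 0.0, np.nan)])
    est = estimate_tf(prof)
    assert est.tf == 0.0
    assert (est.model == 2).all()
    assert not est.detected


def test_estimate_tf_closed_form_mixture():
    # 10% of bins gained (CN3), 10% lost (CN1), rest diploid, tf=0.40
    prof = _seg_profile(
        [
            ("chr1", 0, 40_000_000, 800, 0.0, np.nan),
            ("chr1", 40_000_000, 45_000_000, 100, np.log2(1.2), np.nan),
            ("chr1", 45_000_000, 50_000_000, 100, np.log2(0.8), np.nan),
        ]
    )
    est = estimate_tf(prof, grid_step=0.01)
    assert abs(est.tf - 0.40) <= 0.0100001
    assert est.model[1] == 3 and est.model[2] == 1


@pytest.mark.parametrize("tf", [0.1, 0.2, 0.4, 0.6])
def test_render_segment_estimate_exact_inversion(noiseless_config, tf):
    """Noiseless render -> segment -> estimate recovers tf to one grid step."""
    rng = np.random.default_rng(100 + int(tf * 100))
    prof = simulate_tumor_profile(noiseless_config, rng, "s")
    bp = render_logR(prof, tf, noiseless_config, rng)
    est = estimate_tf(segment(bp))
    assert abs(est.tf - tf) <= 0.0100001


def test_low_tf_small_event_recovery(noiseless_config):
    """A single large CN=3 event at tf=0.05 is recovered noiselessly."""
    bins = make_bins(noiseless_config.genome, 50_000)
    x = np.zeros(len(bins))
    x[200:900] = np.log2(0.05 * 1.5 + 0.95)
    bins["logr"] = x
    est = estimate_tf(segment(BinnedProfile("s", bins)))
    assert abs(est.tf - 0.05) <= 0.0100001


def test_identifiability_guard_small_altered_fraction(small_config):
    """A single altered segment covering <1% of bins at low tf is not
    detected under default noise: the low-TF sensitivity limit."""
    bins = make_bins(small_config.genome, 50_000)
    n = len(bins)
    x = np.random.default_rng(7).normal(0, 0.3, n)
    k = int(0.008 * n)
    x[500:500 + k] += np.log2(0.03 * 1.5 + 0.97)  # CN=3 at tf=0.03
    bins["logr"] = x
    prof = BinnedProfile("s", bins)
    est = estimate_tf(segment(prof), noise_sd=estimate_noise_sd(prof))
    assert not est.detected


def test_estimated_tf_monotone_in_true_tf(small_config):
    prof = simulate_tumor_profile(small_config, np.random.default_rng(3), "s")
    prev = -1.0
    for tf in np.arange(0.05, 0.65, 0.05):
        bp = render_logR(prof, float(tf), small_config, np.random.default_rng(11))
        est = estimate_tf(segment(bp), noise_sd=estimate_noise_sd(bp))
        assert est.tf >= prev - 0.0100001
        prev = est.tf


def test_mixture_consistency_grid():
    """With zero noise, expected_logr inverts exactly for CN 0..6 on a tf grid."""
    for tf in np.arange(0.0, 0.85, 0.05):
        for cn in range(7):
            r = expected_logr(float(tf), cn)
            back = (2.0 ** r - (1 - tf)) * 2 / tf if tf > 0 else None
            if tf > 0 and r > -8:
                assert abs(back - cn) < 1e-9


def test_ctdna_status_threshold_semantics():
    est = estimate_tf(_seg_profile([("chr1", 0, 5_000_000, 100, 0.0, np.nan)]))
    assert ctdna_status(est) == "negative"
    est.tf = 0.02
    assert ctdna_status(est) == "positive"
    assert ctdna_status(est, detection_threshold=0.03) == "negative"
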