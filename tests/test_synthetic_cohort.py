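"""Cohort generator: determinism, ground-truth laws, rendering."""

import numpy as np
import pandas as pd
import pytest

from plasmacna.synthetic_cohort import (
    SimConfig,
    evolve_profile,
    overlaps_loci,
    render_logR,
    simulate_cohort,
    simulate_tumor_profile,
)

TINY = [("chr1", 60_000_000), ("chr2", 50_000_000)]


def _cfg(**kw):
    base = dict(n_patients=5, genome=list(TINY), seed=42,
                event_length=(2_000_000, 10_000_000), n_cna_events=(2, 5),
                pathway_loci=(("chr1", 20_000_000, 21_000_000),))
    base.update(kw)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# tumor profiles
# ---------------------------------------------------------------------------

def test_no_events_gives_diploid_genome():
    cfg = _cfg(n_cna_events=(0, 0))
    prof = simulate_tumor_profile(cfg, np.random.default_rng(1))
    assert (prof.segments["cn"] == 2).all()
    assert prof.segments["end"].iloc[-1] == TINY[1][1]


def test_same_seed_identical_profiles():
    cfg = _cfg()
    a = simulate_tumor_profile(cfg, np.random.default_rng(7))
    b = simulate_tumor_profile(cfg, np.random.default_rng(7))
    pd.testing.assert_frame_equal(a.segments, b.segments)


def test_event_count_and_disjointness():
    cfg = _cfg(genome=[("chr1", 1_500_000_000), ("chr2", 1_500_000_000)],
               n_cna_events=(20, 20), event_length=(1_000_000, 50_000_000),
               pathway_loci=())
    prof = simulate_tumor_profile(cfg, np.random.default_rng(3))
    events = prof.segments[prof.segments.cn != 2]
    assert len(events) == 20
    # pairwise disjoint by interval sweep within chromosomes
    for _, sub in events.groupby("chrom"):
        s = sub.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


def test_overdense_configuration_errors():
    cfg = _cfg(genome=[("chr1", 10_000_000)], n_cna_events=(30, 30),
               event_length=(2_000_000, 5_000_000), pathway_loci=())
    with pytest.raises(RuntimeError, match="dense"):
        simulate_tumor_profile(cfg, np.random.default_rng(0))


def test_required_and_forbidden_loci():
    loci = (("chr1", 20_000_000, 21_000_000),)
    cfg = _cfg()
    hit = simulate_tumor_profile(cfg, np.random.default_rng(5), required_loci=loci)
    assert overlaps_loci(hit, loci)
    for seed in range(5):
        miss = simulate_tumor_profile(
            cfg, np.random.default_rng(seed), forbidden_loci=loci
        )
        assert not overlaps_loci(miss, loci)


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def test_full_conservation_identity():
    cfg = _cfg(conserve_gain_prob=1.0, conserve_loss_prob=1.0, n_emergent_events=(0, 0))
    base = simulate_tumor_profile(cfg, np.random.default_rng(2))
    prog, ledger = evolve_profile(base, cfg, np.random.default_rng(3))
    assert all(ev["fate"] == "conserved" for ev in ledger)
    pd.testing.assert_frame_equal(
        base.segments.drop(columns="logr"),
        prog.segments.drop(columns="logr"),
    )


def test_zero_conservation_reverts_everything():
    cfg = _cfg(conserve_gain_prob=0.0, conserve_loss_prob=0.0, n_emergent_events=(0, 0))
    base = simulate_tumor_profile(cfg, np.random.default_rng(2))
    prog, ledger = evolve_profile(base, cfg, np.random.default_rng(3))
    assert (prog.segments["cn"] == 2).all()
    assert all(ev["fate"] == "reverted" for ev in ledger)


def test_emergent_events_absent_from_baseline():
    cfg = _cfg(n_emergent_events=(2, 2))
    base = simulate_tumor_profile(cfg, np.random.default_rng(4))
    _, ledger = evolve_profile(base, cfg, np.random.default_rng(5))
    base_events = base.segments[base.segments.cn != 2]
    for ev in ledger:
        if ev["fate"] != "emergent":
            continue
        overlap = base_events[
            (base_events.chrom == ev["chrom"])
            & (base_events.start < ev["end"])
            & (ev["start"] < base_events.end)
        ]
        assert overlap.empty


def test_conservation_fractions_converge_to_probabilities():
    """Binomial law: conserved fractions approach the configured
    probabilities over many replicate evolutions (10 gains, 10 losses)."""
    cfg = _cfg(genome=[("chr1", 2_000_000_000)], conserve_loss_prob=0.83,
               conserve_gain_prob=0.71, n_emergent_events=(0, 0), pathway_loci=())
    # fixed baseline: 10 gains and 10 losses
    rows = []
    pos = 0
    for i in range(20):
        rows.append(("chr1", pos, pos + 5_000_000, 5_000_000 // 50_000,
                     0.0, 3.0 if i < 10 else 1.0))
        rows.append(("chr1", pos + 5_000_000, pos + 50_000_000, 1, 0.0, 2.0))
        pos += 50_000_000
    from plasmacna.cn_profile import SEGMENT_COLUMNS, SegmentProfile
    base = SegmentProfile("b", pd.DataFrame(rows, columns=SEGMENT_COLUMNS))
    rng = np.random.default_rng(11)
    n_rep = 1000
    kept_g = kept_l = 0
    for _ in range(n_rep):
        _, ledger = evolve_profile(base, cfg, rng)
        kept_g += sum(e["fate"] == "conserved" for e in ledger if e["direction"] == "gain")
        kept_l += sum(e["fate"] == "conserved" for e in ledger if e["direction"] == "loss")
    n = 10 * n_rep
    se_g = np.sqrt(0.71 * 0.29 / n)
    se_l = np.sqrt(0.83 * 0.17 / n)
    assert abs(kept_g / n - 0.71) <= 3 * se_g
    assert abs(kept_l / n - 0.83) <= 3 * se_l


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def test_render_pure_normal_plasma_zero():
    cfg = _cfg(noise_sd=0.0)
    prof = simulate_tumor_profile(cfg, np.random.default_rng(1))
    bp = render_logR(prof, 0.0, cfg, np.random.default_rng(2))
    assert np.allclose(bp.bins["logr"], 0.0)


def test_render_closed_form_values():
    cfg = _cfg(noise_sd=0.0, n_cna_events=(0, 0))
    prof = simulate_tumor_profile(cfg, np.random.default_rng(1))
    seg = prof.segments.copy()
    seg.loc[0, "cn"] = 3.0
    seg.loc[1, "cn"] = 1.0
    from plasmacna.cn_profile import SegmentProfile
    prof = SegmentProfile("s", seg)
    bp = render_logR(prof, 0.4, cfg, np.random.default_rng(2))
    chr1 = bp.bins[bp.bins.chrom == "chr1"]["logr"]
    chr2 = bp.bins[bp.bins.chrom == "chr2"]["logr"]
    assert np.allclose(chr1, np.log2(1.2))   # CN=3 at tf=0.4
    assert np.allclose(chr2, np.log2(0.8))   # CN=1 at tf=0.4


def test_render_rejects_bad_tf():
    cfg = _cfg()
    prof = simulate_tumor_profile(cfg, np.random.default_rng(1))
    with pytest.raises(ValueError):
        render_logR(prof, 1.0, cfg, np.random.default_rng(2))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def test_cohort_determinism():
    cfg = _cfg(n_patients=4)
    c1, t1 = simulate_cohort(cfg)
    c2, t2 = simulate_cohort(cfg)
    pd.testing.assert_frame_equal(c1.to_clinical_frame(), c2.to_clinical_frame())
    for pid in t1.records:
        pd.testing.assert_frame_equal(
            t1.records[pid].baseline_segments.segments,
            t2.records[pid].baseline_segments.segments,
        )


def test_cohort_requires_patients():
    with pytest.raises(ValueError):
        simulate_cohort(_cfg(n_patients=0))


def test_baseline_positive_fraction_binomial():
    cfg = _cfg(n_patients=4000, render_profiles=False, baseline_positive_prob=0.675)
    cohort, _ = simulate_cohort(cfg)
    frac = cohort.to_clinical_frame()["ctdna_baseline"].mean()
    se = np.sqrt(0.675 * 0.325 / 4000)
    assert abs(frac - 0.675) <= 3 * se


def test_truth_invariants_and_sample_structure():
    cfg = _cfg(n_patients=12)
    cohort, truth = simulate_cohort(cfg)
    for p in cohort.patients:
        rec = truth.records[p.patient_id]
        assert set(p.samples) == {"baseline", "week7", "eot"}
        for tp, tf in rec.tf.items():
            assert 0 <= tf < 1
            assert rec.status[tp] == ("positive" if tf > 0 else "negative")
        assert p.pfs_months <= cfg.censor_time + 1e-9
        if p.pfs_event == 0:
            assert p.pfs_months <= cfg.censor_time
        if rec.maf:
            # MAF tracks TF/2 up to noise
            for tp, maf in rec.maf.items():
                assert maf == pytest.approx(rec.tf[tp] / 2, abs=0.05)


def test_survival_hazard_ratio_converges():
    """Empirical HR over a large cohort approaches exp(true_log_hr)."""
    cfg = _cfg(n_patients=5000, render_profiles=False)
    cohort, _ = simulate_cohort(cfg)
    df = cohort.to_clinical_frame()
    from plasmacna.clinical_stats import cox
    fit = cox(df, covariates=["ctdna_baseline"])["ctdna_baseline"]
    assert fit.ci95[0] < 3.45 < fit.ci95[1] or abs(fit.hr - 3.45) / 3.45 < 0.15
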