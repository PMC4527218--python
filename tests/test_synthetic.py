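"""The generators reproduce their configured statistical structure."""

import numpy as np
import pandas as pd
import pytest

from scwga import (
    Breakpoint,
    CNVTruthProfile,
    GenomeLayout,
    MethodProfile,
    ado_fp_counts,
    make_bins,
    match_breakpoints,
    simulate_binned_counts,
    simulate_breakpoints,
    simulate_golden_control,
    simulate_single_cell_calls,
)
from scwga.profiles import normalize_mix

# golden-control category counts for YH-like proportions
YH_PROPORTIONS = np.array([1_584_649, 270_225, 351_490]) / 2_206_364


def test_degenerate_proportions_give_single_category(layout):
    control = simulate_golden_control(1000, (1.0, 0.0, 0.0), layout, seed=0)
    assert control.category_counts == {"HOMref": 1000, "HOMmut": 0, "HETref": 0}


def test_golden_control_is_deterministic_and_sorted(layout):
    a = simulate_golden_control(2000, (0.5, 0.2, 0.3), layout, seed=9)
    b = simulate_golden_control(2000, (0.5, 0.2, 0.3), layout, seed=9)
    pd.testing.assert_frame_equal(a.sites, b.sites)
    for _, grp in a.sites.groupby("chrom"):
        assert grp["pos"].is_monotonic_increasing
        assert grp["pos"].is_unique


def test_golden_control_category_counts_multinomial(layout):
    """Scaled YH-like proportions land within 3 s.d. of expectation."""
    n = 22_064
    control = simulate_golden_control(n, tuple(YH_PROPORTIONS), layout, seed=2)
    counts = control.category_counts
    for cat, p in zip(("HOMref", "HOMmut", "HETref"), YH_PROPORTIONS):
        sd = np.sqrt(n * p * (1 - p))
        assert abs(counts[cat] - n * p) <= 3 * sd


def test_golden_control_rejects_bad_input(layout):
    with pytest.raises(ValueError):
        simulate_golden_control(0, (1, 0, 0), layout)
    with pytest.raises(ValueError):
        simulate_golden_control(10, (0.5, 0.2, 0.2), layout)
    tiny = GenomeLayout({"chr1": 5})
    with pytest.raises(ValueError):
        simulate_golden_control(10, (1, 0, 0), tiny)


def test_no_noise_calls_identical_to_control(small_control, quiet_profile):
    calls = simulate_single_cell_calls(small_control, quiet_profile, seed=1)
    assert len(calls) == len(small_control)
    assert (calls.truth_labels["label"] == "faithful").all()
    merged = small_control.sites.merge(calls.calls, on=["chrom", "pos"],
                                       suffixes=("_c", "_s"))
    assert (merged["a1_c"] == merged["a1_s"]).all()
    assert (merged["a2_c"] == merged["a2_s"]).all()


def test_ado_and_fp_counts_match_binomial(layout):
    control = simulate_golden_control(10_000, (0.0, 0.0, 1.0), layout, seed=4)
    profile = MethodProfile(name="m", ado_rate=0.334, fp_rate=0.0, site_coverage=1.0)
    calls = simulate_single_cell_calls(control, profile, seed=5)
    n_ado = (calls.truth_labels["label"] == "ADO").sum()
    sd = np.sqrt(10_000 * 0.334 * 0.666)
    assert abs(n_ado - 10_000 * 0.334) <= 3 * sd
    # every labeled ADO site is het in the control and hom in the call
    ado_sites = calls.truth_labels.loc[calls.truth_labels["label"] == "ADO",
                                       ["chrom", "pos"]]
    hit = ado_sites.merge(calls.calls, on=["chrom", "pos"])
    assert (hit["a1"] == hit["a2"]).all()


def test_fp_counts_match_binomial(layout):
    n = 1_000_000
    control = simulate_golden_control(n, (1.0, 0.0, 0.0), layout, seed=6)
    profile = MethodProfile(name="m", ado_rate=0.0, fp_rate=1.32e-4, site_coverage=1.0)
    calls = simulate_single_cell_calls(control, profile, seed=7)
    n_fp = (calls.truth_labels["label"] == "FP").sum()
    expected = n * 1.32e-4
    sd = np.sqrt(expected)
    assert abs(n_fp - expected) <= 3 * sd


def test_estimator_counts_equal_truth_labels(small_control):
    """Label consistency: ADO/FP estimates match truth exactly."""
    profile = MethodProfile(name="m", ado_rate=0.3, fp_rate=0.01, site_coverage=0.85)
    calls = simulate_single_cell_calls(small_control, profile, seed=8)
    est = ado_fp_counts(calls, small_control)
    truth = calls.truth_labels["label"].value_counts()
    assert est["ado"] == truth.get("ADO", 0)
    assert est["fp"] == truth.get("FP", 0)
    assert est["detected"] == len(calls)


@pytest.mark.parametrize("ado_rate", [0.01, 0.05, 0.334])
@pytest.mark.parametrize("fp_rate", [1e-5, 1e-4, 1e-3])
def test_parameter_recovery_grid(layout, ado_rate, fp_rate):
    """Estimators recover simulated rates within 3 binomial s.e. at n=1e5."""
    n = 100_000
    control = simulate_golden_control(n, (0.5, 0.1, 0.4), layout, seed=17)
    profile = MethodProfile(name="m", ado_rate=ado_rate, fp_rate=fp_rate,
                            site_coverage=0.9)
    calls = simulate_single_cell_calls(control, profile, seed=23)
    est = ado_fp_counts(calls, control)
    labels = calls.truth_labels.merge(control.sites[["chrom", "pos", "category"]],
                                      on=["chrom", "pos"])
    n_het_cov = (
        (labels["category"] == "HETref") & (labels["label"] != "uncovered")
    ).sum()
    est_ado = est["ado"] / n_het_cov
    se_ado = np.sqrt(ado_rate * (1 - ado_rate) / n_het_cov)
    assert abs(est_ado - ado_rate) <= 3 * se_ado
    n_fp_trials = (labels["label"] != "uncovered").sum() - est["ado"]
    est_fp = est["fp"] / n_fp_trials
    se_fp = np.sqrt(fp_rate * (1 - fp_rate) / n_fp_trials)
    assert abs(est_fp - fp_rate) <= 3 * se_fp


def test_binned_counts_poisson_limit(layout):
    bins = make_bins(layout, 2000)
    truth = CNVTruthProfile(pd.DataFrame(columns=["chrom", "start", "end",
                                                  "copy_number"]))
    profile = MethodProfile(name="m", bin_dispersion=1e-9)
    counts = simulate_binned_counts(bins, truth, profile, 50.0, seed=3)
    c = counts.counts
    assert abs(c.mean() - 50.0) < 3 * np.sqrt(50.0 / len(c))
    # index of dispersion ~ 1 for plain Poisson
    assert 0.9 < c.var() / c.mean() < 1.1


def test_binned_counts_dispersion_monotonicity(layout):
    bins = make_bins(layout, 10_000)
    truth = CNVTruthProfile(pd.DataFrame(columns=["chrom", "start", "end",
                                                  "copy_number"]))
    lo = simulate_binned_counts(bins, truth,
                                MethodProfile(name="l", bin_dispersion=0.1),
                                50.0, seed=4)
    hi = simulate_binned_counts(bins, truth,
                                MethodProfile(name="h", bin_dispersion=0.8),
                                50.0, seed=4)
    assert hi.counts.var() > lo.counts.var()


def test_binned_counts_embedded_gain_doubles_mean(layout):
    bins = make_bins(layout, 2000)
    # N=4 region spanning 100 bins of chr1 (bin width 50 Mb / ... use coords)
    widths = bins.widths
    region_end = int(bins.bins.loc[99, "end"])
    truth = CNVTruthProfile(pd.DataFrame(
        [("chr1", 0, region_end, 4)],
        columns=["chrom", "start", "end", "copy_number"],
    ))
    profile = MethodProfile(name="m", bin_dispersion=1e-9)
    counts = simulate_binned_counts(bins, truth, profile, 100.0, seed=5)
    inside = counts.counts[:100].mean()
    outside = counts.counts[200:].mean()
    se = np.sqrt(200.0 / 100)
    assert abs(inside - 2 * outside) <= 3 * (se + np.sqrt(100.0 / len(counts)))


def test_breakpoints_no_chimeras_all_matchable(layout, quiet_profile):
    rng = np.random.default_rng(12)
    true_bps = [
        Breakpoint("ITX", "chr1", int(p), "chr1", int(p) + 2_000_000)
        for p in rng.integers(1, 40_000_000, 50)
    ]
    control, sc, labels = simulate_breakpoints(true_bps, quiet_profile, layout, seed=13)
    assert control == true_bps
    assert len(sc) == len(true_bps)
    assert (labels == "true").all()
    assert (match_breakpoints(sc, control) == "true").all()


def test_breakpoint_type_mix_recovery(layout):
    mix = normalize_mix({"ITX": 0.8208, "CTX": 0.0113, "DEL": 0.0809,
                         "INS": 0.0507, "INV": 0.0368})
    profile = MethodProfile(name="m", chimera_rate=100.0, chimera_type_mix=mix)
    true_bps = [Breakpoint("ITX", "chr1", 1_000_000, "chr1", 9_000_000)] * 100
    _, sc, labels = simulate_breakpoints(true_bps, profile, layout, seed=14)
    injected = [bp for bp, lab in zip(sc, labels) if lab == "chimera"]
    n = len(injected)
    assert n > 5_000
    for btype, p in mix.items():
        frac = sum(bp.type == btype for bp in injected) / n
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 3 * sd


def test_injected_itx_shorter_than_true(layout):
    from scwga import itx_length_compare

    rng = np.random.default_rng(15)
    true_bps = [
        Breakpoint("ITX", "chr1", int(p), "chr1",
                   int(p) + int(rng.integers(1_000_000, 5_000_000)))
        for p in rng.integers(1, 40_000_000, 200)
    ]
    profile = MethodProfile(name="m", chimera_rate=1.0,
                            chimera_itx_length_scale=5_000.0)
    _, sc, labels = simulate_breakpoints(true_bps, profile, layout, seed=16)
    true_spans = [bp.span for bp, lab in zip(sc, labels)
                  if lab == "true" and bp.type == "ITX"]
    chim_spans = [bp.span for bp, lab in zip(sc, labels)
                  if lab == "chimera" and bp.chromA == bp.chromB][:200]
    out = itx_length_compare(true_spans[:200], chim_spans, alternative="greater")
    assert out["result"].p_value < 0.01
    assert out["median_chimera"] < out["median_true"]


def test_simulation_determinism(small_control):
    profile = MethodProfile(name="m", ado_rate=0.2, fp_rate=0.01, site_coverage=0.8)
    a = simulate_single_cell_calls(small_control, profile, seed=21)
    b = simulate_single_cell_calls(small_control, profile, seed=21)
    pd.testing.assert_frame_equal(a.calls, b.calls)
    pd.testing.assert_frame_equal(a.truth_labels, b.truth_labels)
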