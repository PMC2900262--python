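"""MFI pipeline: medians, background QC, spike normalization, error propagation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beadquant import quantify, simassay, workflow
from beadquant.quantify import (
    background_correct,
    compute_mfi,
    specificity_score,
    spike_normalize,
    summarize_expression,
)


def _events(well, region, values):
    return pd.DataFrame(
        {
            "well": well,
            "region": region,
            "event": np.arange(1, len(values) + 1),
            "fluorescence": values,
        }
    )


def test_compute_mfi_median_and_order_invariance():
    ev = _events("A1", 1, [1.0, 2.0, 3.0, 4.0, 5.0])
    out = compute_mfi(ev, min_events=5)
    assert out["mfi"].iloc[0] == 3.0 and out["qc"].iloc[0] == ""
    shuffled = ev.sample(frac=1, random_state=0)
    pd.testing.assert_frame_equal(compute_mfi(shuffled, min_events=5), out)


def test_compute_mfi_constant_events():
    out = compute_mfi(_events("A1", 1, [7.5] * 100))
    assert out["mfi"].iloc[0] == 7.5


def test_low_event_count_flagged_and_excluded():
    ev = pd.concat(
        [_events("A1", 1, [5.0] * 99), _events("A2", 1, [5.0] * 100), _events("B1", 1, [4.0] * 100)]
    )
    layout = pd.DataFrame(
        {
            "well": ["A1", "A2", "B1"],
            "sample_id": ["s", "s", "BACKGROUND"],
            "role": ["test", "test", "background"],
            "replicate": [1, 2, 1],
        }
    )
    mfis = compute_mfi(ev, min_events=100)
    assert mfis.set_index("well").loc["A1", "qc"] == "low_count"
    corrected, _ = background_correct(mfis, layout)
    assert set(corrected.loc[corrected["qc"] == "", "well"]) == {"A2"}


def test_background_subtraction_rule():
    ev = pd.concat(
        [_events("A1", 1, [500.0] * 100)]
        + [_events(w, 1, [v] * 100) for w, v in [("G1", 30.0), ("G2", 34.0), ("G3", 32.0)]]
    )
    layout = pd.DataFrame(
        {
            "well": ["A1", "G1", "G2", "G3"],
            "sample_id": ["s", "B", "B", "B"],
            "role": ["test"] + ["background"] * 3,
            "replicate": [1, 1, 2, 3],
        }
    )
    corrected, model = background_correct(compute_mfi(ev), layout)
    assert model.mean(1) == 32.0
    assert corrected["net"].iloc[0] == 468.0


def test_reading_below_background_marked_not_dropped():
    ev = pd.concat(
        [_events("A1", 1, [25.0] * 100), _events("G1", 1, [32.0] * 100)]
    )
    layout = pd.DataFrame(
        {
            "well": ["A1", "G1"],
            "sample_id": ["s", "B"],
            "role": ["test", "background"],
            "replicate": [1, 1],
        }
    )
    corrected, _ = background_correct(compute_mfi(ev), layout)
    assert corrected["qc"].iloc[0] == "below_background"
    assert len(corrected) == 1  # marked, still present


def test_background_required_per_region():
    ev = _events("A1", 1, [10.0] * 100)
    layout = pd.DataFrame(
        {"well": ["A1"], "sample_id": ["s"], "role": ["test"], "replicate": [1]}
    )
    with pytest.raises(ValueError, match="no background wells"):
        background_correct(compute_mfi(ev), layout)


def test_spike_ratio_and_exclusion():
    corrected = pd.DataFrame(
        {
            "well": ["A1", "A1", "A2", "A2"],
            "sample_id": ["s", "s", "s", "s"],
            "role": ["test"] * 4,
            "replicate": [1, 1, 2, 2],
            "region": [1, 57, 1, 57],
            "mfi": [500.0, 2372.0, 400.0, 32.0],
            "net": [468.0, 2340.0, 368.0, 0.0],
            "qc": ["", "", "", ""],
        }
    )
    with pytest.warns(UserWarning, match="A2"):
        norm = spike_normalize(corrected, spike_region=57)
    assert norm["norm"].tolist() == [pytest.approx(0.2)]
    corrected.loc[:, "net"] = [468.0, 0.0, 368.0, 0.0]
    with pytest.raises(ValueError, match="all wells excluded"):
        with pytest.warns(UserWarning):
            spike_normalize(corrected, spike_region=57)


def _norm_table(sample_to_values, probe="miR-27a"):
    rows = []
    w = 0
    for sample, values in sample_to_values.items():
        role = "reference" if sample == "POOL" else "test"
        for i, v in enumerate(values, 1):
            w += 1
            rows.append((f"A{w}", sample, role, i, 21, v, probe))
    return pd.DataFrame(
        rows, columns=["well", "sample_id", "role", "replicate", "region", "norm", "probe_id"]
    )


def test_summarize_matches_direct_formula_oracle():
    table = _norm_table({"S": [0.2, 0.25, 0.21], "POOL": [0.10, 0.10, 0.12]})
    out = summarize_expression(table, reference_sample="POOL").set_index("sample")
    mean_s, sd_s = np.mean([0.2, 0.25, 0.21]), np.std([0.2, 0.25, 0.21], ddof=1)
    mean_r, sd_r = np.mean([0.10, 0.10, 0.12]), np.std([0.10, 0.10, 0.12], ddof=1)
    ratio = mean_s / mean_r
    rel = math.sqrt((sd_s / mean_s) ** 2 + (sd_r / mean_r) ** 2)
    row = out.loc["S"]
    assert row["log2_ratio"] == pytest.approx(math.log2(ratio), abs=1e-12)
    assert row["log2_ratio"] == pytest.approx(1.044, abs=5e-4)
    assert row["log2_sd"] == pytest.approx(rel / math.log(2), abs=1e-12)
    assert rel == pytest.approx(0.1618, abs=2e-4)
    half = stats.t.ppf(0.975, 2) * sd_s / math.sqrt(3)
    assert row["ci95_low"] == pytest.approx(mean_s - half, abs=1e-12)
    assert row["ci95_high"] == pytest.approx(mean_s + half, abs=1e-12)
    assert row["ci95_low"] < row["norm_mfi_mean"] < row["ci95_high"]


def test_reference_vs_itself_log2_zero():
    table = _norm_table({"POOL": [0.11, 0.12, 0.10], "S": [0.2, 0.3, 0.25]})
    out = summarize_expression(table, reference_sample="POOL").set_index("sample")
    assert out.loc["POOL", "log2_ratio"] == 0.0


def test_reference_zero_sd_degenerate_quadrature():
    table = _norm_table({"S": [0.2, 0.25, 0.21], "POOL": [0.1, 0.1, 0.1]})
    out = summarize_expression(table, reference_sample="POOL").set_index("sample")
    sd_s = np.std([0.2, 0.25, 0.21], ddof=1)
    rel_s = sd_s / np.mean([0.2, 0.25, 0.21])
    assert out.loc["S", "log2_sd"] == pytest.approx(rel_s / math.log(2), abs=1e-15)


def test_single_well_sample_reported_without_sd():
    table = _norm_table({"S": [0.2], "POOL": [0.1, 0.1, 0.12]})
    out = summarize_expression(table, reference_sample="POOL").set_index("sample")
    assert math.isnan(out.loc["S", "log2_sd"]) and math.isnan(out.loc["S", "ci95_low"])
    assert out.loc["S", "log2_ratio"] == pytest.approx(math.log2(0.2 / np.mean([0.1, 0.1, 0.12])))


def test_reference_needs_two_wells():
    table = _norm_table({"S": [0.2, 0.25], "POOL": [0.1]})
    with pytest.raises(ValueError, match="reference sample"):
        summarize_expression(table, reference_sample="POOL")


def test_specificity_score_arithmetic_and_welch_oracle():
    norm = pd.DataFrame(
        {
            "well": list("ABCDEF"),
            "sample_id": "s",
            "role": "test",
            "replicate": [1, 2, 3, 1, 2, 3],
            "region": [21] * 3 + [51] * 3,
            "norm": [1000.0, 1000.0, 1000.0, 380.0, 380.0, 380.0],
            "probe_id": ["PM"] * 3 + ["MM"] * 3,
        }
    )
    out = specificity_score(norm, "PM", ["MM"])
    assert out["pct_of_pm"].iloc[0] == pytest.approx(38.0)
    assert out["drop_pct"].iloc[0] == pytest.approx(62.0)

    # Welch statistic against the textbook formula on {5,6,7} vs {1,2,3}
    mm, pm = np.array([1.0, 2.0, 3.0]), np.array([5.0, 6.0, 7.0])
    res = stats.ttest_ind(mm, pm, equal_var=False, alternative="less")
    se = math.sqrt(mm.var(ddof=1) / 3 + pm.var(ddof=1) / 3)
    t_direct = (mm.mean() - pm.mean()) / se
    assert res.statistic == pytest.approx(t_direct, abs=1e-12)
    df_direct = se**4 / (
        (mm.var(ddof=1) / 3) ** 2 / 2 + (pm.var(ddof=1) / 3) ** 2 / 2
    )
    assert res.df == pytest.approx(df_direct, abs=1e-12)
    norm2 = norm.assign(norm=[5.0, 6.0, 7.0, 1.0, 2.0, 3.0])
    out2 = specificity_score(norm2, "PM", ["MM"])
    assert out2["p_value"].iloc[0] == pytest.approx(stats.t.cdf(t_direct, df_direct), abs=1e-12)


def test_specificity_identical_probes():
    norm = _norm_table({"s": [1.0, 1.0, 1.1]})
    norm2 = norm.assign(probe_id="MM")
    both = pd.concat([norm, norm2], ignore_index=True)
    out = specificity_score(both, "miR-27a", ["MM"])
    assert out["pct_of_pm"].iloc[0] == pytest.approx(100.0)
    assert 0.4 <= out["p_value"].iloc[0] <= 1.0


def test_gain_invariance_of_normalized_pipeline(quiet_config):
    """A global multiplicative gain on all fluorescence in a well cancels."""
    plate = simassay.simulate_expression(quiet_config)
    spike_region = plate.truth["spike_region"]

    def normalized(events):
        mfis = compute_mfi(events)
        corrected, _ = background_correct(mfis, plate.layout)
        return spike_normalize(corrected, spike_region)["norm"].to_numpy()

    base = normalized(plate.events)
    scaled_events = plate.events.assign(fluorescence=plate.events["fluorescence"] * 3.0)
    scaled = normalized(scaled_events)
    np.testing.assert_allclose(scaled, base, rtol=1e-9)


def test_end_to_end_zero_noise_recovers_latent_ratios(quiet_config, panel):
    expr = workflow.expression_analysis(quiet_config, panel).set_index(["sample", "mirna"])
    for (s, m), row in expr.iterrows():
        true = math.log2(panel.latent_abundance[(s, m)] / panel.latent_abundance[("POOL", m)])
        assert row["log2_ratio"] == pytest.approx(true, abs=1e-9)


def test_ci_coverage_of_latent_truth_over_seeds(panel):
    """95% t-intervals on the normalized scale cover the latent truth."""
    covered = total = 0
    for seed in range(200):
        cfg = simassay.AssayConfig(seed=seed)
        expr = workflow.expression_analysis(cfg, panel)
        for _, r in expr.iterrows():
            true = panel.latent_abundance[(r["sample"], r["mirna"])] / cfg.spike_level
            total += 1
            covered += r["ci95_low"] <= true <= r["ci95_high"]
    assert covered / total >= 0.90


def test_pipeline_drop_recovers_configured_efficiency():
    drops = []
    for seed in range(30):
        cfg = simassay.AssayConfig(seed=seed)
        s = workflow.specificity_analysis(cfg, mirna="miR-199a")
        drops.append(s.loc[s["probe_id"] == "miR-199a-2MM", "drop_pct"].iloc[0])
    assert np.mean(drops) == pytest.approx(100 * (1 - 0.15), abs=1.0)
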