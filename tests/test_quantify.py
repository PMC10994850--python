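"""Normalization equations, standard curves, correction factors."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import mobactag as m
from mobactag.quantify import QuantificationError


def table_from_tuples(rows, extra=None):
    """Build a table with one bacterial feature and both spikes per sample."""
    counts = pd.DataFrame(
        rows, columns=["bact_16S", "spike_16S", "plant_ITS", "spike_pITS"]
    )
    counts.index = [f"s{i}" for i in range(len(counts))]
    if extra is not None:
        for col, values in extra.items():
            counts[col] = values
    classes = {
        "bact_16S": "endogenous_16S",
        "spike_16S": "spike_tag",
        "plant_ITS": "plant_ITS",
        "spike_pITS": "spike_tag",
    }
    for col in counts.columns:
        classes.setdefault(col, "barcode_tag")
    return m.CountTable(counts=counts, feature_classes=pd.Series(classes))


@pytest.fixture
def spike():
    return m.SpikeDesign(
        spike_16s_feature="spike_16S",
        spike_plant_feature="spike_pITS",
        secondary_spike_feature="spike2",
    )


def test_spike_design_mass_ratio_default():
    design = m.SpikeDesign(spike_16s_feature="s", sample_mass_ng=6.0, spike_mass_ng=0.001)
    assert design.mass_ratio == 6000
    with pytest.raises(QuantificationError):
        m.SpikeDesign(spike_16s_feature="s", spike_mass_ng=0.0)


def test_normalization_arithmetic_and_ratio_invariance(spike):
    table = table_from_tuples([(6000, 1000, 2000, 200)])
    norm = m.normalize_to_spike(table, spike)
    assert norm.nb.loc["s0", "bact_16S"] == 6.0
    scaled = table_from_tuples([(60000, 10000, 20000, 2000)])
    norm10 = m.normalize_to_spike(scaled, spike)
    assert norm10.nb.loc["s0", "bact_16S"] == 6.0  # depth invariance


def test_zero_spike_sample_flagged_not_zeroed(spike):
    table = table_from_tuples([(500, 0, 100, 10), (500, 100, 100, 10)])
    norm = m.normalize_to_spike(table, spike)
    assert "s0" in norm.flagged
    assert np.isnan(norm.nb.loc["s0", "bact_16S"])
    assert norm.nb.loc["s1", "bact_16S"] == 5.0
    assert norm.valid_samples == ["s1"]


def test_load_worked_example(spike):
    table = table_from_tuples([(500, 100, 2000, 200)])
    load = m.bacteria_to_plant_load(m.normalize_to_spike(table, spike))
    assert load.loc["s0", "bact_16S"] == pytest.approx(0.5, rel=1e-12)
    zero = table_from_tuples([(0, 100, 2000, 200)])
    load0 = m.bacteria_to_plant_load(m.normalize_to_spike(zero, spike))
    assert load0.loc["s0", "bact_16S"] == 0.0


def test_load_errors_when_plant_reads_missing(spike):
    table = table_from_tuples([(500, 100, 0, 200)])
    with pytest.raises(QuantificationError, match="s0"):
        m.bacteria_to_plant_load(m.normalize_to_spike(table, spike))


def test_equation_identities_on_random_tuples(spike):
    # Exact-arithmetic oracle over 1000 random count tuples.
    rng = np.random.default_rng(12)
    tuples = rng.integers(1, 10_000, size=(1000, 4))
    table = table_from_tuples([tuple(row) for row in tuples])
    norm = m.normalize_to_spike(table, spike)
    load = m.bacteria_to_plant_load(norm)
    for i, (rb, rs16, rp, rsp) in enumerate(tuples):
        sample = f"s{i}"
        nb_exact = Fraction(int(rb), int(rs16))
        np_exact = Fraction(int(rp), int(rsp))
        load_exact = Fraction(int(rb) * int(rsp), int(rp) * int(rs16))
        assert abs(norm.nb.loc[sample, "bact_16S"] - float(nb_exact)) <= 1e-12 * float(nb_exact)
        assert abs(norm.np_[sample] - float(np_exact)) <= 1e-12 * float(np_exact)
        assert load_exact == nb_exact / np_exact  # the defining identity, exactly
        assert abs(load.loc[sample, "bact_16S"] - float(load_exact)) <= 1e-12 * float(load_exact)


# -- standard curve -----------------------------------------------------

def dilution_rows(masses, ref_mass=0.15, base=100_000, noise=None):
    rows = []
    for i, mass in enumerate(masses):
        rs2 = base * mass / ref_mass
        if noise is not None:
            rs2 *= noise[i]
        rows.append(pd.Series({"spike_16S": float(base), "spike2": round(rs2)}))
    return list(zip(masses, rows))


def test_tenfold_series_spans_four_orders(spike):
    masses = [1.5, 0.15, 0.015, 0.0015, 0.00015]
    fit = m.fit_standard_curve(dilution_rows(masses), spike)
    assert fit.dynamic_range == pytest.approx(4.0)
    assert len(fit.points) == 5


def test_perfectly_proportional_counts_give_unit_slope(spike):
    masses = [1.5, 0.15, 0.015, 0.0015, 0.00015]
    fit = m.fit_standard_curve(dilution_rows(masses), spike)
    assert fit.slope == pytest.approx(1.0, abs=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_lognormal_noise_keeps_slope_near_unity(spike):
    rng = np.random.default_rng(3)
    masses = [1.5, 0.15, 0.015, 0.0015, 0.00015]
    noise = np.exp(rng.normal(0, 0.1, size=5))
    fit = m.fit_standard_curve(dilution_rows(masses, noise=noise), spike)
    assert abs(fit.slope - 1.0) < 0.15
    assert fit.r_squared > 0.95


def test_zero_count_points_dropped_then_error(spike):
    masses = [1.5, 0.15, 0.015, 0.0015]
    samples = dilution_rows(masses)
    samples[-1][1]["spike2"] = 0
    with pytest.warns(UserWarning, match="zero spike reads"):
        fit = m.fit_standard_curve(samples, spike)
    assert len(fit.points) == 3 and fit.n_dropped == 1
    for _, row in samples[1:]:
        row["spike2"] = 0
    with pytest.raises(QuantificationError, match="usable dilution points"):
        with pytest.warns(UserWarning):
            m.fit_standard_curve(samples, spike)
    with pytest.raises(QuantificationError, match="3 distinct masses"):
        m.fit_standard_curve(samples[:2], spike)


# -- correction factors -------------------------------------------------

def test_tag119_ratio_recovered_from_embodying_counts():
    cf = m.estimate_correction_factor(
        {"tag119": [(350, 100), (700, 200), (1750, 500)]}, seed=0
    )
    assert cf["tag119"].factor == pytest.approx(3.5, rel=1e-12)
    assert cf["tag119"].ci_low <= 3.5 <= cf["tag119"].ci_high


def test_identity_pairs_give_unit_factor():
    cf = m.estimate_correction_factor({"t": [(7.0, 7.0)] * 4}, seed=0)
    assert cf["t"].factor == pytest.approx(1.0)


def test_estimator_input_errors():
    with pytest.raises(QuantificationError, match=">= 2 calibration"):
        m.estimate_correction_factor({"t": [(1.0, 1.0)]}, seed=0)
    with pytest.raises(QuantificationError, match="positive"):
        m.estimate_correction_factor({"t": [(1.0, 0.0), (1.0, 1.0)]}, seed=0)
    with pytest.raises(QuantificationError, match="all tag reads are zero"):
        m.estimate_correction_factor({"t": [(0.0, 10.0), (0.0, 20.0)]}, seed=0)


@pytest.mark.parametrize("bias", [1.4, 1.5, 1.6, 1.8, 1.9, 3.5])
def test_calibration_recovery_within_two_percent(bias):
    pairs = m.generate_calibration_pairs(bias, 16, mean_16s=1000.0, seed=97)
    cf = m.estimate_correction_factor({"t": pairs}, seed=1, n_bootstrap=200)
    assert abs(cf["t"].factor - bias) / bias < 0.02


def test_bootstrap_ci_coverage_of_true_ratio():
    # Coverage oracle: the 95% CI should contain the truth in >= 93 of 100
    # independent Poisson replications at n = 16.
    true_ratio, hits = 1.6, 0
    for rep in range(100):
        pairs = m.generate_calibration_pairs(true_ratio, 16, seed=1000 + rep)
        cf = m.estimate_correction_factor({"t": pairs}, seed=rep, n_bootstrap=1000)
        if cf["t"].ci_low <= true_ratio <= cf["t"].ci_high:
            hits += 1
    assert hits >= 93


def test_ratio_mean_estimator_agrees_on_constant_ratio():
    pairs = [(35.0, 10.0), (70.0, 20.0), (7.0, 2.0)]
    slope = m.estimate_correction_factor({"t": pairs}, seed=0)["t"].factor
    mean = m.estimate_correction_factor({"t": pairs}, method="ratio_mean", seed=0)["t"].factor
    assert slope == pytest.approx(3.5) and mean == pytest.approx(3.5)


def test_apply_correction_divides_tags_only(spike):
    table = table_from_tuples([(1000, 100, 500, 50)], extra={"tag119": [350]})
    cf = m.estimate_correction_factor(
        {"tag119": [(350, 100), (700, 200), (1750, 500)]}, seed=0
    )
    corrected = m.apply_correction(table, cf)
    assert corrected.counts.loc["s0", "tag119"] == pytest.approx(100.0)
    assert corrected.counts.loc["s0", "bact_16S"] == 1000
    unit = m.CorrectionFactorSet(
        {"tag119": m.CorrectionFactor(1.0, 0.9, 1.1, 3, "slope")}
    )
    assert m.apply_correction(table, unit).counts.loc["s0", "tag119"] == 350
    with pytest.raises(QuantificationError, match="tag119"):
        m.apply_correction(table, m.CorrectionFactorSet({}))


# -- abundance summary --------------------------------------------------

def test_single_feature_relative_abundance_is_one(spike):
    table = table_from_tuples([(800, 100, 500, 50)])
    report = m.summarize_abundance(table, spike)
    rel = report.query("view == 'relative'")
    assert rel.value.tolist() == [1.0]


def test_doubling_counts_doubles_nb_not_relative(spike):
    base = table_from_tuples([(800, 100, 500, 50)], extra={"tag119": [200]})
    cf = m.CorrectionFactorSet({"tag119": m.CorrectionFactor(2.0, 1.9, 2.1, 3, "slope")})
    doubled = table_from_tuples([(1600, 100, 500, 50)], extra={"tag119": [400]})
    r1 = m.summarize_abundance(base, spike, cf).set_index(["feature_id", "view"]).value
    r2 = m.summarize_abundance(doubled, spike, cf).set_index(["feature_id", "view"]).value
    assert r2[("bact_16S", "spike_normalized")] == 2 * r1[("bact_16S", "spike_normalized")]
    assert r2[("bact_16S", "relative")] == pytest.approx(r1[("bact_16S", "relative")])
    # Relative abundances sum to 1 over bacterial features.
    total = m.summarize_abundance(base, spike, cf).query("view == 'relative'").value.sum()
    assert total == pytest.approx(1.0, abs=1e-9)


def test_compositionality_demonstration_relative_view_misleads(spike):
    """Halved total load with shifted composition: the relative view shows a
    strain increasing while the spike-normalized view shows every strain
    decreasing."""
    strains = {
        "baseline": [("R1310_16S", 0.2), ("R61_16S", 0.5), ("other_16S", 0.3)],
        "perturbed": [("R1310_16S", 0.3), ("R61_16S", 0.3), ("other_16S", 0.4)],
    }
    tables = {}
    for name, comp in strains.items():
        # Total bacterial load relative to the fixed spike: halved in `perturbed`.
        scale = 3000 if name == "baseline" else 1500
        counts = {fid: [round(scale * ab)] for fid, ab in comp}
        counts.update({"spike_16S": [1000], "plant_ITS": [2000], "spike_pITS": [400]})
        frame = pd.DataFrame(counts, index=["s0"])
        classes = {fid: "endogenous_16S" for fid, _ in comp}
        classes.update(
            {"spike_16S": "spike_tag", "plant_ITS": "plant_ITS", "spike_pITS": "spike_tag"}
        )
        tables[name] = m.CountTable(counts=frame, feature_classes=pd.Series(classes))
    reports = {
        name: m.summarize_abundance(t, spike).set_index(["feature_id", "view"]).value
        for name, t in tables.items()
    }
    rel_up = (
        reports["perturbed"][("R1310_16S", "relative")]
        > reports["baseline"][("R1310_16S", "relative")]
    )
    assert rel_up  # the compositional view suggests R1310 increased
    for fid in ("R1310_16S", "R61_16S", "other_16S"):
        assert (
            reports["perturbed"][(fid, "spike_normalized")]
            < reports["baseline"][(fid, "spike_normalized")]
        )
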