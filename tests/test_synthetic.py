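import numpy as np
import pandas as pd
import pytest

import cordmeth as cm
from cordmeth.synthetic import SimulationConfig


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SimulationConfig(n_pce=0)
    with pytest.raises(ValueError):
        SimulationConfig(ga_range_weeks=(41.0, 37.0))
    with pytest.raises(ValueError):
        SimulationConfig(noise_sd=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(cell_shift=(0.1, -0.1))  # wrong length for 5 cell types


def test_toy_clock_construction_and_determinism():
    clock = cm.make_toy_clock(1, intercept_weeks=30.0, coef_scale=10.0, seed=5)
    assert clock.intercept == 30.0
    assert len(clock.coefficients) == 1
    a = cm.make_toy_clock(50, seed=7)
    b = cm.make_toy_clock(50, seed=7)
    pd.testing.assert_series_equal(a.coefficients, b.coefficients)
    assert (a.coefficients != 0).all()
    assert not a.coefficients.index.has_duplicates
    with pytest.raises(ValueError):
        cm.make_toy_clock(0)


def test_toy_clock_noiseless_inversion():
    """Betas solved from a known GA predict that GA exactly."""
    config = SimulationConfig(
        n_clock_probes=50, noise_sd=0.0, deceleration_delta_weeks=0.0, seed=7
    )
    clock = cm.make_toy_clock(50, intercept_weeks=38.0, coef_scale=5.0, seed=7)
    reference = cm.make_cell_reference(5, 50, seed=7)
    beta, cohort, _, _, truth = cm.simulate_cohort(
        dataclasses_replace(config, n_background_probes=50), clock, reference, {}
    )
    dnam, _ = cm.predict_dnam_age(beta, clock)
    np.testing.assert_allclose(dnam, truth.true_ga, atol=1e-10)


def dataclasses_replace(config, **kw):
    import dataclasses

    return dataclasses.replace(config, **kw)


def test_cell_reference_noiseless_round_trip():
    reference = cm.make_cell_reference(2, 10, separation=0.4, seed=1)
    S = reference.signature.to_numpy()
    beta = pd.DataFrame({"s": 0.3 * S[0] + 0.7 * S[1]}, index=reference.probe_ids)
    comp = cm.estimate_composition(beta, reference)
    np.testing.assert_allclose(
        comp.iloc[0, :2].to_numpy(), [0.3, 0.7], atol=1e-10
    )


def test_same_seed_bit_identical_cohorts():
    def build():
        config = SimulationConfig(seed=13)
        clock = cm.make_toy_clock(config.n_clock_probes, seed=13)
        reference = cm.make_cell_reference(5, config.n_background_probes, seed=13)
        es = cm.default_es_models(seed=13)
        return cm.simulate_cohort(config, clock, reference, es)

    first, second = build(), build()
    pd.testing.assert_frame_equal(first[0], second[0])
    pd.testing.assert_frame_equal(first[1], second[1])
    pd.testing.assert_frame_equal(first[2], second[2])
    pd.testing.assert_frame_equal(first[3], second[3])
    pd.testing.assert_series_equal(first[4].true_ga, second[4].true_ga)


def test_true_cell_fractions_on_simplex(noisy_cohort):
    fracs = noisy_cohort["truth"].true_cell_fractions
    assert (fracs.to_numpy() >= 0).all()
    np.testing.assert_allclose(fracs.sum(axis=1), 1.0, atol=1e-12)


def test_planted_deceleration_exact_when_noiseless(noiseless_cohort):
    dnam, _ = cm.predict_dnam_age(noiseless_cohort["beta"], noiseless_cohort["clock"])
    gap = dnam - noiseless_cohort["truth"].true_ga
    pce = noiseless_cohort["cohort"]["group"] == "PCE"
    np.testing.assert_allclose(gap[pce.to_numpy()], -2.0, atol=1e-10)
    np.testing.assert_allclose(gap[(~pce).to_numpy()], 0.0, atol=1e-10)


def test_es_probe_shift_carries_stated_direction(noiseless_cohort):
    beta = noiseless_cohort["beta"]
    cohort = noiseless_cohort["cohort"]
    model = noiseless_cohort["es_models"]["diabetes"]
    pce = (cohort["group"] == "PCE").to_numpy()
    shift = noiseless_cohort["config"].phenotype_shift("diabetes")
    sub = beta.loc[model.probes.index]
    diff = sub.loc[:, pce].mean(axis=1) - sub.loc[:, ~pce].mean(axis=1)
    sign = np.where(model.probes["direction"] == "hyper", 1.0, -1.0)
    np.testing.assert_allclose(diff, sign * shift, atol=1e-10)


def test_unshifted_phenotypes_have_no_group_difference(noiseless_cohort):
    beta = noiseless_cohort["beta"]
    pce = (noiseless_cohort["cohort"]["group"] == "PCE").to_numpy()
    model = noiseless_cohort["es_models"]["obesity"]
    sub = beta.loc[model.probes.index]
    diff = sub.loc[:, pce].mean(axis=1) - sub.loc[:, ~pce].mean(axis=1)
    np.testing.assert_allclose(diff, 0.0, atol=1e-10)


def test_bdnf_linear_in_planted_acceleration(noiseless_cohort):
    cohort = noiseless_cohort["cohort"]
    config = noiseless_cohort["config"]
    pce = cohort["group"] == "PCE"
    intercept, slope, _ = noiseless_cohort["truth"].true_bdnf_params
    planted = config.deceleration_delta_weeks
    # noise_sd applies to betas only; BDNF keeps its own sd, so test group means
    expected_gap = slope * planted
    observed_gap = cohort.loc[pce.to_numpy(), "bdnf_ng_ml"].mean() - \
        cohort.loc[(~pce).to_numpy(), "bdnf_ng_ml"].mean()
    assert observed_gap == pytest.approx(expected_gap, abs=1.5)
    assert slope < 0


def test_probe_collision_rejected():
    config = SimulationConfig(seed=1)
    clock = cm.make_toy_clock(config.n_clock_probes, seed=1)
    reference = cm.make_cell_reference(5, config.n_background_probes, seed=1)
    colliding = cm.ESModel(
        phenotype="bad",
        probes=pd.DataFrame(
            {"coefficient": [0.1], "direction": ["hyper"]},
            index=[clock.probe_ids[0]],
        ),
    )
    with pytest.raises(ValueError, match="collision"):
        cm.simulate_cohort(config, clock, reference, {"bad": colliding})


def test_qc_decoys_are_flagged_and_fail_detection(noisy_cohort):
    annot = noisy_cohort["annotation"]
    detp = noisy_cohort["detection_p"]
    config = noisy_cohort["config"]
    assert annot["chromosome"].isin(["X", "Y"]).sum() == config.n_flagged_sex
    assert annot["snp_proximal"].sum() == config.n_flagged_snp
    assert annot["cross_reactive"].sum() == config.n_flagged_cross
    assert (detp.to_numpy() >= 0.05).sum() == config.n_detection_failures
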