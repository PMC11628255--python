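"""Synthetic plate and experiment generator: determinism, calibration,
artefact injection, scenario presets, end-to-end round trip."""

import numpy as np
import pytest

from lumiqc import (
    ArtifactSpec,
    AssayConfig,
    LL4Params,
    SimulationSpec,
    TrueResponse,
    available_scenarios,
    closed_form_sb,
    closed_form_zprime,
    control_stats,
    fit_ll4,
    join_plate,
    ll4,
    normalize,
    qc_plate,
    scenario_library,
    simulate_experiment,
    simulate_plate,
    zprime,
)
from lumiqc.errors import InvalidRange, LayoutOverflow, UnknownScenario
from lumiqc.simulate import ASSAY_QUALITY, build_platemap


def basic_spec(seed=0, **kw):
    defaults = dict(assay=AssayConfig(), mu_n=100.0, sd_n=5.0, mu_p=10.0, sd_p=1.0, seed=seed)
    defaults.update(kw)
    return SimulationSpec(**defaults)


AG = TrueResponse("Ag", LL4Params(1, 0, 100, 0.24))


class TestSimulatePlate:
    def test_same_seed_is_bit_identical(self):
        spec = basic_spec(seed=42)
        p1, _ = simulate_plate(spec, [AG], [1.0], plate_id="X")
        p2, _ = simulate_plate(spec, [AG], [1.0], plate_id="X")
        assert p1.wells == p2.wells

    def test_different_plate_ids_differ(self):
        spec = basic_spec(seed=42)
        p1, _ = simulate_plate(spec, [AG], [1.0], plate_id="X")
        p2, _ = simulate_plate(spec, [AG], [1.0], plate_id="Y")
        assert p1.wells != p2.wells

    def test_negative_control_mean_near_truth(self):
        """Mean of 16 wells at mu=100, sd=5 stays within 3 standard errors."""
        spec = basic_spec(seed=7)
        misses = 0
        for s in range(50):
            spec.seed = s
            plate, pm = simulate_plate(spec, [AG], [1.0], plate_id="N")
            neg = [plate.wells[a] for a in pm.wells_with_kind("negative_control")]
            if abs(np.mean(neg) - 100.0) > 3 * 5.0 / np.sqrt(16):
                misses += 1
        assert misses <= 2  # ~0.3% expected miss rate per seed

    def test_empirical_zprime_matches_closed_form(self):
        spec = basic_spec(sd_n=4.0, sd_p=2.0)  # closed form Z' = 0.8
        assert closed_form_zprime(spec) == pytest.approx(0.8)
        zs = []
        for s in range(60):
            spec.seed = s
            plate, pm = simulate_plate(spec, [AG], [1.0], plate_id="Z")
            wells = join_plate(plate, pm)
            zs.append(zprime(control_stats(wells)))
        assert abs(np.median(zs) - 0.8) < 0.1

    def test_noiseless_sample_wells_follow_truth(self):
        spec = basic_spec(noise_cv=0.0)
        plate, pm = simulate_plate(spec, [AG], [0.24], plate_id="S")
        sample_wells = [a for a, r in pm.entries.items() if r.kind == "sample"]
        expect = 10.0 + 0.5 * (100.0 - 10.0)  # inflection: half the window
        for a in sample_wells:
            assert plate.wells[a] == pytest.approx(expect)

    def test_layout_overflow(self):
        with pytest.raises(LayoutOverflow):
            build_platemap([AG], list(range(1, 200)), n_rep=3)

    def test_injected_outliers_recovered_by_qc(self):
        spec = basic_spec(sd_n=3.0, sd_p=0.5)
        art = ArtifactSpec(outlier_count=2, outlier_multiplier=0.05,
                           outlier_role="negative_control")
        spec.seed = 5
        plate, pm = simulate_plate(spec, [AG], [1.0], artifacts=art, plate_id="O")
        qc = qc_plate(join_plate(plate, pm), spec.assay)
        assert qc.status == "PASS_AFTER_REMOVAL"
        assert len(qc.outliers_removed) == 2


class TestSimulateExperiment:
    def test_noiseless_limit_is_exact(self):
        data = simulate_experiment(AG, 11, 3, (0.001, 100.0), noise_cv=0.0, seed=0)
        np.testing.assert_allclose(data.response, ll4(data.concentration_um, AG.params))

    def test_design_size(self):
        data = simulate_experiment(AG, 11, 3, (0.001, 100.0), noise_cv=10.0, seed=0)
        assert len(data.response) == 33
        assert len(np.unique(data.concentration_um)) == 11

    def test_invalid_range(self):
        with pytest.raises(InvalidRange):
            simulate_experiment(AG, 11, 3, (10.0, 1.0))

    def test_recovery_of_inflection(self):
        es = [
            fit_ll4(simulate_experiment(AG, 11, 3, (0.001, 100.0), 10.0, seed=s)).params.e
            for s in range(30)
        ]
        assert abs(np.median(es) - 0.24) / 0.24 < 0.25


class TestScenarioLibrary:
    @pytest.mark.parametrize("name", sorted(ASSAY_QUALITY))
    def test_presets_reproduce_quality_parameters(self, name):
        spec, truths = scenario_library(name)
        zp, sb = ASSAY_QUALITY[name]
        assert closed_form_zprime(spec) == pytest.approx(zp)
        assert closed_form_sb(spec) == pytest.approx(sb)
        assert len(truths) == 14

    def test_nluc_h_preset_value(self):
        spec, _ = scenario_library("NLuc_H")
        assert closed_form_zprime(spec) == pytest.approx(0.88)

    def test_fluc_sc_preset_value(self):
        spec, _ = scenario_library("FLuc_SC")
        assert closed_form_sb(spec) == pytest.approx(136.0)

    def test_gsh_scenario_collapses_window(self):
        base, _ = scenario_library("FLuc_SC")
        gsh, _ = scenario_library("GSH_2mM_FLuc")
        assert gsh.mu_n - gsh.mu_p < 0.01 * (base.mu_n - base.mu_p)

    def test_unknown_scenario(self):
        with pytest.raises(UnknownScenario):
            scenario_library("XLuc_Q")

    def test_all_listed_scenarios_load(self):
        for name in available_scenarios():
            spec, truths = scenario_library(name)
            assert truths


class TestEndToEnd:
    def test_scenario_to_ic50_round_trip(self):
        """Simulate an FLuc SC screen of one metal and recover its IC50."""
        spec, truths = scenario_library("FLuc_SC")
        ag = next(t for t in truths if t.compound_id == "Ag")
        doses = list(np.geomspace(0.001, 100.0, 11))
        spec.seed = 11
        plate, pm = simulate_plate(spec, [ag], doses, plate_id="E2E")
        wells = join_plate(plate, pm)
        qc = qc_plate(wells, spec.assay)
        assert qc.status in ("PASS", "PASS_AFTER_REMOVAL")
        stats = control_stats(wells[~wells["well"].isin(qc.outliers_removed)])
        norm = normalize(wells, stats)
        samples = norm[norm["role"] == "sample"]
        from lumiqc import DoseResponseData

        data = DoseResponseData(
            "Ag",
            samples["concentration_um"].to_numpy(),
            samples["pct_n_value"].to_numpy(),
        )
        fit = fit_ll4(data)
        assert fit.ic50.kind == "point"
        assert fit.ic50.value_um == pytest.approx(0.24, rel=0.5)
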