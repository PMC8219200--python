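import numpy as np
import pytest

from aerodep.aerosol import APIComponent, PlumeCharacteristics, Product, build_psd
from aerodep.breathing import optimal_profile
from aerodep.cohort import AirwayGeneration
from aerodep.deposition import (
    RegionalTargets,
    SurrogateCalibration,
    calibrate,
    diffusion_probability,
    extrathoracic_fraction,
    generation_deposition_probability,
    impaction_probability,
    sedimentation_probability,
    settling_velocity,
    simulate_patient,
    _cohort_regional_means,
)
from aerodep.errors import NumericError
from aerodep.metrics import product_cp


def _tube(diameter_cm, length_cm, gravity_angle=90.0, branch_angle=0.0, central=False):
    return AirwayGeneration(
        index=5,
        count=1,
        diameter=diameter_cm,
        length=length_cm,
        branch_angle=branch_angle,
        gravity_angle=gravity_angle,
        is_central=central,
    )


def _mc_sedimentation(gen, d_um, flow_l_min, n=100_000, seed=0):
    """Brute-force settling oracle: Poiseuille flow, constant settling velocity.

    Inlet positions are flux-weighted; the axial distance travelled while a
    particle falls from its inlet height to the wall is integrated
    analytically along the vertical chord, so the only error is Monte Carlo.
    """
    rng = np.random.default_rng(seed)
    radius = gen.diameter / 2 * 1e-2
    length = gen.length * 1e-2
    u_mean = (flow_l_min * 1e-3 / 60.0) / (np.pi * radius**2)
    v_s = settling_velocity(d_um)
    s = 1.0 - np.sqrt(1.0 - rng.random(n))
    r = radius * np.sqrt(s)
    phi = rng.random(n) * 2 * np.pi
    x, y0 = r * np.cos(phi), r * np.sin(phi)
    y_wall = -np.sqrt(radius**2 - x**2)
    z = (2 * u_mean / v_s) * (
        (1 - x**2 / radius**2) * (y0 - y_wall) - (y0**3 - y_wall**3) / (3 * radius**2)
    )
    return float((z <= length).mean())


class TestSedimentation:
    @pytest.mark.parametrize(
        "d_um,diameter,length,flow",
        [(3.0, 0.2, 1.0, 9.4e-4), (2.0, 0.1, 0.5, 4e-4), (4.0, 0.3, 2.0, 2e-3)],
    )
    def test_matches_monte_carlo_tube_oracle_within_2pct(self, d_um, diameter, length, flow):
        gen = _tube(diameter, length, gravity_angle=90.0)
        analytic = float(sedimentation_probability(d_um, gen, flow))
        mc = _mc_sedimentation(gen, d_um, flow)
        assert analytic == pytest.approx(mc, rel=0.02)

    def test_vertical_tube_has_no_cross_stream_settling(self):
        gen = _tube(0.2, 1.0, gravity_angle=0.0)
        assert sedimentation_probability(3.0, gen, 9.4e-4) == 0.0

    def test_vanishes_at_high_flow(self):
        gen = _tube(0.2, 1.0)
        assert sedimentation_probability(1.0, gen, 50.0) < 1e-3
        assert diffusion_probability(1.0, gen, 50.0) < 1e-4


class TestImpactionAndCombined:
    def test_vanishing_size_limit(self):
        # slip correction makes the impaction parameter ~linear in d near 0
        gen = _tube(0.3, 1.0, branch_angle=35.0)
        probs = [float(impaction_probability(d, gen, 1.0)) for d in (1.0, 0.1, 0.01, 1e-3)]
        assert probs == sorted(probs, reverse=True)
        assert probs[-1] < 1e-6

    def test_extrathoracic_monotone_in_k_et_and_size(self, products):
        psd = build_psd(1.3, 2.4).truncated(5.0)
        profile = optimal_profile(4.5, 30.0)
        plume = products["BDP/FF"].plume
        lo = extrathoracic_fraction(psd, plume, profile, SurrogateCalibration(k_et=1e-3))
        hi = extrathoracic_fraction(psd, plume, profile, SurrogateCalibration(k_et=2e-3))
        assert 0.0 < lo < hi < 1.0

    def test_combined_probability_monotone_in_size(self):
        gen = _tube(0.3, 1.0, branch_angle=35.0, gravity_angle=60.0, central=True)
        calib = SurrogateCalibration()
        d = np.linspace(0.5, 5.0, 40)
        p = generation_deposition_probability(d, gen, 0.5, calib)
        assert np.all(np.diff(p) >= -1e-12)
        assert np.all((p >= 0) & (p <= 1))

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(NumericError):
            generation_deposition_probability(1.0, _tube(0.3, 1.0), 0.0, SurrogateCalibration())


def _uniform_product(mmad, fpf=0.43, gsd=2.0):
    apis = (
        APIComponent("A", 100.0, 87.0, mmad, gsd, fpf),
        APIComponent("B", 6.0, 5.0, mmad, gsd, fpf),
    )
    plume = PlumeCharacteristics(0.07, 20.0, 21.0, 6.0, 229.4)
    return Product(name=f"X-{mmad}", apis=apis, plume=plume)


class TestSimulatePatient:
    def test_mass_conservation_and_lobar_closure(self, cohort20, trees20, profiles20, products):
        patient, tree, profile = cohort20[0], trees20[0], profiles20[0]
        for res in simulate_patient(patient, tree, products["BDP/FF/GB"], profile,
                                    SurrogateCalibration()):
            assert res.et + res.central + res.peripheral == pytest.approx(
                100.0 * res.dd_over_nominal, abs=1e-9
            )
            assert sum(res.lobar.values()) == pytest.approx(res.intrathoracic, abs=1e-9)
            assert res.basis_dd["et"] + res.basis_dd["intrathoracic"] == pytest.approx(
                100.0, abs=1e-9
            )

    def test_no_fine_fraction_means_no_lung_dose(self, cohort20, trees20, profiles20):
        product = _uniform_product(1.1, fpf=0.0)
        results = simulate_patient(
            cohort20[0], trees20[0], product, profiles20[0], SurrogateCalibration()
        )
        for res in results:
            assert res.intrathoracic == pytest.approx(0.0, abs=1e-12)
            assert res.et == pytest.approx(100.0 * res.dd_over_nominal, abs=1e-9)

    def test_cp_ratio_monotone_in_mmad(self, cohort20, trees20, profiles20, dual_calibration):
        """Smaller MMAD shifts deposition peripherally, lowering C:P."""
        calib = dual_calibration.calibration
        cps = []
        for mmad in (0.8, 1.1, 1.3, 1.6, 2.0):
            results = simulate_patient(
                cohort20[0], trees20[0], _uniform_product(mmad), profiles20[0], calib
            )
            cps.append(product_cp(results))
        assert cps == sorted(cps)


class TestCalibration:
    def test_reference_targets_fit_within_half_point(self, dual_calibration):
        res = dual_calibration
        assert abs(res.residuals["et"]) < 0.5
        assert abs(res.residuals["it"]) < 0.5
        assert abs(res.residuals["cp"]) < 0.005

    def test_constants_nonnegative(self, dual_calibration):
        c = dual_calibration.calibration
        assert c.k_et >= 0 and c.k_plume >= 0 and c.k_central >= 0

    def test_self_consistency_recovers_known_constants(
        self, cohort20, trees20, profiles20, products
    ):
        """Targets produced by the model itself are refit to the same constants."""
        truth = SurrogateCalibration(k_et=2.4e-3, k_plume=2.2, k_central=380.0)
        et, it, cp = _cohort_regional_means(
            cohort20, trees20, products["BDP/FF"], profiles20, truth
        )
        res = calibrate(
            products["BDP/FF"],
            RegionalTargets(et=et, it=it, cp=cp),
            cohort20,
            profiles20,
            trees=trees20,
            initial=truth,
        )
        assert res.calibration.k_et == pytest.approx(truth.k_et, rel=0.01)
        assert res.calibration.k_plume == pytest.approx(truth.k_plume, rel=0.01)
        assert res.calibration.k_central == pytest.approx(truth.k_central, rel=0.01)
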