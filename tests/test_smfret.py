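"""FRET corrections, bleach detection, state/dwell fits, dye clouds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igmhinge.errors import (
    BuriedSiteError,
    NoRecoveryError,
    SamplingError,
)
from igmhinge.model_geometry import AtomicModel
from igmhinge.smfret import (
    AVParams,
    CorrectionFactors,
    DyeCloud,
    FluorescenceTrace,
    accessible_volume,
    detect_bleach_step,
    distance_of_fret,
    dwell_analysis,
    estimate_direct_excitation,
    estimate_donor_bleed,
    estimate_gamma,
    fit_states,
    fret_efficiency,
    fret_of_distance,
    mean_fret_distance,
    recovered_donor,
)
from igmhinge.synthetic_data import (
    FretGroundTruth,
    simulate_fret_traces,
    simulate_reference_traces,
)


def _trace(d, f, a=0.0):
    d = np.asarray(d, float)
    return FluorescenceTrace("m", d, np.asarray(f, float),
                             np.broadcast_to(np.asarray(a, float),
                                             d.shape).copy())


class TestFactorEstimation:
    def test_donor_bleed_zero_and_exact(self):
        d = np.full(50, 200.0)
        assert estimate_donor_bleed([_trace(d, np.zeros(50))]) == 0.0
        assert estimate_donor_bleed([_trace(d, 0.09 * d)]) == pytest.approx(0.09)

    def test_donor_bleed_simulated_recovery(self):
        truth = FretGroundTruth(
            factors=CorrectionFactors(0.12, 0.08, 1.8), seed=9)
        traces = simulate_reference_traces(truth, "donor-only", 50, 3.0)
        assert estimate_donor_bleed(traces) == pytest.approx(0.12, abs=0.01)

    def test_direct_excitation_exact_and_simulated(self):
        a = np.full(50, 150.0)
        assert estimate_direct_excitation(
            [_trace(np.zeros(50), 0.08 * a, a)]) == pytest.approx(0.08)
        truth = FretGroundTruth(
            factors=CorrectionFactors(0.09, 0.10, 1.8), seed=9)
        traces = simulate_reference_traces(truth, "acceptor-only", 50, 3.0)
        assert estimate_direct_excitation(traces) == pytest.approx(0.10,
                                                                   abs=0.01)

    def test_gamma_direct_arithmetic(self):
        f = np.r_[np.full(20, 200.0), np.full(20, 20.0)]
        d = np.r_[np.full(20, 50.0), np.full(20, 150.0)]
        assert estimate_gamma(_trace(d, f), 19) == pytest.approx(
            (200 - 20) / (150 - 50), rel=1e-3)
        assert (200 - 20) / (150 - 50) == pytest.approx(1.8)

    def test_gamma_no_recovery_rejected(self):
        f = np.r_[np.full(20, 200.0), np.full(20, 200.0)]
        d = np.full(40, 100.0)
        with pytest.raises(NoRecoveryError):
            estimate_gamma(_trace(d, f), 19)

    def test_gamma_simulated_recovery(self):
        from igmhinge.smfret import estimate_gamma_pooled

        truth = FretGroundTruth(factors=CorrectionFactors(0.09, 0.08, 2.0),
                                seed=13)
        traces = [s.trace for s in simulate_fret_traces(truth, 100, 10.0)]
        assert estimate_gamma_pooled(traces) == pytest.approx(2.0, abs=0.06)


class TestEfficiency:
    def test_recovered_donor(self):
        assert recovered_donor(100.0, 0.0, 1.8) == 100.0
        assert recovered_donor(100.0, 90.0, 1.8) == pytest.approx(150.0)
        assert recovered_donor(100.0, 50.0, 1.0) == pytest.approx(150.0)

    def test_zero_numerator_gives_zero(self):
        fac = CorrectionFactors(0.09, 0.08, 1.8)
        e, valid = fret_efficiency(100.0 * np.ones(3),
                                   (0.09 * 100 + 0.08 * 50) * np.ones(3),
                                   50.0 * np.ones(3), fac)
        assert valid.all()
        np.testing.assert_allclose(e, 0.0, atol=1e-12)

    def test_donor_dark_limit_is_one(self):
        fac = CorrectionFactors(0.09, 0.08, 1.8)
        e, valid = fret_efficiency(np.zeros(2), np.full(2, 80.0),
                                   np.zeros(2), fac)
        assert valid.all()
        np.testing.assert_allclose(e, 1.0)

    def test_worked_example(self):
        fac = CorrectionFactors(0.09, 0.08, 1.8)
        e, valid = fret_efficiency(np.array([100.0]), np.array([59.0]),
                                   np.array([50.0]), fac)
        assert valid[0]
        assert e[0] == pytest.approx(46.0 / 226.0)
        assert e[0] == pytest.approx(0.2035, abs=5e-4)

    @given(scale=st.floats(min_value=1e-3, max_value=1e4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        fac = CorrectionFactors(0.09, 0.08, 1.8)
        d, f, a = 100.0, 59.0, 50.0
        e1, _ = fret_efficiency(np.array([d]), np.array([f]),
                                np.array([a]), fac)
        e2, _ = fret_efficiency(np.array([d * scale]), np.array([f * scale]),
                                np.array([a * scale]), fac)
        assert e2[0] == pytest.approx(e1[0], rel=1e-9)

    def test_invalid_frames_masked_not_raised(self):
        fac = CorrectionFactors(0.09, 0.08, 1.8)
        e, valid = fret_efficiency(np.array([100.0, 0.0]),
                                   np.array([0.0, 0.0]),
                                   np.array([0.0, 0.0]), fac)
        # frame 0: E < -0.2 bound is fine (E=-0.09/(...)), frame 1: den <= 0
        assert not valid[1]
        assert np.isnan(e[1])


class TestBleachDetection:
    def test_flat_series_none(self):
        rng = np.random.default_rng(0)
        step = detect_bleach_step(100.0 + rng.normal(0, 3, 200))
        assert step.status == "none" and step.index is None

    def test_single_step_located(self):
        rng = np.random.default_rng(1)
        x = np.r_[np.full(57, 100.0), np.zeros(143)] + rng.normal(0, 5, 200)
        step = detect_bleach_step(x)
        assert step.status == "single"
        assert abs(step.index - 57) <= 1

    def test_two_equal_steps_rejected_as_multistep(self):
        rng = np.random.default_rng(2)
        x = np.r_[np.full(60, 100.0), np.full(60, 50.0), np.zeros(60)]
        step = detect_bleach_step(x + rng.normal(0, 2, 180))
        assert step.status == "multi"
        assert step.index is None

    def test_short_series_rejected(self):
        with pytest.raises(SamplingError):
            detect_bleach_step(np.ones(5))


class TestStateFit:
    def test_single_state_selected(self):
        rng = np.random.default_rng(10)
        e = rng.normal(0.6, 0.05, 5000)
        fit = fit_states(e)
        assert fit.k == 1
        assert fit.means[0] == pytest.approx(0.6, abs=0.01)

    def test_balanced_two_state(self):
        rng = np.random.default_rng(11)
        e = np.r_[rng.normal(0.3, 0.05, 2500), rng.normal(0.8, 0.05, 2500)]
        fit = fit_states(e)
        assert fit.k == 2
        assert fit.means[0] == pytest.approx(0.3, abs=0.02)
        assert fit.means[1] == pytest.approx(0.8, abs=0.02)

    def test_minority_state_recovered(self):
        rng = np.random.default_rng(12)
        e = np.r_[rng.normal(0.3, 0.05, 4500), rng.normal(0.8, 0.05, 500)]
        fit = fit_states(e)
        assert fit.k == 2
        assert fit.means[1] == pytest.approx(0.8, abs=0.05)
        assert fit.weights[1] == pytest.approx(0.1, abs=0.03)

    def test_too_few_values(self):
        with pytest.raises(SamplingError):
            fit_states(np.random.default_rng(0).normal(0.5, 0.1, 50))


class TestDwell:
    def _analyzed(self, truth, n=100, dur=10.0):
        from igmhinge.smfret import analyze_traces

        sims = simulate_fret_traces(truth, n, dur)
        traces = [s.trace for s in sims]
        ft = analyze_traces(traces, truth.factors)
        pooled = np.concatenate([t.valid_efficiencies for t in ft])
        return ft, fit_states(pooled[np.isfinite(pooled)], seed=0)

    def test_constant_state_no_transitions(self):
        truth = FretGroundTruth(k12=0.0, k21=0.0, seed=20,
                                donor_bleach_mean_s=1e6,
                                acceptor_bleach_mean_s=1e6)
        ft, fit = self._analyzed(truth, n=30, dur=5.0)
        dw = dwell_analysis(ft, fit)
        # with frozen kinetics each trace stays in one state
        assert dw.transitions_per_s == pytest.approx(0.0, abs=0.05)

    def test_symmetric_rates_recovered(self):
        truth = FretGroundTruth(k12=2.0, k21=2.0, seed=21)
        ft, fit = self._analyzed(truth)
        dw = dwell_analysis(ft, fit)
        assert dw.transitions_per_s == pytest.approx(2.0, abs=0.3)
        assert dw.occupancy[0] == pytest.approx(0.5, abs=0.05)

    def test_asymmetric_occupancy_matches_stationary_distribution(self):
        truth = FretGroundTruth(k12=1.0, k21=3.0, seed=22)
        ft, fit = self._analyzed(truth)
        dw = dwell_analysis(ft, fit)
        # stationary occupancy of the low state = k21 / (k12 + k21)
        assert dw.occupancy[0] == pytest.approx(0.75, abs=0.05)

    def test_one_state_fit_not_applicable(self):
        rng = np.random.default_rng(23)
        fit = fit_states(rng.normal(0.6, 0.05, 1000))
        dw = dwell_analysis([], fit)
        assert not dw.applicable


FREE_RESIDUE = [("A", 1, "CYS", "N", "N", (0.0, 0.0, 0.0)),
                ("A", 1, "CYS", "CA", "C", (1.5, 0.0, 0.0)),
                ("A", 1, "CYS", "C", "C", (2.2, 1.2, 0.0)),
                ("A", 1, "CYS", "CB", "C", (1.5, 0.0, 1.5))]


class TestAccessibleVolume:
    def test_unobstructed_cloud_is_a_ball(self):
        model = AtomicModel.from_atoms(FREE_RESIDUE)
        cloud = accessible_volume(model, "A", 1)
        r = np.linalg.norm(cloud.positions - cloud.attachment, axis=1)
        assert r.max() <= 20.0 + 1e-9
        # centroid at the attachment within the grid pitch
        assert np.linalg.norm(cloud.centroid - cloud.attachment) < 1.0
        # ball volume ~ (4/3) pi L^3 at 1 A pitch
        assert cloud.positions.shape[0] == pytest.approx(4 / 3 * np.pi * 20**3,
                                                         rel=0.01)

    def test_wall_displaces_centroid_away(self):
        wall = [("B", 100 + i, "ALA", "CA", "C", (x, y, -4.0))
                for i, (x, y) in enumerate(
                    (x, y) for x in range(-30, 31, 2) for y in range(-30, 31, 2))]
        model = AtomicModel.from_atoms(FREE_RESIDUE + wall)
        cloud = accessible_volume(model, "A", 1)
        assert cloud.centroid[2] - cloud.attachment[2] > 1.0

    def test_no_position_clashes(self):
        wall = [("B", 100 + i, "ALA", "CA", "C", (x, y, -4.0))
                for i, (x, y) in enumerate(
                    (x, y) for x in range(-30, 31, 2) for y in range(-30, 31, 2))]
        model = AtomicModel.from_atoms(FREE_RESIDUE + wall)
        params = AVParams()
        cloud = accessible_volume(model, "A", 1, params)
        obstacles = model.coords[~((model.chain == "A")
                                   & (model.resnum == 1))]
        from scipy.spatial import cKDTree
        d, _ = cKDTree(obstacles).query(cloud.positions, k=1)
        assert (d > params.dye_radius + params.atom_radius).all()

    def test_buried_site(self):
        # enclose the residue in a tight cage of atoms
        cage = []
        k = 0
        for x in np.arange(-6, 8.0, 2.0):
            for y in np.arange(-6, 8.0, 2.0):
                for z in np.arange(-5, 9.0, 2.0):
                    if np.hypot(np.hypot(x - 1.5, y), z - 1.5) > 3.0:
                        cage.append(("C", 200 + k, "ALA", "CA", "C",
                                     (x, y, z)))
                        k += 1
        model = AtomicModel.from_atoms(FREE_RESIDUE + cage)
        with pytest.raises(BuriedSiteError):
            accessible_volume(model, "A", 1)

    def test_glycine_pseudo_cbeta(self):
        gly = [a for a in FREE_RESIDUE if a[3] != "CB"]
        model = AtomicModel.from_atoms(
            [(c, r, "GLY", n, e, p) for c, r, _, n, e, p in gly])
        cloud = accessible_volume(model, "A", 1)
        assert cloud.positions.shape[0] > 1000


class TestDistancePrediction:
    def test_foerster_closed_forms(self):
        p1 = DyeCloud((0, 0, 0), [(0.0, 0.0, 0.0)], [1.0], AVParams())
        p2 = DyeCloud((51, 0, 0), [(51.0, 0.0, 0.0)], [1.0], AVParams())
        pred = mean_fret_distance(p1, p2, r0=51.0)
        assert pred.efficiency == pytest.approx(0.5)
        assert pred.mean_distance == pytest.approx(51.0)
        assert fret_of_distance(2 * 51.0, 51.0) == pytest.approx(1.0 / 65.0)
        assert fret_of_distance(1e-9, 51.0) == pytest.approx(1.0)

    def test_distance_of_fret_inverts(self):
        for r in (20.0, 51.0, 80.0):
            assert distance_of_fret(float(fret_of_distance(r, 51.0)),
                                    51.0) == pytest.approx(r, rel=1e-9)

    def test_cloud_pair_average_matches_monte_carlo(self):
        rng = np.random.default_rng(30)
        pos1 = rng.normal(0, 6, (1000, 3))
        pos2 = rng.normal(0, 6, (1000, 3)) + np.array([45.0, 0, 0])
        c1 = DyeCloud((0, 0, 0), pos1, np.ones(1000), AVParams())
        c2 = DyeCloud((45, 0, 0), pos2, np.ones(1000), AVParams())
        exact = mean_fret_distance(c1, c2).efficiency
        # independent Monte-Carlo oracle
        i = rng.integers(0, 1000, 200_000)
        j = rng.integers(0, 1000, 200_000)
        mc = float(fret_of_distance(
            np.linalg.norm(pos1[i] - pos2[j], axis=1)).mean())
        assert exact == pytest.approx(mc, abs=0.005)

    def test_symmetry_and_monotonicity(self):
        rng = np.random.default_rng(31)
        pos = rng.normal(0, 4, (500, 3))
        c1 = DyeCloud((0, 0, 0), pos, np.ones(500), AVParams())
        effs = []
        for sep in (30.0, 45.0, 60.0):
            c2 = DyeCloud((sep, 0, 0), pos + np.array([sep, 0, 0]),
                          np.ones(500), AVParams())
            e12 = mean_fret_distance(c1, c2).efficiency
            e21 = mean_fret_distance(c2, c1).efficiency
            assert e12 == pytest.approx(e21, rel=1e-9)
            effs.append(e12)
        assert effs[0] > effs[1] > effs[2]
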