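from dataclasses import replace

import numpy as np
import pytest

from bfprobe.bead_tracker import BeadDetection, BeadTrack
from bfprobe.pipette_tracker import PipetteDetection, PipetteTrack
from bfprobe.probe_model import (
    GENERIC_GEOMETRY,
    ModelDomainError,
    ProbeGeometry,
    compute_deformation,
    compute_force,
    compute_stiffness,
    stiffness_uncertainty,
)

# Arbitrary-precision substitution of the generic parameters (R_p = 1.0 um,
# R_0 = 2.5 um, R_c = 0.75 um, dP = 200 Pa) into the stiffness formula,
# evaluated independently with sympy before this implementation existed.
GENERIC_K_ORACLE = 406.43276531291804  # pN/um
# Same oracle for the first-order relative uncertainty with sigma_R = 0.1 um
# per radius and sigma_P = 5 Pa (analytic partials, not finite differences).
DELTA_K_ORACLE_PCT = 21.540373866938779


def _tracks(bead_xy, anchor_xy):
    """Minimal aligned tracks from raw position arrays."""
    bead = BeadTrack(
        detections=[
            BeadDetection(i, tuple(p), 12.0, 1.0, 1.0, 1.0, "ok")
            for i, p in enumerate(bead_xy)
        ]
    )
    pipette = PipetteTrack(
        detections=[
            PipetteDetection(i, tuple(p), 1.0, "p0", "ok")
            for i, p in enumerate(anchor_xy)
        ]
    )
    return bead, pipette


class TestStiffness:
    def test_generic_parameters_match_arbitrary_precision_oracle(self):
        assert compute_stiffness(GENERIC_GEOMETRY) == pytest.approx(
            GENERIC_K_ORACLE, rel=1e-9
        )

    def test_linear_in_pressure(self):
        k1 = compute_stiffness(GENERIC_GEOMETRY)
        k2 = compute_stiffness(replace(GENERIC_GEOMETRY, dP=400.0))
        assert k2 == pytest.approx(2.0 * k1, rel=1e-12)

    def test_scaling_all_radii_scales_k_linearly(self):
        g = GENERIC_GEOMETRY
        c = 1.7
        scaled = ProbeGeometry(R_p=c * g.R_p, R_c=c * g.R_c, R_0=c * g.R_0, dP=g.dP)
        assert compute_stiffness(scaled) == pytest.approx(
            c * compute_stiffness(g), rel=1e-12
        )

    def test_si_unit_path_is_dimensionally_consistent(self):
        """Radii in metres with the pN/m -> pN/um conversion agree to 1e-9."""
        g = GENERIC_GEOMETRY
        k_um = compute_stiffness(g)
        si = ProbeGeometry(R_p=g.R_p * 1e-6, R_c=g.R_c * 1e-6, R_0=g.R_0 * 1e-6, dP=g.dP)
        # R_p*dP in m*Pa = 1e12 pN/m = 1e6 pN/um ... net factor 1e-6 vs um path
        assert si.R_p * 1e6 == pytest.approx(g.R_p)
        k_si = compute_stiffness(si) * 1e6
        assert k_si == pytest.approx(k_um, rel=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"R_p": 2.5},  # R_p >= R_0
            {"R_p": 0.0},
            {"R_c": 0.0},
            {"dP": -5.0},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        base = dict(R_p=1.0, R_c=0.75, R_0=2.5, dP=200.0)
        base.update(kwargs)
        with pytest.raises(ModelDomainError):
            ProbeGeometry(**base)

    def test_out_of_domain_denominator_named_in_error(self):
        # a large contact radius pushes the bracket above the log term
        with pytest.raises(ModelDomainError, match="denominator"):
            compute_stiffness(ProbeGeometry(R_p=2.0, R_c=5.0, R_0=2.5, dP=200.0))


class TestForce:
    def test_worked_example_82_pN(self):
        """k = 274 pN/um at dx = 0.3 um carries 82 pN (2 significant figures)."""
        force, nonlinear = compute_force(np.array([0.3]), 274.0)
        assert f"{force[0]:.2g}" == "82"
        assert not nonlinear[0]

    def test_zero_deformation_zero_force(self):
        force, _ = compute_force(np.array([0.0]), 274.0)
        assert force[0] == 0.0

    def test_linear_regime_flagging(self):
        force, nonlinear = compute_force(np.array([0.6, -0.7, 0.49]), 100.0)
        assert force[0] == pytest.approx(60.0)
        assert list(nonlinear) == [True, True, False]

    def test_force_uncertainty_examples(self):
        """eps_F = k * eps_Delta for the two worked courses (~10 and ~12 pN)."""
        assert 198.0 * 0.050 == pytest.approx(10.0, abs=0.5)
        assert 274.0 * 0.044 == pytest.approx(12.0, abs=0.5)


class TestDeformation:
    def test_static_scene_gives_zero_dx(self):
        bead, pipette = _tracks([(100.0, 50.0)] * 5, [(40.0, 50.0)] * 5)
        x_um, x0, dx, calibrated = compute_deformation(bead, pipette, 0.1, t0=0)
        assert calibrated
        np.testing.assert_allclose(x_um, 6.0)
        np.testing.assert_allclose(dx, 0.0)

    def test_axial_displacement_reads_back_exactly(self):
        bead_xy = [(100.0, 50.0), (105.0, 50.0)]  # +5 px = +0.5 um from anchor
        bead, pipette = _tracks(bead_xy, [(40.0, 50.0)] * 2)
        _, x0, dx, calibrated = compute_deformation(bead, pipette, 0.1, t0=0)
        assert calibrated
        assert dx[1] == pytest.approx(0.5, abs=1e-12)

    def test_missing_t0_falls_back_to_first_frame_uncalibrated(self):
        bead, pipette = _tracks([(100.0, 50.0), (101.0, 50.0)], [(40.0, 50.0)] * 2)
        x_um, x0, dx, calibrated = compute_deformation(bead, pipette, 0.1, t0=None)
        assert not calibrated
        assert x0 == pytest.approx(x_um[0])
        assert dx[0] == 0.0

    def test_mismatched_tracks_rejected(self):
        bead, _ = _tracks([(1.0, 1.0)] * 3, [(0.0, 0.0)] * 3)
        _, pipette = _tracks([(1.0, 1.0)] * 2, [(0.0, 0.0)] * 2)
        with pytest.raises(ValueError, match="different frames"):
            compute_deformation(bead, pipette, 0.1)

    def test_force_of_deformation_is_linear_in_distance(self):
        rng = np.random.default_rng(4)
        anchor = [(40.0, 50.0)] * 20
        bead = [(100.0 + d, 50.0) for d in rng.uniform(-3, 3, 20)]
        bt, pt = _tracks(bead, anchor)
        _, _, dx, _ = compute_deformation(bt, pt, 0.1, t0=0)
        f1, _ = compute_force(dx, 200.0)
        f2, _ = compute_force(2.0 * dx, 200.0)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)


class TestStiffnessUncertainty:
    def test_typical_geometry_is_roughly_twenty_percent(self):
        dk = stiffness_uncertainty(GENERIC_GEOMETRY)
        assert dk == pytest.approx(DELTA_K_ORACLE_PCT, rel=1e-6)
        assert 15.0 < dk < 25.0

    def test_zero_uncertainties_give_zero(self):
        g = replace(GENERIC_GEOMETRY, sigma_R=0.0, sigma_P=0.0)
        assert stiffness_uncertainty(g) == 0.0

    def test_pressure_only_term_is_exactly_2_5_percent(self):
        g = replace(GENERIC_GEOMETRY, sigma_R=0.0, sigma_P=5.0)
        assert stiffness_uncertainty(g) == pytest.approx(2.5, rel=1e-9)

    def test_monte_carlo_cross_check(self):
        """10^5-sample propagation agrees with first-order within 15%."""
        rng = np.random.default_rng(12)
        g = GENERIC_GEOMETRY
        n = 100_000
        samples = np.empty(n)
        rp = rng.normal(g.R_p, g.sigma_R, n)
        rc = rng.normal(g.R_c, g.sigma_R, n)
        r0 = rng.normal(g.R_0, g.sigma_R, n)
        dp = rng.normal(g.dP, g.sigma_P, n)
        kept = 0
        for i in range(n):
            try:
                samples[kept] = compute_stiffness(
                    ProbeGeometry(R_p=rp[i], R_c=rc[i], R_0=r0[i], dP=dp[i])
                )
                kept += 1
            except ModelDomainError:
                continue
        mc = 100.0 * samples[:kept].std() / samples[:kept].mean()
        first_order = stiffness_uncertainty(g)
        assert abs(mc - first_order) / first_order < 0.15
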