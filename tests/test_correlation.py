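"""Covariance, DCCM, correlation scores and switch-region detection."""

import dataclasses

import numpy as np
import pytest

import heatdyn as hd
from heatdyn import synthetic as syn
from heatdyn.correlation import (CrossCorrelationMatrix, correlation_scores,
                                 covariance, cross_correlation,
                                 detect_switch_regions)
from heatdyn.io import ComponentMap, Ensemble
from heatdyn.superpose import superpose


def _bead_ensemble(coords):
    coords = np.asarray(coords, dtype=float)
    return Ensemble(syn.make_bead_table(coords.shape[1]), coords)


def _aligned(ens, cmap=None):
    beads = hd.select_beads(ens, cmap)
    return superpose(ens, beads, fit="none")


class TestCovariance:
    def test_requires_superposed_input(self, hinge_setup):
        ens, *_ = hinge_setup
        with pytest.raises(TypeError, match="superpose"):
            covariance(ens)

    def test_static_ensemble_gives_zero_matrix(self):
        base = np.random.default_rng(0).normal(size=(4, 3))
        ens = _bead_ensemble(np.broadcast_to(base, (5, 4, 3)).copy())
        cov = covariance(_aligned(ens))
        np.testing.assert_array_equal(cov.matrix, 0.0)

    def test_single_bead_two_frame_hand_example(self):
        # positions (0,0,0) and (2,0,0): deviations +-1 along x, population
        # variance 1, mass-weighted xx entry = m * 1
        coords = np.zeros((2, 1, 3))
        coords[1, 0, 0] = 2.0
        ens = _bead_ensemble(coords)
        beads = hd.select_beads(ens)
        sup = superpose(ens, beads, fit="none")
        cov = covariance(sup)
        m = beads.masses[0]  # carbon standard atomic weight
        assert cov.matrix[0, 0] == pytest.approx(m * 1.0, rel=1e-12)
        assert np.abs(cov.matrix).sum() == pytest.approx(m, rel=1e-12)

    def test_mass_scaling_doubles_covariance_not_cc(self, hinge_setup):
        ens, _, _, beads = hinge_setup
        sup = superpose(ens, beads)
        cov1 = covariance(sup)
        heavy = dataclasses.replace(beads, masses=2 * beads.masses)
        sup2 = dataclasses.replace(sup, beads=heavy)
        cov2 = covariance(sup2)
        np.testing.assert_allclose(cov2.matrix, 2 * cov1.matrix, rtol=1e-12)
        np.testing.assert_allclose(cross_correlation(cov2).matrix,
                                   cross_correlation(cov1).matrix,
                                   rtol=1e-10)


class TestCrossCorrelation:
    def test_identical_and_negated_displacements(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=100)
        coords = np.zeros((100, 3, 3))
        coords[:, 0, 0] = z        # bead 0
        coords[:, 1, 0] = z        # identical -> CC = 1
        coords[:, 2, 0] = -z       # negated  -> CC = -1
        cc = cross_correlation(covariance(_aligned(_bead_ensemble(coords))))
        assert cc.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert cc.matrix[0, 2] == pytest.approx(-1.0, abs=1e-12)
        np.testing.assert_allclose(np.diag(cc.matrix), 1.0, atol=1e-12)

    def test_zero_variance_bead_raises_with_name(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 0, 0] = np.arange(10.0)
        with pytest.raises(ValueError, match="immobile|zero-variance"):
            cross_correlation(covariance(_aligned(_bead_ensemble(coords))))

    def test_planted_block_correlation_recovered(self, two_block_ensemble,
                                                 two_block_map):
        ens, spec = two_block_ensemble
        cc = cross_correlation(covariance(_aligned(ens, two_block_map)))
        off = cc.matrix[:8, 8:]
        assert -0.53 <= off.mean() <= -0.47            # planted -0.5
        intra = cc.matrix[:8, :8][np.triu_indices(8, 1)]
        assert abs(intra.mean() - 0.9) < 0.01

    def test_invariant_to_rigid_motion_and_matrix_bounds(self, hinge_setup,
                                                         apply_rigid):
        ens, _, _, beads = hinge_setup
        small = ens.with_coords(ens.coords[:400])
        cc0 = cross_correlation(covariance(superpose(small, beads)))
        cc1 = cross_correlation(covariance(superpose(
            apply_rigid(small, seed=3), beads)))
        np.testing.assert_allclose(cc1.matrix, cc0.matrix, atol=1e-6)
        assert cc0.matrix.max() <= 1 + 1e-9
        assert cc0.matrix.min() >= -1 - 1e-9
        np.testing.assert_allclose(cc0.matrix, cc0.matrix.T, atol=1e-12)


class TestCorrelationScores:
    def _cc_from_matrix(self, mat, components):
        beads = hd.select_beads(_bead_ensemble(
            np.zeros((1, mat.shape[0], 3))))
        beads = dataclasses.replace(beads,
                                    components=np.asarray(components,
                                                          dtype=object))
        return CrossCorrelationMatrix(mat, beads, (0, 1))

    def test_single_bead_components_reduce_to_cc(self):
        mat = np.array([[1.0, 0.3], [0.3, 1.0]])
        cs = correlation_scores(self._cc_from_matrix(mat, ["A", "B"]))
        assert cs.as_frame().loc["A", "B"] == 0.3
        assert cs.as_frame().loc["A", "A"] == 1.0

    def test_constant_block_mean(self):
        mat = np.ones((5, 5))
        mat[:2, 2:] = mat[2:, :2] = 0.4
        cs = correlation_scores(self._cc_from_matrix(
            mat, ["A", "A", "B", "B", "B"]))
        assert cs.as_frame().loc["A", "B"] == pytest.approx(0.4, abs=1e-15)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(-1, 1, size=(5, 5))
        mat = (raw + raw.T) / 2
        np.fill_diagonal(mat, 1.0)
        comps = ["A", "A", "B", "B", "B"]
        cs = correlation_scores(self._cc_from_matrix(mat, comps))
        # independent brute-force oracle
        total, count = 0.0, 0
        for i in range(5):
            for j in range(5):
                if comps[i] == "A" and comps[j] == "B":
                    total += mat[i, j]
                    count += 1
        assert count == 6
        assert cs.as_frame().loc["A", "B"] == pytest.approx(total / count,
                                                            abs=1e-12)

    def test_trivial_map_gives_grand_mean(self, hinge_setup):
        ens, _, _, _ = hinge_setup
        cmap = ComponentMap.from_entries([("all", "A", 1, 60)])
        beads = hd.select_beads(ens, cmap)
        cc = cross_correlation(covariance(superpose(ens, beads)))
        cs = correlation_scores(cc)
        assert cs.matrix[0, 0] == pytest.approx(cc.matrix.mean(), abs=1e-12)

    def test_unassigned_beads_excluded(self, hinge_setup):
        ens, *_ = hinge_setup
        cmap = ComponentMap.from_entries([("seg1", "A", 1, 30)])
        beads = hd.select_beads(ens, cmap)
        cc = cross_correlation(covariance(superpose(ens, beads)))
        cs = correlation_scores(cc)
        assert cs.component_names == ["seg1"]
        assert cs.matrix.shape == (1, 1)


class TestSwitchRegions:
    def test_rigid_body_gives_empty_list(self):
        # common translation noise: all beads perfectly correlated
        rng = np.random.default_rng(6)
        shift = rng.normal(size=(500, 1, 3))
        mean = syn._straight_chain(40)
        jitter = 1e-3 * rng.normal(size=(500, 40, 3))  # break exact ties
        ens = _bead_ensemble(mean[None] + shift + jitter)
        cmap = ComponentMap.from_entries([("probe", "A", 1, 20),
                                          ("rest", "A", 21, 40)])
        sup = _aligned(ens, cmap)
        cov = covariance(sup)
        cc = cross_correlation(cov)
        pca = hd.pca_modes(cov, 3)
        assert detect_switch_regions(cc, pca, "probe") == []

    def test_hinge_yields_one_region_containing_pivot(self, hinge_setup):
        ens, pivot, cmap, beads = hinge_setup
        sup = superpose(ens, beads)
        cov = covariance(sup)
        cc = cross_correlation(cov)
        pca = hd.pca_modes(cov, 3)
        regions = detect_switch_regions(cc, pca, "seg1")
        assert len(regions) == 1
        assert regions[0].bead_start <= pivot < regions[0].bead_stop
        assert regions[0].flanking_before == "seg2" or \
            regions[0].bead_start > 0  # flanks labelled from the map

    def test_unknown_probe_block_raises(self, hinge_setup):
        ens, _, cmap, beads = hinge_setup
        sup = superpose(ens, beads)
        cov = covariance(sup)
        cc = cross_correlation(cov)
        pca = hd.pca_modes(cov, 3)
        with pytest.raises(ValueError, match="probe"):
            detect_switch_regions(cc, pca, "nope")

    def test_anticorrelated_blocks_with_quiet_bridge(self):
        # blocks [0..48] and [52..99] move oppositely along one axis; the
        # bridge beads 49-51 have 5% amplitude -> one region within [48, 52]
        rng = np.random.default_rng(8)
        n, nb = 4000, 100
        z = rng.normal(size=n)
        amp = np.ones(nb)
        amp[49:52] = 0.05
        sign = np.where(np.arange(nb) <= 48, 1.0, -1.0)
        noise = 0.05 * rng.normal(size=(n, nb))
        coords = syn._straight_chain(nb)[None].repeat(n, axis=0)
        coords[:, :, 1] += (z[:, None] * sign * amp + noise)
        ens = _bead_ensemble(coords)
        cmap = ComponentMap.from_entries([("left", "A", 1, 49),
                                          ("right", "A", 53, 100)])
        beads = hd.select_beads(ens, cmap)
        sup = superpose(ens, beads, fit="none")
        cov = covariance(sup)
        cc = cross_correlation(cov)
        pca = hd.pca_modes(cov, 3)
        # percentile matched to the planted bridge width (3 beads of 100);
        # away from the bridge the amplitude profile is flat, so a larger
        # percentile would sweep in ties
        regions = detect_switch_regions(cc, pca, "left",
                                        amplitude_percentile=5)
        assert len(regions) == 1
        assert regions[0].bead_start >= 48
        assert regions[0].bead_stop <= 53


class TestParameterRecovery:
    @pytest.mark.parametrize("inter", [-0.8, -0.5, 0.0, 0.5, 0.9])
    def test_block_mean_cs_within_three_standard_errors(self, inter):
        # blocks of 6 with intra 0.9 keep the matrix PSD for every planted
        # inter value here: 1 + 5*0.9 = 5.5 >= 6*|inter|
        size, intra_used = 6, 0.9
        corr = syn.build_correlation_matrix(syn.BlockCovarianceSpec(
            blocks=(("A", size), ("B", size)),
            intra=(intra_used, intra_used),
            inter=((intra_used, inter), (inter, intra_used))))
        n = 20_000
        ens = syn.sample_gaussian_ensemble(syn._straight_chain(2 * size),
                                           corr, 1.0, n, seed=17)
        labels = ["A"] * size + ["B"] * size
        beads = dataclasses.replace(hd.select_beads(ens),
                                    components=np.asarray(labels,
                                                          dtype=object))
        sup = superpose(ens, beads, fit="none")
        cc = cross_correlation(covariance(sup))
        cs = correlation_scores(cc, components=np.asarray(labels,
                                                          dtype=object))
        se = (1 - inter ** 2) / np.sqrt(n)
        got = cs.as_frame().loc["A", "B"]
        assert abs(got - inter) <= 3 * max(se, 1e-4)
        # CS equals the brute-force block mean exactly
        brute = cc.matrix[:size, size:].mean()
        assert got == pytest.approx(brute, abs=1e-12)
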