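"""Ensemble statistics vs brute-force oracles on toy and simulated data."""

import numpy as np
import pandas as pd
import pytest

from yeastnuc.geometry import NuclearGeometry, classify_shell
from yeastnuc.karyotype import Karyotype, simple_chromosome
from yeastnuc.simulate import Conformation, Ensemble
from yeastnuc.structure import (
    contact_map,
    density_map_2d,
    gene_percent_peripheral,
    gene_position_table,
    locus_ne_displacement_10kb,
    matrix_distance_correlation,
    pair_distance_stats,
    shell_occupancy,
    spb_distance_difference,
    telomere_pair_median_distances,
)


def make_ensemble(frames: np.ndarray, name="toy") -> Ensemble:
    return Ensemble(
        conformations=[
            Conformation(positions=f, karyotype_name=name, replicate=i)
            for i, f in enumerate(frames)
        ],
        karyotype_name=name,
    )


@pytest.fixture(scope="module")
def toy_chains():
    k = Karyotype(
        chromosomes=[
            simple_chromosome("a", 9600, 4000),  # 3 beads
            simple_chromosome("b", 6400, 3000),  # 2 beads
        ],
        name="toy",
    )
    return k, k.build_chains()


class TestShellOccupancy:
    def test_uniform_points_fill_thirds(self, geometry):
        rng = np.random.default_rng(0)
        n_conf, n_beads = 400, 50
        pts = rng.normal(size=(n_conf, n_beads, 3))
        r = 1000.0 * rng.random((n_conf, n_beads)) ** (1 / 3)
        pts *= (r / np.linalg.norm(pts, axis=-1))[..., None]
        occ = shell_occupancy(make_ensemble(pts), geometry)
        for frac in (occ.central, occ.middle, occ.peripheral):
            assert frac.mean() == pytest.approx(1 / 3, abs=0.01)
        assert np.allclose(occ.central + occ.middle + occ.peripheral, 1.0, atol=1e-9)

    def test_single_conformation_gives_indicator_fractions(self, geometry):
        pts = np.array([[[0.0, 0, 0], [900.0, 0, 0], [700.0, 0, 0]]])
        occ = shell_occupancy(make_ensemble(pts), geometry)
        assert set(np.concatenate([occ.central, occ.middle, occ.peripheral])) <= {0.0, 1.0}
        assert occ.central[0] == 1.0 and occ.peripheral[1] == 1.0 and occ.middle[2] == 1.0

    def test_outside_points_count_as_peripheral(self, geometry):
        pts = np.array([[[1200.0, 0, 0]]])
        occ = shell_occupancy(make_ensemble(pts), geometry)
        assert occ.peripheral[0] == 1.0

    def test_rotation_invariance(self, geometry):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-500, 500, size=(20, 10, 3))
        occ1 = shell_occupancy(make_ensemble(pts), geometry)
        # rotate all conformations by 90 degrees about z
        R = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        occ2 = shell_occupancy(make_ensemble(pts @ R.T), geometry)
        assert np.allclose(occ1.peripheral, occ2.peripheral)


class TestGeneMapping:
    def test_gene_within_one_bead(self, geometry, toy_chains):
        _, chains = toy_chains
        pts = np.array([[[900.0, 0, 0]] * 5])  # all 5 beads peripheral
        occ = shell_occupancy(make_ensemble(pts), geometry)
        genes = pd.DataFrame([{"gene": "g1", "chrom": "a", "start": 100, "end": 200}])
        pp = gene_percent_peripheral(occ, chains, genes)
        assert pp["g1"] == pytest.approx(100.0 * occ.peripheral[0])

    def test_gene_spanning_beads_averages(self, geometry, toy_chains):
        _, chains = toy_chains
        # bead 0 peripheral in 1 of 5 confs (0.2), bead 1 in 2 of 5 (0.4)
        frames = []
        for i in range(5):
            f = np.zeros((5, 3))
            f[0, 0] = 900.0 if i < 1 else 100.0
            f[1, 0] = 900.0 if i < 2 else 100.0
            frames.append(f)
        occ = shell_occupancy(make_ensemble(np.array(frames)), geometry)
        genes = pd.DataFrame([{"gene": "g", "chrom": "a", "start": 1000, "end": 5000}])
        pp = gene_percent_peripheral(occ, chains, genes)
        assert pp["g"] == pytest.approx(30.0)

    def test_deleted_gene_is_nan_and_flagged(self, geometry, toy_chains):
        k, chains = toy_chains
        pts = np.zeros((2, 5, 3))
        occ = shell_occupancy(make_ensemble(pts), geometry)
        genes = pd.DataFrame(
            [
                {"gene": "ok", "chrom": "a", "start": 0, "end": 1000},
                {"gene": "gone", "chrom": "zz", "start": 0, "end": 1000},
            ]
        )
        tbl = gene_position_table(occ, chains, occ, chains, genes)
        assert not tbl.loc["ok", "deleted"]
        assert tbl.loc["gone", "deleted"]
        assert np.isnan(tbl.loc["gone", "percent_peripheral_strain"])


class TestDisplacementTables:
    def test_identical_ensembles_zero_displacement(self, geometry, toy_chains):
        _, chains = toy_chains
        rng = np.random.default_rng(1)
        pts = rng.uniform(-400, 400, size=(4, 5, 3))
        ens = make_ensemble(pts)
        tbl = locus_ne_displacement_10kb(ens, ens, chains, geometry)
        assert np.allclose(tbl["displacement_nm"], 0.0)
        # 3-bead loci plus the 2-bead remainder of chain a, 1 locus for b
        assert list(tbl["chromosome"]) == ["a", "b"]

    def test_radial_shift_changes_ne_distance_by_shift(self, geometry, toy_chains):
        _, chains = toy_chains
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 5, 3))
        base *= (500.0 / np.linalg.norm(base, axis=-1))[..., None]
        shifted = base * (550.0 / 500.0)  # +50 nm radial shift
        tbl = locus_ne_displacement_10kb(
            make_ensemble(base), make_ensemble(shifted), chains, geometry
        )
        assert np.allclose(tbl["displacement_nm"], -50.0, atol=1e-9)

    def test_three_bead_average_matches_brute_force(self, geometry, toy_chains):
        _, chains = toy_chains
        rng = np.random.default_rng(3)
        a = rng.uniform(-400, 400, size=(5, 5, 3))
        b = rng.uniform(-400, 400, size=(5, 5, 3))
        tbl = locus_ne_displacement_10kb(make_ensemble(a), make_ensemble(b), chains, geometry)
        brute_a = np.mean([1000.0 - np.linalg.norm(a[c, i]) for c in range(5) for i in range(3)])
        assert tbl.loc[0, "ne_dist_a_nm"] == pytest.approx(brute_a)

    def test_spb_difference_sign_and_brute_force(self, geometry):
        rng = np.random.default_rng(4)
        base = rng.uniform(-300, 300, size=(5, 4, 3))
        away = base + np.array([200.0, 0, 0])  # away from SPB at (-850,0,0)
        diff = spb_distance_difference(make_ensemble(base), make_ensemble(away), geometry)
        assert (diff > 0).all()
        c = np.asarray(geometry.c_spb)
        brute = np.mean([np.linalg.norm(away[k, 0] - c) for k in range(5)]) - np.mean(
            [np.linalg.norm(base[k, 0] - c) for k in range(5)]
        )
        assert diff[0] == pytest.approx(brute)

    def test_identical_ensembles_zero_spb_difference(self, geometry, toy_ensemble):
        diff = spb_distance_difference(toy_ensemble, toy_ensemble, geometry)
        assert np.allclose(diff, 0.0)


class TestPairDistances:
    def test_locus_to_itself_is_zero(self, toy_ensemble):
        s = pair_distance_stats(toy_ensemble, np.array([2]), beads_b=np.array([2]))
        assert s["mean_nm"] == 0.0 and s["median_nm"] == 0.0

    def test_median_of_three_conformations(self, geometry):
        frames = np.zeros((3, 2, 3))
        for i, d in enumerate((100.0, 300.0, 900.0)):
            frames[i, 1, 0] = d
        s = pair_distance_stats(make_ensemble(frames), np.array([0]), beads_b=np.array([1]))
        assert s["median_nm"] == 300.0

    def test_ne_and_spb_references_match_brute_force(self, geometry, toy_ensemble):
        P = toy_ensemble.positions_array()
        s_ne = pair_distance_stats(toy_ensemble, np.array([1]), reference="NE")
        brute = (1000.0 - np.linalg.norm(P[:, 1], axis=-1)).mean()
        assert s_ne["mean_nm"] == pytest.approx(brute)
        s_spb = pair_distance_stats(toy_ensemble, np.array([0, 1]), reference="SPB")
        c = np.asarray(geometry.c_spb)
        brute2 = np.linalg.norm(P[:, [0, 1]] - c, axis=-1).mean(axis=1).mean()
        assert s_spb["mean_nm"] == pytest.approx(brute2)

    def test_telomere_pair_medians_match_brute_force(self, geometry, toy_chains):
        _, chains = toy_chains
        rng = np.random.default_rng(8)
        pts = rng.uniform(-500, 500, size=(7, 5, 3))
        ens = make_ensemble(pts)
        tbl = telomere_pair_median_distances(ens, chains)
        # chains a (beads 0,2) and b (beads 3,4): 4 telomeres, 6 pairs
        assert len(tbl) == 6
        row = tbl[(tbl.telomere_a == "a-L") & (tbl.telomere_b == "b-R")].iloc[0]
        brute = np.median(np.linalg.norm(pts[:, 0] - pts[:, 4], axis=-1))
        assert row["median_nm"] == pytest.approx(brute)


class TestDensityMap:
    def test_single_bead_at_origin(self):
        ens = make_ensemble(np.zeros((1, 1, 3)))
        H = density_map_2d(ens)
        assert H.shape == (200, 200)
        assert H.max() == 1.0
        # peak at the (a=0, rho=0) cell
        i, j = np.unravel_index(H.argmax(), H.shape)
        assert i == 100 and j == 0

    def test_normalized_to_unit_maximum(self, toy_ensemble):
        H = density_map_2d(toy_ensemble)
        assert H.max() == pytest.approx(1.0)
        assert H.min() >= 0.0

    def test_png_rendering(self, toy_ensemble, tmp_path):
        from yeastnuc.structure import save_density_map_png

        H = density_map_2d(toy_ensemble)
        out = tmp_path / "density.png"
        save_density_map_png(H, out)
        assert out.stat().st_size > 1000

    def test_mass_is_conserved_before_normalization(self):
        # blur + histogram conserve total mass away from the grid edge
        from scipy.ndimage import gaussian_filter

        # interior points (> 3 blur sigmas from every grid edge)
        pts = np.array([[[-200.0, 150.0, 80.0], [300.0, -180.0, 90.0]]])
        a = pts[0, :, 0]
        rho = np.hypot(pts[0, :, 1], pts[0, :, 2])
        H, _, _ = np.histogram2d(a, rho, bins=200, range=[[-1000, 1000], [0, 2000]])
        assert gaussian_filter(H, 3.0, mode="constant").sum() == pytest.approx(2.0)


class TestContactMap:
    def test_symmetry_diagonal_and_binning(self, small_ensemble, small_karyotype):
        chains = small_karyotype.build_chains()
        cm = contact_map(small_ensemble, chains)
        assert np.array_equal(cm.matrix, cm.matrix.T)
        assert np.allclose(np.diag(cm.matrix), 1.0)
        assert cm.matrix.min() >= 0.0 and cm.matrix.max() <= 1.0
        # 10-bead bins: 63+47+32 beads -> 7+5+4 bins
        assert cm.n_bins == 16
        assert cm.bin_end[0] - cm.bin_start[0] == 10 * 3200

    def test_adjacent_bins_nearly_always_touch(self, small_ensemble, small_karyotype):
        chains = small_karyotype.build_chains()
        cm = contact_map(small_ensemble, chains)
        chrom = np.asarray(cm.bin_chrom, dtype=object)
        vals = [
            cm.matrix[i, i + 1]
            for i in range(cm.n_bins - 1)
            if chrom[i] == chrom[i + 1]
        ]
        # bonded beads are < 45 nm apart, far below the 120-nm cutoff
        assert min(vals) == 1.0

    def test_contact_frequency_decays_with_distance(self, small_ensemble, small_karyotype):
        chains = small_karyotype.build_chains()
        cm = contact_map(small_ensemble, chains)
        chrom = np.asarray(cm.bin_chrom, dtype=object)
        ii, jj = np.triu_indices(cm.n_bins, k=1)
        intra = chrom[ii] == chrom[jj]
        dist = (jj - ii)[intra]
        vals = cm.matrix[ii[intra], jj[intra]]
        short = vals[dist <= 2].mean()
        long = vals[dist >= 4].mean()
        assert short > long

    def test_count_mode_unbounded(self, small_ensemble, small_karyotype):
        chains = small_karyotype.build_chains()
        cm = contact_map(small_ensemble, chains, mode="count")
        assert cm.matrix.max() > 1.0  # raw pair counts exceed probabilities

    def test_toy_map_matches_brute_force(self, geometry, toy_chains):
        _, chains = toy_chains
        rng = np.random.default_rng(12)
        pts = rng.uniform(-200, 200, size=(3, 5, 3))
        cm = contact_map(make_ensemble(pts), chains, beads_per_bin=2)
        # brute force for bin pair (0, 1) of chain a: beads {0,1} vs {2}
        hits = 0
        for c in range(3):
            d = np.linalg.norm(pts[c, [0, 1]] - pts[c, 2], axis=-1)
            hits += (d <= 120.0).any()
        assert cm.matrix[0, 1] == pytest.approx(hits / 3)


class TestMatrixCorrelation:
    def test_self_correlation_is_one(self, small_ensemble, small_karyotype):
        chains = small_karyotype.build_chains()
        cm = contact_map(small_ensemble, chains)
        prof = matrix_distance_correlation(cm, cm.matrix, cm.bin_chrom)
        vals = prof[prof.distance_bins >= 0]["spearman"].dropna().to_numpy()
        assert np.allclose(vals, 1.0)

    def test_shuffled_matrix_decorrelates(self, small_ensemble, small_karyotype):
        chains = small_karyotype.build_chains()
        cm = contact_map(small_ensemble, chains)
        rng = np.random.default_rng(0)
        shuf = cm.matrix.copy()
        iu = np.triu_indices_from(shuf, k=1)
        vals = shuf[iu]
        rng.shuffle(vals)
        shuf[iu] = vals
        shuf.T[iu] = vals
        prof = matrix_distance_correlation(cm, shuf, cm.bin_chrom)
        overall = prof.loc[prof.distance_bins == -1, "spearman"].iloc[0]
        assert abs(overall) < 0.3

    def test_rejects_mismatched_bins(self, small_ensemble, small_karyotype):
        chains = small_karyotype.build_chains()
        cm = contact_map(small_ensemble, chains)
        with pytest.raises(ValueError):
            matrix_distance_correlation(cm, np.eye(3), ["a", "a", "b"])
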