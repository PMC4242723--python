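"""Knowledge-based tables: normalization, periodic interpolation, and the
two statistical derivations (torsion tables round-trip; pair potential
reference consistency and parameter recovery)."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from loopcsa.tables import (RT, ChiTable, PairPotentialTable, PhiPsiTable,
                            derive_pair_potential, derive_torsion_tables,
                            pair_counts_to_potential, reference_chi_table,
                            reference_phipsi_table)


class TestPhiPsiTable:
    def test_reference_tables_normalized(self):
        assert reference_phipsi_table().check_normalization()
        assert reference_chi_table().check_normalization()

    def test_uniform_table_is_flat(self):
        t = PhiPsiTable({"generic": np.zeros((36, 36))})
        vals = [t.energy("ALA", p, s)
                for p in (-171.3, 0.0, 55.2) for s in (-88.8, 140.0)]
        assert np.ptp(vals) < 1e-9

    def test_bin_centers_exact(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(36, 36))
        t = PhiPsiTable({"generic": grid}, interpolation="bilinear")
        g = t.grids["generic"]
        for i, j in ((0, 0), (5, 20), (35, 35)):
            ph = -180.0 + 10.0 * (i + 0.5)
            ps = -180.0 + 10.0 * (j + 0.5)
            assert t.energy("ALA", ph, ps) == pytest.approx(g[i, j])

    def test_bilinear_bounded_by_neighbours(self):
        rng = np.random.default_rng(1)
        t = PhiPsiTable({"generic": rng.normal(size=(36, 36))},
                        interpolation="bilinear")
        g = t.grids["generic"]
        for _ in range(200):
            ph = rng.uniform(-180, 180)
            ps = rng.uniform(-180, 180)
            i = int(np.floor((ph + 180) / 10 - 0.5)) % 36
            j = int(np.floor((ps + 180) / 10 - 0.5)) % 36
            corners = [g[(i + a) % 36, (j + b) % 36]
                       for a in (0, 1) for b in (0, 1)]
            v = t.energy("ALA", ph, ps)
            assert min(corners) - 1e-9 <= v <= max(corners) + 1e-9

    def test_periodic_continuity(self):
        t = reference_phipsi_table()
        for ps in (-120.0, 0.0, 77.0):
            a = t.energy("ALA", 180.0 - 1e-7, ps)
            b = t.energy("ALA", -180.0 + 1e-7, ps)
            assert abs(a - b) < 1e-5

    def test_text_round_trip(self, tmp_path):
        t = reference_phipsi_table()
        path = tmp_path / "pp.txt"
        t.to_text(path)
        back = PhiPsiTable.from_text(path)
        for cls in t.grids:
            assert np.allclose(t.grids[cls], back.grids[cls], atol=1e-7)


class TestTorsionDerivation:
    def test_helix_training_peaks_at_helix(self):
        from loopcsa.structure import build_chain_from_torsions
        n = 24
        sts = [build_chain_from_torsions("A" * n, np.full(n, -57.0),
                                         np.full(n, -47.0))]
        pp, chi = derive_torsion_tables(sts)
        g = pp.grids["generic"]
        i, j = np.unravel_index(np.argmin(g), g.shape)
        assert -180 + 10 * (i + 0.5) == pytest.approx(-55, abs=10)
        assert -180 + 10 * (j + 0.5) == pytest.approx(-45, abs=10)
        assert pp.check_normalization()

    def test_round_trip_recovery(self):
        """Angles sampled from exp(-table) re-derive the table within
        binning noise."""
        from loopcsa.structure import build_chain_from_torsions
        rng = np.random.default_rng(5)
        t = reference_phipsi_table()
        p = np.exp(-t.grids["generic"]).ravel()
        draws = rng.choice(36 * 36, size=40000, p=p / p.sum())
        i, j = np.unravel_index(draws, (36, 36))
        centers = -180.0 + 10.0 * (np.arange(36) + 0.5)
        phis = centers[i] + rng.uniform(-5, 5, len(i))
        psis = centers[j] + rng.uniform(-5, 5, len(j))
        # feed the sampled angles through the derivation path in chunks
        sts = []
        for k in range(0, 40000, 400):
            n = 400
            sts.append(build_chain_from_torsions(
                "A" * n, phis[k:k + n], psis[k:k + n]))
        derived, _ = derive_torsion_tables(sts)
        # compare probabilities on well-populated bins
        p0 = np.exp(-t.grids["generic"])
        p1 = np.exp(-derived.grids["generic"])
        mask = p0 > 5.0 / 40000
        # interior residues only shift counts slightly; 25% tolerance on
        # per-bin probability captures multinomial noise at this n
        assert np.median(np.abs(p1[mask] - p0[mask]) / p0[mask]) < 0.25


class TestPairPotential:
    def test_reference_bin_is_zero(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(50, 500, size=(8, 8, 30)).astype(float)
        counts = counts + counts.transpose(1, 0, 2)
        t = pair_counts_to_potential(counts)
        assert np.all(t.u[:, :, -1] == 0.0)
        assert np.all(np.isfinite(t.u))

    def test_lookup_linearity_and_cutoff(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(50, 500, size=(8, 8, 30)).astype(float)
        counts = counts + counts.transpose(1, 0, 2)
        t = pair_counts_to_potential(counts)
        doubled = PairPotentialTable(2 * t.u, t.classes, t.bin_width, t.r_cut)
        ci = np.zeros(5, int)
        cj = np.ones(5, int)
        r = np.array([0.7, 3.3, 9.9, 14.9, 15.6])
        a = t.lookup(ci, cj, r)
        b = doubled.lookup(ci, cj, r)
        assert np.allclose(b, 2 * a)
        assert a[-1] == 0.0  # beyond r_cut

    def test_uniform_gas_residual_small(self):
        """Ideal-gas counts against the alpha=2 reference give ~zero."""
        rng = np.random.default_rng(4)
        R, npts = 150.0, 30000
        u = rng.uniform(size=npts) ** (1 / 3)
        costh = rng.uniform(-1, 1, npts)
        ph = rng.uniform(0, 2 * np.pi, npts)
        sinth = np.sqrt(1 - costh ** 2)
        pos = (R * u)[:, None] * np.c_[sinth * np.cos(ph),
                                       sinth * np.sin(ph), costh]
        pairs = cKDTree(pos).query_pairs(r=15.0, output_type="ndarray")
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        counts = np.zeros((8, 8, 30))
        np.add.at(counts, (0, 0, np.minimum((d / 0.5).astype(int), 29)), 1.0)
        t = pair_counts_to_potential(counts, alpha=2.0)
        # bins with meaningful counts (r >= 1 A)
        assert np.abs(t.u[0, 0, 2:]).max() < 0.1

    def test_planted_boltzmann_well_recovered(self):
        rng = np.random.default_rng(5)
        centers = 0.5 * (np.arange(30) + 0.5)
        depth = -1.0
        u0 = depth * np.exp(-0.5 * ((centers - 5.0) / 0.8) ** 2)
        p = centers ** 2 * np.exp(-u0 / RT)
        p /= p.sum()
        counts = np.zeros((8, 8, 30))
        counts[0, 0, :] = rng.multinomial(100000, p)
        t = pair_counts_to_potential(counts, alpha=2.0)
        assert t.u[0, 0].min() == pytest.approx(depth, rel=0.15)

    def test_training_set_scale_consistency(self):
        """Doubling the training set leaves the table essentially fixed."""
        from loopcsa.fixtures import ScaffoldSpec, make_scaffold
        sts = [make_scaffold(ScaffoldSpec(rng_seed=s)) for s in range(8)]
        t1 = derive_pair_potential(sts)
        t2 = derive_pair_potential(sts + sts)
        live = (np.abs(t1.u).sum(axis=2) > 0) & (np.abs(t2.u).sum(axis=2) > 0)
        diff = np.abs(t1.u - t2.u)[live]
        assert np.median(diff) < 0.25

    def test_text_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        counts = rng.integers(50, 500, size=(8, 8, 30)).astype(float)
        counts = counts + counts.transpose(1, 0, 2)
        t = pair_counts_to_potential(counts)
        path = tmp_path / "pair.txt"
        t.to_text(path)
        back = PairPotentialTable.from_text(path)
        for ci in t.classes:
            for cj in t.classes:
                i1, j1 = t.class_index[ci], t.class_index[cj]
                i2, j2 = back.class_index[ci], back.class_index[cj]
                assert np.allclose(t.u[i1, j1], back.u[i2, j2], atol=1e-7)

    def test_chi_table_normalization_after_derivation(self, chain20):
        _, chi = derive_torsion_tables([chain20])
        assert chi.check_normalization()
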