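"""Evaluation metrics: Kabsch optimality, RMSD conventions, symmetric-flip
minimization against brute force, environment selection, E-RMSD."""

import itertools

import numpy as np
import pytest

from loopcsa.geom import rotation_about_axis
from loopcsa.metrics import (FLIP_GROUPS, e_rmsd, environment_residues,
                             kabsch_superpose, loop_mainchain_rmsd,
                             rmsd_report, symmetric_flip_rmsd)


def _rigid(structure, R, t):
    out = structure.copy()
    for cid, r in out.iter_residues():
        for a in r.atoms:
            a.pos = R @ a.pos + t
    return out


class TestKabsch:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        rot, trans, rms = kabsch_superpose(pts, pts)
        assert rms < 1e-12
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_exact_transform_recovery(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3)) * 4
        R = rotation_about_axis([0, 0, 1], 90.0)
        t = np.array([1.0, 2.0, 3.0])
        rot, trans, rms = kabsch_superpose(pts @ R.T + t, pts)
        assert rms < 1e-10
        assert np.allclose(rot @ R, np.eye(3), atol=1e-10)

    def test_beats_random_rotations(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        _, _, rms = kabsch_superpose(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        for _ in range(1000):
            R = rotation_about_axis(rng.normal(size=3),
                                    rng.uniform(0, 360))
            trial = np.sqrt(np.mean(np.sum((ac @ R.T - bc) ** 2, axis=1)))
            assert rms <= trial + 1e-12

    def test_degenerate_inputs_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestLoopRmsd:
    def test_zero_on_self(self, chain20, loop8):
        assert loop_mainchain_rmsd(chain20, chain20, loop8) < 1e-12

    def test_rigid_translation_is_exact(self, chain20, loop8):
        m = chain20.copy()
        for i in loop8.indices:
            for a in m.residue("A", i).atoms:
                a.pos = a.pos + np.array([1.0, 0.0, 0.0])
        assert loop_mainchain_rmsd(m, chain20, loop8) == pytest.approx(1.0)

    def test_matches_naive_sum(self, chain20, loop8):
        rng = np.random.default_rng(3)
        m = chain20.copy()
        for cid, r in m.iter_residues():
            for a in r.atoms:
                a.pos = a.pos + rng.normal(scale=0.4, size=3)
        got = loop_mainchain_rmsd(m, chain20, loop8)
        sq, cnt = 0.0, 0
        for i in loop8.indices:
            for nm in ("N", "CA", "C", "O"):
                sq += np.sum((m.atom("A", i, nm).pos
                              - chain20.atom("A", i, nm).pos) ** 2)
                cnt += 1
        assert got == pytest.approx(np.sqrt(sq / cnt), abs=1e-9)


class TestSymmetricFlips:
    def test_label_swap_gives_zero(self, chain20):
        m = chain20.copy()
        for cid, r in m.iter_residues():
            if r.name in ("ASP", "PHE", "ARG", "LEU", "VAL"):
                for a, b in FLIP_GROUPS[r.name]:
                    pa = r.atom(a).pos.copy()
                    r.atom(a).pos = r.atom(b).pos.copy()
                    r.atom(b).pos = pa
        keys = [("A", r.index) for _, r in chain20.iter_residues()]
        assert symmetric_flip_rmsd(m, chain20, keys) < 1e-12

    def test_never_exceeds_identity_assignment(self, chain20):
        rng = np.random.default_rng(4)
        m = chain20.copy()
        for cid, r in m.iter_residues():
            for a in r.atoms:
                a.pos = a.pos + rng.normal(scale=0.5, size=3)
        keys = [("A", r.index) for _, r in chain20.iter_residues()]
        flipped = symmetric_flip_rmsd(m, chain20, keys)
        plain = symmetric_flip_rmsd(
            m, chain20, [k for k in keys
                         if chain20.residue(*k).name not in FLIP_GROUPS])
        # identity assignment, computed by zeroing the flip table
        sq, cnt = 0.0, 0
        for cid, idx in keys:
            rm, rr = m.residue(cid, idx), chain20.residue(cid, idx)
            for a in rr.atoms:
                if a.element == "H":
                    continue
                sq += np.sum((rm.atom(a.name).pos - a.pos) ** 2)
                cnt += 1
        assert flipped <= np.sqrt(sq / cnt) + 1e-12

    def test_matches_exhaustive_enumeration(self, chain20):
        rng = np.random.default_rng(5)
        m = chain20.copy()
        for cid, r in m.iter_residues():
            for a in r.atoms:
                a.pos = a.pos + rng.normal(scale=0.3, size=3)
        keys = [("A", i) for i in range(4, 12)]
        flippable = [k for k in keys
                     if chain20.residue(*k).name in FLIP_GROUPS]
        best = None
        for mask in itertools.product([0, 1], repeat=len(flippable)):
            mm = m.copy()
            for bit, (cid, i) in zip(mask, flippable):
                if bit:
                    r = mm.residue(cid, i)
                    for a, b in FLIP_GROUPS[r.name]:
                        pa = r.atom(a).pos.copy()
                        r.atom(a).pos = r.atom(b).pos.copy()
                        r.atom(b).pos = pa
            sq, cnt = 0.0, 0
            for cid, i in keys:
                rm, rr = mm.residue(cid, i), chain20.residue(cid, i)
                for a in rr.atoms:
                    if a.element == "H":
                        continue
                    sq += np.sum((rm.atom(a.name).pos - a.pos) ** 2)
                    cnt += 1
            v = np.sqrt(sq / cnt)
            best = v if best is None else min(best, v)
        assert symmetric_flip_rmsd(m, chain20, keys) == pytest.approx(
            best, abs=1e-12)


class TestEnvironment:
    def test_matches_brute_force_scan(self, scaffold, scaffold_loop):
        got = environment_residues(scaffold, scaffold_loop, 10.0)
        cb = []
        for i in scaffold_loop.indices:
            r = scaffold.residue("A", i)
            cb.append(r.atom("CB").pos if r.has_atom("CB")
                      else r.atom("CA").pos)
        expected = []
        loop_set = set(scaffold_loop.indices)
        for cid, r in scaffold.iter_residues():
            if r.index in loop_set:
                continue
            dmin = min(np.linalg.norm(a.pos - c)
                       for a in r.atoms for c in cb)
            if dmin <= 10.0:
                expected.append((cid, r.index))
        assert got == expected

    def test_boundary_is_closed_interval(self, scaffold, scaffold_loop):
        # place a probe residue at exactly / just beyond the cutoff from the
        # *nearest* loop C-beta (probe sits on an outward ray so no other
        # C-beta is closer)
        st = scaffold.copy()
        cbs = []
        for i in scaffold_loop.indices:
            r = st.residue("A", i)
            cbs.append(r.atom("CB").pos if r.has_atom("CB")
                       else r.atom("CA").pos)
        cbs = np.array(cbs)
        centroid = cbs.mean(axis=0)
        k = int(np.argmax(np.linalg.norm(cbs - centroid, axis=1)))
        u = (cbs[k] - centroid) / np.linalg.norm(cbs[k] - centroid)
        probe = st.residues("A")[0].copy()
        probe.index = 99
        for dist, expect in ((10.0 - 1e-9, True), (10.0 + 0.01, False)):
            pos = cbs[k] + dist * u
            dmin = np.min(np.linalg.norm(cbs - pos, axis=1))
            assert abs(dmin - dist) < 1e-9  # the ray construction holds
            for a in probe.atoms:
                a.pos = cbs[k] + 300.0 * u
            probe.atoms[0].pos = pos
            st.chains["B"] = [probe]
            sel = environment_residues(st, scaffold_loop, 10.0)
            assert (("B", 99) in sel) == expect

    def test_monotone_in_cutoff(self, scaffold, scaffold_loop):
        prev = set()
        for cutoff in (4.0, 7.0, 10.0, 14.0):
            sel = set(environment_residues(scaffold, scaffold_loop, cutoff))
            assert prev <= sel
            prev = sel

    def test_positive_cutoff_required(self, scaffold, scaffold_loop):
        with pytest.raises(ValueError):
            environment_residues(scaffold, scaffold_loop, 0.0)


class TestERmsd:
    def test_zero_on_self(self, scaffold, scaffold_loop):
        assert e_rmsd(scaffold, scaffold, scaffold_loop) < 1e-10

    def test_rigid_transform_invariant(self, scaffold, scaffold_loop):
        rng = np.random.default_rng(6)
        m = scaffold.copy()
        for cid, r in m.iter_residues():
            for a in r.atoms:
                a.pos = a.pos + rng.normal(scale=0.3, size=3)
        base = e_rmsd(m, scaffold, scaffold_loop)
        R = rotation_about_axis(rng.normal(size=3), 61.0)
        t = np.array([7.0, -4.0, 2.0])
        assert abs(e_rmsd(_rigid(m, R, t), scaffold, scaffold_loop)
                   - base) < 1e-8
        assert abs(e_rmsd(m, _rigid(scaffold, R, t), scaffold_loop)
                   - base) < 1e-8

    def test_report_fields(self, scaffold, scaffold_loop):
        rep = rmsd_report(scaffold, scaffold, scaffold_loop)
        assert rep.loop_mainchain_rmsd < 1e-10
        assert rep.loop_allatom_rmsd < 1e-10
        assert rep.e_rmsd < 1e-10
        assert rep.n_env_residues > 0
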