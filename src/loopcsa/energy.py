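"""Hybrid energy function: physics-based molecular mechanics terms plus
knowledge-based statistical corrections.

    E_total = E_bonded + E_vdW
            + w_elec * (E_Coulomb + E_GB) + w_sa * E_SA
            + w_phipsi * E_phi/psi + w_chi * E_chi
            + w_hbond * E_Hbond + w_atompair * E_atom-pair

The default weights are (w_elec, w_sa, w_phipsi, w_chi, w_hbond,
w_atompair) = (0.16, 0.05, 1.2, 1.0, 4.0, 12.0).

Energies are evaluated over the *loop region*: loop-loop and
loop-environment interactions only (the environment-environment part is
constant while the loop is sampled and is dropped).  Physics terms:

* bonded: harmonic bonds and angles, a periodic planarity term on peptide
  omega, and a harmonic carbonyl improper; equilibria come from the ideal
  residue geometry the builder itself uses, so rebuilt loops sit at the
  minimum by construction.
* van der Waals: 12-6 Lennard-Jones (rmin/epsilon combination rules),
  1-2/1-3 pairs excluded, 1-4 scaled, switched off between 8 and 10 A, and
  linearly continued below 0.6 rmin_ij so the optimizer never sees an
  unbounded wall.
* electrostatics: vacuum Coulomb plus a generalized-Born pair term (Still's
  f_GB) with effective radii from a pairwise HCT descreening sum; the
  solvent-accessible surface-area term uses Shrake-Rupley sampling with
  per-class surface tensions.

Analytic Cartesian gradients are provided for the bonded, van der Waals and
Coulomb terms (the ones local minimization exercises hardest); the
remaining terms are evaluated energy-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import topology as topo
from .geom import dihedral, wrap_angle
from .structure import (LoopDefinition, ProteinStructure, TorsionState,
                        build_chain_from_torsions, measure_chi)
from .tables import (ChiTable, PairPotentialTable, PhiPsiTable,
                     PAIR_CLASS_OF, PAIR_CLASSES, reference_chi_table,
                     reference_phipsi_table)

__all__ = [
    "EnergyWeights",
    "EnergyBreakdown",
    "EnergyConfig",
    "EnergyModel",
    "BoundLoopEnergy",
    "e_bonded", "e_vdw", "e_coulomb_gb", "e_sa", "e_hbond", "e_atompair",
    "e_phipsi", "e_chi", "total_energy",
]

COULOMB_K = 332.0716   # kcal mol^-1 A e^-2
GB_K = 166.0358        # Still prefactor (half the Coulomb constant)


@dataclass(frozen=True)
class EnergyWeights:
    w_electrostatics: float = 0.16
    w_sa: float = 0.05
    w_phipsi: float = 1.2
    w_chi: float = 1.0
    w_hbond: float = 4.0
    w_atompair: float = 12.0

    def __post_init__(self):
        for f in ("w_electrostatics", "w_sa", "w_phipsi", "w_chi",
                  "w_hbond", "w_atompair"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    def as_tuple(self):
        return (self.w_electrostatics, self.w_sa, self.w_phipsi,
                self.w_chi, self.w_hbond, self.w_atompair)


@dataclass
class EnergyBreakdown:
    e_bonded: float = 0.0
    e_vdw: float = 0.0
    e_coulomb: float = 0.0
    e_gb: float = 0.0
    e_sa: float = 0.0
    e_phipsi: float = 0.0
    e_chi: float = 0.0
    e_hbond: float = 0.0
    e_atompair: float = 0.0
    weights: EnergyWeights = field(default_factory=EnergyWeights)

    @property
    def e_total(self) -> float:
        w = self.weights
        return (self.e_bonded + self.e_vdw
                + w.w_electrostatics * (self.e_coulomb + self.e_gb)
                + w.w_sa * self.e_sa
                + w.w_phipsi * self.e_phipsi
                + w.w_chi * self.e_chi
                + w.w_hbond * self.e_hbond
                + w.w_atompair * self.e_atompair)

    def as_dict(self):
        d = {k: getattr(self, k) for k in
             ("e_bonded", "e_vdw", "e_coulomb", "e_gb", "e_sa", "e_phipsi",
              "e_chi", "e_hbond", "e_atompair")}
        d["e_total"] = self.e_total
        return d


@dataclass(frozen=True)
class EnergyConfig:
    r_on: float = 8.0            # switching start, A
    r_off: float = 10.0          # nonbonded cutoff, A
    scale_14: float = 0.5        # 1-4 LJ/Coulomb scaling
    cap_factor: float = 0.6      # linear LJ continuation below cap*rmin_ij
    eps_solvent: float = 78.5
    born_scale: float = 0.8      # HCT descreening scale
    sasa_points: int = 192
    sasa_probe: float = 1.4
    hbond_d0: float = 1.95       # H...A well centre, A
    hbond_dw: float = 0.65       # distance well half-width
    hbond_cut: float = 2.6       # H...A hard cutoff
    kb: float = 300.0            # bond force constant, kcal/mol/A^2
    ka: float = 50.0             # angle force constant, kcal/mol/rad^2
    komega: float = 12.0         # peptide planarity
    kimp: float = 15.0           # carbonyl improper


# ---------------------------------------------------------------------------
# ideal geometry lookups (equilibrium bond lengths/angles per residue type)
# ---------------------------------------------------------------------------

_IDEAL_CACHE: dict[str, tuple[dict, dict]] = {}


def _ideal_geometry(resname: str):
    """Equilibrium bonds/angles measured from an ideally built dipeptide of
    the residue type (self-consistent with the chain builder)."""
    if resname not in _IDEAL_CACHE:
        one = topo.THREE_TO_ONE[resname]
        st = build_chain_from_torsions("G" + one + "G",
                                       [-120.0, -120.0, -120.0],
                                       [140.0, 140.0, 140.0])
        residues = st.residues("A")
        pos = {}
        for r in residues:
            for a in r.atoms:
                pos[(r.index, a.name)] = a.pos
        adj: dict[tuple, list] = {}
        for (c1, i1, n1), (c2, i2, n2) in st.bonds:
            adj.setdefault((i1, n1), []).append((i2, n2))
            adj.setdefault((i2, n2), []).append((i1, n1))
        bonds, angles = {}, {}
        for (a, b) in {tuple(sorted(k)) for k in
                       [((i1, n1), (i2, n2)) for (c1, i1, n1), (c2, i2, n2)
                        in st.bonds]}:
            r = float(np.linalg.norm(pos[a] - pos[b]))
            bonds[_name_key(a, b)] = r
        for j, nbrs in adj.items():
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    a, c = nbrs[x], nbrs[y]
                    u = pos[a] - pos[j]
                    v = pos[c] - pos[j]
                    th = math.degrees(math.acos(np.clip(
                        np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)),
                        -1, 1)))
                    angles[_angle_key(a, j, c)] = th
        _IDEAL_CACHE[resname] = (bonds, angles)
    return _IDEAL_CACHE[resname]


def _name_key(a, b):
    (ia, na), (ib, nb) = a, b
    di = ib - ia
    if di < 0 or (di == 0 and na > nb):
        na, nb, di = nb, na, -di
    return (na, nb, di)


def _angle_key(a, j, c):
    (ia, na), (ij, nj), (ic, nc) = a, j, c
    left = (na, ia - ij)
    right = (nc, ic - ij)
    if left > right:
        left, right = right, left
    return (left[0], nj, right[0], left[1], right[1])


# ---------------------------------------------------------------------------
# the bound system
# ---------------------------------------------------------------------------

class BoundLoopEnergy:
    """Flattened view of one (structure, loop) pair with cached pair lists.

    ``evaluate()`` re-reads atom positions from the structure, so the view
    stays valid across in-place loop rebuilds.
    """

    def __init__(self, model: "EnergyModel", structure: ProteinStructure,
                 loop: LoopDefinition):
        self.model = model
        self.structure = structure
        self.loop = loop
        cfg = model.config
        loop.validate(structure)
        cid = loop.chain_id
        loop_keys = {(cid, i) for i in loop.indices}

        # broad-phase: keep environment atoms the loop can ever reach
        a0 = structure.atom(cid, loop.start - 1, "CA").pos
        a1 = structure.atom(cid, loop.end + 1, "CA").pos
        mid = 0.5 * (a0 + a1)
        reach = 2.1 * loop.n_residues + cfg.r_off + 6.0

        atoms, keys = [], []
        self.loop_idx, self.env_idx = [], []
        resseq = []          # global residue serial for sequence separation
        chain_of = []
        serial = {}
        for ci, (ccid, r) in enumerate(structure.iter_residues()):
            serial[(ccid, r.index)] = len(serial)
        for ccid, r in structure.iter_residues():
            in_loop = (ccid, r.index) in loop_keys
            for a in r.atoms:
                if not in_loop and np.linalg.norm(a.pos - mid) > reach:
                    continue
                idx = len(atoms)
                atoms.append(a)
                keys.append((ccid, r.index, a.name))
                resseq.append(serial[(ccid, r.index)])
                chain_of.append(ccid)
                (self.loop_idx if in_loop else self.env_idx).append(idx)
        self.atoms = atoms
        self.key_index = {k: i for i, k in enumerate(keys)}
        self.n = len(atoms)
        self.loop_idx = np.array(self.loop_idx, dtype=int)
        self.env_idx = np.array(self.env_idx, dtype=int)
        self.resseq = np.array(resseq)
        self.charge = np.array([a.partial_charge for a in atoms])
        self.rmin = np.array([a.vdw_radius for a in atoms])
        self.eps = np.array([a.epsilon for a in atoms])
        self.gamma = np.array([a.gamma_sa for a in atoms])
        self.heavy = np.array([a.element != "H" for a in atoms])
        same_chain = np.array([chain_of[i] for i in range(self.n)])
        self.pos = np.zeros((self.n, 3))

        # nonbonded pair list: loop-loop (i<j) + loop-env
        li = self.loop_idx
        pi, pj = [], []
        for x in range(len(li)):
            for y in range(x + 1, len(li)):
                pi.append(li[x]); pj.append(li[y])
        for x in li:
            for y in self.env_idx:
                pi.append(x); pj.append(y)
        self.pi = np.array(pi, dtype=int)
        self.pj = np.array(pj, dtype=int)

        # bond graph distances for exclusions / 1-4 scaling
        nbr = [[] for _ in range(self.n)]
        self.bond_pairs = []
        for ka, kb in structure.bonds:
            ia = self.key_index.get(ka)
            ib = self.key_index.get(kb)
            if ia is None or ib is None:
                continue
            nbr[ia].append(ib)
            nbr[ib].append(ia)
            self.bond_pairs.append((ia, ib))
        self.scale = np.ones(len(self.pi))
        topo_dist = {}
        for s_ in range(self.n):
            # BFS to depth 3
            dist = {s_: 0}
            frontier = [s_]
            for depth in range(1, 4):
                nxt = []
                for u in frontier:
                    for v in nbr[u]:
                        if v not in dist:
                            dist[v] = depth
                            nxt.append(v)
                frontier = nxt
            for v, d in dist.items():
                if d:
                    topo_dist[(s_, v)] = d
        for k, (x, y) in enumerate(zip(self.pi, self.pj)):
            d = topo_dist.get((int(x), int(y)))
            if d in (1, 2):
                self.scale[k] = 0.0
            elif d == 3:
                self.scale[k] = cfg.scale_14
        keep = self.scale > 0
        self.nb_i = self.pi[keep]
        self.nb_j = self.pj[keep]
        self.nb_scale = self.scale[keep]

        self._build_bonded(structure, loop, nbr)
        self._build_hbond(structure, loop)
        self._build_atompair()
        self._build_torsion_atoms(structure, loop)
        # SASA set: loop atoms + nearby environment, frozen at bind time
        self.refresh()
        in_loop = np.zeros(self.n, bool)
        in_loop[self.loop_idx] = True
        lp = self.pos[self.loop_idx]
        dmin = np.linalg.norm(self.pos[:, None, :] - lp[None, :, :],
                              axis=-1).min(axis=1)
        self.sasa_set = np.nonzero((in_loop | (dmin < 8.0)) & self.heavy)[0]

    # -- construction helpers ---------------------------------------------
    def _build_bonded(self, structure, loop, nbr):
        cfg = self.model.config
        in_loop = np.zeros(self.n, bool)
        in_loop[self.loop_idx] = True
        resname = {}
        for ccid, r in structure.iter_residues():
            for a in r.atoms:
                resname[(ccid, r.index, a.name)] = r.name
        keys = {v: k for k, v in self.key_index.items()}
        bonds = []
        for ia, ib in self.bond_pairs:
            if not (in_loop[ia] or in_loop[ib]):
                continue
            ka, kb = keys[ia], keys[ib]
            rn = resname[ka]
            ideal_b, _ = _ideal_geometry(rn)
            r0 = ideal_b.get(_name_key((ka[1], ka[2]), (kb[1], kb[2])))
            if r0 is None:
                ideal_b2, _ = _ideal_geometry(resname[kb])
                r0 = ideal_b2.get(_name_key((ka[1], ka[2]), (kb[1], kb[2])))
            if r0 is not None:
                bonds.append((ia, ib, r0))
        self.bonded_bonds = np.array([(a, b) for a, b, _ in bonds], int
                                     ).reshape(-1, 2)
        self.bonded_r0 = np.array([r for _, _, r in bonds])
        angles = []
        for j in range(self.n):
            ns = nbr[j]
            for x in range(len(ns)):
                for y in range(x + 1, len(ns)):
                    a, c = ns[x], ns[y]
                    if not (in_loop[a] or in_loop[j] or in_loop[c]):
                        continue
                    ka, kj, kc = keys[a], keys[j], keys[c]
                    th = None
                    for rn in (resname[kj], resname[ka], resname[kc]):
                        _, ideal_a = _ideal_geometry(rn)
                        th = ideal_a.get(_angle_key(
                            (ka[1], ka[2]), (kj[1], kj[2]), (kc[1], kc[2])))
                        if th is not None:
                            break
                    if th is not None:
                        angles.append((a, j, c, th))
        self.bonded_angles = np.array([(a, j, c) for a, j, c, _ in angles],
                                      int).reshape(-1, 3)
        self.bonded_theta0 = np.radians(np.array([t for *_ , t in angles]))
        # peptide omega quads CA-C-N'-CA' and carbonyl impropers O-CA-N'-C
        omegas, imps = [], []
        cid = loop.chain_id
        for i in range(loop.start - 1, loop.end + 1):
            q = [(cid, i, "CA"), (cid, i, "C"), (cid, i + 1, "N"),
                 (cid, i + 1, "CA")]
            if all(k in self.key_index for k in q):
                quad = [self.key_index[k] for k in q]
                if any(in_loop[t] for t in quad):
                    omegas.append(quad)
            # carbonyl planarity: O sits trans to N(i+1) about the CA-C axis
            p = [(cid, i + 1, "N"), (cid, i, "CA"), (cid, i, "C"),
                 (cid, i, "O")]
            if all(k in self.key_index for k in p):
                quad = [self.key_index[t] for t in p]
                if any(in_loop[t] for t in quad):
                    imps.append(quad)
        self.omega_quads = np.array(omegas, int).reshape(-1, 4)
        self.improper_quads = np.array(imps, int).reshape(-1, 4)

    def _build_hbond(self, structure, loop):
        donors = []   # (H index, parent heavy index)
        accept = []   # (acceptor index, base heavy index)
        nbr = {}
        for ia, ib in self.bond_pairs:
            nbr.setdefault(ia, []).append(ib)
            nbr.setdefault(ib, []).append(ia)
        for i, a in enumerate(self.atoms):
            if a.element == "H":
                parents = [j for j in nbr.get(i, [])
                           if self.atoms[j].element in ("N", "O", "S")]
                if parents:
                    donors.append((i, parents[0]))
            elif a.element == "O" or a.atom_class == "NR":
                bases = [j for j in nbr.get(i, [])
                         if self.atoms[j].element != "H"]
                if bases:
                    accept.append((i, bases[0]))
        in_loop = np.zeros(self.n, bool)
        in_loop[self.loop_idx] = True
        pairs = []
        for (h, d) in donors:
            for (acc, base) in accept:
                if acc == d or acc == h:
                    continue
                if in_loop[h] or in_loop[acc]:
                    pairs.append((h, d, acc, base))
        self.hb_pairs = np.array(pairs, int).reshape(-1, 4)

    def _build_atompair(self):
        sep = np.abs(self.resseq[self.pi] - self.resseq[self.pj])
        heavy = self.heavy[self.pi] & self.heavy[self.pj]
        keep = (sep >= 2) & heavy
        self.ap_i = self.pi[keep]
        self.ap_j = self.pj[keep]
        cls_idx = np.array([PAIR_CLASSES.index(PAIR_CLASS_OF[a.atom_class])
                            if a.atom_class in PAIR_CLASS_OF else -1
                            for a in self.atoms])
        ok = (cls_idx[self.ap_i] >= 0) & (cls_idx[self.ap_j] >= 0)
        self.ap_i = self.ap_i[ok]
        self.ap_j = self.ap_j[ok]
        self.ap_ci = cls_idx[self.ap_i]
        self.ap_cj = cls_idx[self.ap_j]

    def _build_torsion_atoms(self, structure, loop):
        cid = loop.chain_id
        quads = []
        for i in loop.indices:
            quads.append([self.key_index[(cid, i - 1, "C")],
                          self.key_index[(cid, i, "N")],
                          self.key_index[(cid, i, "CA")],
                          self.key_index[(cid, i, "C")]])
            quads.append([self.key_index[(cid, i, "N")],
                          self.key_index[(cid, i, "CA")],
                          self.key_index[(cid, i, "C")],
                          self.key_index[(cid, i + 1, "N")]])
        self.phipsi_quads = np.array(quads, int).reshape(-1, 4)
        self.loop_resnames = [structure.residue(cid, i).name
                              for i in loop.indices]
        chi_quads, chi_meta = [], []
        for i in loop.indices:
            r = structure.residue(cid, i)
            for k, quad in enumerate(r.chi_definitions):
                idxs = [self.key_index.get((cid, i, nm)) for nm in quad]
                if None not in idxs:
                    chi_quads.append(idxs)
                    chi_meta.append((r.name, k))
        self.chi_quads = np.array(chi_quads, int).reshape(-1, 4)
        self.chi_meta = chi_meta

    # -- evaluation --------------------------------------------------------
    def refresh(self):
        for i, a in enumerate(self.atoms):
            self.pos[i] = a.pos

    def evaluate(self) -> EnergyBreakdown:
        self.refresh()
        m = self.model
        w = m.weights
        out = EnergyBreakdown(weights=w)
        if m.include_physics:
            out.e_bonded = self._e_bonded()
            out.e_vdw = self._e_vdw()
            if w.w_electrostatics > 0:
                out.e_coulomb, out.e_gb = self._e_coulomb_gb()
            if w.w_sa > 0:
                out.e_sa = self._e_sa()
        if w.w_phipsi > 0 and m.phipsi_table is not None:
            out.e_phipsi = self._e_phipsi()
        if w.w_chi > 0 and m.chi_table is not None:
            out.e_chi = self._e_chi()
        if w.w_hbond > 0:
            out.e_hbond = self._e_hbond()
        if w.w_atompair > 0 and m.pair_table is not None:
            out.e_atompair = self._e_atompair()
        return out

    def gradient(self) -> np.ndarray:
        """Analytic Cartesian gradient of the gradient-supported part
        (bonded + vdW + w_elec * Coulomb), shape (n_atoms, 3)."""
        self.refresh()
        g = np.zeros_like(self.pos)
        self._e_bonded(grad=g)
        self._e_vdw(grad=g)
        if self.model.weights.w_electrostatics > 0:
            self._e_coulomb(grad=g,
                            scale=self.model.weights.w_electrostatics)
        return g

    def gradient_supported_energy(self) -> float:
        """Energy of exactly the terms covered by :meth:`gradient`."""
        self.refresh()
        e = self._e_bonded() + self._e_vdw()
        if self.model.weights.w_electrostatics > 0:
            e += self.model.weights.w_electrostatics * self._e_coulomb()
        return float(e)

    # bonded ----------------------------------------------------------------
    def _e_bonded(self, grad=None):
        cfg = self.model.config
        p = self.pos
        e = 0.0
        if len(self.bonded_bonds):
            d = p[self.bonded_bonds[:, 0]] - p[self.bonded_bonds[:, 1]]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.bonded_r0
            e += cfg.kb * np.sum(dr ** 2)
            if grad is not None:
                gvec = (2 * cfg.kb * dr / r)[:, None] * d
                np.add.at(grad, self.bonded_bonds[:, 0], gvec)
                np.add.at(grad, self.bonded_bonds[:, 1], -gvec)
        if len(self.bonded_angles):
            ia, ij, ic = (self.bonded_angles[:, k] for k in range(3))
            u = p[ia] - p[ij]
            v = p[ic] - p[ij]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cosr = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
            th = np.arccos(cosr)
            dth = th - self.bonded_theta0
            e += cfg.ka * np.sum(dth ** 2)
            if grad is not None:
                sin = np.sqrt(np.maximum(1 - cosr ** 2, 1e-12))
                uh = u / nu[:, None]
                vh = v / nv[:, None]
                dthi = (cosr[:, None] * uh - vh) / (nu * sin)[:, None]
                dthc = (cosr[:, None] * vh - uh) / (nv * sin)[:, None]
                coef = (2 * cfg.ka * dth)[:, None]
                np.add.at(grad, ia, coef * dthi)
                np.add.at(grad, ic, coef * dthc)
                np.add.at(grad, ij, -coef * (dthi + dthc))
        for quads, which in ((self.omega_quads, "omega"),
                             (self.improper_quads, "imp")):
            if not len(quads):
                continue
            phi, dphi_dx = _dihedral_batch(p, quads, grad is not None)
            if which == "omega":
                e += cfg.komega * np.sum(1.0 - np.cos(2.0 * phi))
                dedphi = cfg.komega * 2.0 * np.sin(2.0 * phi)
            else:
                dev = np.arctan2(np.sin(phi - np.pi), np.cos(phi - np.pi))
                e += cfg.kimp * np.sum(dev ** 2)
                dedphi = 2.0 * cfg.kimp * dev
            if grad is not None:
                for k in range(4):
                    np.add.at(grad, quads[:, k],
                              dedphi[:, None] * dphi_dx[k])
        return float(e)

    # vdW --------------------------------------------------------------------
    def _nb_distances(self):
        d = self.pos[self.nb_i] - self.pos[self.nb_j]
        r = np.linalg.norm(d, axis=1)
        return d, r

    def _e_vdw(self, grad=None):
        cfg = self.model.config
        d, r = self._nb_distances()
        rm = self.rmin[self.nb_i] + self.rmin[self.nb_j]
        eps = np.sqrt(self.eps[self.nb_i] * self.eps[self.nb_j]) * self.nb_scale
        e_pair, de_dr = _lj_capped(r, rm, eps, cfg)
        s, ds = _switch(r, cfg.r_on, cfg.r_off)
        e = float(np.sum(e_pair * s))
        if grad is not None:
            dtot = de_dr * s + e_pair * ds
            gvec = (dtot / r)[:, None] * d
            np.add.at(grad, self.nb_i, gvec)
            np.add.at(grad, self.nb_j, -gvec)
        return e

    # electrostatics ----------------------------------------------------------
    def _e_coulomb(self, grad=None, scale=1.0):
        cfg = self.model.config
        d, r = self._nb_distances()
        qq = (COULOMB_K * self.charge[self.nb_i] * self.charge[self.nb_j]
              * self.nb_scale)
        e_pair = qq / r
        s, ds = _switch(r, cfg.r_on, cfg.r_off)
        e = float(np.sum(e_pair * s))
        if grad is not None:
            dtot = (-qq / r ** 2) * s + e_pair * ds
            gvec = (scale * dtot / r)[:, None] * d
            np.add.at(grad, self.nb_i, gvec)
            np.add.at(grad, self.nb_j, -gvec)
        return e

    def born_radii(self):
        cfg = self.model.config
        p = self.pos
        rho = np.maximum(self.rmin, 0.8)
        s = cfg.born_scale
        diff = p[:, None, :] - p[None, :, :]
        r = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(r, 1.0)  # placeholder; diagonal zeroed below
        sr = s * rho[None, :]
        U = r + sr
        L = np.maximum(rho[:, None], np.abs(r - sr))
        term = 0.5 * (1.0 / L - 1.0 / U
                      + 0.25 * (r - sr ** 2 / r) * (1.0 / U ** 2 - 1.0 / L ** 2)
                      + 0.5 / r * np.log(L / U))
        term[rho[:, None] >= U] = 0.0
        np.fill_diagonal(term, 0.0)
        inv = 1.0 / rho - term.sum(axis=1)
        return 1.0 / np.maximum(inv, 1.0 / 30.0)

    def _e_coulomb_gb(self):
        cfg = self.model.config
        e_c = self._e_coulomb()
        R = self.born_radii()
        tau = 1.0 - 1.0 / cfg.eps_solvent
        # pair part over the loop-region pair list (all pairs incl. excluded;
        # each i<j pair carries the factor 2 of the symmetric double sum)
        d = self.pos[self.pi] - self.pos[self.pj]
        r2 = np.sum(d * d, axis=1)
        RiRj = R[self.pi] * R[self.pj]
        f = np.sqrt(r2 + RiRj * np.exp(-r2 / (4.0 * RiRj)))
        e_gb = -COULOMB_K * tau * float(np.sum(
            self.charge[self.pi] * self.charge[self.pj] / f))
        # self terms for loop atoms
        li = self.loop_idx
        e_gb -= GB_K * tau * float(np.sum(self.charge[li] ** 2 / R[li]))
        return float(e_c), float(e_gb)

    # surface area -------------------------------------------------------------
    def _e_sa(self):
        cfg = self.model.config
        areas = shrake_rupley(self.pos, self.rmin + cfg.sasa_probe,
                              subset=self.sasa_set, n_points=cfg.sasa_points)
        return float(np.sum(self.gamma[self.sasa_set] * areas))

    # hydrogen bonds -------------------------------------------------------------
    def _e_hbond(self):
        if not len(self.hb_pairs):
            return 0.0
        cfg = self.model.config
        h = self.pos[self.hb_pairs[:, 0]]
        dn = self.pos[self.hb_pairs[:, 1]]
        ac = self.pos[self.hb_pairs[:, 2]]
        ab = self.pos[self.hb_pairs[:, 3]]
        return float(hbond_energy(h, dn, ac, ab, cfg))

    # knowledge terms -------------------------------------------------------------
    def _e_atompair(self):
        t = self.model.pair_table
        d = np.linalg.norm(self.pos[self.ap_i] - self.pos[self.ap_j], axis=1)
        return float(np.sum(t.lookup(self.ap_ci, self.ap_cj, d)))

    def _e_phipsi(self):
        t = self.model.phipsi_table
        q = self.phipsi_quads
        vals, _ = _dihedral_batch(self.pos, q, False)
        vals = np.degrees(vals)
        e = 0.0
        for k, name in enumerate(self.loop_resnames):
            e += t.energy(name, vals[2 * k], vals[2 * k + 1])
        return float(e)

    def _e_chi(self):
        if not len(self.chi_quads):
            return 0.0
        t = self.model.chi_table
        vals, _ = _dihedral_batch(self.pos, self.chi_quads, False)
        vals = np.degrees(vals)
        e = 0.0
        for (name, k), v in zip(self.chi_meta, vals):
            e += t.energy(name, k, v)
        return float(e)


# ---------------------------------------------------------------------------
# term helpers
# ---------------------------------------------------------------------------

def _switch(r, r_on, r_off):
    """CHARMM switching function and its derivative."""
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > r_on) & (r < r_off)
    off2, on2 = r_off ** 2, r_on ** 2
    r2 = r[mid] ** 2
    denom = (off2 - on2) ** 3
    s[mid] = (off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2) / denom
    ds[mid] = (2 * (off2 - r2) * (-2 * r[mid]) * (off2 + 2 * r2 - 3 * on2)
               + (off2 - r2) ** 2 * 4 * r[mid]) / denom
    s[r >= r_off] = 0.0
    return s, ds


def _lj_capped(r, rm, eps, cfg):
    """12-6 LJ with linear continuation below cap_factor * rmin."""
    rc = cfg.cap_factor * rm
    rr = np.maximum(r, rc)
    q6 = (rm / rr) ** 6
    e = eps * (q6 * q6 - 2.0 * q6)
    de = -12.0 * eps / rr * (q6 * q6 - q6)
    below = r < rc
    if np.any(below):
        e = np.where(below, e + de * (r - rc), e)
        # de already equals the slope at rc for capped entries
    return e, de


def hbond_energy(h, donor, acceptor, base, cfg: EnergyConfig):
    """Orientation-dependent hydrogen-bond well (Kortemme-style form).

    Sum of a distance well (H...A), a donor-H...A angular well centred at
    linearity, and an H...A-base well centred at 120 deg, gated by a smooth
    distance envelope so the term is C1 and exactly zero beyond the cutoff.
    """
    d = np.linalg.norm(h - acceptor, axis=-1)
    fd = _well(d, cfg.hbond_d0, cfg.hbond_dw)
    th = _angles_deg(donor, h, acceptor)
    fth = _well(th, 180.0, 80.0)
    ps = _angles_deg(h, acceptor, base)
    fps = _well(ps, 120.0, 60.0)
    env = _envelope(d, cfg.hbond_cut - 0.3, cfg.hbond_cut)
    return np.sum(env * (fd + fth + fps))


def _well(x, center, half_width):
    """-cos^2 well: -1 at the centre, exactly 0 with zero slope at edges."""
    t = (x - center) / half_width
    inside = np.abs(t) < 1.0
    return np.where(inside, -np.cos(0.5 * np.pi * np.clip(t, -1, 1)) ** 2, 0.0)


def _envelope(d, start, stop):
    t = (d - start) / (stop - start)
    out = np.cos(0.5 * np.pi * np.clip(t, 0.0, 1.0)) ** 2
    return np.where(t >= 1.0, 0.0, np.where(t <= 0.0, 1.0, out))


def _angles_deg(a, b, c):
    u = a - b
    v = c - b
    cu = np.linalg.norm(u, axis=-1)
    cv = np.linalg.norm(v, axis=-1)
    return np.degrees(np.arccos(np.clip(
        np.sum(u * v, axis=-1) / (cu * cv), -1.0, 1.0)))


def _dihedral_batch(pos, quads, want_grad):
    """Dihedrals (radians) for (m, 4) index quads; optionally the gradients
    with respect to the four atoms (list of four (m, 3) arrays)."""
    p0, p1, p2, p3 = (pos[quads[:, k]] for k in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * (b2 / nb2[:, None]), axis=1)
    phi = np.arctan2(y, x)
    if not want_grad:
        return phi, None
    n1sq = np.sum(n1 * n1, axis=1)
    n2sq = np.sum(n2 * n2, axis=1)
    g0 = -(nb2 / n1sq)[:, None] * n1
    g3 = (nb2 / n2sq)[:, None] * n2
    c12 = (np.sum(b1 * b2, axis=1) / nb2 ** 2)[:, None]
    c32 = (np.sum(b3 * b2, axis=1) / nb2 ** 2)[:, None]
    g1 = -(1.0 + c12) * g0 + c32 * g3
    g2 = c12 * g0 - (1.0 + c32) * g3
    return phi, [g0, g1, g2, g3]


def _canonical_frame(pos):
    """Right-handed principal-axis frame with moment-fixed signs, so sphere
    sampling rotates with the molecule (exact rigid-transform invariance)."""
    x = pos - pos.mean(axis=0)
    w, v = np.linalg.eigh(x.T @ x)
    v = v[:, ::-1]
    for k in range(3):
        if np.sum((x @ v[:, k]) ** 3) < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def shrake_rupley(pos, radii, subset=None, n_points=192):
    """Solvent-accessible surface areas by sphere-point sampling.

    ``radii`` must already include the probe radius.  Returns one area per
    subset atom (A^2).
    """
    n = len(pos)
    subset = np.arange(n) if subset is None else np.asarray(subset)
    # golden-spiral unit sphere, oriented along the molecular frame
    k = np.arange(n_points) + 0.5
    phi = np.arccos(1 - 2 * k / n_points)
    theta = np.pi * (1 + 5 ** 0.5) * k
    sphere = np.stack([np.cos(theta) * np.sin(phi),
                       np.sin(theta) * np.sin(phi),
                       np.cos(phi)], axis=1)
    sphere = sphere @ _canonical_frame(pos).T
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    areas = np.zeros(len(subset))
    for out_i, i in enumerate(subset):
        cand = np.nonzero(d2[i] < (radii[i] + radii) ** 2)[0]
        cand = cand[cand != i]
        pts = pos[i] + radii[i] * sphere
        if len(cand):
            dd = np.sum((pts[:, None, :] - pos[cand][None, :, :]) ** 2,
                        axis=-1)
            buried = np.any(dd < radii[cand][None, :] ** 2, axis=1)
        else:
            buried = np.zeros(n_points, bool)
        areas[out_i] = (4.0 * np.pi * radii[i] ** 2
                        * (n_points - buried.sum()) / n_points)
    return areas


# ---------------------------------------------------------------------------
# the model facade
# ---------------------------------------------------------------------------

class EnergyModel:
    """Weights + parameter tables + configuration; produces bound views."""

    def __init__(self, weights: EnergyWeights | None = None,
                 phipsi_table: PhiPsiTable | None = None,
                 chi_table: ChiTable | None = None,
                 pair_table: PairPotentialTable | None = None,
                 config: EnergyConfig | None = None,
                 include_physics: bool = True):
        self.weights = weights or EnergyWeights()
        self.phipsi_table = phipsi_table
        self.chi_table = chi_table
        self.pair_table = pair_table
        self.config = config or EnergyConfig()
        self.include_physics = include_physics

    @classmethod
    def with_reference_tables(cls, pair_table=None, **kw):
        return cls(phipsi_table=reference_phipsi_table(),
                   chi_table=reference_chi_table(),
                   pair_table=pair_table or PairPotentialTable.zeros(), **kw)

    def bind(self, structure: ProteinStructure,
             loop: LoopDefinition) -> BoundLoopEnergy:
        return BoundLoopEnergy(self, structure, loop)

    def evaluate(self, structure: ProteinStructure,
                 loop: LoopDefinition) -> EnergyBreakdown:
        return self.bind(structure, loop).evaluate()


def _default_bound(structure, loop, **model_kw) -> BoundLoopEnergy:
    return EnergyModel.with_reference_tables(**model_kw).bind(structure, loop)


# -- public per-term functions ------------------------------------------------

def e_bonded(structure, loop_region) -> float:
    b = _default_bound(structure, loop_region)
    b.refresh()
    return b._e_bonded()


def e_vdw(structure, loop_region) -> float:
    b = _default_bound(structure, loop_region)
    b.refresh()
    return b._e_vdw()


def e_coulomb_gb(structure, loop_region):
    b = _default_bound(structure, loop_region)
    b.refresh()
    return b._e_coulomb_gb()


def e_sa(structure, loop_region) -> float:
    b = _default_bound(structure, loop_region)
    b.refresh()
    return b._e_sa()


def e_hbond(structure, loop_region) -> float:
    b = _default_bound(structure, loop_region)
    b.refresh()
    return b._e_hbond()


def e_atompair(structure, loop_region, table: PairPotentialTable) -> float:
    b = _default_bound(structure, loop_region, pair_table=table)
    b.refresh()
    return b._e_atompair()


def e_phipsi(structure, loop_region, table: PhiPsiTable) -> float:
    b = _default_bound(structure, loop_region)
    b.model.phipsi_table = table
    b.refresh()
    return b._e_phipsi()


def e_chi(structure, loop_region, table: ChiTable) -> float:
    b = _default_bound(structure, loop_region)
    b.model.chi_table = table
    b.refresh()
    return b._e_chi()


def total_energy(structure, loop_region, weights: EnergyWeights | None = None,
                 phipsi_table=None, chi_table=None, pair_table=None,
                 config=None) -> EnergyBreakdown:
    model = EnergyModel(weights=weights,
                        phipsi_table=phipsi_table or reference_phipsi_table(),
                        chi_table=chi_table or reference_chi_table(),
                        pair_table=pair_table or PairPotentialTable.zeros(),
                        config=config)
    return model.evaluate(structure, loop_region)
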