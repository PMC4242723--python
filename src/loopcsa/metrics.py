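"""Superposition and evaluation metrics for loop models.

Implements the benchmark conventions used throughout the package:

* loop main-chain RMSD over N, CA, C, O;
* all-atom RMSD minimized over 2-fold symmetric side-chain relabelings
  (ASP, GLU, PHE/TYR rings, ARG, LEU, VAL);
* E-RMSD: the all-atom RMSD of the *environment* (every non-loop residue
  with an atom within 10 A of a loop C-beta) after superposing the
  environment onto the reference — the measure of framework inaccuracy.

Hydrogens are excluded from all RMSD sums by default (methods differ in
their hydrogen models); pass ``include_hydrogens=True`` to keep them.
The distance cutoff is a closed interval: an atom at exactly the cutoff is
inside.  For loop glycines, CA substitutes for the missing C-beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import LoopDefinition, ProteinStructure

__all__ = [
    "RmsdReport",
    "kabsch_superpose",
    "loop_mainchain_rmsd",
    "symmetric_flip_rmsd",
    "environment_residues",
    "e_rmsd",
    "rmsd_report",
]

MAINCHAIN = ("N", "CA", "C", "O")
DEFAULT_ENV_CUTOFF = 10.0  # Angstrom, from loop C-beta atoms

# per-residue 2-fold symmetric atom relabelings
FLIP_GROUPS = {
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
    "ARG": [("NH1", "NH2")],
    "LEU": [("CD1", "CD2")],
    "VAL": [("CG1", "CG2")],
}


@dataclass
class RmsdReport:
    loop_mainchain_rmsd: float
    loop_allatom_rmsd: float
    e_rmsd: float
    n_env_residues: int
    superposition_rms: float

    def as_dict(self):
        return {
            "loop_mainchain_rmsd": self.loop_mainchain_rmsd,
            "loop_allatom_rmsd": self.loop_allatom_rmsd,
            "e_rmsd": self.e_rmsd,
            "n_env_residues": self.n_env_residues,
            "superposition_rms": self.superposition_rms,
        }


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None):
    """Optimal weighted rigid superposition of paired coordinate sets.

    Returns ``(rotation, translation, rms)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD to
    ``reference``.  The rotation is proper (det +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate sets required")
    n = len(mobile)
    if n < 3:
        raise ValueError("at least 3 points required for superposition")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mu_m = w @ mobile
    mu_r = w @ reference
    x = mobile - mu_m
    y = reference - mu_r
    h = x.T @ (y * w[:, None])
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:
        raise ValueError("degenerate (collinear) coordinate set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_r - rot @ mu_m
    moved = x @ rot.T
    rms = float(np.sqrt(np.sum(w * np.sum((moved - y) ** 2, axis=1))))
    return rot, trans, rms


def _loop_set(loop: LoopDefinition) -> set[tuple[str, int]]:
    return {(loop.chain_id, i) for i in loop.indices}


def _matched_coords(model: ProteinStructure, reference: ProteinStructure,
                    residue_keys, atom_filter, include_hydrogens=False):
    """Paired coordinate arrays over matched atoms of the given residues."""
    mdl, ref, names = [], [], []
    for cid, idx in residue_keys:
        rm = model.residue(cid, idx)
        rr = reference.residue(cid, idx)
        if rm.name != rr.name:
            raise ValueError(f"sequence mismatch at {cid}:{idx}: "
                             f"{rm.name} vs {rr.name}")
        for a in rr.atoms:
            if a.element == "H" and not include_hydrogens:
                continue
            if atom_filter is not None and a.name not in atom_filter:
                continue
            if rm.has_atom(a.name):
                mdl.append(rm.atom(a.name).pos)
                ref.append(a.pos)
                names.append((cid, idx, rr.name, a.name))
    return np.array(mdl), np.array(ref), names


def loop_mainchain_rmsd(model: ProteinStructure, reference: ProteinStructure,
                        loop: LoopDefinition,
                        presuperpose_on: str = "none") -> float:
    """Loop RMSD over main-chain atoms N, CA, C, O.

    With ``presuperpose_on="environment"`` the model is first superposed on
    the reference using environment atoms, so environmental error leaks
    into the loop RMSD — the convention used when frameworks are inexact.
    """
    keys = [(loop.chain_id, i) for i in loop.indices]
    mdl, ref, _ = _matched_coords(model, reference, keys, MAINCHAIN)
    if presuperpose_on == "environment":
        env = environment_residues(reference, loop, DEFAULT_ENV_CUTOFF)
        em, er, _ = _matched_coords(model, reference, env, None)
        rot, trans, _ = kabsch_superpose(em, er)
        mdl = mdl @ rot.T + trans
    elif presuperpose_on != "none":
        raise ValueError("presuperpose_on must be 'environment' or 'none'")
    return float(np.sqrt(np.mean(np.sum((mdl - ref) ** 2, axis=1))))


def _flip_residue_sq(rm, rr, include_hydrogens=False):
    """Summed squared deviation for one residue under the best relabeling."""
    pairs = FLIP_GROUPS.get(rr.name, [])
    swap = {}
    for a, b in pairs:
        swap[a] = b
        swap[b] = a
    ident = flip = 0.0
    count = 0
    for a in rr.atoms:
        if a.element == "H" and not include_hydrogens:
            continue
        if not rm.has_atom(a.name):
            continue
        count += 1
        ident += float(np.sum((rm.atom(a.name).pos - a.pos) ** 2))
        alt = swap.get(a.name, a.name)
        if rm.has_atom(alt):
            flip += float(np.sum((rm.atom(alt).pos - a.pos) ** 2))
        else:
            flip += float(np.sum((rm.atom(a.name).pos - a.pos) ** 2))
    best = min(ident, flip) if pairs else ident
    return best, count


def symmetric_flip_rmsd(model: ProteinStructure, reference: ProteinStructure,
                        residue_keys, include_hydrogens: bool = False) -> float:
    """All-atom RMSD minimized over per-residue symmetric relabelings.

    The per-residue greedy choice is exact: residues contribute independent
    sums, so minimizing each residue's contribution minimizes the total.
    """
    total = 0.0
    count = 0
    for cid, idx in residue_keys:
        rm = model.residue(cid, idx)
        rr = reference.residue(cid, idx)
        if rm.name != rr.name:
            raise ValueError(f"sequence mismatch at {cid}:{idx}")
        sq, n = _flip_residue_sq(rm, rr, include_hydrogens)
        total += sq
        count += n
    if count == 0:
        raise ValueError("no matched atoms")
    return float(np.sqrt(total / count))


def environment_residues(structure: ProteinStructure, loop: LoopDefinition,
                         cutoff: float = DEFAULT_ENV_CUTOFF):
    """Non-loop residues with any atom within ``cutoff`` of a loop C-beta.

    CA substitutes for C-beta on loop glycines.  Returns an ordered list of
    ``(chain_id, residue_index)`` keys.  The interval is closed: an atom at
    exactly the cutoff is included.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cb = []
    for i in loop.indices:
        r = structure.residue(loop.chain_id, i)
        if r.has_atom("CB"):
            cb.append(r.atom("CB").pos)
        elif r.has_atom("CA"):
            cb.append(r.atom("CA").pos)
        else:
            raise ValueError(f"loop residue {i} has neither CB nor CA")
    cb = np.array(cb)
    loop_keys = _loop_set(loop)
    selected = []
    for cid, r in structure.iter_residues():
        if (cid, r.index) in loop_keys:
            continue
        pos = np.array([a.pos for a in r.atoms])
        d = np.linalg.norm(pos[:, None, :] - cb[None, :, :], axis=-1)
        if np.min(d) <= cutoff:
            selected.append((cid, r.index))
    return selected


def e_rmsd(model: ProteinStructure, reference: ProteinStructure,
           loop: LoopDefinition, cutoff: float = DEFAULT_ENV_CUTOFF,
           include_hydrogens: bool = False) -> float:
    """Environment accuracy: superpose environment atoms, then all-atom
    RMSD over the environment with symmetric side-chain flips.

    Environment residues are selected on the reference structure (whose
    loop is always present).
    """
    env = environment_residues(reference, loop, cutoff)
    if not env:
        raise ValueError("empty environment selection")
    em, er, _ = _matched_coords(model, reference, env, None, include_hydrogens)
    rot, trans, _ = kabsch_superpose(em, er)
    moved = model.copy()
    for cid, r in moved.iter_residues():
        for a in r.atoms:
            a.pos = rot @ a.pos + trans
    return symmetric_flip_rmsd(moved, reference, env, include_hydrogens)


def rmsd_report(model: ProteinStructure, reference: ProteinStructure,
                loop: LoopDefinition,
                cutoff: float = DEFAULT_ENV_CUTOFF) -> RmsdReport:
    """Full evaluation of a loop model against its reference."""
    env = environment_residues(reference, loop, cutoff)
    loop_keys = [(loop.chain_id, i) for i in loop.indices]
    sup_rms = np.nan
    model_sup = model
    if env:
        em, er, _ = _matched_coords(model, reference, env, None)
        rot, trans, sup_rms = kabsch_superpose(em, er)
        model_sup = model.copy()
        for cid, r in model_sup.iter_residues():
            for a in r.atoms:
                a.pos = rot @ a.pos + trans
    mc = loop_mainchain_rmsd(model_sup, reference, loop, presuperpose_on="none")
    aa = symmetric_flip_rmsd(model_sup, reference, loop_keys)
    er_val = e_rmsd(model, reference, loop, cutoff) if env else np.nan
    return RmsdReport(mc, aa, er_val, len(env), float(sup_rms))
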