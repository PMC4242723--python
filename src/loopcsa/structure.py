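"""Protein structure data model, PDB I/O and internal-coordinate machinery.

The model is deliberately small: a :class:`ProteinStructure` is an ordered
set of chains of :class:`Residue` objects holding :class:`Atom` records in
a polar-hydrogen (united-atom) representation.  Loops are identified by a
:class:`LoopDefinition` (chain + 1-based inclusive residue range) and their
degrees of freedom are carried by a :class:`TorsionState`.

Torsion conventions
-------------------
IUPAC dihedrals in degrees, wrapped to (-180, 180].  For loop residue ``i``:

* ``phi[i]``   = C(i-1)-N(i)-CA(i)-C(i)
* ``psi[i]``   = N(i)-CA(i)-C(i)-N(i+1)
* ``omega[i]`` = CA(i)-C(i)-N(i+1)-CA(i+1)   (the peptide bond *following* i)

``pre_psi``/``pre_omega`` hold the fixed torsions of the N-side anchor that
position the first loop N and CA during a rebuild.  Rebuilds use ideal bond
lengths/angles (chain extension), so the C-side anchor is generally not met
until a closure step adjusts pivot torsions.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import topology as topo
from .geom import dihedral, place_atom, wrap_angle
from .params import default_parameters

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "LoopDefinition",
    "TorsionState",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "build_polar_hydrogen_topology",
    "torsions_from_coords",
    "coords_from_torsions",
    "build_chain_from_torsions",
]

CHAIN_BREAK_CN = 2.5  # Angstrom; larger C(i)-N(i+1) distances break the chain


class StructureError(ValueError):
    """Raised for invalid or incomplete structures."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    partial_charge: float = 0.0
    vdw_radius: float = 0.0     # Lennard-Jones rmin/2, Angstrom
    epsilon: float = 0.0        # kcal/mol
    gamma_sa: float = 0.0       # kcal/mol/A^2
    atom_class: str = ""
    occupancy: float = 1.0

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy(), self.partial_charge,
                    self.vdw_radius, self.epsilon, self.gamma_sa, self.atom_class,
                    self.occupancy)


class Residue:
    """One amino-acid residue; ``index`` is its 1-based sequence position."""

    def __init__(self, index: int, name: str, atoms=None, is_cis_proline=False):
        self.index = int(index)
        self.name = name
        self.atoms: list[Atom] = list(atoms or [])
        self.is_cis_proline = is_cis_proline

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name}{self.index} has no atom {name}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def remove_atom(self, name: str) -> None:
        self.atoms = [a for a in self.atoms if a.name != name]

    @property
    def chi_definitions(self):
        return topo.RESIDUE_TEMPLATES[self.name]["chi"] if self.name in topo.RESIDUE_TEMPLATES else []

    def copy(self) -> "Residue":
        return Residue(self.index, self.name, [a.copy() for a in self.atoms],
                       self.is_cis_proline)

    def __repr__(self):
        return f"<Residue {self.name}{self.index} ({len(self.atoms)} atoms)>"


class ProteinStructure:
    """Chains of residues plus bonded topology and provenance."""

    def __init__(self, chains=None, source: str = ""):
        self.chains: "OrderedDict[str, list[Residue]]" = OrderedDict(chains or {})
        self.source = source
        # bonds as ((chain, res_index, atom_name), (chain, res_index, atom_name))
        self.bonds: list[tuple[tuple, tuple]] = []
        self.chain_breaks: set[tuple[str, int]] = set()  # break after (chain, index)

    # -- accessors ---------------------------------------------------------
    def residues(self, chain_id: str) -> list[Residue]:
        return self.chains[chain_id]

    def residue(self, chain_id: str, index: int) -> Residue:
        for r in self.chains[chain_id]:
            if r.index == index:
                return r
        raise KeyError(f"no residue {index} in chain {chain_id}")

    def has_residue(self, chain_id: str, index: int) -> bool:
        return chain_id in self.chains and any(r.index == index for r in self.chains[chain_id])

    def atom(self, chain_id: str, index: int, name: str) -> Atom:
        return self.residue(chain_id, index).atom(name)

    def iter_residues(self):
        for cid, residues in self.chains.items():
            for r in residues:
                yield cid, r

    def iter_atoms(self):
        for cid, r in self.iter_residues():
            for a in r.atoms:
                yield cid, r, a

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    def copy(self) -> "ProteinStructure":
        s = ProteinStructure(
            OrderedDict((cid, [r.copy() for r in res]) for cid, res in self.chains.items()),
            source=self.source,
        )
        s.bonds = list(self.bonds)
        s.chain_breaks = set(self.chain_breaks)
        return s


@dataclass(frozen=True)
class LoopDefinition:
    chain_id: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1

    @property
    def indices(self):
        return range(self.start, self.end + 1)

    def validate(self, structure: ProteinStructure) -> None:
        if not (3 <= self.n_residues <= 20):
            raise StructureError(f"loop length {self.n_residues} outside [3, 20]")
        for idx in (self.start - 1, self.end + 1):
            if not structure.has_residue(self.chain_id, idx):
                raise StructureError(f"anchor residue {self.chain_id}:{idx} missing")
        for cid, idx in structure.chain_breaks:
            if cid == self.chain_id and self.start - 1 <= idx <= self.end:
                raise StructureError("loop spans a chain break")

    @classmethod
    def from_string(cls, spec: str) -> "LoopDefinition":
        """Parse 'CHAIN:START-END' (1-based inclusive)."""
        chain, _, rng = spec.partition(":")
        lo, _, hi = rng.partition("-")
        if not (chain and lo and hi):
            raise ValueError(f"bad loop spec {spec!r}; expected CHAIN:START-END")
        return cls(chain, int(lo), int(hi))


@dataclass
class TorsionState:
    """Mutable torsional degrees of freedom of one loop."""

    start: int                      # first loop residue index
    phi: np.ndarray                 # (n,)
    psi: np.ndarray                 # (n,)
    omega: np.ndarray               # (n,), omega[i] follows residue start+i
    chi: dict = field(default_factory=dict)  # residue index -> np.ndarray
    pre_psi: float = 140.0          # anchor psi placing the first loop N
    pre_omega: float = 180.0        # anchor peptide omega placing the first CA

    @property
    def n(self) -> int:
        return len(self.phi)

    def copy(self) -> "TorsionState":
        return TorsionState(self.start, self.phi.copy(), self.psi.copy(),
                            self.omega.copy(),
                            {k: v.copy() for k, v in self.chi.items()},
                            self.pre_psi, self.pre_omega)

    def backbone_vector(self) -> np.ndarray:
        return np.concatenate([self.phi, self.psi])

    def validate(self) -> None:
        for arr in (self.phi, self.psi, self.omega):
            if np.any(~np.isfinite(arr)) or np.any(arr <= -180.0) or np.any(arr > 180.0):
                raise ValueError("torsions must be finite and in (-180, 180]")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path, model_index: int = 0) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Alternate locations are resolved to the highest occupancy (ties broken
    by altLoc letter); heteroatoms and non-standard residues are skipped
    with a warning; a missing backbone atom raises :class:`StructureError`.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no coordinate models")
    model = st[model_index]
    out = ProteinStructure(source=str(path))
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.name not in topo.RESIDUE_TEMPLATES:
                warnings.warn(f"skipping non-standard residue {res.name} "
                              f"{chain.name}:{res.seqid.num}")
                continue
            if res.seqid.icode not in ("", " "):
                warnings.warn(f"skipping residue with insertion code "
                              f"{chain.name}:{res.seqid.num}{res.seqid.icode}")
                continue
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None or (at.occ, -ord(at.altloc or "A")) > (
                        prev.occ, -ord(prev.altloc or "A")):
                    by_name[at.name] = at
            atoms = [
                Atom(name=a.name, element=topo.element_of(a.name),
                     pos=np.array([a.pos.x, a.pos.y, a.pos.z]), occupancy=a.occ)
                for a in by_name.values()
            ]
            r = Residue(res.seqid.num, res.name, atoms)
            for bb in ("N", "CA", "C", "O"):
                if not r.has_atom(bb):
                    raise StructureError(
                        f"residue {res.name} {chain.name}:{res.seqid.num} "
                        f"is missing backbone atom {bb}")
            residues.append(r)
        if residues:
            out.chains[chain.name] = residues
    if out.n_residues == 0:
        raise StructureError(f"{path}: no standard protein residues")
    _detect_chain_breaks(out)
    return out


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write standard ATOM/TER records (residue numbering preserved)."""
    if structure.n_atoms == 0:
        raise StructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = "loopcsa"
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.index, " ")
            for a in r.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.pos)
                at.occ = a.occupancy
                at.b_iso = 0.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _detect_chain_breaks(structure: ProteinStructure) -> None:
    structure.chain_breaks.clear()
    for cid, residues in structure.chains.items():
        for r0, r1 in zip(residues, residues[1:]):
            try:
                d = np.linalg.norm(r1.atom("N").pos - r0.atom("C").pos)
            except KeyError:
                d = np.inf
            if d > CHAIN_BREAK_CN or r1.index != r0.index + 1:
                structure.chain_breaks.add((cid, r0.index))


# ---------------------------------------------------------------------------
# polar-hydrogen topology
# ---------------------------------------------------------------------------

def _assign_params(residue: Residue) -> None:
    params = default_parameters()
    tpl = topo.RESIDUE_TEMPLATES[residue.name]
    classes = dict(topo.BACKBONE_CLASSES)
    classes.update(topo.BACKBONE_CLASS_OVERRIDES.get(residue.name, {}))
    for entry in tpl["sidechain"]:
        classes[entry[0]] = entry[1]
    for a in residue.atoms:
        cls = classes.get(a.name)
        if cls is None:
            raise StructureError(f"atom {a.name} of {residue.name}{residue.index} "
                                 f"has no atom class")
        p = params[cls]
        a.atom_class = cls
        a.partial_charge = p.charge
        a.vdw_radius = p.rmin_half
        a.epsilon = p.epsilon
        a.gamma_sa = p.gamma_sa


def measure_chi(residue: Residue) -> np.ndarray:
    """Chi torsions measurable from the present atoms (NaN when incomplete)."""
    vals = []
    for quad in residue.chi_definitions:
        try:
            pts = [residue.atom(n).pos for n in quad]
            vals.append(dihedral(*pts))
        except KeyError:
            vals.append(np.nan)
    return np.array(vals)


def rebuild_sidechain(residue: Residue, chi: np.ndarray | None = None) -> None:
    """(Re)build all side-chain atoms (and polar H) at the given chi angles.

    Missing chi values fall back to the residue's most common rotamer.
    Backbone atoms must be present; existing side-chain atoms are replaced.
    """
    tpl = topo.RESIDUE_TEMPLATES[residue.name]
    rot = np.array(tpl["rotamer"], float)
    if chi is None:
        chi = rot.copy()
    chi = np.asarray(chi, float).copy()
    if len(chi) < len(rot):
        chi = np.concatenate([chi, rot[len(chi):]])
    bad = ~np.isfinite(chi[: len(rot)]) if len(rot) else np.zeros(0, bool)
    if len(rot):
        chi[: len(rot)][bad] = rot[bad]
    keep = [a for a in residue.atoms if a.name in ("N", "CA", "C", "O", "H")]
    existing = {a.name: a for a in residue.atoms}
    placed = {a.name: a.pos for a in keep}
    new_atoms = list(keep)
    for entry in tpl["sidechain"]:
        name, cls, refs, bond, angle, dih = entry
        if isinstance(dih, tuple):
            _, k, off = dih
            value = wrap_angle(chi[k - 1] + off)
        else:
            value = dih
        pos = place_atom(placed[refs[0]], placed[refs[1]], placed[refs[2]],
                         bond, angle, value)
        placed[name] = pos
        if name in existing:  # keep object identity for bound energy views
            atom = existing[name]
            atom.pos = pos
        else:
            atom = Atom(name=name, element=topo.element_of(name), pos=pos)
        new_atoms.append(atom)
    residue.atoms = new_atoms
    _assign_params(residue)


def _place_amide_h(residue: Residue, prev_c: np.ndarray | None) -> None:
    if residue.name == "PRO":
        return
    n, ca, c = (residue.atom(x).pos for x in ("N", "CA", "C"))
    if prev_c is not None:
        dih = wrap_angle(dihedral(c, ca, n, prev_c) - 180.0)
    else:
        dih = 180.0  # chain terminus: anti to C
    pos = place_atom(c, ca, n, topo.BOND_N_H, topo.ANGLE_CA_N_H, dih)
    if residue.has_atom("H"):
        residue.atom("H").pos = pos
    else:
        residue.atoms.insert(1, Atom("H", "H", pos))


def build_polar_hydrogen_topology(structure: ProteinStructure) -> ProteinStructure:
    """Return a copy with polar hydrogens, parameters and bonds assigned.

    Hydrogens on N/O/S are placed at ideal geometry; carbon-bound hydrogens
    are absent (united atoms).  Missing side-chain heavy atoms are rebuilt
    at measurable chi values, falling back to the most common rotamer.
    Idempotent: applying twice equals applying once.
    """
    out = structure.copy()
    _detect_chain_breaks(out)
    for cid, residues in out.chains.items():
        for prev, r in zip([None] + residues[:-1], residues):
            if r.name not in topo.RESIDUE_TEMPLATES:
                raise StructureError(f"unknown residue name {r.name}")
            for bb in ("N", "CA", "C", "O"):
                if not r.has_atom(bb):
                    raise StructureError(
                        f"residue {r.name} {cid}:{r.index} missing backbone {bb}")
            expected = set(topo.expected_atom_names(r.name))
            # drop nonpolar hydrogens and unknown atoms
            r.atoms = [a for a in r.atoms if a.name in expected]
            heavy_needed = topo.heavy_sidechain_atoms(r.name)
            if (not all(r.has_atom(n) for n in heavy_needed)) or \
               (not all(r.has_atom(n) for n in topo.polar_hydrogens(r.name))):
                rebuild = not all(r.has_atom(n) for n in heavy_needed)
                chi = measure_chi(r)
                if rebuild:
                    rebuild_sidechain(r, chi)
                else:  # only polar H missing: rebuild preserves heavy geometry
                    rebuild_sidechain(r, chi)
            linked = prev is not None and (cid, prev.index) not in out.chain_breaks
            _place_amide_h(r, prev.atom("C").pos if linked else None)
            _assign_params(r)
            # cis-proline flag from the preceding peptide omega
            if r.name == "PRO" and linked and prev.has_atom("CA"):
                om = dihedral(prev.atom("CA").pos, prev.atom("C").pos,
                              r.atom("N").pos, r.atom("CA").pos)
                r.is_cis_proline = abs(om) < 30.0
    _build_bonds(out)
    return out


def _build_bonds(structure: ProteinStructure) -> None:
    bonds = []
    for cid, residues in structure.chains.items():
        for r in residues:
            ref = lambda name, _r=r: (cid, _r.index, name)
            for pair in [("N", "CA"), ("CA", "C"), ("C", "O")]:
                bonds.append((ref(pair[0]), ref(pair[1])))
            if r.has_atom("H"):
                bonds.append((ref("N"), ref("H")))
            for a, b in topo.RESIDUE_TEMPLATES[r.name]["bonds"]:
                if r.has_atom(a) and r.has_atom(b):
                    bonds.append((ref(a), ref(b)))
        for r0, r1 in zip(residues, residues[1:]):
            if (cid, r0.index) not in structure.chain_breaks:
                bonds.append(((cid, r0.index, "C"), (cid, r1.index, "N")))
    structure.bonds = bonds


# ---------------------------------------------------------------------------
# torsions <-> coordinates
# ---------------------------------------------------------------------------

def torsions_from_coords(structure: ProteinStructure, loop: LoopDefinition) -> TorsionState:
    """Measure the loop's torsional state from Cartesian coordinates."""
    loop.validate(structure)
    cid = loop.chain_id
    n = loop.n_residues
    phi = np.zeros(n)
    psi = np.zeros(n)
    omega = np.zeros(n)
    chi = {}
    pos = lambda idx, name: structure.atom(cid, idx, name).pos
    for j, i in enumerate(loop.indices):
        phi[j] = dihedral(pos(i - 1, "C"), pos(i, "N"), pos(i, "CA"), pos(i, "C"))
        psi[j] = dihedral(pos(i, "N"), pos(i, "CA"), pos(i, "C"), pos(i + 1, "N"))
        omega[j] = dihedral(pos(i, "CA"), pos(i, "C"), pos(i + 1, "N"), pos(i + 1, "CA"))
        r = structure.residue(cid, i)
        if r.chi_definitions:
            chi[i] = measure_chi(r)
    s = loop.start
    pre_psi = dihedral(pos(s - 1, "N"), pos(s - 1, "CA"), pos(s - 1, "C"), pos(s, "N"))
    pre_omega = dihedral(pos(s - 1, "CA"), pos(s - 1, "C"), pos(s, "N"), pos(s, "CA"))
    return TorsionState(loop.start, phi, psi, omega, chi, pre_psi, pre_omega)


def coords_from_torsions(structure: ProteinStructure, loop: LoopDefinition,
                         torsions: TorsionState, in_place: bool = False
                         ) -> ProteinStructure:
    """Rebuild loop atoms from torsions by ideal-geometry chain extension.

    The chain grows from the N-side anchor; environment atoms are untouched
    and the C-side anchor is generally *not* matched (closure is separate).
    """
    out = structure if in_place else structure.copy()
    cid = loop.chain_id
    anchor = out.residue(cid, loop.start - 1)
    a_n, a_ca, a_c = (anchor.atom(x).pos for x in ("N", "CA", "C"))
    # N and CA of the first loop residue, from the fixed anchor torsions
    n_pos = place_atom(a_n, a_ca, a_c, topo.BOND_C_N, topo.ANGLE_CA_C_N,
                       torsions.pre_psi)
    ca_pos = place_atom(a_ca, a_c, n_pos, topo.BOND_N_CA, topo.ANGLE_C_N_CA,
                        torsions.pre_omega)
    prev_c = a_c
    prev = (a_ca, a_c)  # CA(i-1), C(i-1) for the next extension step
    for j, i in enumerate(loop.indices):
        r = out.residue(cid, i)
        c_pos = place_atom(prev_c, n_pos, ca_pos, topo.BOND_CA_C,
                           topo.ANGLE_N_CA_C, torsions.phi[j])
        o_pos = place_atom(n_pos, ca_pos, c_pos, topo.BOND_C_O,
                           topo.ANGLE_CA_C_O, wrap_angle(torsions.psi[j] + 180.0))
        _set_atom(r, "N", n_pos)
        _set_atom(r, "CA", ca_pos)
        _set_atom(r, "C", c_pos)
        _set_atom(r, "O", o_pos)
        rebuild_sidechain(r, torsions.chi.get(i))
        _place_amide_h(r, prev_c)
        # extend to the next residue
        next_n = place_atom(n_pos, ca_pos, c_pos, topo.BOND_C_N,
                            topo.ANGLE_CA_C_N, torsions.psi[j])
        next_ca = place_atom(ca_pos, c_pos, next_n, topo.BOND_N_CA,
                             topo.ANGLE_C_N_CA, torsions.omega[j])
        prev_c, n_pos, ca_pos = c_pos, next_n, next_ca
    return out


def _set_atom(residue: Residue, name: str, pos: np.ndarray) -> None:
    if residue.has_atom(name):
        residue.atom(name).pos = np.asarray(pos, float)
    else:
        residue.atoms.append(Atom(name, topo.element_of(name), np.asarray(pos, float)))


def rebuilt_anchor_positions(structure: ProteinStructure, loop: LoopDefinition,
                             torsions: TorsionState) -> dict[str, np.ndarray]:
    """Positions of N/CA of the C-side anchor implied by the loop torsions.

    Used to verify closure: an exactly closed state reproduces the anchor's
    actual N and CA coordinates (and, through the anchor's own phi, its C).
    """
    tmp = coords_from_torsions(structure, loop, torsions)
    cid = loop.chain_id
    e = loop.end
    anchor = structure.residue(cid, e + 1)
    # use the anchor's own N-CA bond length so that an exactly closed state
    # reproduces the anchor CA even for slightly non-ideal input geometry
    nca_bond = float(np.linalg.norm(anchor.atom("CA").pos - anchor.atom("N").pos))
    n_pos = place_atom(tmp.atom(cid, e, "N").pos, tmp.atom(cid, e, "CA").pos,
                       tmp.atom(cid, e, "C").pos, topo.BOND_C_N,
                       topo.ANGLE_CA_C_N, torsions.psi[-1])
    ca_pos = place_atom(tmp.atom(cid, e, "CA").pos, tmp.atom(cid, e, "C").pos,
                        n_pos, nca_bond, topo.ANGLE_C_N_CA,
                        torsions.omega[-1])
    return {"N": n_pos, "CA": ca_pos}


def closure_error(structure: ProteinStructure, loop: LoopDefinition,
                  torsions: TorsionState) -> float:
    """Max |rebuilt - actual| over the C-anchor N and CA positions (Angstrom)."""
    got = rebuilt_anchor_positions(structure, loop, torsions)
    cid = loop.chain_id
    err = 0.0
    for name in ("N", "CA"):
        actual = structure.atom(cid, loop.end + 1, name).pos
        err = max(err, float(np.linalg.norm(got[name] - actual)))
    return err


# ---------------------------------------------------------------------------
# de novo chain building (used by the fixture generators)
# ---------------------------------------------------------------------------

def build_chain_from_torsions(sequence: str, phi, psi, omega=None,
                              chain_id: str = "A",
                              chi: dict | None = None) -> ProteinStructure:
    """Build a full chain from scratch at ideal geometry.

    ``sequence`` is one-letter code; ``phi``/``psi`` are per-residue arrays
    (phi of the first and psi of the last residue are ignored for geometry
    but recorded implicitly by the build).  Side chains are placed at the
    most common rotamer unless ``chi`` supplies values per residue index.
    """
    n = len(sequence)
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    omega = np.full(n, 180.0) if omega is None else np.asarray(omega, float)
    if not (len(phi) == len(psi) == len(omega) == n):
        raise ValueError("sequence and torsion arrays disagree in length")
    names = [topo.ONE_TO_THREE[c] for c in sequence.upper()]
    residues = [Residue(i + 1, nm) for i, nm in enumerate(names)]
    # seed frame for residue 1
    n_pos = np.array([0.0, 0.0, 0.0])
    ca_pos = np.array([topo.BOND_N_CA, 0.0, 0.0])
    c_pos = place_atom(n_pos + np.array([0.0, -1.0, 0.0]), n_pos, ca_pos,
                       topo.BOND_CA_C, topo.ANGLE_N_CA_C, phi[0] if n else 0.0)
    prev_c = None
    for j, r in enumerate(residues):
        if j > 0:
            c_pos = place_atom(prev_c, n_pos, ca_pos, topo.BOND_CA_C,
                               topo.ANGLE_N_CA_C, phi[j])
        o_pos = place_atom(n_pos, ca_pos, c_pos, topo.BOND_C_O,
                           topo.ANGLE_CA_C_O, wrap_angle(psi[j] + 180.0))
        _set_atom(r, "N", n_pos)
        _set_atom(r, "CA", ca_pos)
        _set_atom(r, "C", c_pos)
        _set_atom(r, "O", o_pos)
        rebuild_sidechain(r, None if chi is None else chi.get(j + 1))
        _place_amide_h(r, prev_c)
        next_n = place_atom(n_pos, ca_pos, c_pos, topo.BOND_C_N,
                            topo.ANGLE_CA_C_N, psi[j])
        next_ca = place_atom(ca_pos, c_pos, next_n, topo.BOND_N_CA,
                             topo.ANGLE_C_N_CA, omega[j])
        prev_c, n_pos, ca_pos = c_pos, next_n, next_ca
    st = ProteinStructure(OrderedDict([(chain_id, residues)]), source="built")
    return build_polar_hydrogen_topology(st)
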