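"""Knowledge-based statistical potentials: backbone phi/psi and side-chain
chi torsion tables, and the distance-binned atom-pair potential of mean
force with an ideal-gas r^alpha reference (DFIRE-style, distance-only).

Tables store -ln(frequency) on 10-degree torsion bins (periodic) or 0.5 A
distance bins (0-15 A, last bin is the zero reference).  Torsion tables are
interpolated periodically (bicubic by default, bilinear on request);
derivations add a pseudocount of 1 per bin so every entry is finite.

Default tables are generated analytically from mixtures of wrapped
Gaussians over the canonical Ramachandran/rotamer basins, keeping the
package self-contained; `derive_*` functions build tables from any set of
training structures instead.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure import ProteinStructure, measure_chi
from .geom import dihedral

__all__ = [
    "RT",
    "PhiPsiTable",
    "ChiTable",
    "PairPotentialTable",
    "derive_torsion_tables",
    "derive_pair_potential",
    "pair_counts_to_potential",
    "reference_phipsi_table",
    "reference_chi_table",
    "PAIR_CLASS_OF",
]

RT = 0.5917            # kcal/mol at T = 298 K
TORSION_BIN = 10.0     # degrees
N_TORSION_BINS = 36
PAIR_BIN = 0.5         # Angstrom
PAIR_RCUT = 15.0       # Angstrom
N_PAIR_BINS = int(round(PAIR_RCUT / PAIR_BIN))

# coarse atom-class grouping for the pair potential (heavy atoms only);
# grouping keeps the count matrix dense at fixture-scale training sets
PAIR_CLASS_OF = {
    "CT1": "CAL", "CT1P": "CAL", "CT1S": "CAL", "CT2": "CAL",
    "CT2P": "CAL", "CT3": "CAL",
    "CAH": "CAR", "CAN": "CAR", "CAP": "CAR", "CRP": "CAR",
    "C": "CCO", "CCARB": "CCO", "CR": "CCO",
    "NH1": "NPO", "NH2": "NPO", "NR": "NPO", "NP": "NPO",
    "NH3": "NCH", "NC2": "NCH",
    "O": "OPO", "OH1": "OPO",
    "OC": "OCH",
    "S": "S", "S1": "S",
}
PAIR_CLASSES = ("CAL", "CAR", "CCO", "NPO", "NCH", "OPO", "OCH", "S")


def _wrap_index(angles_deg):
    """Fractional bin coordinates for periodic map_coordinates lookups."""
    return (np.asarray(angles_deg, float) + 180.0) / TORSION_BIN - 0.5


class _PeriodicGrid:
    """Periodic interpolation of one -ln(f) grid (1D or 2D)."""

    def __init__(self, values: np.ndarray, mode: str = "bicubic"):
        self.values = np.asarray(values, float)
        self.mode = mode
        if mode == "bicubic":
            self._coeff = ndimage.spline_filter(self.values, order=3,
                                                mode="grid-wrap")
            self._order = 3
        elif mode == "bilinear":
            self._coeff = self.values
            self._order = 1
        else:
            raise ValueError("interpolation must be 'bicubic' or 'bilinear'")

    def __call__(self, *angles):
        coords = np.broadcast_arrays(*(np.atleast_1d(_wrap_index(a))
                                       for a in angles))
        shape = coords[0].shape
        stacked = np.stack([c.ravel() for c in coords])
        out = ndimage.map_coordinates(self._coeff, stacked,
                                      order=self._order, mode="grid-wrap",
                                      prefilter=False).reshape(shape)
        scalar = all(np.ndim(a) == 0 for a in angles)
        return float(out[0]) if scalar else out


def _normalize(grid: np.ndarray) -> np.ndarray:
    """Shift -ln f so the bin probabilities sum to one."""
    p = np.exp(-grid)
    return grid + np.log(p.sum())


class PhiPsiTable:
    """Residue-class x 36x36 grid of -ln(frequency) over (phi, psi)."""

    def __init__(self, grids: dict[str, np.ndarray], class_map=None,
                 interpolation: str = "bicubic"):
        self.grids = {k: _normalize(np.asarray(v, float)) for k, v in grids.items()}
        self.class_map = class_map or {}
        self.interpolation = interpolation
        self._interp = {k: _PeriodicGrid(v, interpolation)
                        for k, v in self.grids.items()}

    def class_for(self, resname: str) -> str:
        if resname in self.class_map:
            return self.class_map[resname]
        if resname in self.grids:
            return resname
        return "generic"

    def energy(self, resname: str, phi, psi):
        """Interpolated -ln f at (phi, psi) degrees."""
        return self._interp[self.class_for(resname)](phi, psi)

    def check_normalization(self, tol: float = 1e-6) -> bool:
        return all(abs(np.exp(-g).sum() - 1.0) < tol for g in self.grids.values())

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# phi/psi statistical table: class phi_bin psi_bin value\n")
            centers = -180.0 + TORSION_BIN * (np.arange(N_TORSION_BINS) + 0.5)
            for cls, grid in sorted(self.grids.items()):
                for i, ph in enumerate(centers):
                    for j, ps in enumerate(centers):
                        fh.write(f"{cls} {ph:.1f} {ps:.1f} {grid[i, j]:.8f}\n")

    @classmethod
    def from_text(cls, path, class_map=None, interpolation="bicubic"):
        grids: dict[str, np.ndarray] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, ph, ps, v = line.split()
                g = grids.setdefault(name, np.zeros((N_TORSION_BINS, N_TORSION_BINS)))
                i = int((float(ph) + 180.0) // TORSION_BIN)
                j = int((float(ps) + 180.0) // TORSION_BIN)
                g[i, j] = float(v)
        return cls(grids, class_map, interpolation)


class ChiTable:
    """Residue-class x chi-index -> periodic -ln(frequency) profile."""

    def __init__(self, profiles: dict[str, list[np.ndarray]], class_map=None,
                 interpolation: str = "bicubic"):
        self.profiles = {k: [_normalize(np.asarray(p, float)) for p in v]
                         for k, v in profiles.items()}
        self.class_map = class_map or {}
        self.interpolation = interpolation
        self._interp = {k: [_PeriodicGrid(p, interpolation) for p in v]
                        for k, v in self.profiles.items()}

    def class_for(self, resname: str) -> str:
        if resname in self.class_map:
            return self.class_map[resname]
        if resname in self.profiles:
            return resname
        return "generic"

    def energy(self, resname: str, chi_index: int, chi):
        """Interpolated -ln f for chi torsion ``chi_index`` (0-based)."""
        profs = self._interp[self.class_for(resname)]
        k = min(chi_index, len(profs) - 1)
        return profs[k](chi)

    def check_normalization(self, tol: float = 1e-6) -> bool:
        return all(abs(np.exp(-p).sum() - 1.0) < tol
                   for v in self.profiles.values() for p in v)


class PairPotentialTable:
    """Atom-class pair x 0.5 A distance bin -> energy (kcal/mol).

    The last bin is the reference state and is exactly zero for every pair;
    distances beyond ``r_cut`` contribute nothing.
    """

    def __init__(self, u: np.ndarray, classes=PAIR_CLASSES,
                 bin_width: float = PAIR_BIN, r_cut: float = PAIR_RCUT):
        self.u = np.asarray(u, float)          # (C, C, B)
        self.classes = tuple(classes)
        self.bin_width = bin_width
        self.r_cut = r_cut
        c = len(self.classes)
        if self.u.shape[:2] != (c, c):
            raise ValueError("pair table shape does not match class count")
        if not np.allclose(self.u[:, :, -1], 0.0):
            raise ValueError("reference (last) bin must be zero")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("pair table must be finite")
        self.class_index = {c: i for i, c in enumerate(self.classes)}

    @property
    def n_bins(self) -> int:
        return self.u.shape[2]

    def lookup(self, ci, cj, r):
        """Vectorized energy lookup for class-index arrays and distances."""
        r = np.asarray(r, float)
        bins = np.minimum((r / self.bin_width).astype(int), self.n_bins - 1)
        out = self.u[ci, cj, bins]
        return np.where(r < self.r_cut, out, 0.0)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# atom-pair potential: class_i class_j r_center value\n")
            centers = self.bin_width * (np.arange(self.n_bins) + 0.5)
            for i, ci in enumerate(self.classes):
                for j, cj in enumerate(self.classes):
                    if j < i:
                        continue
                    for b, r in enumerate(centers):
                        fh.write(f"{ci} {cj} {r:.2f} {self.u[i, j, b]:.8f}\n")

    @classmethod
    def from_text(cls, path):
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rows.append(line.split())
        classes = tuple(sorted({r[0] for r in rows} | {r[1] for r in rows}))
        idx = {c: i for i, c in enumerate(classes)}
        nb = len({r[2] for r in rows})
        u = np.zeros((len(classes), len(classes), nb))
        bw = PAIR_BIN
        for ci, cj, r, v in rows:
            b = int(float(r) / bw)
            u[idx[ci], idx[cj], b] = float(v)
            u[idx[cj], idx[ci], b] = float(v)
        return cls(u, classes, bw, bw * nb)

    @classmethod
    def zeros(cls):
        c = len(PAIR_CLASSES)
        return cls(np.zeros((c, c, N_PAIR_BINS)))


# ---------------------------------------------------------------------------
# derivations
# ---------------------------------------------------------------------------

def pair_counts_to_potential(counts: np.ndarray, alpha: float = 1.61,
                             bin_width: float = PAIR_BIN,
                             r_cut: float = PAIR_RCUT,
                             pseudocount: float = 1.0,
                             classes=PAIR_CLASSES,
                             short_range_plateau: float = 3.0,
                             min_reference_count: float = 5.0
                             ) -> PairPotentialTable:
    """Convert binned pair counts (C, C, B) into a potential of mean force.

    u(i,j,r) = -RT ln[ N(i,j,r) / ((r/r_ref)^alpha N(i,j,r_ref)) ], with the
    last-bin center as the reference distance r_ref and ``pseudocount``
    added to every bin.  Pairs with no observations at all yield a zero row
    (with a warning).

    Leading bins a pair was *never* observed in (distances below its first
    contact) are physically excluded volume; for sparsely counted pairs the
    pseudocount ratio would make them spuriously attractive, so they are
    set to the repulsive ``short_range_plateau`` instead.
    """
    counts = np.asarray(counts, float)
    nb = counts.shape[2]
    centers = bin_width * (np.arange(nb) + 0.5)
    r_ref = centers[-1]
    # pairs without a usable reference shell carry no signal: zero row
    empty = (counts.sum(axis=2) == 0) | (counts[:, :, -1] < min_reference_count)
    n = counts + pseudocount
    ref = n[:, :, -1][:, :, None]
    expect = (centers / r_ref) ** alpha
    u = -RT * np.log(n / (expect[None, None, :] * ref))
    # repulsive plateau over each pair's leading never-observed bins
    never = counts == 0
    leading = np.cumprod(never, axis=2).astype(bool)
    leading[:, :, -1] = False
    u[leading] = short_range_plateau
    u[empty] = 0.0
    if np.any(empty[np.triu_indices_from(empty)]):
        warnings.warn("pair classes with no observed contacts; rows set to 0")
    u[:, :, -1] = 0.0  # exact by construction; clears rounding
    return PairPotentialTable(u, classes, bin_width, r_cut)


def _heavy_atom_arrays(structures):
    pos, cls, resi, chain, struct = [], [], [], [], []
    for si, st in enumerate(structures):
        for cid, r in st.iter_residues():
            for a in r.atoms:
                if a.element == "H":
                    continue
                pc = PAIR_CLASS_OF.get(a.atom_class)
                if pc is None:
                    continue
                pos.append(a.pos)
                cls.append(PAIR_CLASSES.index(pc))
                resi.append(r.index)
                chain.append((si, cid))
                struct.append(si)
    uniq = {c: i for i, c in enumerate(dict.fromkeys(chain))}
    return (np.array(pos), np.array(cls), np.array(resi),
            np.array([uniq[c] for c in chain]), np.array(struct))


def derive_pair_potential(training_structures, alpha: float = 1.61,
                          bin_width: float = PAIR_BIN,
                          r_cut: float = PAIR_RCUT,
                          pseudocount: float = 1.0) -> PairPotentialTable:
    """Accumulate heavy-atom pair counts (sequence separation >= 2) over the
    training structures and convert them to a potential of mean force."""
    if not training_structures:
        raise ValueError("at least one training structure required")
    pos, cls, resi, chain, struct = _heavy_atom_arrays(training_structures)
    nb = int(round(r_cut / bin_width))
    counts = np.zeros((len(PAIR_CLASSES), len(PAIR_CLASSES), nb))
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=r_cut, output_type="ndarray")
    i, j = pairs[:, 0], pairs[:, 1]
    # pairs must come from the same structure; within it, either different
    # chains or sequence separation >= 2
    keep = (struct[i] == struct[j]) & (
        (chain[i] != chain[j]) | (np.abs(resi[i] - resi[j]) >= 2))
    i, j = i[keep], j[keep]
    d = np.linalg.norm(pos[i] - pos[j], axis=1)
    b = np.minimum((d / bin_width).astype(int), nb - 1)
    np.add.at(counts, (cls[i], cls[j], b), 1.0)
    np.add.at(counts, (cls[j], cls[i], b), 1.0)
    return pair_counts_to_potential(counts, alpha, bin_width, r_cut, pseudocount)


def derive_torsion_tables(training_structures, pseudocount: float = 1.0,
                          interpolation: str = "bicubic"):
    """Binned -ln frequencies of (phi, psi) and chi from training structures.

    Backbone classes: GLY, PRO and generic; chi profiles are pooled over
    residue types per chi index (class 'generic').
    """
    pp_counts = {k: np.full((N_TORSION_BINS, N_TORSION_BINS), 0.0)
                 for k in ("GLY", "PRO", "generic")}
    max_chi = 4
    chi_counts = [np.zeros(N_TORSION_BINS) for _ in range(max_chi)]
    for st in training_structures:
        for cid, residues in st.chains.items():
            for prev, r, nxt in zip(residues, residues[1:], residues[2:]):
                if not (prev.index == r.index - 1 and nxt.index == r.index + 1):
                    continue
                try:
                    ph = dihedral(prev.atom("C").pos, r.atom("N").pos,
                                  r.atom("CA").pos, r.atom("C").pos)
                    ps = dihedral(r.atom("N").pos, r.atom("CA").pos,
                                  r.atom("C").pos, nxt.atom("N").pos)
                except KeyError:
                    continue
                key = r.name if r.name in ("GLY", "PRO") else "generic"
                i = min(int((ph + 180.0) // TORSION_BIN), N_TORSION_BINS - 1)
                j = min(int((ps + 180.0) // TORSION_BIN), N_TORSION_BINS - 1)
                pp_counts[key][i, j] += 1.0
            for r in residues:
                for k, chi in enumerate(measure_chi(r)):
                    if np.isfinite(chi) and k < max_chi:
                        b = min(int((chi + 180.0) // TORSION_BIN), N_TORSION_BINS - 1)
                        chi_counts[k][b] += 1.0
    pp = {k: -np.log(v + pseudocount) for k, v in pp_counts.items()}
    chi = {"generic": [-np.log(v + pseudocount) for v in chi_counts]}
    return (PhiPsiTable(pp, interpolation=interpolation),
            ChiTable(chi, interpolation=interpolation))


# ---------------------------------------------------------------------------
# analytic default tables
# ---------------------------------------------------------------------------

def _wrapped_gaussian_2d(centers_weights, uniform_weight):
    ax = -180.0 + TORSION_BIN * (np.arange(N_TORSION_BINS) + 0.5)
    ph, ps = np.meshgrid(ax, ax, indexing="ij")
    dens = np.full(ph.shape, uniform_weight / (N_TORSION_BINS ** 2))
    for (c_ph, c_ps, s_ph, s_ps, w) in centers_weights:
        acc = np.zeros_like(ph)
        for dph in (-360.0, 0.0, 360.0):
            for dps in (-360.0, 0.0, 360.0):
                acc += np.exp(-0.5 * (((ph - c_ph + dph) / s_ph) ** 2
                                      + ((ps - c_ps + dps) / s_ps) ** 2))
        dens += w * acc / acc.sum()
    return -np.log(dens / dens.sum())


def _wrapped_gaussian_1d(centers_weights, uniform_weight):
    ax = -180.0 + TORSION_BIN * (np.arange(N_TORSION_BINS) + 0.5)
    dens = np.full(ax.shape, uniform_weight / N_TORSION_BINS)
    for (c, s, w) in centers_weights:
        acc = np.zeros_like(ax)
        for d in (-360.0, 0.0, 360.0):
            acc += np.exp(-0.5 * ((ax - c + d) / s) ** 2)
        dens += w * acc / acc.sum()
    return -np.log(dens / dens.sum())


def reference_phipsi_table(interpolation: str = "bicubic") -> PhiPsiTable:
    """Default backbone table: canonical Ramachandran basins (alpha, beta,
    left-handed alpha; glycine symmetrized; proline phi-restricted)."""
    generic = _wrapped_gaussian_2d(
        [(-63.0, -43.0, 12.0, 12.0, 0.36),
         (-120.0, 135.0, 25.0, 25.0, 0.34),
         (-70.0, 150.0, 15.0, 15.0, 0.10),
         (55.0, 45.0, 12.0, 12.0, 0.06)], 0.14)
    gly = _wrapped_gaussian_2d(
        [(-63.0, -43.0, 15.0, 15.0, 0.18),
         (63.0, 43.0, 15.0, 15.0, 0.18),
         (-90.0, 150.0, 20.0, 20.0, 0.18),
         (90.0, -150.0, 20.0, 20.0, 0.18)], 0.28)
    pro = _wrapped_gaussian_2d(
        [(-63.0, -35.0, 8.0, 12.0, 0.45),
         (-63.0, 148.0, 8.0, 14.0, 0.38)], 0.17)
    return PhiPsiTable({"generic": generic, "GLY": gly, "PRO": pro},
                       interpolation=interpolation)


def reference_chi_table(interpolation: str = "bicubic") -> ChiTable:
    """Default chi profiles: gauche-/trans/gauche+ rotamer mixture."""
    prof = _wrapped_gaussian_1d(
        [(-60.0, 12.0, 0.48), (180.0, 12.0, 0.32), (60.0, 12.0, 0.14)], 0.06)
    return ChiTable({"generic": [prof.copy() for _ in range(4)]},
                    interpolation=interpolation)
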