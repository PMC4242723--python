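"""Fragment-assembly loop sampling with analytic closure (FALC-style).

Initial loop conformations are generated by drawing backbone (phi, psi)
fragments from a Ramachandran statistics table for every non-pivot residue,
then solving tri-axial closure for three pivot residues so the chain meets
the C-side anchor exactly.  Among closure roots, the solution with the
fewest steric clashes (ties: least total torsion change) is kept.

Peptide omegas stay trans (180 deg) except for flagged cis-prolines, whose
cis state is preserved, never discovered, by sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import topology as topo
from .closure import ClosureProblem, forward_backbone, tlc_solve
from .structure import (LoopDefinition, ProteinStructure, TorsionState,
                        torsions_from_coords)
from .tables import PhiPsiTable, TORSION_BIN

__all__ = ["FragmentLibrary", "falc_sample", "valid_pivot_triples", "count_clashes"]

DEFAULT_CLASH_FACTOR = 0.7   # clash when d < factor * (rmin_i + rmin_j)
DEFAULT_RETRIES = 50

# approximate rmin/2 radii for quick backbone clash screening
_BB_RADII = {"N": 1.85, "CA": 2.27, "C": 2.00}


@dataclass
class FragmentLibrary:
    """Per-class (phi, psi) fragment sets with sampling weights.

    ``class_of`` maps a loop position (0-based) to a fragment class; the
    default construction uses the Ramachandran classes of the loop sequence
    (GLY / PRO / generic).  ``jitter`` is the half-width (deg) of the
    uniform in-bin smearing applied on draw.
    """

    frags: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    class_of: list[str]
    jitter: float = TORSION_BIN / 2.0

    def __post_init__(self):
        for cls, (ph, ps, w) in self.frags.items():
            w = np.asarray(w, float)
            if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"fragment weights of {cls!r} must be "
                                 f"positive and sum to 1")

    @property
    def n_positions(self) -> int:
        return len(self.class_of)

    def sample(self, position: int, rng: np.random.Generator):
        """Draw one (phi, psi) pair for a loop position."""
        ph, ps, w = self.frags[self.class_of[position]]
        k = rng.choice(len(w), p=w)
        jit = self.jitter
        return (float(ph[k] + rng.uniform(-jit, jit)),
                float(ps[k] + rng.uniform(-jit, jit)))

    @classmethod
    def from_phipsi_table(cls, table: PhiPsiTable, sequence: list[str],
                          top_k: int = 120, jitter: float = TORSION_BIN / 2.0):
        """Fragment sets from the top-k bins of a phi/psi table."""
        frags = {}
        class_of = [table.class_for(nm) for nm in sequence]
        centers = -180.0 + TORSION_BIN * (np.arange(len(table.grids[
            next(iter(table.grids))])) + 0.5)
        for name in set(class_of):
            grid = table.grids[name]
            p = np.exp(-grid)
            flat = np.argsort(p.ravel())[::-1][:top_k]
            i, j = np.unravel_index(flat, grid.shape)
            w = p.ravel()[flat]
            frags[name] = (centers[i], centers[j], w / w.sum())
        return cls(frags, class_of, jitter)

    @classmethod
    def concentrated(cls, phi, psi, width: float = 2.0):
        """Library sharply peaked at given per-position torsions (testing
        and planted-native benchmarks)."""
        phi = np.asarray(phi, float)
        psi = np.asarray(psi, float)
        frags = {}
        class_of = []
        for k in range(len(phi)):
            name = f"pos{k}"
            frags[name] = (np.array([phi[k]]), np.array([psi[k]]),
                           np.array([1.0]))
            class_of.append(name)
        return cls(frags, class_of, jitter=width)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# fragment library: class phi_center psi_center weight\n")
            for name, (ph, ps, w) in sorted(self.frags.items()):
                for a, b, c in zip(ph, ps, w):
                    fh.write(f"{name} {a:.2f} {b:.2f} {c:.8e}\n")

    @classmethod
    def from_text(cls, path, class_of: list[str]):
        rows: dict[str, list] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, a, b, c = line.split()
                rows.setdefault(name, []).append((float(a), float(b), float(c)))
        frags = {}
        for name, items in rows.items():
            arr = np.array(items)
            frags[name] = (arr[:, 0], arr[:, 1], arr[:, 2] / arr[:, 2].sum())
        return cls(frags, class_of)


def valid_pivot_triples(n: int) -> list[tuple[int, int, int]]:
    """Pivot triples with at least one residue between consecutive pivots
    when the loop is long enough (adjacent pivots allowed for short loops)."""
    gap = 2 if n >= 5 else 1
    triples = [(a, b, c)
               for a in range(n) for b in range(a + gap, n)
               for c in range(b + gap, n)]
    if not triples:
        triples = [(a, b, c)
                   for a in range(n) for b in range(a + 1, n)
                   for c in range(b + 1, n)]
    return triples


def _environment_heavy(structure: ProteinStructure, loop: LoopDefinition):
    pos, rad = [], []
    loop_keys = {(loop.chain_id, i) for i in loop.indices}
    for cid, r in structure.iter_residues():
        if (cid, r.index) in loop_keys:
            continue
        for a in r.atoms:
            if a.element != "H":
                pos.append(a.pos)
                rad.append(a.vdw_radius if a.vdw_radius > 0 else 1.9)
    return np.array(pos), np.array(rad)


def count_clashes(structure: ProteinStructure, loop: LoopDefinition,
                  torsions: TorsionState,
                  clash_factor: float = DEFAULT_CLASH_FACTOR,
                  env=None) -> int:
    """Steric clash count of a loop backbone against the environment and
    itself (N/CA/C atoms; pairs closer than ``clash_factor`` times the sum
    of vdW radii)."""
    anchor = structure.residue(loop.chain_id, loop.start - 1)
    N, CA, C = forward_backbone(anchor.atom("N").pos, anchor.atom("CA").pos,
                                anchor.atom("C").pos, torsions)
    n = torsions.n
    pos = np.concatenate([N, CA, C])
    rad = np.concatenate([np.full(n, _BB_RADII["N"]),
                          np.full(n, _BB_RADII["CA"]),
                          np.full(n, _BB_RADII["C"])])
    resid = np.tile(np.arange(n), 3)
    if env is None:
        env = _environment_heavy(structure, loop)
    epos, erad = env
    count = 0
    if len(epos):
        d = np.linalg.norm(pos[:, None, :] - epos[None, :, :], axis=-1)
        # exclude bonded neighbourhood of the anchors (first/last residue)
        lim = clash_factor * (rad[:, None] + erad[None, :])
        mask = d < lim
        mask[resid == 0] &= d[resid == 0] > 2.0
        mask[resid == n - 1] &= d[resid == n - 1] > 2.0
        count += int(mask.sum())
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    lim = clash_factor * (rad[:, None] + rad[None, :])
    far = np.abs(resid[:, None] - resid[None, :]) >= 2
    count += int(((d < lim) & far).sum()) // 2
    return count


def falc_sample(structure: ProteinStructure, loop: LoopDefinition,
                library: FragmentLibrary, n_samples: int, rng_seed: int,
                max_retries: int = DEFAULT_RETRIES,
                clash_factor: float = DEFAULT_CLASH_FACTOR,
                chi_noise: float = 0.0) -> list[TorsionState]:
    """Generate ``n_samples`` closed loop torsion states.

    Deterministic for a given ``rng_seed``.  Raises ``RuntimeError`` only
    when every sample exhausts its retries.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n = loop.n_residues
    cid = loop.chain_id
    residues = [structure.residue(cid, i) for i in loop.indices]
    has_native = all(r.has_atom("C") for r in residues)
    if has_native:
        base = torsions_from_coords(structure, loop)
    else:
        base = TorsionState(loop.start, np.full(n, -120.0), np.full(n, 140.0),
                            np.full(n, 180.0))
    # preserve cis-proline peptide bonds: omega preceding residue j is
    # omega[j-1] in the following-bond convention
    omega = np.full(n, 180.0)
    for j, r in enumerate(residues):
        if r.is_cis_proline and j > 0:
            omega[j - 1] = 0.0
    triples = valid_pivot_triples(n)
    env = _environment_heavy(structure, loop)
    out: list[TorsionState] = []
    log: list[str] = []
    for k in range(n_samples):
        state = None
        for attempt in range(max_retries):
            ts = base.copy()
            ts.omega = omega.copy()
            for j in range(n):
                ts.phi[j], ts.psi[j] = library.sample(j, rng)
            pivots = triples[rng.integers(len(triples))]
            sols = tlc_solve(ClosureProblem(structure, loop, ts, pivots))
            if not sols:
                continue
            scored = sorted(
                ((count_clashes(structure, loop, s.torsions, clash_factor, env),
                  s.total_change, i) for i, s in enumerate(sols)))
            best = sols[scored[0][2]]
            state = best.torsions
            break
        if state is None:
            log.append(f"sample {k}: closure failed after {max_retries} retries")
            continue
        # side chains: most common rotamer, optionally randomized
        for j, r in enumerate(residues):
            nrot = len(topo.RESIDUE_TEMPLATES[r.name]["rotamer"])
            if nrot:
                chi = np.array(topo.RESIDUE_TEMPLATES[r.name]["rotamer"], float)
                if chi_noise > 0:
                    chi = chi + rng.normal(scale=chi_noise, size=nrot)
                state.chi[loop.start + j] = chi
        out.append(state)
    if not out:
        raise RuntimeError("all FALC samples failed closure: " + "; ".join(log))
    falc_sample.last_log = log
    return out


falc_sample.last_log = []
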