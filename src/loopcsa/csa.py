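"""Conformational space annealing (CSA) of loop conformations.

A fixed-size bank of closed loop conformations is evolved by genetic-style
mixing: seed members are recombined with partners (a contiguous torsion
segment is spliced in and the chain re-closed analytically), trials undergo
up to three greedy side-chain exchanges with bank members, a short noisy
descent plus local minimization, and then replace bank members under the
D_cut rule:

* if the nearest bank member (unsuperposed loop main-chain RMSD) is closer
  than D_cut, the trial replaces *that* member when its energy is lower;
* otherwise it replaces the highest-energy member when it beats it.

D_cut anneals geometrically from half the average initial pairwise bank
distance down to a fifth of it, shrinking diversity until the bank
concentrates around low-energy basins.  The energy minimum of the final
bank is the prediction.  Default bank sizes: (seeds M, bank N) = (10, 30)
for loops shorter than 12 residues, (20, 50) for 12 residues or longer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize

from . import topology as topo
from .closure import (ClosureProblem, forward_backbone, tlc_solve,
                      tlc_solve_local)
from .energy import EnergyBreakdown, EnergyModel, EnergyWeights
from .geom import place_atom, wrap_angle
from .sampling import FragmentLibrary, falc_sample, valid_pivot_triples
from .structure import (LoopDefinition, ProteinStructure, TorsionState,
                        coords_from_torsions, torsions_from_coords)

__all__ = [
    "CsaConfig", "BankMember", "Bank", "run_csa", "initialize_bank",
    "generate_trial", "sidechain_exchange", "refine_trial", "update_bank",
    "TorsionWellEnergy", "TorsionStatisticsEnergy",
]

RECLOSE_GRID = 192   # coarse circle grid for cheap re-closure during refinement


@dataclass
class CsaConfig:
    bank_size: int | None = None          # default 30 (<12 res) / 50 (>=12)
    n_seeds: int | None = None            # default 10 / 20
    d_cut_init: float | None = None       # default: avg initial distance / 2
    d_cut_final: float | None = None      # default: avg initial distance / 5
    n_iterations: int = 50
    trials_per_seed: int = 10
    sidechain_exchange_max: int = 3
    rng_seed: int = 0
    closure_retries: int = 10
    refine_steps: int = 20                # noisy-descent proposals
    refine_maxfev: int = 60               # surrogate minimization budget/cycle
    refine_cycles: int = 2                # relax/re-close alternations
    patience: int = 5                     # stop after this many idle iterations
    minimize_initial_bank: bool = False

    def resolved(self, n_residues: int) -> "CsaConfig":
        cfg = CsaConfig(**asdict(self))
        if cfg.bank_size is None:
            cfg.bank_size = 30 if n_residues < 12 else 50
        if cfg.n_seeds is None:
            cfg.n_seeds = 10 if n_residues < 12 else 20
        return cfg


@dataclass
class BankMember:
    torsions: TorsionState
    coords: np.ndarray          # (n, 4, 3) loop main-chain N/CA/C/O
    energy: EnergyBreakdown
    age: int = 0
    used_as_seed: bool = False


class Bank:
    """Fixed-size pool of loop conformations."""

    def __init__(self, members: list[BankMember]):
        self.members = members

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def energies(self) -> np.ndarray:
        return np.array([m.energy.e_total for m in self.members])

    def best(self) -> BankMember:
        return min(self.members, key=lambda m: m.energy.e_total)

    def mean_pairwise_distance(self) -> float:
        ds = [bank_distance(a, b)
              for i, a in enumerate(self.members)
              for b in self.members[i + 1:]]
        return float(np.mean(ds)) if ds else 0.0


def mainchain_array(structure: ProteinStructure, loop: LoopDefinition,
                    torsions: TorsionState) -> np.ndarray:
    """Loop main-chain (N, CA, C, O) coordinates implied by a torsion state."""
    anchor = structure.residue(loop.chain_id, loop.start - 1)
    N, CA, C = forward_backbone(anchor.atom("N").pos, anchor.atom("CA").pos,
                                anchor.atom("C").pos, torsions)
    n = torsions.n
    out = np.zeros((n, 4, 3))
    out[:, 0], out[:, 1], out[:, 2] = N, CA, C
    for j in range(n):
        out[j, 3] = place_atom(N[j], CA[j], C[j], topo.BOND_C_O,
                               topo.ANGLE_CA_C_O,
                               wrap_angle(torsions.psi[j] + 180.0))
    return out


def bank_distance(a: BankMember, b: BankMember) -> float:
    """Unsuperposed loop main-chain RMSD between two members (anchors are
    shared, so no superposition is applied)."""
    d = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


class _Evaluator:
    """Rebuilds the working structure from a torsion state and scores it.

    Energy models whose bound view exposes ``evaluate_torsions`` (pure
    torsion-space scores) are evaluated without the Cartesian rebuild."""

    def __init__(self, structure: ProteinStructure, loop: LoopDefinition,
                 energy_model):
        self.work = structure.copy()
        self.loop = loop
        self.bound = energy_model.bind(self.work, loop)
        self.fast = getattr(self.bound, "evaluate_torsions", None)
        self.n_evaluations = 0

    def __call__(self, torsions: TorsionState) -> EnergyBreakdown:
        self.n_evaluations += 1
        if self.fast is not None:
            return self.fast(torsions)
        coords_from_torsions(self.work, self.loop, torsions, in_place=True)
        return self.bound.evaluate()

    def member(self, torsions: TorsionState) -> BankMember:
        e = self(torsions)
        return BankMember(torsions, mainchain_array(self.work, self.loop,
                                                    torsions), e)


# ---------------------------------------------------------------------------
# CSA operations
# ---------------------------------------------------------------------------

def initialize_bank(structure: ProteinStructure, loop: LoopDefinition,
                    library: FragmentLibrary, config: CsaConfig,
                    energy_model, evaluator: _Evaluator | None = None) -> Bank:
    """FALC-generate the initial bank of distinct closed conformations."""
    cfg = config.resolved(loop.n_residues)
    ev = evaluator or _Evaluator(structure, loop, energy_model)
    states = falc_sample(structure, loop, library, cfg.bank_size,
                         rng_seed=cfg.rng_seed)
    rng = np.random.default_rng(cfg.rng_seed + 1)
    members: list[BankMember] = []
    for ts in states:
        m = ev.member(ts)
        if any(bank_distance(m, other) < 1e-9 for other in members):
            continue
        members.append(m)
    extra_seed = cfg.rng_seed + 1000
    while len(members) < cfg.bank_size:
        ts = falc_sample(structure, loop, library, 1, rng_seed=extra_seed)[0]
        extra_seed += 1
        m = ev.member(ts)
        if all(bank_distance(m, other) >= 1e-9 for other in members):
            members.append(m)
    if cfg.minimize_initial_bank:
        members = [refine_trial(structure, loop, m.torsions, ev, rng, cfg)
                   for m in members]
    return Bank(members)


def _splice_pivots(n: int, start: int, seg_len: int):
    """Pivot triple flanking a spliced segment (clipped to the loop)."""
    p1 = max(0, start - 1)
    p3 = min(n - 1, start + seg_len)
    if p3 - p1 < 2:
        p1, p3 = 0, n - 1
    p2 = (p1 + p3) // 2
    if p2 in (p1, p3):
        p2 = p1 + 1
    return (p1, p2, p3)


def generate_trial(structure: ProteinStructure, loop: LoopDefinition,
                   bank: Bank, seed_member: BankMember,
                   partner_member: BankMember, rng: np.random.Generator,
                   config: CsaConfig) -> TorsionState:
    """Crossover move: splice a contiguous partner segment into the seed and
    re-close on pivots flanking the splice.  Falls back to a single-torsion
    perturbation when closure keeps failing, and to the seed itself as a
    last resort (always returns a closed state)."""
    n = loop.n_residues
    seed = seed_member.torsions
    partner = partner_member.torsions
    for attempt in range(config.closure_retries):
        seg_len = int(rng.integers(2, max(n // 2, 3) + 1))
        start = int(rng.integers(0, n - seg_len + 1))
        ts = seed.copy()
        sl = slice(start, start + seg_len)
        ts.phi[sl] = partner.phi[sl]
        ts.psi[sl] = partner.psi[sl]
        for i in range(loop.start + start, loop.start + start + seg_len):
            if i in partner.chi:
                ts.chi[i] = partner.chi[i].copy()
        pivots = _splice_pivots(n, start, seg_len)
        sols = tlc_solve(ClosureProblem(structure, loop, ts, pivots),
                         grid_size=384)
        if sols:
            return sols[0].torsions  # sorted: least torsion change first
    # fallback: single-torsion perturbation of the seed
    for attempt in range(config.closure_retries):
        ts = seed.copy()
        j = int(rng.integers(0, n))
        if rng.random() < 0.5:
            ts.phi[j] = wrap_angle(ts.phi[j] + rng.normal(scale=30.0))
        else:
            ts.psi[j] = wrap_angle(ts.psi[j] + rng.normal(scale=30.0))
        triples = valid_pivot_triples(n)
        pivots = triples[int(rng.integers(len(triples)))]
        sols = tlc_solve(ClosureProblem(structure, loop, ts, pivots),
                         grid_size=384)
        if sols:
            return sols[0].torsions
    return seed.copy()


def sidechain_exchange(trial: TorsionState, bank: Bank, evaluator,
                       rng: np.random.Generator,
                       max_trials: int = 3) -> TorsionState:
    """Greedy side-chain exchange: copy the full chi set of a random bank
    member onto the trial, keeping the exchange iff the energy decreases."""
    if max_trials <= 0 or len(bank) == 0:
        return trial
    best = trial
    e_best = evaluator(trial).e_total
    for _ in range(max_trials):
        donor = bank.members[int(rng.integers(len(bank)))]
        cand = best.copy()
        cand.chi = {k: v.copy() for k, v in donor.torsions.chi.items()}
        e = evaluator(cand).e_total
        if e < e_best:
            best, e_best = cand, e
    return best


def _reclose(structure, loop, ts, pivots):
    """Least-change re-closure: local window search first, then a coarse
    full solve (refinement inner loop)."""
    problem = ClosureProblem(structure, loop, ts, pivots)
    sols = tlc_solve_local(problem)
    if not sols:
        sols = tlc_solve(problem, grid_size=RECLOSE_GRID)
    return sols[0].torsions if sols else None


def refine_trial(structure: ProteinStructure, loop: LoopDefinition,
                 trial: TorsionState, evaluator, rng: np.random.Generator,
                 config: CsaConfig) -> BankMember:
    """Thermal shake plus local minimization in closed torsion space.

    Phase 1 is a short run of random side-chain/backbone proposals accepted
    only downhill (the stand-in for a brief constant-temperature MD; each
    backbone proposal is re-closed analytically).  Phase 2 alternates an
    unconstrained torsion-space relaxation with a least-change closure
    re-projection, accepting the projected state only when it improves.
    The returned member never has higher energy than the input state.
    """
    n = loop.n_residues
    best = trial.copy()
    e_best = evaluator(best).e_total
    triples = valid_pivot_triples(n)
    pivots = triples[len(triples) // 2]
    # phase 1: noisy downhill proposals
    chi_keys = [k for k, v in best.chi.items() if len(v)]
    for _ in range(config.refine_steps):
        cand = best.copy()
        if chi_keys and rng.random() < 0.5:
            k = chi_keys[int(rng.integers(len(chi_keys)))]
            idx = int(rng.integers(len(cand.chi[k])))
            cand.chi[k][idx] = wrap_angle(cand.chi[k][idx]
                                          + rng.normal(scale=20.0))
        else:
            j = int(rng.integers(n))
            if rng.random() < 0.5:
                cand.phi[j] = wrap_angle(cand.phi[j] + rng.normal(scale=8.0))
            else:
                cand.psi[j] = wrap_angle(cand.psi[j] + rng.normal(scale=8.0))
            cand = _reclose(structure, loop, cand, pivots)
            if cand is None:
                continue
        e = evaluator(cand).e_total
        if e < e_best:
            best, e_best = cand, e
    # phase 2: relax (unconstrained) then re-project onto the closed manifold
    for _ in range(max(config.refine_cycles, 0)):
        if config.refine_maxfev <= 0:
            break
        ref = best.copy()

        def surrogate(x):
            cand = ref.copy()
            cand.phi = wrap_angle(ref.phi + x[:n])
            cand.psi = wrap_angle(ref.psi + x[n:])
            return evaluator(cand).e_total

        res = minimize(surrogate, np.zeros(2 * n), method="Powell",
                       options={"maxfev": config.refine_maxfev,
                                "xtol": 0.1, "ftol": 1e-5})
        cand = ref.copy()
        cand.phi = wrap_angle(ref.phi + res.x[:n])
        cand.psi = wrap_angle(ref.psi + res.x[n:])
        closed = _reclose(structure, loop, cand, pivots)
        if closed is None:
            break
        closed.chi = {k: v.copy() for k, v in best.chi.items()}
        e = evaluator(closed).e_total
        if e < e_best - 1e-12:
            best, e_best = closed, e
        else:
            break
    e_final = evaluator(best)
    return BankMember(best, mainchain_array(structure, loop, best), e_final)


def update_bank(bank: Bank, candidate: BankMember, d_cut: float) -> bool:
    """CSA replacement rule; returns True when a member was replaced."""
    dists = np.array([bank_distance(candidate, m) for m in bank.members])
    nearest = int(np.argmin(dists))
    if dists[nearest] < d_cut:
        if candidate.energy.e_total < bank.members[nearest].energy.e_total:
            bank.members[nearest] = candidate
            return True
        return False
    worst = int(np.argmax(bank.energies()))
    if candidate.energy.e_total < bank.members[worst].energy.e_total:
        bank.members[worst] = candidate
        return True
    return False


def run_csa(structure: ProteinStructure, loop: LoopDefinition,
            energy_model, config: CsaConfig | None = None,
            library: FragmentLibrary | None = None):
    """Full CSA protocol; returns (final structure, final bank, trace)."""
    from .tables import reference_phipsi_table
    config = (config or CsaConfig()).resolved(loop.n_residues)
    loop.validate(structure)
    if library is None:
        names = [structure.residue(loop.chain_id, i).name
                 for i in loop.indices]
        library = FragmentLibrary.from_phipsi_table(reference_phipsi_table(),
                                                    names)
    rng = np.random.default_rng(config.rng_seed)
    ev = _Evaluator(structure, loop, energy_model)
    bank = initialize_bank(structure, loop, library, config, energy_model, ev)
    d0 = config.d_cut_init or max(bank.mean_pairwise_distance() / 2.0, 0.1)
    d1 = config.d_cut_final or max(bank.mean_pairwise_distance() / 5.0, 0.05)
    trace = {"config": {**asdict(config)},
             "d_cut_init": d0, "d_cut_final": d1, "iterations": []}
    idle = 0
    for it in range(config.n_iterations):
        frac = it / max(config.n_iterations - 1, 1)
        d_cut = d0 * (d1 / d0) ** frac
        # seed selection: lowest-energy members not yet used this cycle
        unused = [m for m in bank.members if not m.used_as_seed]
        if len(unused) < config.n_seeds:
            for m in bank.members:
                m.used_as_seed = False
            unused = list(bank.members)
        unused.sort(key=lambda m: m.energy.e_total)
        seeds = unused[:config.n_seeds]
        n_replaced = 0
        n_trials = 0
        for seed in seeds:
            seed.used_as_seed = True
            for _ in range(config.trials_per_seed):
                others = [m for m in bank.members if m is not seed]
                partner = others[int(rng.integers(len(others)))]
                ts = generate_trial(structure, loop, bank, seed, partner,
                                    rng, config)
                ts = sidechain_exchange(ts, bank, ev, rng,
                                        config.sidechain_exchange_max)
                member = refine_trial(structure, loop, ts, ev, rng, config)
                n_trials += 1
                if update_bank(bank, member, d_cut):
                    n_replaced += 1
        for m in bank.members:
            m.age += 1
        energies = bank.energies()
        trace["iterations"].append({
            "iteration": it, "d_cut": d_cut, "e_min": float(energies.min()),
            "e_mean": float(energies.mean()), "replacements": n_replaced,
            "trials": n_trials,
        })
        idle = idle + 1 if n_replaced == 0 else 0
        if idle >= config.patience:
            break
    best = bank.best()
    final = coords_from_torsions(structure, loop, best.torsions)
    return final, bank, trace


class TorsionWellEnergy:
    """Separable toy landscape with a unique known minimum at the target
    torsions: E = sum_j [1 - cos(phi_j - phi*_j)] + [1 - cos(psi_j - psi*_j)].

    Implements the energy-model binding protocol; used for optimizer
    validation (the global minimum and its energy, zero, are known)."""

    def __init__(self, phi_target, psi_target):
        self.phi = np.asarray(phi_target, float)
        self.psi = np.asarray(psi_target, float)

    def bind(self, structure, loop):
        outer = self

        class _Bound:
            def evaluate_torsions(self, ts):
                dphi = np.radians(ts.phi - outer.phi)
                dpsi = np.radians(ts.psi - outer.psi)
                e = float(np.sum(1 - np.cos(dphi)) + np.sum(1 - np.cos(dpsi)))
                return EnergyBreakdown(e_bonded=e)

            def evaluate(self):
                return self.evaluate_torsions(torsions_from_coords(structure,
                                                                   loop))

        return _Bound()


class TorsionStatisticsEnergy:
    """Knowledge-only energy (phi/psi and chi statistical tables) evaluated
    directly in torsion space — the fast scoring path for planted-table
    benchmarks where the tables alone define the landscape."""

    def __init__(self, phipsi_table, chi_table=None,
                 w_phipsi: float = 1.0, w_chi: float = 1.0):
        self.phipsi = phipsi_table
        self.chi = chi_table
        self.w_phipsi = w_phipsi
        self.w_chi = w_chi

    def bind(self, structure, loop):
        outer = self
        names = [structure.residue(loop.chain_id, i).name
                 for i in loop.indices]

        class _Bound:
            def evaluate_torsions(self, ts):
                e_pp = sum(outer.phipsi.energy(nm, ts.phi[j], ts.psi[j])
                           for j, nm in enumerate(names))
                e_chi = 0.0
                if outer.chi is not None:
                    for i, chis in ts.chi.items():
                        nm = names[i - loop.start]
                        for k, c in enumerate(chis):
                            e_chi += outer.chi.energy(nm, k, c)
                return EnergyBreakdown(
                    e_phipsi=float(e_pp), e_chi=float(e_chi),
                    weights=EnergyWeights(
                        w_electrostatics=0.0, w_sa=0.0,
                        w_phipsi=outer.w_phipsi, w_chi=outer.w_chi,
                        w_hbond=0.0, w_atompair=0.0))

            def evaluate(self):
                return self.evaluate_torsions(torsions_from_coords(structure,
                                                                   loop))

        return _Bound()
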