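"""CSA optimizer: bank mechanics, trial generation, greedy side-chain
exchange, monotone refinement, the D_cut replacement rule and a seeded
end-to-end run."""

import numpy as np
import pytest

from loopcsa.csa import (Bank, BankMember, CsaConfig, TorsionWellEnergy,
                         _Evaluator, bank_distance, generate_trial,
                         initialize_bank, mainchain_array, refine_trial,
                         run_csa, sidechain_exchange, update_bank)
from loopcsa.energy import EnergyBreakdown
from loopcsa.sampling import FragmentLibrary
from loopcsa.structure import closure_error, torsions_from_coords
from loopcsa.tables import reference_phipsi_table


@pytest.fixture(scope="module")
def library(chain20, loop8):
    names = [chain20.residue("A", i).name for i in loop8.indices]
    return FragmentLibrary.from_phipsi_table(reference_phipsi_table(), names)


@pytest.fixture(scope="module")
def toy(chain20, loop8, native_torsions):
    return TorsionWellEnergy(native_torsions.phi, native_torsions.psi)


@pytest.fixture()
def small_cfg():
    return CsaConfig(bank_size=8, n_seeds=3, n_iterations=3,
                     trials_per_seed=1, refine_steps=3, refine_maxfev=40,
                     refine_cycles=1, rng_seed=2)


def test_config_defaults_follow_loop_length():
    assert (CsaConfig().resolved(8).bank_size,
            CsaConfig().resolved(8).n_seeds) == (30, 10)
    assert (CsaConfig().resolved(12).bank_size,
            CsaConfig().resolved(12).n_seeds) == (50, 20)
    assert CsaConfig().sidechain_exchange_max == 3


def test_initialize_bank_closed_and_reproducible(chain20, loop8, library,
                                                 toy, small_cfg):
    b1 = initialize_bank(chain20, loop8, library, small_cfg, toy)
    b2 = initialize_bank(chain20, loop8, library, small_cfg, toy)
    assert len(b1) == small_cfg.bank_size
    for m1, m2 in zip(b1, b2):
        assert closure_error(chain20, loop8, m1.torsions) < 1e-4
        assert np.array_equal(m1.torsions.phi, m2.torsions.phi)
        assert m1.energy.e_total == m2.energy.e_total
    assert np.all(np.isfinite(b1.energies()))


def test_trial_from_identical_parents_is_seed(chain20, loop8, library, toy,
                                              small_cfg):
    bank = initialize_bank(chain20, loop8, library, small_cfg, toy)
    rng = np.random.default_rng(3)
    seed = bank.members[0]
    trial = generate_trial(chain20, loop8, bank, seed, seed, rng, small_cfg)
    assert np.max(np.abs(trial.phi - seed.torsions.phi)) < 1e-6
    assert np.max(np.abs(trial.psi - seed.torsions.psi)) < 1e-6


def test_trials_always_closed(chain20, loop8, library, toy, small_cfg):
    bank = initialize_bank(chain20, loop8, library, small_cfg, toy)
    rng = np.random.default_rng(4)
    for _ in range(10):
        a, b = rng.choice(len(bank), size=2, replace=False)
        trial = generate_trial(chain20, loop8, bank, bank.members[a],
                               bank.members[b], rng, small_cfg)
        assert closure_error(chain20, loop8, trial) < 1e-4


def test_sidechain_exchange_never_raises_energy(chain20, loop8, library,
                                                small_cfg):
    class ChiEnergy:
        """Scores only side-chain chi deviations from zero."""

        def bind(self, structure, loop):
            class _B:
                def evaluate_torsions(self, ts):
                    e = sum(float(np.sum((np.radians(v)) ** 2))
                            for v in ts.chi.values())
                    return EnergyBreakdown(e_bonded=e)
            return _B()

    ev = _Evaluator(chain20, loop8, ChiEnergy())
    bank = initialize_bank(chain20, loop8, library, small_cfg, ChiEnergy(),
                           ev)
    rng = np.random.default_rng(5)
    trial = bank.members[0].torsions
    e0 = ev(trial).e_total
    out = sidechain_exchange(trial, bank, ev, rng, max_trials=3)
    assert ev(out).e_total <= e0 + 1e-12
    # max_trials=0 leaves the trial untouched
    same = sidechain_exchange(trial, bank, ev, rng, max_trials=0)
    assert same is trial


def test_refine_monotone_and_converges_to_analytic_minimum(
        chain20, loop8, native_torsions, toy, small_cfg):
    """On the separable quadratic-near-minimum toy landscape, refinement
    from a nearby closed state reaches the known minimum (energy 0)."""
    ev = _Evaluator(chain20, loop8, toy)
    rng = np.random.default_rng(6)
    start = native_torsions.copy()
    start.phi = start.phi + rng.normal(scale=5.0, size=start.n)
    start.psi = start.psi + rng.normal(scale=5.0, size=start.n)
    from loopcsa.csa import _reclose
    from loopcsa.sampling import valid_pivot_triples
    triples = valid_pivot_triples(loop8.n_residues)
    start = _reclose(chain20, loop8, start, triples[len(triples) // 2])
    assert start is not None
    e_in = ev(start).e_total
    cfg = CsaConfig(refine_steps=4, refine_maxfev=200, refine_cycles=3,
                    rng_seed=7)
    member = refine_trial(chain20, loop8, start, ev, rng, cfg)
    assert member.energy.e_total <= e_in + 1e-12
    assert member.energy.e_total < 1e-4


def test_update_bank_rules(chain20, loop8, library, toy, small_cfg):
    bank = initialize_bank(chain20, loop8, library, small_cfg, toy)
    energies = bank.energies()
    # distant candidate worse than everyone: no replacement
    worst = bank.members[int(np.argmax(energies))]
    bad = BankMember(worst.torsions.copy(), worst.coords + 100.0,
                     EnergyBreakdown(e_bonded=energies.max() + 50.0))
    assert not update_bank(bank, bad, d_cut=1.0)
    # near-duplicate of a member with lower energy replaces that member
    target = bank.members[3]
    better = BankMember(target.torsions.copy(), target.coords.copy(),
                        EnergyBreakdown(
                            e_bonded=target.energy.e_total - 10.0))
    assert update_bank(bank, better, d_cut=1.0)
    assert bank.members[3] is better
    # distant candidate better than the worst replaces the worst
    energies = bank.energies()
    worst_idx = int(np.argmax(energies))
    far = BankMember(target.torsions.copy(), target.coords + 50.0,
                     EnergyBreakdown(e_bonded=energies.max() - 1.0))
    assert update_bank(bank, far, d_cut=0.5)
    assert bank.members[worst_idx] is far


def test_bank_distance_is_unsuperposed_rmsd(chain20, loop8,
                                            native_torsions):
    a = BankMember(native_torsions,
                   mainchain_array(chain20, loop8, native_torsions),
                   EnergyBreakdown())
    shifted = BankMember(native_torsions, a.coords + np.array([1.0, 0, 0]),
                         EnergyBreakdown())
    assert bank_distance(a, shifted) == pytest.approx(1.0)


def test_run_csa_monotone_deterministic(chain20, loop8, toy, small_cfg):
    final1, bank1, trace1 = run_csa(chain20, loop8, toy, small_cfg)
    final2, bank2, trace2 = run_csa(chain20, loop8, toy, small_cfg)
    mins = [it["e_min"] for it in trace1["iterations"]]
    assert all(b <= a + 1e-12 for a, b in zip(mins, mins[1:]))
    assert bank1.best().energy.e_total == bank2.best().energy.e_total
    dcuts = [it["d_cut"] for it in trace1["iterations"]]
    assert all(b < a for a, b in zip(dcuts, dcuts[1:]))
    assert len(bank1) == small_cfg.bank_size
    for m in bank1:
        assert closure_error(chain20, loop8, m.torsions) < 1e-4
    # the final model carries the best member's conformation
    ts = torsions_from_coords(final1, loop8)
    assert np.max(np.abs(ts.phi - bank1.best().torsions.phi)) < 1e-6
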