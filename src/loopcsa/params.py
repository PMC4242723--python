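"""Atom-class parameter set: charges, Lennard-Jones radii/well depths and
surface-tension coefficients, loaded from a plain-text table.

The packaged table (``data/atom_classes.txt``) is a reduced, self-contained
polar-hydrogen set: functional forms, not parameter provenance, are what
this package specifies, so users may substitute their own table with
``load_parameter_table(path)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass


@dataclass(frozen=True)
class AtomClassParams:
    charge: float      # elementary charges
    rmin_half: float   # Angstrom; pair minimum at rmin_i + rmin_j
    epsilon: float     # kcal/mol
    gamma_sa: float    # kcal/mol/A^2


def load_parameter_table(path=None) -> dict[str, AtomClassParams]:
    """Parse an atom-class table; defaults to the packaged set."""
    if path is None:
        text = (
            importlib.resources.files("loopcsa.data")
            .joinpath("atom_classes.txt")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, AtomClassParams] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, q, r, eps, gamma = line.split()
        table[cls] = AtomClassParams(float(q), float(r), float(eps), float(gamma))
    if not table:
        raise ValueError("empty atom-class parameter table")
    return table


_DEFAULT: dict[str, AtomClassParams] | None = None


def default_parameters() -> dict[str, AtomClassParams]:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_parameter_table()
    return _DEFAULT
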