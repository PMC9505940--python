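"""Residue-pair statistical contact potentials and their spring constants.

The model weights the springs of a Gaussian network by the Miyazawa-Jernigan
(MJ) knowledge-based contact energy of the interacting residue pair: a pair
with a more favourable (more negative) contact energy gets a stiffer spring,
and therefore a smaller mean-squared fluctuation of its inter-residue
distance. Covalently adjacent residues (|i-j| = 1 along the chain) always get
the stiffest spring, built from the minimum entry of the table minus one.

The 20x20 table ships as an AAindex matrix flat-file record (MIYS960101, the
upper half of the original MJ table, energies in RT units) and any other
AAindex-format matrix may be substituted.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field
from typing import Iterable

from .errors import PotentialParseError, UnknownResidueError

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

#: Spring-constant sign conventions for non-bonded pairs.
#: ``boltzmann_negated`` (default): k_ij = exp(-MJ_ij), so favourable contacts
#: are stiff.  ``literal_eq2``: k_ij = exp(MJ_ij), the form printed in the
#: source equation.
CONVENTIONS = ("boltzmann_negated", "literal_eq2")


@dataclass(frozen=True)
class ContactPotential:
    """Symmetric 20x20 amino-acid contact-energy table in RT units."""

    source_id: str
    energies: dict[tuple[str, str], float] = field(repr=False)
    min_energy: float = field(init=False)

    def __post_init__(self) -> None:
        pairs = {frozenset(k) if k[0] != k[1] else (k[0],) for k in self.energies}
        if len(pairs) != 210:
            raise ValueError(
                f"expected 210 unordered residue pairs, got {len(pairs)}"
            )
        for (a, b), e in list(self.energies.items()):
            if self.energies.get((b, a), e) != e:
                raise ValueError(f"asymmetric entry for pair {a}{b}")
        object.__setattr__(self, "min_energy", min(self.energies.values()))

    def energy(self, aa_i: str, aa_j: str) -> float:
        """Contact energy MJ_ij; raises for non-standard residue codes."""
        try:
            return self.energies[(aa_i, aa_j)]
        except KeyError:
            bad = aa_i if aa_i not in STANDARD_AAS else aa_j
            raise UnknownResidueError(f"non-standard residue code {bad!r}") from None

    def to_aaindex(self) -> str:
        """Serialize back to an AAindex matrix record (lower-triangular body)."""
        order = _aaindex_order(self)
        lines = [
            f"H {self.source_id}",
            "D serialized contact potential",
            f"M rows = {order}, cols = {order}",
        ]
        for i, a in enumerate(order):
            row = "".join(f"{self.energies[(a, b)]:10.4f}" for b in order[: i + 1])
            lines.append(row)
        lines.append("//")
        return "\n".join(lines) + "\n"


def _aaindex_order(potential: ContactPotential) -> str:
    order = getattr(potential, "_order", None)
    return order if order else STANDARD_AAS


def parse_aaindex_matrix(text: str) -> ContactPotential:
    """Parse one AAindex matrix record into a :class:`ContactPotential`.

    The record must contain an ``M rows = ..., cols = ...`` header followed by
    a triangular numeric body (one row per amino acid, up to the diagonal).
    The table is symmetrized from the triangle.
    """
    source_id = ""
    order: str | None = None
    rows: list[list[float]] = []
    in_body = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("//"):
            break
        if line.startswith("H ") and not source_id:
            source_id = line[2:].strip()
            continue
        if line.startswith("M "):
            m = re.match(
                r"M\s+rows\s*=\s*([A-Z]+)\s*,\s*cols\s*=\s*([A-Z]+)\s*$", line
            )
            if m is None:
                raise PotentialParseError(
                    f"malformed M header at line {lineno}: {line!r}"
                )
            row_order, col_order = m.group(1), m.group(2)
            if len(row_order) != 20 or sorted(row_order) != sorted(STANDARD_AAS):
                raise PotentialParseError(
                    f"alphabet in M header at line {lineno} is not the 20 standard "
                    f"amino acids: {row_order!r}"
                )
            if col_order != row_order:
                raise PotentialParseError(
                    f"row/column alphabets differ at line {lineno}"
                )
            order = row_order
            in_body = True
            continue
        if in_body:
            if line[0].isalpha():
                continue  # wrapped description line inside header block
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError:
                raise PotentialParseError(
                    f"non-numeric cell at line {lineno}: {line!r}"
                )
    if order is None:
        raise PotentialParseError("no 'M rows = ..., cols = ...' header found")
    if len(rows) != 20:
        raise PotentialParseError(
            f"expected 20 body rows, found {len(rows)}"
        )
    energies: dict[tuple[str, str], float] = {}
    for i, row in enumerate(rows):
        if len(row) != i + 1:
            raise PotentialParseError(
                f"body row {i + 1} has {len(row)} entries, expected {i + 1}"
            )
        for j, value in enumerate(row):
            a, b = order[i], order[j]
            energies[(a, b)] = value
            energies[(b, a)] = value
    pot = ContactPotential(source_id=source_id, energies=energies)
    object.__setattr__(pot, "_order", order)
    return pot


def load_packaged_potential(name: str = "MIYS960101") -> ContactPotential:
    """Load a contact potential shipped as package data."""
    text = (
        importlib.resources.files("pspgnm.data").joinpath(f"{name}.txt").read_text()
    )
    return parse_aaindex_matrix(text)


def spring_constant(
    potential: ContactPotential,
    aa_i: str,
    aa_j: str,
    bonded: bool = False,
    convention: str = "boltzmann_negated",
) -> float:
    """Spring stiffness for a residue pair.

    Bonded (chain-adjacent) pairs get exp(-(min(MJ) - 1)) irrespective of the
    residue identities; non-bonded pairs get exp(-MJ_ij) under the default
    ``boltzmann_negated`` convention or exp(MJ_ij) under ``literal_eq2``.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if bonded:
        # Touch the table so unknown residues fail the same way as non-bonded.
        potential.energy(aa_i, aa_j)
        return math.exp(-(potential.min_energy - 1.0))
    mj = potential.energy(aa_i, aa_j)
    return math.exp(-mj if convention == "boltzmann_negated" else mj)


def make_uniform_potential(value: float = 0.0) -> ContactPotential:
    """A synthetic table with every entry equal; useful for controlled tests."""
    energies = {
        (a, b): value for a in STANDARD_AAS for b in STANDARD_AAS
    }
    return ContactPotential(source_id="UNIFORM", energies=energies)
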