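"""PDB parsing into C-alpha coarse-grained chains, and in-silico point mutants.

The model is one-bead-per-residue: a chain is reduced to its ordered CA trace
with one-letter residue identities and author numbering.  A point mutant is
the same trace with a single residue identity replaced — coordinates are never
modified, which is exactly how the weighted network "sees" a mutation (only
the spring constants touching the mutated residue change).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import gemmi
import numpy as np

from .errors import ChainNotFoundError, StructureError, WildtypeMismatchError

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues mapped to their standard parent
    "MSE": "M", "SEC": "C", "PYL": "K",
}

#: Warn when chain-adjacent CA atoms are further apart than this (chain break).
PEPTIDE_BOND_WARN_DISTANCE = 4.5


@dataclass(frozen=True)
class ResidueLabel:
    """Author residue numbering: sequence number plus optional insertion code."""

    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.number}{self.icode}"

    @classmethod
    def parse(cls, token: str) -> "ResidueLabel":
        token = token.strip()
        if token and token[-1].isalpha():
            return cls(int(token[:-1]), token[-1].upper())
        return cls(int(token))


@dataclass(frozen=True)
class MutationSpec:
    """A single amino-acid substitution, e.g. D89E on chain A."""

    chain_id: str
    position: ResidueLabel
    wt_res: str
    mut_res: str

    def __post_init__(self) -> None:
        for code in (self.wt_res, self.mut_res):
            if code not in THREE_TO_ONE.values():
                raise ValueError(f"non-standard residue code {code!r}")
        if self.wt_res == self.mut_res:
            raise ValueError("wildtype and mutant residues must differ")

    @classmethod
    def parse(cls, token: str, chain_id: str) -> "MutationSpec":
        """Parse a mutation token like ``D89E`` or ``D89AE`` (insertion code A)."""
        token = token.strip().upper()
        if len(token) < 3:
            raise ValueError(f"unparsable mutation token {token!r}")
        return cls(
            chain_id=chain_id,
            position=ResidueLabel.parse(token[1:-1]),
            wt_res=token[0],
            mut_res=token[-1],
        )

    def inverted(self) -> "MutationSpec":
        return replace(self, wt_res=self.mut_res, mut_res=self.wt_res)

    def __str__(self) -> str:
        return f"{self.wt_res}{self.position}{self.mut_res}"


@dataclass(frozen=True)
class CoarseGrainedStructure:
    """Ordered CA trace of one chain.

    ``residues`` holds (author label, one-letter code) in file order;
    ``coordinates`` is the matching (N, 3) array in Angstrom; ``bfactors`` is
    the CA temperature-factor column when the source file carried one.
    """

    structure_id: str
    chain_id: str
    residues: tuple[tuple[ResidueLabel, str], ...]
    coordinates: np.ndarray
    bfactors: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.shape != (len(self.residues), 3):
            raise StructureError(
                f"coordinate shape {coords.shape} does not match "
                f"{len(self.residues)} residues"
            )
        labels = [label for label, _ in self.residues]
        if len(set(labels)) != len(labels):
            raise StructureError("duplicate author numbering within chain")
        if self.bfactors is not None:
            b = np.asarray(self.bfactors, dtype=float)
            if b.shape != (len(self.residues),):
                raise StructureError("bfactor length mismatch")
            object.__setattr__(self, "bfactors", b)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(code for _, code in self.residues)

    def index_of(self, position: ResidueLabel) -> int:
        """0-based chain index of an author residue label."""
        for i, (label, _) in enumerate(self.residues):
            if label == position:
                return i
        raise StructureError(
            f"residue {position} not found in chain {self.chain_id}"
        )


def _pick_ca(residue: "gemmi.Residue") -> "gemmi.Atom | None":
    """Highest-occupancy CA of a residue; ties resolved by altloc order."""
    cas = [a for a in residue if a.name == "CA"]
    if not cas:
        return None
    return min(cas, key=lambda a: (-a.occ, a.altloc or "A"))


def parse_calpha(pdb_text: str, chain_id: str, structure_id: str = "") -> CoarseGrainedStructure:
    """Extract the CA trace of one chain from PDB-format text.

    Keeps the highest-occupancy alternate location, maps modified residues
    with a standard parent (e.g. MSE -> M), and skips other non-standard
    residues with a warning.  The B-factor column is retained when present.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"unreadable PDB text: {exc}") from exc
    if len(st) == 0:
        raise StructureError("PDB text contains no model")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found; available: "
            f"{[c.name for c in model]}"
        )
    residues: list[tuple[ResidueLabel, str]] = []
    coords: list[tuple[float, float, float]] = []
    bfactors: list[float] = []
    for res in chain:
        one = THREE_TO_ONE.get(res.name)
        if one is None:
            if any(a.name == "CA" for a in res):
                logger.warning(
                    "skipping non-standard residue %s %s in chain %s",
                    res.name, res.seqid, chain_id,
                )
            continue
        ca = _pick_ca(res)
        if ca is None:
            logger.warning(
                "residue %s %s has no CA atom; skipped", res.name, res.seqid
            )
            continue
        label = ResidueLabel(res.seqid.num, (res.seqid.icode or "").strip())
        residues.append((label, one))
        coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
        bfactors.append(ca.b_iso)
    if not residues:
        raise StructureError(f"no CA atoms of standard residues in chain {chain_id}")
    structure = CoarseGrainedStructure(
        structure_id=structure_id or (st.name or "unknown"),
        chain_id=chain_id,
        residues=tuple(residues),
        coordinates=np.array(coords, dtype=float),
        bfactors=np.array(bfactors, dtype=float),
    )
    _warn_chain_breaks(structure)
    return structure


def _warn_chain_breaks(structure: CoarseGrainedStructure) -> None:
    d = np.linalg.norm(np.diff(structure.coordinates, axis=0), axis=1)
    for i in np.nonzero(d > PEPTIDE_BOND_WARN_DISTANCE)[0]:
        logger.warning(
            "chain %s: CA-CA distance %.2f A between consecutive residues "
            "%s and %s exceeds %.1f A (chain break treated as bonded)",
            structure.chain_id, d[i], structure.residues[i][0],
            structure.residues[i + 1][0], PEPTIDE_BOND_WARN_DISTANCE,
        )


def apply_mutation(
    structure: CoarseGrainedStructure, spec: MutationSpec
) -> CoarseGrainedStructure:
    """Build the point mutant: same trace, one residue identity replaced.

    Rejects the mutation when the stated wildtype residue does not match the
    structure (the benchmark curation rule for mismatched wildtypes).
    """
    idx = structure.index_of(spec.position)
    label, found = structure.residues[idx]
    if found != spec.wt_res:
        raise WildtypeMismatchError(
            f"structure has {found} at {label}, mutation states {spec.wt_res}"
        )
    residues = list(structure.residues)
    residues[idx] = (label, spec.mut_res)
    return replace(structure, residues=tuple(residues))


def transform_rigid(
    structure: CoarseGrainedStructure,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> CoarseGrainedStructure:
    """Apply a rigid-body transform to the coordinates (testing aid).

    The network model depends only on inter-residue distances, so all derived
    quantities must be invariant under this operation.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not math.isclose(abs(np.linalg.det(R)), 1.0, abs_tol=1e-9):
        raise ValueError("rotation must be a 3x3 orthogonal matrix")
    coords = structure.coordinates @ R.T + np.asarray(translation, dtype=float)
    return replace(structure, coordinates=coords)
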