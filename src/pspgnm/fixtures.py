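"""Deterministic synthetic structures and benchmark tables.

Every test input is generated from a seed: ideal or perturbed alpha-helical
CA traces (rise 1.5 A, radius 2.3 A, 100 degrees per residue — which puts
|i-j| in {2, 3, 4} within a 9 A cutoff, the contact regime the model
assumes), extended chains with no non-bonded contacts, and compact random
coils.  Synthetic B-factors are an affine image of the model's own
mean-squared fluctuations plus seeded noise, so the expected sign of the
B-factor agreement is known by construction.

These fixtures emulate the geometry and bookkeeping of real benchmark data
(one chain, author numbering, experimental conditions around 25 C and pH 7)
but not its physics: they carry no side chains, no packing heterogeneity and
no experimental noise model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .potentials import STANDARD_AAS, ContactPotential, load_packaged_potential
from .structure_io import (
    CoarseGrainedStructure,
    MutationSpec,
    ResidueLabel,
    THREE_TO_ONE,
)

HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TURN_DEG = 100.0
EXTENDED_SPACING = 10.0

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k not in ("MSE", "SEC", "PYL")}

GEOMETRIES = ("ideal_helix", "perturbed_helix", "extended", "random_compact")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic chain; the seed fully determines the output."""

    n_residues: int
    geometry: str = "ideal_helix"
    seed: int = 0
    sequence: str | None = None
    perturbation_sigma: float = 0.3  # A, used by perturbed_helix

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.sequence is not None:
            if len(self.sequence) != self.n_residues:
                raise ValueError("sequence length mismatch")
            if any(c not in STANDARD_AAS for c in self.sequence):
                raise ValueError("sequence contains non-standard residues")


def _helix_coords(n: int) -> np.ndarray:
    theta = np.deg2rad(HELIX_TURN_DEG) * np.arange(n)
    return np.column_stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * np.arange(n, dtype=float),
    ])


def _random_compact_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding-ish random walk with 3.8 A steps, biased to stay compact."""
    coords = [np.zeros(3)]
    for _ in range(1, n):
        pos = coords[-1]
        centroid = np.mean(coords, axis=0)
        for _attempt in range(100):
            step = rng.normal(size=3)
            pull = centroid - pos
            norm = np.linalg.norm(pull)
            if norm > 1e-9:
                step = step + 0.5 * pull / norm
            step = 3.8 * step / np.linalg.norm(step)
            cand = pos + step
            prior = np.asarray(coords[:-1])
            if prior.size == 0 or np.min(
                np.linalg.norm(prior - cand, axis=1)
            ) > 3.5:
                break
        coords.append(cand)
    return np.asarray(coords)


def _synthetic_bfactors(
    structure: CoarseGrainedStructure,
    rng: np.random.Generator,
    potential: ContactPotential | None = None,
) -> np.ndarray:
    from .gnm_core import build_kirchhoff, decompose, pseudo_inverse, residue_msf

    potential = potential or load_packaged_potential()
    modes = decompose(build_kirchhoff(structure, potential, rc=9.0))
    if modes.zero_mode_count == 1:
        msf = residue_msf(pseudo_inverse(modes, len(structure) - 1))
        scale = np.ptp(msf) or 1.0
        base = 10.0 + 20.0 * (msf - msf.min()) / scale
    else:  # disconnected geometry (e.g. extended chain beyond cutoff)
        base = np.full(len(structure), 15.0)
    return base + rng.normal(0.0, 0.5, size=len(structure))


def make_toy_chain(
    spec: FixtureSpec, with_bfactors: bool = True
) -> tuple[CoarseGrainedStructure, str]:
    """Build a synthetic CA chain and its PDB-format text."""
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence or "".join(
        rng.choice(list(STANDARD_AAS), size=spec.n_residues)
    )
    n = spec.n_residues
    if spec.geometry in ("ideal_helix", "perturbed_helix"):
        coords = _helix_coords(n)
        if spec.geometry == "perturbed_helix":
            coords = coords + rng.normal(0, spec.perturbation_sigma, coords.shape)
    elif spec.geometry == "extended":
        coords = np.column_stack([
            EXTENDED_SPACING * np.arange(n, dtype=float),
            np.zeros(n), np.zeros(n),
        ])
    else:
        coords = _random_compact_coords(n, rng)
    structure = CoarseGrainedStructure(
        structure_id=f"SYN{spec.seed}",
        chain_id="A",
        residues=tuple(
            (ResidueLabel(i + 1), aa) for i, aa in enumerate(seq)
        ),
        coordinates=coords,
    )
    if with_bfactors:
        bf = _synthetic_bfactors(structure, rng)
        structure = CoarseGrainedStructure(
            structure_id=structure.structure_id,
            chain_id=structure.chain_id,
            residues=structure.residues,
            coordinates=structure.coordinates,
            bfactors=bf,
        )
    return structure, structure_to_pdb(structure)


def structure_to_pdb(structure: CoarseGrainedStructure) -> str:
    """Serialize a CA trace to minimal valid PDB text."""
    lines = []
    for serial, ((label, aa), xyz) in enumerate(
        zip(structure.residues, structure.coordinates), start=1
    ):
        b = structure.bfactors[serial - 1] if structure.bfactors is not None else 0.0
        lines.append(
            f"ATOM  {serial:5d}  CA  {ONE_TO_THREE[aa]:>3s} "
            f"{structure.chain_id}{label.number:4d}{label.icode or ' ':1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
            f"           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_mutant_pair(
    spec: FixtureSpec,
    mutation_position: int,
    mut_res: str | None = None,
) -> tuple[CoarseGrainedStructure, CoarseGrainedStructure, MutationSpec]:
    """A wildtype chain, its in-silico point mutant, and the mutation spec.

    ``mutation_position`` is the author residue number (1-based here); the
    mutant residue is drawn from the seed when not given.
    """
    from .structure_io import apply_mutation

    wt, _ = make_toy_chain(spec)
    if not 1 < mutation_position < spec.n_residues:
        raise ValueError("mutation position must be interior to the chain")
    label = ResidueLabel(mutation_position)
    wt_res = wt.residues[wt.index_of(label)][1]
    if mut_res is None:
        rng = np.random.default_rng(spec.seed + 7)
        choices = [a for a in STANDARD_AAS if a != wt_res]
        mut_res = str(rng.choice(choices))
    mutation = MutationSpec(chain_id=wt.chain_id, position=label,
                            wt_res=wt_res, mut_res=mut_res)
    return wt, apply_mutation(wt, mutation), mutation


def make_perturbed_copy(
    structure: CoarseGrainedStructure, sigma: float, seed: int
) -> CoarseGrainedStructure:
    """Coordinate-perturbed copy (independent-structure stand-in), Gaussian
    noise of the stated sigma in Angstrom."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, structure.coordinates.shape) if sigma > 0 else 0.0
    return replace(structure, coordinates=structure.coordinates + noise)


@dataclass(frozen=True)
class BenchmarkTable:
    """Synthetic mutation table plus the generator's own bookkeeping."""

    csv_text: str
    rows: tuple[dict, ...]
    in_range: tuple[bool, ...]  # inside [24,26] C x [6.8,7.2] pH, values present


def make_benchmark_table(n_records: int, seed: int = 0) -> BenchmarkTable:
    """Synthetic benchmark CSV: conditions peaked near 25 C / pH 7 with
    deliberate out-of-range and missing-value rows for filter tests."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(seed)
    header = "pdb_id,chain_id,mutation,temperature,ph,exp_ddg"
    rows: list[dict] = []
    lines = [header]
    flags: list[bool] = []
    for i in range(n_records):
        wt, mut = rng.choice(list(STANDARD_AAS), size=2, replace=False)
        pos = int(rng.integers(2, 60))
        temperature: float | None = round(float(rng.normal(25.0, 1.0)), 1)
        ph: float | None = round(float(rng.normal(7.0, 0.2)), 2)
        if i % 7 == 3:
            ph = None
        if i % 5 == 2:
            temperature = 37.0
        exp_ddg = round(float(rng.normal(-1.0, 1.5)), 2)
        row = {
            "pdb_id": f"SYN{i:03d}",
            "chain_id": "A",
            "mutation": f"{wt}{pos}{mut}",
            "temperature": temperature,
            "ph": ph,
            "exp_ddg": exp_ddg,
        }
        rows.append(row)
        flags.append(
            temperature is not None and ph is not None
            and 24.0 <= temperature <= 26.0 and 6.8 <= ph <= 7.2
        )
        lines.append(
            f"{row['pdb_id']},{row['chain_id']},{row['mutation']},"
            f"{'' if temperature is None else temperature},"
            f"{'' if ph is None else ph},{exp_ddg}"
        )
    return BenchmarkTable(
        csv_text="\n".join(lines) + "\n",
        rows=tuple(rows),
        in_range=tuple(flags),
    )
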