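"""Weighted Kirchhoff matrix, eigen-decomposition and fluctuation quantities.

The Gaussian network model reduces a protein to a graph Laplacian: residues
are nodes, springs are weighted edges, and the (pseudo-)inverse of the
Kirchhoff matrix gives equilibrium fluctuations.  Here the edge weights come
from a residue-pair contact potential (see :mod:`pspgnm.potentials`), chain
neighbours are always connected with the stiff bonded spring, and non-bonded
pairs are connected when their CA-CA distance is within the cutoff ``rc``.

The physical prefactor 3*k_B*T/gamma multiplying the pseudo-inverse is fixed
to 1: it rescales every fluctuation uniformly and therefore cancels in
contact-break orderings, correlations and the free-energy difference; the
model carries no explicit temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.linalg
import scipy.spatial.distance
import scipy.stats

from .errors import DegenerateInputError, UnstableModelError
from .potentials import ContactPotential, spring_constant
from .structure_io import CoarseGrainedStructure

#: Relative eigenvalue tolerance: lambda < ZERO_TOL * max(lambda_max, 1)
#: counts as a zero mode.
ZERO_TOLERANCE = 1e-8

Pair = tuple[int, int]


def _ordered(i: int, j: int) -> Pair:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class KirchhoffMatrix:
    """Symmetric weighted graph Laplacian of the residue network."""

    matrix: np.ndarray
    bonded_pairs: frozenset[Pair]
    contacts: frozenset[Pair]
    rc: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Kirchhoff matrix must be square")

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_springs(
        cls,
        n: int,
        springs: Mapping[Pair, float],
        bonded_pairs: frozenset[Pair] | None = None,
        rc: float = float("nan"),
    ) -> "KirchhoffMatrix":
        """Assemble a Laplacian from an explicit {(i, j): stiffness} map."""
        m = np.zeros((n, n))
        bonded = frozenset(bonded_pairs or ())
        contacts = []
        for (i, j), k in springs.items():
            if i == j:
                raise ValueError("self-springs are not allowed")
            if k <= 0:
                raise ValueError("spring constants must be positive")
            m[i, j] = m[j, i] = -k
            if _ordered(i, j) not in bonded:
                contacts.append(_ordered(i, j))
        np.fill_diagonal(m, 0.0)
        np.fill_diagonal(m, -m.sum(axis=1))
        return cls(matrix=m, bonded_pairs=bonded,
                   contacts=frozenset(contacts), rc=rc)

    def without_contact(self, pair: Pair) -> "KirchhoffMatrix":
        """Return a copy with one non-bonded contact removed."""
        i, j = _ordered(*pair)
        if (i, j) not in self.contacts:
            raise ValueError(f"pair {(i, j)} is not a removable contact")
        m = self.matrix.copy()
        k = -m[i, j]
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= k
        m[j, j] -= k
        return KirchhoffMatrix(
            matrix=m,
            bonded_pairs=self.bonded_pairs,
            contacts=self.contacts - {(i, j)},
            rc=self.rc,
        )


@dataclass(frozen=True)
class ModeSet:
    """Eigensystem of a Kirchhoff matrix, eigenvalues ascending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # column k matches eigenvalues[k]
    zero_mode_count: int = field(init=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.eigenvalues, dtype=float)
        v = np.asarray(self.eigenvectors, dtype=float)
        object.__setattr__(self, "eigenvalues", w)
        object.__setattr__(self, "eigenvectors", v)
        tol = ZERO_TOLERANCE * max(float(w[-1]), 1.0)
        object.__setattr__(self, "zero_mode_count", int(np.sum(w < tol)))


def build_kirchhoff(
    structure: CoarseGrainedStructure,
    potential: ContactPotential,
    rc: float = 9.0,
    convention: str = "boltzmann_negated",
) -> KirchhoffMatrix:
    """Weighted Kirchhoff matrix of a CA trace.

    Chain-adjacent pairs are always connected with the stiff bonded spring;
    other pairs are connected iff their CA-CA distance is <= ``rc``.
    """
    n = len(structure)
    if n < 2:
        raise ValueError("structure must have at least 2 residues")
    seq = structure.sequence
    dist = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(structure.coordinates)
    )
    springs: dict[Pair, float] = {}
    bonded = frozenset((i, i + 1) for i in range(n - 1))
    for i in range(n - 1):
        springs[(i, i + 1)] = spring_constant(
            potential, seq[i], seq[i + 1], bonded=True, convention=convention
        )
    for i in range(n):
        for j in range(i + 2, n):
            if dist[i, j] <= rc:
                springs[(i, j)] = spring_constant(
                    potential, seq[i], seq[j], bonded=False, convention=convention
                )
    return KirchhoffMatrix.from_springs(n, springs, bonded_pairs=bonded, rc=rc)


def decompose(kirchhoff: KirchhoffMatrix) -> ModeSet:
    """Full symmetric eigen-decomposition, eigenvalues ascending."""
    try:
        w, v = scipy.linalg.eigh(kirchhoff.matrix)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise UnstableModelError(f"eigen-decomposition failed: {exc}") from exc
    return ModeSet(eigenvalues=w, eigenvectors=v)


def pseudo_inverse(modes: ModeSet, n_modes: int) -> np.ndarray:
    """Truncated pseudo-inverse from the ``n_modes`` slowest non-zero modes.

    Raises :class:`UnstableModelError` when the network has fragmented
    (more than one zero eigenvalue).
    """
    if modes.zero_mode_count > 1:
        raise UnstableModelError(
            f"network fragmented: {modes.zero_mode_count} zero modes"
        )
    n = modes.eigenvalues.shape[0]
    if not 1 <= n_modes <= n - 1:
        raise ValueError(f"n_modes must be in [1, {n - 1}], got {n_modes}")
    lo = modes.zero_mode_count
    hi = lo + n_modes
    w = modes.eigenvalues[lo:hi]
    v = modes.eigenvectors[:, lo:hi]
    p = (v / w) @ v.T
    # enforce bit-exact symmetry (BLAS products are only symmetric to rounding)
    return (p + p.T) / 2.0


def distance_msf(pinv: np.ndarray, i: int, j: int) -> float:
    """Mean-squared fluctuation of the i-j separation (internal distance).

    For uniform springs and full modes this is the graph effective resistance
    between i and j.
    """
    if i == j:
        raise ValueError("distance MSF requires two distinct residues")
    return float(pinv[i, i] + pinv[j, j] - 2.0 * pinv[i, j])


def residue_msf(pinv: np.ndarray) -> np.ndarray:
    """Per-residue mean-squared fluctuation (diagonal of the pseudo-inverse)."""
    return np.asarray(pinv).diagonal().copy()


def cross_correlation(pinv: np.ndarray) -> np.ndarray:
    """Normalized residue-residue cross-correlation map.

    C_ij = pinv_ij / sqrt(pinv_ii * pinv_jj); the diagonal is exactly 1.
    """
    d = np.asarray(pinv).diagonal()
    if np.any(d <= 0):
        raise DegenerateInputError("pseudo-inverse has a non-positive diagonal entry")
    s = np.sqrt(d)
    c = pinv / np.outer(s, s)
    np.fill_diagonal(c, 1.0)
    return c


def bfactor_agreement(
    structure: CoarseGrainedStructure, msf_vector: np.ndarray
) -> float:
    """Pearson correlation between computed MSF and experimental B-factors."""
    if structure.bfactors is None:
        raise DegenerateInputError("structure carries no B-factors")
    msf = np.asarray(msf_vector, dtype=float)
    if msf.shape != structure.bfactors.shape:
        raise ValueError("MSF vector length does not match structure")
    if np.std(msf) == 0 or np.std(structure.bfactors) == 0:
        raise DegenerateInputError("zero variance in MSF or B-factors")
    return float(scipy.stats.pearsonr(msf, structure.bfactors).statistic)
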