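"""Simulated partial unfolding by iterative removal of high-fluctuation contacts.

Each iteration rebuilds the eigensystem of the current Kirchhoff matrix,
computes the mean-squared fluctuation (MSF) of the inter-residue distance for
every still-connected non-bonded contact from the truncated pseudo-inverse,
and removes the contact with the largest MSF — the contact most likely to
break next.  The loop stops once a target fraction of the initial contacts
(default 50%, a partially unfolded state) is broken, or earlier if the
network fragments (more than one zero eigenvalue).

Bonded (chain-adjacent) springs never break and do not count as contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping

from .errors import UnstableModelError
from .gnm_core import (
    KirchhoffMatrix,
    Pair,
    decompose,
    distance_msf,
    pseudo_inverse,
)
from .potentials import ContactPotential, spring_constant
from .structure_io import CoarseGrainedStructure


@dataclass(frozen=True)
class UnfoldingEvent:
    """One broken contact: iteration (1-based), residue pair i<j, MSF at break."""

    iteration: int
    i: int
    j: int
    msf: float


@dataclass(frozen=True)
class UnfoldingTrace:
    """Ordered record of the contacts broken during partial unfolding."""

    initial_contact_count: int
    events: tuple[UnfoldingEvent, ...]
    termination: str  # "reached_fraction" | "unstable"
    break_fraction: float
    sequence: str | None = None

    def to_tsv(self) -> str:
        lines = ["iteration\tres_i\tres_j\tmsf"]
        lines += [
            f"{e.iteration}\t{e.i}\t{e.j}\t{e.msf!r}" for e in self.events
        ]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class BrokenContactRecord:
    """A contact broken at a given position, re-ranked in break order."""

    rank: int
    partner_index: int
    partner_restype: str
    msf_at_break: float


def enumerate_contacts(structure: CoarseGrainedStructure, rc: float = 9.0) -> set[Pair]:
    """All non-bonded pairs (|i-j| > 1) whose CA-CA distance is within ``rc``."""
    import scipy.spatial.distance as ssd

    n = len(structure)
    dist = ssd.squareform(ssd.pdist(structure.coordinates))
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 2, n)
        if dist[i, j] <= rc
    }


def unfold(
    structure: CoarseGrainedStructure,
    potential: ContactPotential,
    rc: float = 9.0,
    n_modes: int = 10,
    break_fraction: float = 0.5,
    convention: str = "boltzmann_negated",
    breaks_per_iter: int = 1,
) -> UnfoldingTrace:
    """Partially unfold a structure; returns the ordered break trace.

    ``n_modes`` slowest non-zero modes reconstruct the pseudo-inverse each
    iteration (clipped to N-1 for very small chains).  ``breaks_per_iter``
    allows removing the top-k contacts per iteration instead of one.
    """
    n = len(structure)
    seq = structure.sequence
    bonded = frozenset((i, i + 1) for i in range(n - 1))
    springs: dict[Pair, float] = {
        (i, i + 1): spring_constant(potential, seq[i], seq[i + 1], bonded=True,
                                    convention=convention)
        for i in range(n - 1)
    }
    for (i, j) in enumerate_contacts(structure, rc):
        springs[(i, j)] = spring_constant(potential, seq[i], seq[j],
                                          bonded=False, convention=convention)
    trace = unfold_network(
        n, springs, bonded_pairs=bonded, n_modes=n_modes,
        break_fraction=break_fraction, breaks_per_iter=breaks_per_iter, rc=rc,
    )
    return UnfoldingTrace(
        initial_contact_count=trace.initial_contact_count,
        events=trace.events,
        termination=trace.termination,
        break_fraction=trace.break_fraction,
        sequence=seq,
    )


def unfold_network(
    n: int,
    springs: Mapping[Pair, float],
    bonded_pairs: frozenset[Pair],
    n_modes: int = 10,
    break_fraction: float = 0.5,
    breaks_per_iter: int = 1,
    rc: float = float("nan"),
) -> UnfoldingTrace:
    """Unfolding loop on an explicit spring network.

    Exposed separately so the loop can run on arbitrary weighted graphs
    (including networks without a connecting bonded backbone, which can
    fragment and exercise the unstable termination).
    """
    if not 0 < break_fraction <= 1:
        raise ValueError("break_fraction must be in (0, 1]")
    if breaks_per_iter < 1:
        raise ValueError("breaks_per_iter must be >= 1")
    kirchhoff = KirchhoffMatrix.from_springs(n, springs, bonded_pairs, rc=rc)
    initial = len(kirchhoff.contacts)
    if initial == 0:
        raise ValueError("no breakable contacts in the starting network")
    target = math.ceil(break_fraction * initial)
    events: list[UnfoldingEvent] = []
    termination = "reached_fraction"
    iteration = 0
    while len(events) < target:
        iteration += 1
        modes = decompose(kirchhoff)
        if modes.zero_mode_count > 1:
            termination = "unstable"
            break
        pinv = pseudo_inverse(modes, min(n_modes, n - 1))
        ranked = sorted(
            kirchhoff.contacts,
            key=lambda p: (-distance_msf(pinv, *p), p[0], p[1]),
        )
        for pair in ranked[: min(breaks_per_iter, target - len(events))]:
            events.append(
                UnfoldingEvent(iteration, pair[0], pair[1],
                               distance_msf(pinv, *pair))
            )
            kirchhoff = kirchhoff.without_contact(pair)
    return UnfoldingTrace(
        initial_contact_count=initial,
        events=tuple(events),
        termination=termination,
        break_fraction=break_fraction,
    )


def broken_contacts_at(
    trace: UnfoldingTrace, position_index: int
) -> list[BrokenContactRecord]:
    """Contacts broken at one position, re-ranked 1..n in break order.

    Partner residue types are taken from the trace's sequence when available
    (``?`` otherwise).  An empty list is a legal result and signals that the
    free-energy change for a mutation at this position defaults to zero.
    """
    records: list[BrokenContactRecord] = []
    for event in trace.events:
        if position_index in (event.i, event.j):
            partner = event.j if event.i == position_index else event.i
            records.append(
                BrokenContactRecord(
                    rank=len(records) + 1,
                    partner_index=partner,
                    partner_restype=(
                        trace.sequence[partner] if trace.sequence else "?"
                    ),
                    msf_at_break=event.msf,
                )
            )
    return records
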