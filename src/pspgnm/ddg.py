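"""Unfolding free-energy change of a point mutation from rank-matched contacts.

Both the wildtype and the in-silico mutant (same CA trace, one residue
identity changed) are partially unfolded.  The contacts broken at the
mutation position are ranked in break order on each side, and ranks present
on both sides are paired — the k-th contact broken at the site in the
wildtype against the k-th in the mutant, regardless of partner identity.
Over the paired ranks,

    ddG = -[(sum MJ_mut - sum MJ_wt) - (sum MSF_mut - sum MSF_wt)]

where MJ is the contact energy between the residue at the mutation position
(its wildtype identity on one side, mutant identity on the other) and the
partner residue, and the distance MSF recorded when each contact broke acts
as the entropy term.  Positive ddG means the mutation stabilizes the fold.

If no contact involving the mutation position breaks on either side, the two
partially unfolded states are locally indistinguishable and ddG defaults to
zero.  Reverse mutations reuse the same machinery with the two structures
swapped, which makes raw forward and reverse values exactly antisymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .config import RunConfig
from .errors import DegenerateInputError
from .gnm_core import build_kirchhoff, decompose, distance_msf, pseudo_inverse
from .potentials import ContactPotential
from .structure_io import CoarseGrainedStructure, MutationSpec, apply_mutation
from .unfolding import BrokenContactRecord, UnfoldingTrace, broken_contacts_at, unfold


@dataclass(frozen=True)
class DdgResult:
    """Raw and rescaled ddG for one wildtype/mutant pair."""

    raw_ddg: float
    scaled_ddg: float
    n_matched: int
    status: str  # "computed" | "defaulted_zero"
    direction: str  # "forward" | "reverse"
    components: tuple[float, float, float, float]  # (sumMJ_mut, sumMJ_wt, sumMSF_mut, sumMSF_wt)
    mutation: str = ""
    params: RunConfig | None = None


def match_ranks(
    wt_list: list[BrokenContactRecord],
    mut_list: list[BrokenContactRecord],
) -> list[tuple[BrokenContactRecord, BrokenContactRecord]]:
    """Pair wildtype and mutant break records sharing the same rank."""
    return list(zip(wt_list, mut_list))


def _native_msf_lookup(
    structure: CoarseGrainedStructure,
    potential: ContactPotential,
    params: RunConfig,
) -> np.ndarray:
    kirchhoff = build_kirchhoff(structure, potential, rc=params.rc,
                                convention=params.convention)
    modes = decompose(kirchhoff)
    return pseudo_inverse(modes, min(params.n_modes, len(structure) - 1))


def _ddg_between(
    wt_structure: CoarseGrainedStructure,
    mut_structure: CoarseGrainedStructure,
    position_index: int,
    wt_res: str,
    mut_res: str,
    potential: ContactPotential,
    params: RunConfig,
    direction: str,
    mutation_label: str,
) -> DdgResult:
    """Shared forward/reverse core; the caller fixes which structure is which."""
    from .unfolding import enumerate_contacts

    slope, intercept = params.scale
    if not enumerate_contacts(wt_structure, params.rc) or not enumerate_contacts(
        mut_structure, params.rc
    ):
        # nothing can ever break: the theoretical-zero fallback applies
        return DdgResult(
            raw_ddg=0.0, scaled_ddg=0.0, n_matched=0, status="defaulted_zero",
            direction=direction, components=(0.0, 0.0, 0.0, 0.0),
            mutation=mutation_label, params=params,
        )
    wt_trace = unfold(wt_structure, potential, rc=params.rc,
                      n_modes=params.n_modes,
                      break_fraction=params.break_fraction,
                      convention=params.convention,
                      breaks_per_iter=params.breaks_per_iter)
    mut_trace = unfold(mut_structure, potential, rc=params.rc,
                       n_modes=params.n_modes,
                       break_fraction=params.break_fraction,
                       convention=params.convention,
                       breaks_per_iter=params.breaks_per_iter)
    wt_broken = broken_contacts_at(wt_trace, position_index)
    mut_broken = broken_contacts_at(mut_trace, position_index)
    if not wt_broken or not mut_broken:
        return DdgResult(
            raw_ddg=0.0, scaled_ddg=0.0, n_matched=0, status="defaulted_zero",
            direction=direction, components=(0.0, 0.0, 0.0, 0.0),
            mutation=mutation_label, params=params,
        )
    if params.entropy_from == "native":
        wt_pinv = _native_msf_lookup(wt_structure, potential, params)
        mut_pinv = _native_msf_lookup(mut_structure, potential, params)
        wt_msf = [distance_msf(wt_pinv, position_index, r.partner_index)
                  for r in wt_broken]
        mut_msf = [distance_msf(mut_pinv, position_index, r.partner_index)
                   for r in mut_broken]
    else:
        wt_msf = [r.msf_at_break for r in wt_broken]
        mut_msf = [r.msf_at_break for r in mut_broken]
    pairs = match_ranks(wt_broken, mut_broken)
    n = len(pairs)
    sum_mj_wt = sum(potential.energy(wt_res, w.partner_restype)
                    for w, _ in pairs)
    sum_mj_mut = sum(potential.energy(mut_res, m.partner_restype)
                     for _, m in pairs)
    sum_msf_wt = sum(wt_msf[:n])
    sum_msf_mut = sum(mut_msf[:n])
    raw = -((sum_mj_mut - sum_mj_wt) - (sum_msf_mut - sum_msf_wt))
    # Reverse-direction scaled values use -scaled(-raw) so that the scaled
    # forward/reverse pair stays exactly antisymmetric even with a non-zero
    # intercept.
    if direction == "reverse":
        scaled = slope * raw - intercept
    else:
        scaled = slope * raw + intercept
    return DdgResult(
        raw_ddg=raw, scaled_ddg=scaled, n_matched=n, status="computed",
        direction=direction,
        components=(sum_mj_mut, sum_mj_wt, sum_msf_mut, sum_msf_wt),
        mutation=mutation_label, params=params,
    )


def compute_ddg(
    wt_structure: CoarseGrainedStructure,
    mutation: MutationSpec,
    potential: ContactPotential,
    params: RunConfig | None = None,
) -> DdgResult:
    """Forward ddG: the mutant structure is built in silico from the wildtype."""
    params = params or RunConfig()
    mut_structure = apply_mutation(wt_structure, mutation)
    idx = wt_structure.index_of(mutation.position)
    return _ddg_between(
        wt_structure, mut_structure, idx, mutation.wt_res, mutation.mut_res,
        potential, params, direction="forward", mutation_label=str(mutation),
    )


def compute_reverse_ddg(
    wt_structure: CoarseGrainedStructure,
    mut_structure: CoarseGrainedStructure | None,
    mutation: MutationSpec,
    potential: ContactPotential,
    params: RunConfig | None = None,
) -> DdgResult:
    """Reverse ddG: the wildtype and mutant structures swap roles.

    ``mut_structure`` may be the in-silico mutant (None builds it from the
    wildtype) or an independently determined structure of the mutant protein.
    """
    params = params or RunConfig()
    if mut_structure is None:
        mut_structure = apply_mutation(wt_structure, mutation)
    inverted = mutation.inverted()
    idx = mut_structure.index_of(inverted.position)
    found = mut_structure.residues[idx][1]
    if found != inverted.wt_res:
        from .errors import WildtypeMismatchError

        raise WildtypeMismatchError(
            f"mutant structure has {found} at {inverted.position}, "
            f"expected {inverted.wt_res}"
        )
    return _ddg_between(
        mut_structure, wt_structure, idx, inverted.wt_res, inverted.mut_res,
        potential, params, direction="reverse", mutation_label=str(inverted),
    )


def fit_scaling(raw_values, experimental_values) -> tuple[float, float]:
    """Ordinary least squares of experimental on raw ddG: (slope, intercept)."""
    raw = np.asarray(raw_values, dtype=float)
    exp = np.asarray(experimental_values, dtype=float)
    if raw.shape != exp.shape or raw.size < 3:
        raise DegenerateInputError("need >= 3 paired values")
    if np.std(raw) == 0:
        raise DegenerateInputError("raw values have zero variance")
    fit = scipy.stats.linregress(raw, exp)
    return float(fit.slope), float(fit.intercept)
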