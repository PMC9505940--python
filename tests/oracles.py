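"""Independent brute-force implementations used as oracles.

Everything here is written directly from the mathematical definitions
(double loops, explicit modal sums, textbook statistics) and deliberately
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- potentials
def parse_aaindex_brute(text: str) -> dict[tuple[str, str], float]:
    """Minimal second parser for AAindex matrix records."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    order = None
    body = []
    for ln in lines:
        if ln.startswith("M "):
            # letters after 'rows =' up to the comma
            rows_part = ln.split("rows =")[1].split(",")[0]
            order = "".join(c for c in rows_part if c.isalpha())
            continue
        if order is not None and not ln[0].isalpha() and not ln.startswith("//"):
            body.append([float(t) for t in ln.split()])
    assert order is not None and len(body) == len(order)
    table = {}
    for i, row in enumerate(body):
        for j, val in enumerate(row):
            table[(order[i], order[j])] = val
            table[(order[j], order[i])] = val
    return table


def spring_brute(energies, min_energy, a, b, bonded, convention) -> float:
    if bonded:
        return math.exp(-(min_energy - 1.0))
    mj = energies[(a, b)]
    return math.exp(-mj) if convention == "boltzmann_negated" else math.exp(mj)


# ------------------------------------------------------------------ GNM core
def kirchhoff_brute(structure, potential, rc, convention="boltzmann_negated",
                    removed=()):
    """O(N^2) double-loop Kirchhoff construction from first principles."""
    n = len(structure)
    seq = structure.sequence
    xyz = np.asarray(structure.coordinates)
    removed = {tuple(sorted(p)) for p in removed}
    gamma = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if abs(i - j) == 1:
                k = spring_brute(potential.energies, potential.min_energy,
                                 seq[i], seq[j], True, convention)
            else:
                d = math.dist(xyz[i], xyz[j])
                if d > rc or tuple(sorted((i, j))) in removed:
                    continue
                k = spring_brute(potential.energies, potential.min_energy,
                                 seq[i], seq[j], False, convention)
            gamma[i, j] = -k
    for i in range(n):
        gamma[i, i] = -sum(gamma[i, j] for j in range(n) if j != i)
    return gamma


def truncated_pinv_brute(gamma, n_modes, zero_tol=1e-8):
    """Explicit modal-sum pseudo-inverse over the slowest non-zero modes."""
    w, v = np.linalg.eigh(gamma)
    tol = zero_tol * max(w[-1], 1.0)
    nonzero = [k for k in range(len(w)) if w[k] >= tol]
    pinv = np.zeros_like(gamma)
    for k in nonzero[:n_modes]:
        pinv += np.outer(v[:, k], v[:, k]) / w[k]
    return pinv


def distance_msf_brute(gamma, i, j, n_modes, zero_tol=1e-8):
    """Modal sum: sum_k (V_k[i] - V_k[j])^2 / lambda_k."""
    w, v = np.linalg.eigh(gamma)
    tol = zero_tol * max(w[-1], 1.0)
    nonzero = [k for k in range(len(w)) if w[k] >= tol]
    return sum((v[i, k] - v[j, k]) ** 2 / w[k] for k in nonzero[:n_modes])


def contacts_brute(structure, rc):
    n = len(structure)
    xyz = np.asarray(structure.coordinates)
    out = set()
    for i in range(n):
        for j in range(i + 2, n):
            if math.dist(xyz[i], xyz[j]) <= rc:
                out.add((i, j))
    return out


# ----------------------------------------------------------------- unfolding
def unfold_brute(structure, potential, rc=9.0, n_modes=10, break_fraction=0.5,
                 convention="boltzmann_negated", zero_tol=1e-8):
    """From-scratch unfolding: Gamma rebuilt by double loop every iteration.

    Returns (events, termination) with events [(iteration, i, j, msf), ...].
    """
    contacts = sorted(contacts_brute(structure, rc))
    initial = len(contacts)
    target = math.ceil(break_fraction * initial)
    removed: list[tuple[int, int]] = []
    events = []
    iteration = 0
    n = len(structure)
    while len(events) < target:
        iteration += 1
        gamma = kirchhoff_brute(structure, potential, rc, convention, removed)
        w, _ = np.linalg.eigh(gamma)
        tol = zero_tol * max(w[-1], 1.0)
        if sum(1 for x in w if x < tol) > 1:
            return events, "unstable"
        live = [p for p in contacts if p not in removed]
        best_pair, best_msf = None, -math.inf
        for pair in live:
            msf = distance_msf_brute(gamma, *pair, min(n_modes, n - 1), zero_tol)
            # strict '>' over pairs visited in (i, j) order reproduces the
            # smallest-(i, j) tie-break independently
            if msf > best_msf:
                best_pair, best_msf = pair, msf
        events.append((iteration, best_pair[0], best_pair[1], best_msf))
        removed.append(best_pair)
    return events, "reached_fraction"


def broken_at_brute(events, position):
    out = []
    for (_it, i, j, msf) in events:
        if position in (i, j):
            out.append((len(out) + 1, j if i == position else i, msf))
    return out


def ddg_brute(wt_structure, mut_structure, position_index, wt_res, mut_res,
              potential, rc=9.0, n_modes=10, break_fraction=0.5,
              convention="boltzmann_negated"):
    """End-to-end free-energy oracle assembled from the brute-force traces."""
    wt_events, _ = unfold_brute(wt_structure, potential, rc, n_modes,
                                break_fraction, convention)
    mut_events, _ = unfold_brute(mut_structure, potential, rc, n_modes,
                                 break_fraction, convention)
    wt_broken = broken_at_brute(wt_events, position_index)
    mut_broken = broken_at_brute(mut_events, position_index)
    if not wt_broken or not mut_broken:
        return 0.0, 0, "defaulted_zero"
    n = min(len(wt_broken), len(mut_broken))
    seq_wt = wt_structure.sequence
    seq_mut = mut_structure.sequence
    sum_mj_wt = sum(potential.energies[(wt_res, seq_wt[p])]
                    for (_r, p, _m) in wt_broken[:n])
    sum_mj_mut = sum(potential.energies[(mut_res, seq_mut[p])]
                     for (_r, p, _m) in mut_broken[:n])
    sum_msf_wt = sum(m for (_r, _p, m) in wt_broken[:n])
    sum_msf_mut = sum(m for (_r, _p, m) in mut_broken[:n])
    raw = -((sum_mj_mut - sum_mj_wt) - (sum_msf_mut - sum_msf_wt))
    return raw, n, "computed"


# ------------------------------------------------------------------- metrics
def pearson_brute(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def rmse_brute(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)) / len(x))


def bias_brute(fwd, rev):
    return sum(f + r for f, r in zip(fwd, rev)) / (2 * len(fwd))


def effective_resistance_brute(n, edges, i, j):
    """Effective resistance via full Moore-Penrose pseudo-inverse."""
    lap = np.zeros((n, n))
    for (a, b), w in edges.items():
        lap[a, b] -= w
        lap[b, a] -= w
    np.fill_diagonal(lap, 0)
    np.fill_diagonal(lap, -lap.sum(axis=1))
    p = np.linalg.pinv(lap)
    return p[i, i] + p[j, j] - 2 * p[i, j]
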