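# Methods

## Model

The package implements a weighted Gaussian network model (GNM) for
predicting the unfolding free-energy change (ΔΔG) of single point
mutations. A protein chain is reduced to its Cα trace; the potential is the
standard GNM quadratic form V = (γ/2) ΣΔR_i Γ_ij ΔR_j, with the Kirchhoff
(connectivity) matrix Γ carrying all structure and sequence information.
Chain-adjacent residues (|i−j| = 1) are always connected with a stiff
spring exp(−(min(MJ) − 1)) that mimics the covalent backbone; other pairs
are connected when their Cα–Cα distance is within the cutoff r_c, with
stiffness equal to the Boltzmann weight exp(−MJ_ij) of the pair's
Miyazawa–Jernigan contact energy. A pair with a more favorable (more
negative) contact energy therefore gets a stiffer spring and a smaller
mean-squared fluctuation (MSF) of its inter-residue distance.

**Sign convention.** The two published forms of the non-bonded weight
disagree: a literal reading gives exp(MJ_ij), while the Boltzmann-weight
narrative and the bonded-spring formula exp(−(min−1)) both require
exp(−MJ_ij) (stronger interaction → stiffer spring → lower MSF). The
default is `boltzmann_negated` (exp(−MJ)); the literal form is selectable
with `convention="literal_eq2"` for comparison experiments. Note that
under the literal form the bonded spring no longer dominates all
non-bonded springs.

**Prefactor.** The physical prefactor 3k_BT/γ of the pseudo-inverse is set
to 1. It rescales all fluctuations uniformly and cancels in contact-break
orderings, correlations, and the ΔΔG difference; the model carries no
explicit temperature (experimental temperature enters only as a dataset
stratification variable).

## Partial unfolding

Contacts are the non-bonded pairs within r_c in the starting structure.
Each iteration: (1) eigendecompose the current Γ (full symmetric solver —
the matrices are dense and desk-scale, a few thousand residues at most);
(2) if more than one eigenvalue is below tolerance the network has
fragmented and the run terminates `unstable`; (3) rebuild the truncated
pseudo-inverse from the N_modes slowest non-zero modes; (4) remove the
single still-connected contact with the largest distance MSF and record it.
The loop stops once ceil(break_fraction × initial contacts) contacts are
broken (default 0.5, a partially unfolded state). Exact MSF ties are broken
toward the smallest (i, j) pair for determinism; ideal-helix fixtures do
produce such ties. A `breaks_per_iter > 1` option removes the top-k
contacts per iteration instead of one.

Zero tolerance: an eigenvalue counts as zero when λ < 1e−8 × max(λ_max, 1),
which is robust across the spring scales produced by the bonded weight
(~e^8). Because bonded springs never break, a single-chain network can
never fragment during unfolding; the unstable path is reachable through
the lower-level `unfold_network()` entry point, which accepts arbitrary
weighted graphs (and is how the termination contract is exercised in
tests).

## ΔΔG from rank-matched broken contacts

The mutant structure is the wildtype trace with one residue identity
replaced — coordinates are untouched, so only springs touching the mutated
residue change. Both structures are unfolded with identical parameters.
Contacts broken at the mutation site are ranked 1..n in break order on each
side; rank k in the wildtype is paired with rank k in the mutant
(partners need not coincide), over k = 1..min(n_wt, n_mut). Then
ΔΔG = −[(ΣMJ_mut − ΣMJ_wt) − (ΣMSF_mut − ΣMSF_wt)], where the MJ terms use
the site's residue type (wildtype vs mutant identity — the only way the two
sides differ energetically) against each matched partner's type, and the
MSF terms are the values recorded at the iteration each contact broke.

**Entropy term choice.** The per-contact MSF entering the entropy sum is
the at-break value, the only per-contact MSF the unfolding narrative
produces; `entropy_from="native"` substitutes the intact-structure MSF as
an alternative reading.

**Defaulted zero.** When no contact involving the site breaks on either
side (including structures with no contacts at all), the partially unfolded
states are locally indistinguishable and ΔΔG is assigned 0. With min-rank
pairing, "empty on either side" and "empty on both sides" coincide
operationally.

**Reverse mutations** swap the two structures and invert the mutation.
Because unfolding is deterministic and the formula is an exact difference,
raw reverse values are bit-exact negations of forward values when both come
from the same structure pair — antisymmetry −1 and bias 0 are identities of
the construction, which is what the acceptance script measures. With
independently determined mutant structures the identity no longer holds
exactly (the published benchmark with separate forward/reverse crystal
structures reports −0.97).

**Rescaling.** Published predictions are linearly rescaled by a regression
fit on a training benchmark whose coefficients are not public; the default
is the identity (raw output). `fit_scaling` re-derives coefficients from
any paired raw/experimental data. For reverse predictions the scaled value
is −scaled(−raw), i.e. slope·raw − intercept, so a non-zero intercept
cannot break scaled antisymmetry.

## Parameters

| parameter | default | meaning |
|---|---|---|
| r_c | 9 Å | Cα contact cutoff (scan range 7–12 Å) |
| N_modes | 10 | slowest non-zero modes in the pseudo-inverse (20 is the documented alternate) |
| break_fraction | 0.5 | fraction of initial contacts broken |
| convention | boltzmann_negated | non-bonded spring sign (see above) |
| scale | (1, 0) | linear rescaling of raw ΔΔG |
| zero_tolerance | 1e−8 | relative eigenvalue zero threshold |
| zeros | include | whether evaluation includes defaulted-zero records |

## Synthetic data

The fixture generator emulates the geometric regime the method assumes:
ideal helices (rise 1.5 Å, radius 2.3 Å, 100°/residue, giving a connected
|i−j| ∈ {2..4} contact network at 9 Å), noise-perturbed helices, compact
self-avoiding random walks with 3.8 Å virtual bonds, and extended chains
with no non-bonded contacts (the degenerate, defaulted-zero case; their
10 Å virtual bonds deliberately trip the chain-break warning). Sequences
are drawn uniformly from the 20 standard residues unless given. Synthetic
B-factors are an affine image of the model's own residue MSF plus Gaussian
noise (σ = 0.5 on a 10–30 scale), so the expected sign of the
B-factor/MSF agreement is known by construction. Synthetic benchmark
tables draw temperature ~ N(25 °C, 1 °C) and pH ~ N(7.0, 0.2), with
deliberate out-of-range (37 °C) and missing-value rows for filter tests.

What passing on fixtures shows: internal consistency (oracle equivalence,
antisymmetry, determinism, invariants), not predictive accuracy on real
proteins — fixtures have no side-chain packing, no experimental ΔΔG, and
idealized geometry. Accuracy claims require the published benchmarks,
which need structure downloads and are out of desk scope.

## Problem sizes

Tests and the acceptance script use 20–30-residue chains (≈60–120
contacts, ≈30–60 unfolding iterations), 20 wildtype/mutant pairs for the
consistency metrics and 10 fixtures for oracle equivalence — sizes chosen
so the full suite re-verifies every contract in well under a minute of
numerical work while exercising non-trivial contact networks.

## Known limitations

- Single point mutations only; multi-site mutants are out of scope by
  construction (one rank list per site).
- One chain per run; inter-chain contacts are not modeled.
- No explicit temperature or pH dependence in the model; conditions are
  used only to stratify evaluation data.
- The mutation is represented purely as an identity change at fixed
  geometry; real mutant structures relax.
- Chain breaks are bridged with bonded springs (with a warning) because
  the bonded term carries no distance condition; a gap therefore never
  disconnects the network.
- The packaged MJ table is transcribed from the published 20×20 contact
  energies; min(MJ) = −7.37 (Leu–Leu) in RT units.
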