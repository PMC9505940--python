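"""Benchmark-table ingestion, condition filters, and scoring metrics.

Agreement with experiment is scored with the Pearson correlation coefficient
and the root-mean-squared error (divisor N).  Thermodynamic consistency of
forward/reverse predictions is scored with the antisymmetry (Pearson between
forward and reverse values; perfect consistency is -1) and the bias score
delta = sum_i (fwd_i + rev_i) / (2N), which is 0 when neither direction is
systematically favoured.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .ddg import compute_ddg
from .errors import DegenerateInputError, PspGnmError
from .potentials import ContactPotential
from .structure_io import CoarseGrainedStructure, MutationSpec, ResidueLabel

REQUIRED_COLUMNS = ("pdb_id", "chain_id", "mutation", "temperature", "ph", "exp_ddg")


@dataclass(frozen=True)
class MutationTableRecord:
    """One benchmark row: a mutation with its experimental conditions and ddG."""

    pdb_id: str
    chain_id: str
    mutation: MutationSpec
    temperature: float | None  # Celsius
    ph: float | None
    exp_ddg: float
    direction: str = "forward"


@dataclass
class TableReadResult:
    records: list[MutationTableRecord]
    rejects: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(x) else x


def read_mutation_table(
    path_or_text: str | Path, dialect: str = "csv"
) -> TableReadResult:
    """Read a delimited mutation table; malformed rows go to a rejects report.

    The header must name pdb_id, chain_id, mutation, temperature, ph and
    exp_ddg; a ``direction`` column (forward/reverse) is optional.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
        source = Path(path_or_text)
        if not source.exists():
            raise FileNotFoundError(source)
        df = pd.read_csv(source, sep=sep, dtype=str, comment="#")
    else:
        df = pd.read_csv(io.StringIO(str(path_or_text)), sep=sep, dtype=str,
                         comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    result = TableReadResult(records=[])
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            spec = MutationSpec.parse(str(row.mutation), str(row.chain_id))
            exp = _opt_float(row.exp_ddg)
            if exp is None:
                raise ValueError("missing experimental ddG")
            result.records.append(
                MutationTableRecord(
                    pdb_id=str(row.pdb_id),
                    chain_id=str(row.chain_id),
                    mutation=spec,
                    temperature=_opt_float(row.temperature),
                    ph=_opt_float(row.ph),
                    exp_ddg=exp,
                    direction=str(getattr(row, "direction", "forward") or "forward"),
                )
            )
        except (ValueError, IndexError) as exc:
            result.rejects.append((row_num, str(exc)))
    return result


def filter_conditions(
    records: Iterable[MutationTableRecord],
    t_range: tuple[float, float] = (24.0, 26.0),
    ph_range: tuple[float, float] = (6.8, 7.2),
) -> list[MutationTableRecord]:
    """Keep records whose temperature and pH are present and inside the
    closed intervals (the near-physiological stratum)."""
    t_lo, t_hi = t_range
    p_lo, p_hi = ph_range
    return [
        r for r in records
        if r.temperature is not None and r.ph is not None
        and t_lo <= r.temperature <= t_hi and p_lo <= r.ph <= p_hi
    ]


def _validated_pair(x, y, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < min_n:
        raise DegenerateInputError(
            f"need two equal-length 1-d vectors of length >= {min_n}"
        )
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise DegenerateInputError("non-finite values in input")
    return xa, ya


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient."""
    xa, ya = _validated_pair(x, y)
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise DegenerateInputError("zero variance input to pearson")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    """Root-mean-squared error with divisor N, in kcal/mol."""
    xa, ya = _validated_pair(x, y, min_n=1)
    return float(np.sqrt(np.mean((xa - ya) ** 2)))


def antisymmetry(fwd: Sequence[float], rev: Sequence[float]) -> float:
    """Pearson correlation between paired forward and reverse predictions.

    Thermodynamics requires rev = -fwd, i.e. a value of -1.
    """
    return pearson(fwd, rev)


def bias(fwd: Sequence[float], rev: Sequence[float]) -> float:
    """Bias score delta = sum_i (fwd_i + rev_i) / (2N), in kcal/mol."""
    fa, ra = _validated_pair(fwd, rev, min_n=1)
    return float(np.sum(fa + ra) / (2 * fa.size))


@dataclass(frozen=True)
class EvaluationSummary:
    n: int
    pcc: float
    rmse: float
    antisymmetry: float | None = None
    bias: float | None = None


def summarize(
    predicted: Sequence[float],
    experimental: Sequence[float],
    fwd: Sequence[float] | None = None,
    rev: Sequence[float] | None = None,
) -> EvaluationSummary:
    """Bundle the standard metrics for one scored subset."""
    pa, ea = _validated_pair(predicted, experimental)
    return EvaluationSummary(
        n=pa.size,
        pcc=pearson(pa, ea),
        rmse=rmse(pa, ea),
        antisymmetry=antisymmetry(fwd, rev) if fwd is not None else None,
        bias=bias(fwd, rev) if fwd is not None else None,
    )


StructureProvider = Callable[[MutationTableRecord], CoarseGrainedStructure]


def parameter_scan(
    records: Sequence[MutationTableRecord],
    structure_provider: StructureProvider,
    potential: ContactPotential,
    rc_grid: Sequence[float] = (7, 8, 9, 10, 11, 12),
    mode_grid: Sequence[int] = (5, 10, 20, 30, 40, 50),
    params: RunConfig | None = None,
    zeros: str | None = None,
) -> pd.DataFrame:
    """Score every (rc, n_modes) grid point on a mutation set.

    Returns one row per grid point with pcc, rmse and pct_predictions (the
    percentage of mutations with a computed, non-defaulted ddG), sorted by
    pcc descending.  Per-record failures are counted, not fatal.
    """
    base = params or RunConfig()
    zeros_policy = zeros or base.zeros
    rows = []
    for rc in rc_grid:
        for n_modes in mode_grid:
            point = base.with_overrides(rc=float(rc), n_modes=int(n_modes))
            predicted, experimental = [], []
            n_computed = n_failed = 0
            for record in records:
                try:
                    structure = structure_provider(record)
                    result = compute_ddg(structure, record.mutation,
                                         potential, point)
                except PspGnmError:
                    n_failed += 1
                    continue
                if result.status == "computed":
                    n_computed += 1
                    predicted.append(result.scaled_ddg)
                    experimental.append(record.exp_ddg)
                elif zeros_policy == "include":
                    predicted.append(0.0)
                    experimental.append(record.exp_ddg)
            total = len(records)
            try:
                pcc_val = pearson(predicted, experimental)
                rmse_val = rmse(predicted, experimental)
            except DegenerateInputError:
                pcc_val = rmse_val = float("nan")
            rows.append({
                "rc": float(rc),
                "n_modes": int(n_modes),
                "pcc": pcc_val,
                "rmse": rmse_val,
                "pct_predictions": 100.0 * n_computed / total if total else 0.0,
                "n_scored": len(predicted),
                "n_failed": n_failed,
            })
    return (
        pd.DataFrame(rows)
        .sort_values("pcc", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
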