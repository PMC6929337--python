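"""Comparison protocol for first-model RMSD tables.

Given per-protein first-model RMSDs before and after re-ranking, this module
counts how many proteins improved / stayed / worsened, computes column means
and the percent improvement of the mean, and renders the comparison as TSV.
A bundled reference table of 43 proteins (columns for three clustering
methods and their re-ranked counterparts) ships with the package for worked
examples; load it with :func:`load_reference_table`.

Two RMSDs are "the same" when they agree within one unit in the last
reported digit (tables report two decimals, so the default tolerance is
0.01 Å, inclusive).  The percent improvement of the mean is computed from
the means rounded at the same display precision, matching how such tables
are conventionally summarised.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "ComparisonRow",
    "ComparisonSummary",
    "read_comparison_table",
    "load_reference_table",
    "compare_models",
    "count_correct_first",
    "render_table",
]

#: numbers in comparison tables are reported at this many decimals
DISPLAY_DECIMALS = 2
#: inclusive equality tolerance: one unit in the last reported digit
DEFAULT_TOLERANCE = 10.0 ** (-DISPLAY_DECIMALS)

_EPS = 1e-9


@dataclass
class ComparisonRow:
    """One protein's first-model RMSDs for one method, before/after re-ranking."""

    protein_id: str
    length: int
    best_rmsd: float
    original_rmsd: float
    reranked_rmsd: float


@dataclass
class ComparisonSummary:
    """Better/same/worse counts and mean RMSDs for one method."""

    method: str
    n_better: int
    n_same: int
    n_worse: int
    avg_original: float
    avg_reranked: float
    pct_improvement: float

    @property
    def n_rows(self) -> int:
        return self.n_better + self.n_same + self.n_worse


def read_comparison_table(path) -> pd.DataFrame:
    """Read a first-model comparison TSV.

    Expected columns: ``pdb``, ``length``, ``best`` plus
    ``<method>_original`` / ``<method>_reranked`` pairs.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"pdb", "length", "best"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    return df


def load_reference_table() -> pd.DataFrame:
    """The bundled 43-protein first-model RMSD table (three methods)."""
    ref = resources.files("decoyrank.data") / "first_model_rmsd.tsv"
    with resources.as_file(ref) as path:
        return read_comparison_table(path)


def rows_for_method(df: pd.DataFrame, method: str) -> list[ComparisonRow]:
    ocol, rcol = f"{method}_original", f"{method}_reranked"
    for col in (ocol, rcol):
        if col not in df.columns:
            raise ConfigurationError(f"table has no column {col!r}")
    return [
        ComparisonRow(
            protein_id=row["pdb"],
            length=int(row["length"]),
            best_rmsd=float(row["best"]),
            original_rmsd=float(row[ocol]),
            reranked_rmsd=float(row[rcol]),
        )
        for _, row in df.iterrows()
    ]


def compare_models(
    rows: Sequence[ComparisonRow],
    method: str = "",
    tolerance: float = DEFAULT_TOLERANCE,
    display_decimals: int = DISPLAY_DECIMALS,
) -> ComparisonSummary:
    """Summarise a first-model comparison.

    better ⇔ reranked < original − tolerance; same ⇔ |Δ| ≤ tolerance;
    worse otherwise (tolerance inclusive, with a small epsilon so that
    two-decimal inputs exactly one tolerance apart count as the same).
    """
    if not rows:
        raise ConfigurationError("compare_models needs at least one row")
    orig = np.array([r.original_rmsd for r in rows])
    rer = np.array([r.reranked_rmsd for r in rows])
    delta = rer - orig
    n_better = int((delta < -(tolerance + _EPS)).sum())
    n_worse = int((delta > tolerance + _EPS).sum())
    n_same = len(rows) - n_better - n_worse
    avg_o, avg_r = float(orig.mean()), float(rer.mean())
    disp_o = round(avg_o, display_decimals)
    disp_r = round(avg_r, display_decimals)
    pct = 100.0 * (disp_o - disp_r) / disp_o
    return ComparisonSummary(
        method=method,
        n_better=n_better,
        n_same=n_same,
        n_worse=n_worse,
        avg_original=avg_o,
        avg_reranked=avg_r,
        pct_improvement=pct,
    )


def count_correct_first(
    candidate_rmsds: Sequence[Sequence[float]],
    predicted_orders: Sequence[Sequence[int]],
) -> int:
    """Count proteins whose predicted first model is the minimum-RMSD candidate."""
    if len(candidate_rmsds) != len(predicted_orders):
        raise ConfigurationError("one predicted order per protein is required")
    correct = 0
    for rmsds, order in zip(candidate_rmsds, predicted_orders):
        if order[0] == int(np.argmin(rmsds)):
            correct += 1
    return correct


def render_table(
    df: pd.DataFrame,
    summaries: Sequence[ComparisonSummary],
    path: Optional[str] = None,
) -> str:
    """Render a comparison table plus an average line and summary block as TSV."""
    lines = ["\t".join(df.columns)]
    numeric = [c for c in df.columns if c not in ("pdb",)]
    for _, row in df.iterrows():
        cells = []
        for c in df.columns:
            v = row[c]
            if c == "pdb":
                cells.append(str(v))
            elif c == "length":
                cells.append(str(int(v)))
            else:
                cells.append(f"{float(v):.{DISPLAY_DECIMALS}f}")
        lines.append("\t".join(cells))
    if len(df):
        avg_cells = ["Average"]
        for c in numeric:
            avg_cells.append(f"{df[c].mean():.{DISPLAY_DECIMALS}f}")
        lines.append("\t".join(avg_cells))
    for s in summaries:
        lines.append(
            f"# {s.method}\tbetter={s.n_better}\tsame={s.n_same}\t"
            f"worse={s.n_worse}\tavg_original={s.avg_original:.2f}\t"
            f"avg_reranked={s.avg_reranked:.2f}\t"
            f"pct_improvement={s.pct_improvement:.2f}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text
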