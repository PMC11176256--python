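"""Box-plot aggregation of per-model ΔΔG predictions.

Structure-based stability predictions (e.g. FoldX BuildModel run on an
ensemble of predicted complexes) yield one ΔΔG (kcal/mol) per variant,
per complex, per structural model.  This module condenses the per-model
values into the box statistics used to display them — median, quartiles
by linear interpolation of order statistics, Tukey whiskers at 1.5·IQR
clamped to the data — and a coarse directional call (negative ΔΔG is
stabilizing).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BoxStats",
    "summarize_ddg",
    "classify_stability",
    "read_ddg_table",
    "read_foldx_dif",
]

#: Directional-call tolerance, kcal/mol.
STABILITY_TOL = 0.5


@dataclass(frozen=True)
class BoxStats:
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    n: int


def _box(values: np.ndarray) -> BoxStats:
    q25, med, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    lo_bound, hi_bound = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = values[(values >= lo_bound) & (values <= hi_bound)]
    return BoxStats(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n=int(values.size),
    )


def summarize_ddg(records: pd.DataFrame) -> pd.DataFrame:
    """Box statistics per (variant, complex) over structural models.

    ``records`` needs columns ``variant, complex, model_index, ddg``;
    duplicate (variant, complex, model_index) triples are an error.
    """
    required = {"variant", "complex", "model_index", "ddg"}
    if not required <= set(records.columns):
        raise ValueError(f"ddg table needs columns {sorted(required)}")
    if not np.all(np.isfinite(records["ddg"].to_numpy(dtype=float))):
        raise ValueError("non-finite ddg value")
    dup = records.duplicated(["variant", "complex", "model_index"])
    if dup.any():
        raise ValueError(
            "duplicate (variant, complex, model_index): "
            f"{records.loc[dup, ['variant', 'complex', 'model_index']].to_dict('records')}"
        )
    rows = []
    for (variant, cplx), grp in records.groupby(["variant", "complex"], sort=False):
        box = _box(grp["ddg"].to_numpy(dtype=float))
        rows.append(
            {
                "variant": variant,
                "complex": cplx,
                "median": box.median,
                "q25": box.q25,
                "q75": box.q75,
                "whisker_low": box.whisker_low,
                "whisker_high": box.whisker_high,
                "n": box.n,
                "call": classify_stability(box),
            }
        )
    return pd.DataFrame(rows)


def classify_stability(stats: BoxStats | float, tol: float = STABILITY_TOL) -> str:
    """Directional call from the median ΔΔG.

    ``stabilizing`` iff median < −tol, ``destabilizing`` iff median > +tol,
    otherwise ``neutral``.  The tolerance (default 0.5 kcal/mol) reflects
    the typical noise floor of empirical force-field predictions.
    """
    median = stats.median if isinstance(stats, BoxStats) else float(stats)
    if median < -tol:
        return "stabilizing"
    if median > tol:
        return "destabilizing"
    return "neutral"


def read_ddg_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy TSV with columns variant, complex, model_index, ddg."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "complex", "model_index", "ddg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ddg table at {path} missing columns {sorted(missing)}")
    return df


def read_foldx_dif(path: str | Path, variant: str, complex_label: str) -> pd.DataFrame:
    """Tolerant reader for FoldX ``Dif_*.fxout``-style tab tables.

    Takes the first tab-separated numeric column after the PDB name on
    each data row (total energy difference), skipping header/banner
    lines, and assigns model indices in file order.
    """
    rows = []
    model = 0
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0].strip().lower().endswith(".pdb"):
            continue
        try:
            ddg = float(parts[1])
        except ValueError:
            continue
        model += 1
        rows.append(
            {"variant": variant, "complex": complex_label, "model_index": model, "ddg": ddg}
        )
    if not rows:
        raise ValueError(f"no FoldX data rows found in {path}")
    return pd.DataFrame(rows)
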