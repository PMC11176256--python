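"""Dual-luciferase reporter normalization chain and comparison statistics.

The normalization chain for an NF-κB reporter experiment:

1. RLU — Firefly luminescence divided by co-transfected Renilla, per
   well; duplicate wells of one condition are averaged at this stage.
2. fold stimulated — mean stimulated RLU over mean unstimulated RLU for
   the same construct within the same experiment.
3. relative fold — fold stimulated divided by the wild-type construct's
   fold stimulated within the same experiment (so WT ≡ 1).

Comparisons across constructs use one-way ANOVA on the per-experiment
relative folds followed by Dunnett's many-to-one test against the
wild-type, with the Dunnett adjustment computed by seeded Monte Carlo of
the max-|t| null over the correlated comparison family.  Šidák
adjustment is provided for independent pairwise families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_rlu",
    "fold_stimulated",
    "normalize_to_wt",
    "summarize_constructs",
    "one_way_anova",
    "dunnett_vs_control",
    "DunnettComparison",
    "sidak_adjust",
]

WELL_COLUMNS = (
    "construct",
    "tlr",
    "stimulus",
    "stimulated",
    "firefly",
    "renilla",
    "experiment",
    "replicate",
)


def compute_rlu(wells: pd.DataFrame) -> pd.DataFrame:
    """Append the relative-luciferase-units column ``rlu = firefly/renilla``."""
    for col in ("firefly", "renilla"):
        if col not in wells.columns:
            raise ValueError(f"well table needs a {col!r} column")
    if (wells["renilla"] <= 0).any():
        raise ValueError("Renilla luminescence must be positive in every well")
    if (wells["firefly"] < 0).any():
        raise ValueError("Firefly luminescence must be non-negative")
    out = wells.copy()
    out["rlu"] = out["firefly"] / out["renilla"]
    return out


def fold_stimulated(wells: pd.DataFrame) -> pd.DataFrame:
    """Fold induction per construct × experiment.

    Duplicate wells are averaged at the RLU stage; the fold is the ratio
    of mean stimulated RLU to mean unstimulated RLU.  Every construct ×
    experiment must have wells in both stimulation states.
    """
    df = wells if "rlu" in wells.columns else compute_rlu(wells)
    grouped = (
        df.groupby(["construct", "experiment", "stimulated"], sort=False)["rlu"]
        .mean()
        .unstack("stimulated")
    )
    for state, name in ((True, "stimulated"), (False, "unstimulated")):
        if state not in grouped.columns or grouped[state].isna().any():
            bad = (
                grouped.index.tolist()
                if state not in grouped.columns
                else grouped.index[grouped[state].isna()].tolist()
            )
            raise ValueError(f"missing {name} wells for construct/experiment {bad}")
    out = grouped.reset_index()
    out["fold_stimulated"] = out[True] / out[False]
    return out[["construct", "experiment", "fold_stimulated"]]


def normalize_to_wt(folds: pd.DataFrame, wt_label: str = "WT") -> pd.DataFrame:
    """Divide each experiment's folds by that experiment's wild-type fold."""
    if "fold_stimulated" not in folds.columns:
        raise ValueError("expected output of fold_stimulated()")
    wt = folds[folds["construct"] == wt_label].set_index("experiment")[
        "fold_stimulated"
    ]
    missing = sorted(set(folds["experiment"]) - set(wt.index))
    if missing:
        raise ValueError(f"wild-type {wt_label!r} missing in experiment(s) {missing}")
    out = folds.copy()
    out["relative_fold"] = out["fold_stimulated"] / out["experiment"].map(wt).to_numpy()
    return out


def summarize_constructs(relative: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM of relative fold per construct across experiments."""
    g = relative.groupby("construct", sort=False)["relative_fold"]
    out = g.agg(mean="mean", sem="sem", n="count").reset_index()
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Between/within sums-of-squares F statistic and its upper-tail p.

    Each group needs at least two observations and there must be at
    least two groups.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least 2 observations")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    if ss_within == 0:
        raise ValueError("zero within-group variance; ANOVA undefined")
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


@dataclass(frozen=True)
class DunnettComparison:
    label: str
    estimate: float  # group mean − control mean
    t: float
    p_unadjusted: float
    p_adjusted: float


def dunnett_vs_control(
    groups: Mapping[str, Sequence[float]],
    control: str,
    n_mc: int = 100_000,
    seed: int = 0,
) -> dict[str, DunnettComparison]:
    """Dunnett many-to-one comparisons by Monte Carlo of the max-|t| null.

    Two-sided t statistics against the shared control use the variance
    pooled over all groups.  The adjusted p-value of comparison i is the
    null probability that the *largest* |t| in the family exceeds |t_i|,
    estimated from ``n_mc`` seeded draws of the joint null (group means
    normal, pooled variance chi-square); this accounts for the
    correlation induced by the common control arm.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} absent")
    if n_mc < 1:
        raise ValueError("n_mc must be positive")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least 2 observations")
    labels = [k for k in arrays if k != control]
    n0 = arrays[control].size
    n_tot = sum(a.size for a in arrays.values())
    df = n_tot - len(arrays)
    s2 = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df
    if s2 == 0:
        raise ValueError("zero pooled variance; t statistics undefined")

    t_obs = {}
    for k in labels:
        a = arrays[k]
        se = np.sqrt(s2 * (1.0 / a.size + 1.0 / n0))
        t_obs[k] = (a.mean() - arrays[control].mean()) / se

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 97]))
    z0 = rng.standard_normal(n_mc) / np.sqrt(n0)
    s_null = np.sqrt(rng.chisquare(df, n_mc) / df)
    max_abs_t = np.zeros(n_mc)
    for k in labels:
        ni = arrays[k].size
        zi = rng.standard_normal(n_mc) / np.sqrt(ni)
        ti = (zi - z0) / (s_null * np.sqrt(1.0 / ni + 1.0 / n0))
        np.maximum(max_abs_t, np.abs(ti), out=max_abs_t)

    out = {}
    for k in labels:
        # add-one estimator keeps the p-value strictly positive
        p_adj = (1 + np.count_nonzero(max_abs_t >= abs(t_obs[k]))) / (n_mc + 1)
        p_un = 2.0 * float(stats.t.sf(abs(t_obs[k]), df))
        out[k] = DunnettComparison(
            label=k,
            estimate=float(arrays[k].mean() - arrays[control].mean()),
            t=float(t_obs[k]),
            p_unadjusted=min(p_un, 1.0),
            p_adjusted=float(min(max(p_adj, p_un), 1.0)),
        )
    return out


def sidak_adjust(p: float, m: int) -> float:
    """Šidák correction 1 − (1 − p)^m for a family of m independent tests."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return float(min(-np.expm1(m * np.log1p(-p)) if p < 1 else 1.0, 1.0))
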