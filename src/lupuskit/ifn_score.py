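"""Interferon-signature (ISG) scores from qPCR and NanoString panels.

Two scores, same skeleton: normalize each sample's ISG measurements to an
internal reference, express each gene as a fold over the median of
healthy controls, and take the median fold across the panel.

qPCR route (6 ISGs): relative expression 2^(-ΔCt) with ΔCt taken against
the mean Ct of two housekeeping genes; positivity is a fixed published
cutoff (score > 2.46, strict).

NanoString route (24 probes): counts are normalized in three steps —
positive-calibrator scaling, negative-calibrator background subtraction
(floored at 1), reference-probe scaling — then scored the same way; the
positivity cutoff is recomputed from the control cohort as
mean + 2·SD (sample SD, n−1) of the control scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "QpcrPanel",
    "NanoStringPanel",
    "IfnScoreResult",
    "qpcr_relative_expression",
    "fold_vs_control_median",
    "ifn_score_qpcr",
    "nanostring_normalize",
    "ifn_score_nanostring",
]


def _load_panels() -> dict:
    text = resources.files("lupuskit.data").joinpath("panels.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class QpcrPanel:
    isgs: tuple[str, ...]
    housekeeping: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        if set(self.isgs) & set(self.housekeeping):
            raise ValueError("ISG and housekeeping panels must be disjoint")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @classmethod
    def default(cls) -> "QpcrPanel":
        cfg = _load_panels()["qpcr"]
        return cls(
            isgs=tuple(cfg["isgs"]),
            housekeeping=tuple(cfg["housekeeping"]),
            threshold=float(cfg["threshold"]),
        )


@dataclass(frozen=True)
class NanoStringPanel:
    probes: tuple[str, ...]
    reference_probes: tuple[str, ...]
    published_threshold: float

    def __post_init__(self) -> None:
        if len(self.probes) != 24:
            raise ValueError("NanoString ISG panel must have 24 probes")
        if len(self.reference_probes) != 3:
            raise ValueError("NanoString panel must have 3 reference probes")

    @classmethod
    def default(cls) -> "NanoStringPanel":
        cfg = _load_panels()["nanostring"]
        return cls(
            probes=tuple(cfg["probes"]),
            reference_probes=tuple(cfg["reference_probes"]),
            published_threshold=float(cfg["published_threshold"]),
        )


@dataclass(frozen=True)
class IfnScoreResult:
    sample: str
    folds: Mapping[str, float]
    score: float
    threshold: float
    positive: bool


def _median(values: np.ndarray) -> float:
    # even-length medians: mean of the two central order statistics
    return float(np.median(values))


def qpcr_relative_expression(
    ct_table: pd.DataFrame, panel: QpcrPanel | None = None
) -> pd.DataFrame:
    """Per-sample, per-gene relative expression 2^(−ΔCt).

    ``ct_table`` is long-format with columns ``sample, gene, ct`` (an
    optional ``replicate`` column is averaged on the Ct scale first).
    ΔCt = Ct_gene − mean(housekeeping Cts); both housekeeping genes must
    be present for every sample.

    Returns a sample × gene DataFrame of relative expression for the
    panel's ISGs.
    """
    panel = panel or QpcrPanel.default()
    required = {"sample", "gene", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    ct = (
        ct_table.groupby(["sample", "gene"], sort=False)["ct"].mean().unstack("gene")
    )
    missing_hk = [g for g in panel.housekeeping if g not in ct.columns]
    if missing_hk:
        raise ValueError(f"housekeeping gene(s) missing from table: {missing_hk}")
    for g in panel.housekeeping:
        bad = ct.index[ct[g].isna()].tolist()
        if bad:
            raise ValueError(f"missing housekeeping Ct for {g} in samples {bad}")
    missing_isg = [g for g in panel.isgs if g not in ct.columns]
    if missing_isg:
        raise ValueError(f"ISG(s) missing from table: {missing_isg}")
    hk_mean = ct[list(panel.housekeeping)].mean(axis=1)
    delta = ct[list(panel.isgs)].sub(hk_mean, axis=0)
    if delta.isna().any().any():
        bad = delta.isna().any(axis=1)
        raise ValueError(f"missing ISG Ct in samples {delta.index[bad].tolist()}")
    return 2.0 ** (-delta)


def fold_vs_control_median(
    rel_expr: pd.DataFrame, control_samples: Iterable[str]
) -> pd.DataFrame:
    """Per-gene fold of each sample over the control-cohort median."""
    controls = [s for s in control_samples if s in rel_expr.index]
    if len(controls) < 2:
        raise ValueError("need at least 2 control samples")
    med = rel_expr.loc[controls].median(axis=0)
    if (med <= 0).any():
        bad = med.index[med <= 0].tolist()
        raise ValueError(f"control median is zero for gene(s) {bad}")
    return rel_expr.div(med, axis=1)


def ifn_score_qpcr(
    folds: Mapping[str, float] | pd.Series,
    panel: QpcrPanel | None = None,
    sample: str = "",
) -> IfnScoreResult:
    """Median fold over the six-ISG panel; positive iff score > threshold."""
    panel = panel or QpcrPanel.default()
    folds = dict(folds) if not isinstance(folds, pd.Series) else folds.to_dict()
    missing = [g for g in panel.isgs if g not in folds or pd.isna(folds[g])]
    if missing:
        raise ValueError(f"fold missing for ISG(s): {missing}")
    vals = np.array([folds[g] for g in panel.isgs], dtype=float)
    if np.any(vals <= 0):
        raise ValueError("fold changes must be positive")
    score = _median(vals)
    return IfnScoreResult(
        sample=sample,
        folds={g: float(folds[g]) for g in panel.isgs},
        score=score,
        threshold=panel.threshold,
        positive=score > panel.threshold,
    )


def _geomean(x: np.ndarray, axis=None) -> np.ndarray:
    return np.exp(np.mean(np.log(x), axis=axis))


def nanostring_normalize(
    counts: pd.DataFrame, panel: NanoStringPanel | None = None
) -> pd.DataFrame:
    """Three-step count normalization of a NanoString-style run.

    ``counts`` is long-format with columns ``sample, probe, role, count``
    where role ∈ {isg, reference, pos_cal, neg_cal}.  In order:

    1. lane scaling — each sample's counts are multiplied by
       (grand geometric mean of positive-calibrator counts) /
       (that sample's positive-calibrator geometric mean);
    2. background — the sample mean of the (scaled) negative calibrators
       is subtracted from ISG and reference counts, floored at 1;
    3. content scaling — counts are multiplied by (grand geometric mean of
       the three reference probes) / (sample reference-probe geometric mean).

    Returns a sample × probe DataFrame of normalized ISG counts.
    """
    panel = panel or NanoStringPanel.default()
    required = {"sample", "probe", "role", "count"}
    if not required <= set(counts.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")

    wide = counts.pivot_table(
        index="sample", columns="probe", values="count", aggfunc="mean", sort=False
    )
    roles = counts.drop_duplicates("probe").set_index("probe")["role"]
    pos = roles.index[roles == "pos_cal"].tolist()
    neg = roles.index[roles == "neg_cal"].tolist()
    if not pos or not neg:
        raise ValueError("positive and negative calibrator probes are required")
    for group, label in ((pos, "positive calibrator"), (list(panel.reference_probes), "reference probe")):
        missing = [p for p in group if p not in wide.columns]
        if missing:
            raise ValueError(f"{label}(s) missing: {missing}")
        block = wide[group]
        if block.isna().any().any() or (block <= 0).any().any():
            raise ValueError(f"{label} counts must be present and positive")

    # 1. positive-calibrator lane scaling
    pos_gm = _geomean(wide[pos].to_numpy(), axis=1)
    scale = _geomean(pos_gm) / pos_gm
    scaled = wide.mul(scale, axis=0)

    # 2. background subtraction, floored at 1
    background = scaled[neg].mean(axis=1)
    content = list(panel.probes) + list(panel.reference_probes)
    missing = [p for p in panel.probes if p not in scaled.columns]
    if missing:
        raise ValueError(f"ISG probe(s) missing: {missing}")
    sub = scaled[content].sub(background, axis=0).clip(lower=1.0)

    # 3. reference-probe content scaling
    ref_gm = _geomean(sub[list(panel.reference_probes)].to_numpy(), axis=1)
    ref_scale = _geomean(ref_gm) / ref_gm
    return sub[list(panel.probes)].mul(ref_scale, axis=0)


def ifn_score_nanostring(
    normalized: pd.DataFrame,
    control_samples: Sequence[str],
    panel: NanoStringPanel | None = None,
) -> tuple[dict[str, IfnScoreResult], float]:
    """Score all samples and derive the control-based positivity threshold.

    Per-probe folds are taken over the control median; each sample's
    score is the median of its 24 per-probe folds.  The threshold is
    mean + 2·SD (n−1 denominator) of the control scores; a sample is
    positive iff its score exceeds the threshold strictly.

    Returns ``(results_by_sample, threshold)``.
    """
    panel = panel or NanoStringPanel.default()
    controls = [s for s in control_samples if s in normalized.index]
    if len(controls) < 2:
        raise ValueError("need at least 2 control samples")
    folds = fold_vs_control_median(normalized[list(panel.probes)], controls)
    scores = folds.median(axis=1)
    ctrl_scores = scores.loc[controls].to_numpy(dtype=float)
    threshold = float(ctrl_scores.mean() + 2.0 * ctrl_scores.std(ddof=1))
    results = {
        str(s): IfnScoreResult(
            sample=str(s),
            folds=folds.loc[s].to_dict(),
            score=float(scores.loc[s]),
            threshold=threshold,
            positive=bool(scores.loc[s] > threshold),
        )
        for s in normalized.index
    }
    return results, threshold
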