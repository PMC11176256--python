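"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of input the pipeline consumes —
cohort variant tables, predictor-score backgrounds, qPCR Ct tables,
NanoString-style count runs, dual-luciferase plates, per-model ΔΔG
tables — and returns the data *together with* the planted truth (carrier
kindreds, injected fold-changes, construct multipliers, per-variant ΔΔG
means), so recovery can be asserted without ever inferring truth from
the data itself.

One global seed drives independent per-generator substreams (a
SeedSequence keyed by generator id), so adding or re-running one
generator never perturbs another's output, and a fixed seed reproduces
every table byte for byte.

Noise models: Gaussian on the Ct scale for qPCR; log-normal for counts
and luminescence (a coefficient of variation on a positive scale);
per-sample log-normal lane distortions and additive backgrounds for
NanoString runs so that the calibrator arithmetic is actually exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ifn_score import NanoStringPanel, QpcrPanel
from .vep_damage import PredictorCatalog

__all__ = [
    "CohortSimSpec",
    "ExpressionSimSpec",
    "PlateSimSpec",
    "CohortSim",
    "ExpressionSim",
    "PlateSim",
    "simulate_cohort",
    "simulate_background_scores",
    "simulate_qpcr",
    "simulate_nanostring",
    "simulate_reporter_plate",
    "simulate_ddg",
]

# Fixed substream ids: one per generator.
_STREAMS = {
    "cohort": 11,
    "background_scores": 12,
    "qpcr": 13,
    "nanostring": 14,
    "reporter": 15,
    "ddg": 16,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _STREAMS[stream]])
    )


def _sigma_from_cv(cv: float) -> float:
    # log-normal sigma giving the requested coefficient of variation
    return float(np.sqrt(np.log1p(cv**2)))


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = _sigma_from_cv(cv)
    # mean-one noise: E[exp(N(-s²/2, s²))] = 1
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


# ---------------------------------------------------------------------------
# cohort variant tables


@dataclass(frozen=True)
class CohortSimSpec:
    """Study conditions for the cohort simulator.

    Defaults mirror the cohort analysed downstream: 63 kindreds with a
    qualifying-carrier probability of 5/63, plus common-missense and
    rare-synonymous noise variants that each fail at least one
    qualifying criterion.
    """

    n_kindreds: int = 63
    carrier_prob: float = 5 / 63
    n_noise_variants: int = 40
    background_af_range: tuple[float, float] = (1e-4, 1e-2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.carrier_prob <= 1:
            raise ValueError("carrier_prob must lie in [0, 1]")
        if self.n_kindreds < 1:
            raise ValueError("n_kindreds must be >= 1")
        lo, hi = self.background_af_range
        if not 0 < lo <= hi < 1:
            raise ValueError("background_af_range must satisfy 0 < lo <= hi < 1")


@dataclass(frozen=True)
class CohortSim:
    variants: pd.DataFrame  # tidy variant table incl. chrom/pos/ref/alt
    genotypes: pd.DataFrame  # kindred × variant_id allele counts (0/1/2)
    truth: dict


_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()
_BASES = "ACGT"

#: Reference allele-number used for simulated gnomAD-style counts.
_SIM_AN = 1_500_000


def simulate_cohort(spec: CohortSimSpec) -> CohortSim:
    """Simulate a kindred cohort with planted qualifying carriers.

    Each kindred independently carries one private qualifying missense
    variant with probability ``carrier_prob`` (absent from the reference,
    i.e. AC 0 over a valid AN; homozygous in ~20% of carriers).  Noise
    variants alternate between common missense (reference AF inside
    ``background_af_range``, failing the MAF criterion) and ultra-rare
    synonymous (failing the consequence criterion); kindreds carry them
    at their Hardy–Weinberg carrier probability.
    """
    rng = _rng(spec.seed, "cohort")
    kindreds = [f"K{i + 1:03d}" for i in range(spec.n_kindreds)]
    carrier_mask = rng.random(spec.n_kindreds) < spec.carrier_prob
    carriers = [k for k, c in zip(kindreds, carrier_mask) if c]

    rows: list[dict] = []
    geno_cols: dict[str, np.ndarray] = {}
    kindred_index = pd.Index(kindreds, name="kindred")
    pos = 67_758_000

    def _aa_change(i: int) -> tuple[str, str]:
        a, b = rng.choice(len(_AA3), 2, replace=False)
        resid = int(rng.integers(30, 590))
        return f"p.({_AA3[a]}{resid}{_AA3[b]})", f"c.{resid * 3}{_BASES[a % 4]}>{_BASES[b % 4]}"

    qualifying_ids = []
    for j, kindred in enumerate(carriers):
        pos += int(rng.integers(3, 300))
        vid = f"q{j + 1:03d}"
        protein, coding = _aa_change(j)
        zygosity = 2 if rng.random() < 0.2 else 1
        rows.append(
            {
                "chrom": "11",
                "pos": pos,
                "variant_id": vid,
                "ref": _BASES[int(rng.integers(4))],
                "alt": _BASES[int(rng.integers(4))],
                "gene": "UNC93B1",
                "coding_change": coding,
                "protein_change": protein,
                "consequence": "missense",
                "allele_count": 0,
                "allele_number": _SIM_AN,
                "homozygote_count": 0,
            }
        )
        col = np.zeros(spec.n_kindreds, dtype=int)
        col[kindreds.index(kindred)] = zygosity
        geno_cols[vid] = col
        qualifying_ids.append(vid)

    lo, hi = spec.background_af_range
    for j in range(spec.n_noise_variants):
        pos += int(rng.integers(3, 300))
        vid = f"n{j + 1:03d}"
        protein, coding = _aa_change(j)
        if j % 2 == 0:  # common missense: fails the MAF criterion
            af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            consequence = "missense"
        else:  # ultra-rare synonymous: fails the consequence criterion
            af = float(rng.integers(1, 10)) / _SIM_AN
            consequence = "synonymous"
        ac = max(int(round(af * _SIM_AN)), 1)
        rows.append(
            {
                "chrom": "11",
                "pos": pos,
                "variant_id": vid,
                "ref": _BASES[int(rng.integers(4))],
                "alt": _BASES[int(rng.integers(4))],
                "gene": "UNC93B1",
                "coding_change": coding,
                "protein_change": protein,
                "consequence": consequence,
                "allele_count": ac,
                "allele_number": _SIM_AN,
                "homozygote_count": 0,
            }
        )
        p = ac / _SIM_AN
        carrier_p = 2 * p * (1 - p) + p**2
        geno_cols[vid] = (rng.random(spec.n_kindreds) < carrier_p).astype(int)

    variants = pd.DataFrame(rows)
    geno = pd.DataFrame(geno_cols, index=kindred_index, dtype=int)
    truth = {
        "carrier_kindreds": carriers,
        "qualifying_variant_ids": qualifying_ids,
        "carrier_prob": float(spec.carrier_prob),
        "seed": int(spec.seed),
    }
    return CohortSim(variants=variants, genotypes=geno, truth=truth)


# ---------------------------------------------------------------------------
# predictor-score backgrounds

# Native-scale sampling parameters per predictor family: bounded scores
# are Beta-distributed, log-likelihood-style scores Gaussian and negative.
_SCORE_SCALES: dict[str, tuple[str, tuple[float, float]]] = {
    "DeepSequence": ("normal", (-5.0, 2.0)),
    "VARITY_R": ("beta", (1.3, 2.5)),
    "VARITY_ER": ("beta", (1.2, 2.2)),
    "ESM-1v": ("normal", (-8.0, 3.0)),
    "MetaRNN": ("beta", (1.1, 2.0)),
    "ClinPred": ("beta", (1.4, 2.8)),
    "REVEL": ("beta", (1.5, 3.0)),
}


def simulate_background_scores(
    n_variants: int,
    catalog: PredictorCatalog | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw predictor scores for a gene's reference missense background.

    One score per predictor per variant, drawn on each predictor's
    native scale with its declared orientation (log-likelihood-style
    predictors produce negative values where lower = more damaging).
    """
    catalog = catalog or PredictorCatalog.default()
    if not catalog.names:
        raise ValueError("predictor catalog is empty")
    if n_variants < 2:
        raise ValueError("need at least 2 background variants")
    rng = _rng(seed, "background_scores")
    data = {}
    for name in catalog.names:
        kind, params = _SCORE_SCALES.get(name, ("beta", (1.0, 1.0)))
        if kind == "beta":
            data[name] = rng.beta(*params, n_variants)
        else:
            data[name] = rng.normal(*params, n_variants)
    idx = pd.Index([f"bg{i + 1:05d}" for i in range(n_variants)], name="variant_id")
    return pd.DataFrame(data, index=idx)


# ---------------------------------------------------------------------------
# expression assays


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Conditions for the expression simulators.

    ``injected_fold`` is the multiplicative ISG induction planted in
    patients (scalar broadcast to all panel genes, or per-gene mapping);
    the default 10 sits mid-range of typical positive interferon scores.
    ``ct_noise_sd`` is Gaussian noise on the Ct scale for qPCR and the
    log-scale count noise SD for NanoString runs.
    """

    n_patients: int = 7
    n_controls: int = 29
    injected_fold: float | Mapping[str, float] = 10.0
    ct_noise_sd: float = 0.2
    hk_ct_mean: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("need at least 2 controls")
        if self.n_patients < 1:
            raise ValueError("need at least 1 patient")
        folds = (
            self.injected_fold.values()
            if isinstance(self.injected_fold, Mapping)
            else [self.injected_fold]
        )
        if any(f <= 0 for f in folds):
            raise ValueError("injected_fold must be positive for every gene")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    def folds_for(self, genes: Sequence[str]) -> dict[str, float]:
        if isinstance(self.injected_fold, Mapping):
            missing = [g for g in genes if g not in self.injected_fold]
            if missing:
                raise ValueError(f"injected_fold missing for gene(s) {missing}")
            return {g: float(self.injected_fold[g]) for g in genes}
        return {g: float(self.injected_fold) for g in genes}


@dataclass(frozen=True)
class ExpressionSim:
    table: pd.DataFrame
    truth: dict


# Baseline ISG Ct offsets above the housekeeping mean (unstimulated blood).
_QPCR_OFFSETS = {
    "IFI27": 5.0,
    "IFI44L": 4.0,
    "IFIT1": 3.0,
    "ISG15": 2.0,
    "RSAD2": 4.5,
    "SIGLEC1": 6.0,
}


def simulate_qpcr(
    spec: ExpressionSimSpec, panel: QpcrPanel | None = None
) -> ExpressionSim:
    """Ct table for the six-ISG qPCR score.

    Controls sit at per-gene baseline Cts; patients' ISG expression is
    multiplied by the injected fold before noise, i.e. their Ct drops by
    log2(fold).  Housekeeping genes are unshifted in everyone.  The two
    housekeeping genes sit at ``hk_ct_mean`` (HPRT1) and 8 cycles below
    (the high-abundance rRNA species).
    """
    panel = panel or QpcrPanel.default()
    rng = _rng(spec.seed, "qpcr")
    folds = spec.folds_for(panel.isgs)
    hk_ct = {panel.housekeeping[0]: spec.hk_ct_mean}
    for extra in panel.housekeeping[1:]:
        hk_ct[extra] = spec.hk_ct_mean - 8.0
    hk_mean = float(np.mean(list(hk_ct.values())))

    samples = [(f"P{i + 1:02d}", "patient") for i in range(spec.n_patients)]
    samples += [(f"C{i + 1:02d}", "control") for i in range(spec.n_controls)]
    rows = []
    for sample, group in samples:
        for gene in panel.isgs:
            baseline = hk_mean + _QPCR_OFFSETS.get(gene, 4.0)
            shift = np.log2(folds[gene]) if group == "patient" else 0.0
            ct = baseline - shift + rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else baseline - shift
            rows.append(
                {"sample": sample, "group": group, "gene": gene, "role": "isg", "ct": ct}
            )
        for gene in panel.housekeeping:
            ct = hk_ct[gene] + (rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0)
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": gene,
                    "role": "housekeeping",
                    "ct": ct,
                }
            )
    truth = {
        "injected_fold": folds,
        "patients": [s for s, g in samples if g == "patient"],
        "controls": [s for s, g in samples if g == "control"],
        "seed": int(spec.seed),
    }
    return ExpressionSim(table=pd.DataFrame(rows), truth=truth)


_POS_CAL_LEVELS = {  # geometric ladder of spiked positive calibrators
    "POS_A": 8192.0,
    "POS_B": 2048.0,
    "POS_C": 512.0,
    "POS_D": 128.0,
    "POS_E": 32.0,
    "POS_F": 8.0,
}
_NEG_CAL = tuple(f"NEG_{c}" for c in "ABCDEFGH")


def simulate_nanostring(
    spec: ExpressionSimSpec,
    panel: NanoStringPanel | None = None,
    lane_cv: float = 0.3,
    background_mean: float = 12.0,
) -> ExpressionSim:
    """Raw NanoString-style count run with calibrators and references.

    Per-sample log-normal lane distortions multiply *every* probe
    including the positive calibrators (so lane scaling is non-trivial),
    and a per-sample additive background contaminates every probe (so
    the negative calibrators carry real information).  Patients' ISG
    probes are multiplied by the injected fold before distortion.
    """
    panel = panel or NanoStringPanel.default()
    rng = _rng(spec.seed, "nanostring")
    folds = spec.folds_for(panel.probes)

    base = {p: float(200.0 * np.exp(rng.normal(0.0, 0.8))) for p in panel.probes}
    ref_base = {p: float(800.0 * np.exp(rng.normal(0.0, 0.3))) for p in panel.reference_probes}

    samples = [(f"P{i + 1:02d}", "patient") for i in range(spec.n_patients)]
    samples += [(f"C{i + 1:02d}", "control") for i in range(spec.n_controls)]
    rows = []
    lane_factors = {}
    for sample, group in samples:
        lane = float(np.exp(rng.normal(0.0, _sigma_from_cv(lane_cv)))) if lane_cv else 1.0
        lane_factors[sample] = lane
        bg = float(background_mean * np.exp(rng.normal(0.0, 0.2))) if background_mean else 0.0

        def emit(probe: str, true_value: float, role: str) -> None:
            noisy = true_value * (
                float(np.exp(rng.normal(0.0, spec.ct_noise_sd))) if spec.ct_noise_sd else 1.0
            )
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "probe": probe,
                    "role": role,
                    "count": lane * (noisy + bg),
                }
            )

        for probe in panel.probes:
            level = base[probe] * (folds[probe] if group == "patient" else 1.0)
            emit(probe, level, "isg")
        for probe in panel.reference_probes:
            emit(probe, ref_base[probe], "reference")
        for probe, level in _POS_CAL_LEVELS.items():
            emit(probe, level, "pos_cal")
        for probe in _NEG_CAL:
            emit(probe, 0.0, "neg_cal")

    truth = {
        "injected_fold": folds,
        "patients": [s for s, g in samples if g == "patient"],
        "controls": [s for s, g in samples if g == "control"],
        "lane_factors": lane_factors,
        "seed": int(spec.seed),
    }
    return ExpressionSim(table=pd.DataFrame(rows), truth=truth)


# ---------------------------------------------------------------------------
# reporter plates


@dataclass(frozen=True)
class PlateSimSpec:
    """Conditions for the dual-luciferase plate simulator.

    ``effect_multiplier`` plants each construct's fold-stimulated
    relative to the wild-type; the wild-type multiplier is 1 by
    definition.  Defaults mimic a four-experiment reporter series with
    duplicate wells and 10% log-normal luminescence noise.
    """

    constructs: tuple[str, ...] = ("EV", "WT", "G325C", "L330R")
    effect_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"EV": 0.05, "WT": 1.0, "G325C": 3.0, "L330R": 1.0}
    )
    replicate_cv: float = 0.1
    n_experiments: int = 4
    n_replicates: int = 2
    wt_label: str = "WT"
    tlr: str = "TLR7"
    stimulus: str = "R848 0.01 ug/ml"
    wt_fold: float = 10.0  # wild-type fold stimulated (baseline induction)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wt_label not in self.constructs:
            raise ValueError(f"wild-type label {self.wt_label!r} not among constructs")
        missing = [c for c in self.constructs if c not in self.effect_multiplier]
        if missing:
            raise ValueError(f"effect_multiplier missing for construct(s) {missing}")
        if abs(self.effect_multiplier[self.wt_label] - 1.0) > 1e-12:
            raise ValueError("wild-type effect multiplier must be 1 by definition")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.n_experiments < 1 or self.n_replicates < 1:
            raise ValueError("n_experiments and n_replicates must be >= 1")


@dataclass(frozen=True)
class PlateSim:
    wells: pd.DataFrame
    truth: dict


def simulate_reporter_plate(spec: PlateSimSpec) -> PlateSim:
    """Well-level Firefly/Renilla table for one reporter series.

    Within each experiment the unstimulated RLU is shared across
    constructs (same transfection baseline, experiment-specific level);
    the planted stimulated RLU of construct c is
    baseline × wt_fold × effect_multiplier[c], so its expected
    fold-stimulated is the wild-type fold times the multiplier and its
    expected WT-relative fold is the multiplier itself.  Firefly values
    carry mean-one log-normal noise with the requested CV.
    """
    rng = _rng(spec.seed, "reporter")
    rows = []
    for e in range(1, spec.n_experiments + 1):
        baseline_rlu = 0.3 * float(np.exp(rng.normal(0.0, 0.3)))
        renilla_level = 1e5 * float(np.exp(rng.normal(0.0, 0.2)))
        for construct in spec.constructs:
            for stimulated in (False, True):
                target = baseline_rlu * (
                    spec.wt_fold * spec.effect_multiplier[construct] if stimulated else 1.0
                )
                noise = _lognoise(rng, spec.replicate_cv, spec.n_replicates)
                for r in range(spec.n_replicates):
                    renilla = renilla_level
                    rows.append(
                        {
                            "construct": construct,
                            "tlr": spec.tlr,
                            "stimulus": spec.stimulus,
                            "stimulated": stimulated,
                            "firefly": target * renilla * noise[r],
                            "renilla": renilla,
                            "experiment": e,
                            "replicate": r + 1,
                        }
                    )
    truth = {
        "effect_multiplier": dict(spec.effect_multiplier),
        "wt_fold": float(spec.wt_fold),
        "seed": int(spec.seed),
    }
    return PlateSim(wells=pd.DataFrame(rows), truth=truth)


# ---------------------------------------------------------------------------
# structural ΔΔG tables


def simulate_ddg(
    effects: Mapping[tuple[str, str], tuple[float, float]],
    n_models: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-model ΔΔG records with planted per-(variant, complex) means.

    ``effects`` maps (variant, complex) to (mean, sd) in kcal/mol; each
    pair yields ``n_models`` Gaussian draws, one per structural model.
    Returns ``(records, truth)``.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = _rng(seed, "ddg")
    rows = []
    for (variant, cplx), (mean, sd) in effects.items():
        if sd < 0:
            raise ValueError("sd must be >= 0")
        draws = mean + (rng.normal(0.0, sd, n_models) if sd else np.zeros(n_models))
        for m in range(n_models):
            rows.append(
                {
                    "variant": variant,
                    "complex": cplx,
                    "model_index": m + 1,
                    "ddg": float(draws[m]),
                }
            )
    truth = {
        "effects": {f"{v}|{c}": [float(m), float(s)] for (v, c), (m, s) in effects.items()},
        "n_models": int(n_models),
        "seed": int(seed),
    }
    return pd.DataFrame(rows), truth
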