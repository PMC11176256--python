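"""Interferon-signature scoring: ΔCt chain, NanoString normalization, thresholds."""

import numpy as np
import pandas as pd
import pytest

from lupuskit.ifn_score import (
    NanoStringPanel,
    QpcrPanel,
    fold_vs_control_median,
    ifn_score_nanostring,
    ifn_score_qpcr,
    nanostring_normalize,
    qpcr_relative_expression,
)
from lupuskit.synthetic_data import ExpressionSimSpec, simulate_nanostring, simulate_qpcr


@pytest.fixture(scope="module")
def qpanel():
    return QpcrPanel.default()


@pytest.fixture(scope="module")
def npanel():
    return NanoStringPanel.default()


def _ct_table(qpanel, sample_cts):
    rows = []
    for sample, (isg_ct, hk_cts) in sample_cts.items():
        for g in qpanel.isgs:
            rows.append({"sample": sample, "gene": g, "ct": isg_ct})
        for g, ct in zip(qpanel.housekeeping, hk_cts):
            rows.append({"sample": sample, "gene": g, "ct": ct})
    return pd.DataFrame(rows)


class TestQpcrRelativeExpression:
    def test_gene_at_housekeeping_mean_is_one(self, qpanel):
        table = _ct_table(qpanel, {"S1": (24.0, (26.0, 22.0))})
        rel = qpcr_relative_expression(table, qpanel)
        assert np.allclose(rel.loc["S1"], 1.0)

    def test_three_cycles_below_is_eightfold(self, qpanel):
        table = _ct_table(qpanel, {"S1": (21.0, (26.0, 22.0))})
        rel = qpcr_relative_expression(table, qpanel)
        assert np.allclose(rel.loc["S1"], 8.0)

    def test_replicates_averaged_on_ct_scale(self, qpanel):
        t1 = _ct_table(qpanel, {"S1": (23.0, (24.0, 24.0))})
        t2 = _ct_table(qpanel, {"S1": (25.0, (24.0, 24.0))})
        rel = qpcr_relative_expression(pd.concat([t1, t2]), qpanel)
        # mean Ct 24 -> ΔCt 0 -> expression 1 (not mean of 2 and 0.5)
        assert np.allclose(rel.loc["S1"], 1.0)

    def test_missing_housekeeping_names_sample(self, qpanel):
        table = _ct_table(qpanel, {"S1": (24.0, (26.0, 22.0))})
        table = table[table["gene"] != qpanel.housekeeping[0]]
        with pytest.raises(ValueError, match="housekeeping"):
            qpcr_relative_expression(table, qpanel)


class TestFoldVsControlMedian:
    def test_sample_at_control_median_is_one(self, qpanel):
        rel = pd.DataFrame(
            {g: [1.0, 2.0, 3.0, 2.0] for g in qpanel.isgs},
            index=["C1", "C2", "C3", "S1"],
        )
        folds = fold_vs_control_median(rel, ["C1", "C2", "C3"])
        assert np.allclose(folds.loc["S1"], 1.0)

    def test_global_rescale_invariance(self, qpanel):
        rel = pd.DataFrame(
            {g: [1.0, 2.0, 3.0, 5.0] for g in qpanel.isgs},
            index=["C1", "C2", "C3", "S1"],
        )
        f1 = fold_vs_control_median(rel, ["C1", "C2", "C3"])
        f2 = fold_vs_control_median(rel * 7.0, ["C1", "C2", "C3"])
        assert np.allclose(f1, f2)

    def test_too_few_controls(self, qpanel):
        rel = pd.DataFrame({g: [1.0] for g in qpanel.isgs}, index=["C1"])
        with pytest.raises(ValueError):
            fold_vs_control_median(rel, ["C1"])


class TestQpcrScore:
    def test_null_sample_negative(self, qpanel):
        res = ifn_score_qpcr({g: 1.0 for g in qpanel.isgs}, qpanel)
        assert res.score == 1.0 and not res.positive

    def test_even_median_of_sorted_folds(self, qpanel):
        folds = dict(zip(qpanel.isgs, [9.63, 10, 12, 15, 20, 21.48]))
        res = ifn_score_qpcr(folds, qpanel)
        assert res.score == pytest.approx(13.5)
        assert res.positive

    def test_boundary_is_strict(self, qpanel):
        res = ifn_score_qpcr({g: 2.46 for g in qpanel.isgs}, qpanel)
        assert res.score == pytest.approx(2.46) and not res.positive

    def test_missing_gene_named(self, qpanel):
        folds = {g: 1.0 for g in qpanel.isgs[:-1]}
        with pytest.raises(ValueError, match=qpanel.isgs[-1]):
            ifn_score_qpcr(folds, qpanel)

    def test_median_robust_to_two_corrupted_genes(self, qpanel):
        folds = {g: 1.0 for g in qpanel.isgs}
        folds[qpanel.isgs[0]] = 500.0
        folds[qpanel.isgs[1]] = 900.0
        assert ifn_score_qpcr(folds, qpanel).score == 1.0

    def test_null_simulation_positive_rate_below_nominal(self, qpanel):
        """At fold 1 and Ct noise <= 0.3, <5% of samples call positive at 2.46."""
        spec = ExpressionSimSpec(
            n_patients=1000, n_controls=29, injected_fold=1.0, ct_noise_sd=0.3, seed=11
        )
        sim = simulate_qpcr(spec, qpanel)
        rel = qpcr_relative_expression(sim.table, qpanel)
        folds = fold_vs_control_median(rel, sim.truth["controls"])
        calls = [
            ifn_score_qpcr(folds.loc[s], qpanel).positive for s in sim.truth["patients"]
        ]
        assert np.mean(calls) < 0.05


def _clean_run(npanel, n_patients=2, n_controls=3, fold=1.0):
    spec = ExpressionSimSpec(
        n_patients=n_patients, n_controls=n_controls, injected_fold=fold,
        ct_noise_sd=0.0, seed=2,
    )
    return simulate_nanostring(spec, npanel, lane_cv=0.0, background_mean=0.0)


class TestNanoStringNormalize:
    def test_clean_run_normalization_is_identity(self, npanel):
        sim = _clean_run(npanel)
        norm = nanostring_normalize(sim.table, npanel)
        raw = sim.table[sim.table.role == "isg"].pivot_table(
            index="sample", columns="probe", values="count", sort=False
        )
        assert np.allclose(norm, raw.loc[norm.index, norm.columns], rtol=1e-12)

    def test_doubled_sample_normalizes_identically_to_its_twin(self, npanel):
        # lane scaling must remove a pure per-sample scale distortion
        sim = _clean_run(npanel)
        twin = sim.table[sim.table["sample"] == "C01"].copy()
        twin["sample"] = "C01x2"
        twin["count"] *= 2.0
        norm = nanostring_normalize(pd.concat([sim.table, twin]), npanel)
        assert np.allclose(norm.loc["C01"], norm.loc["C01x2"], rtol=1e-10)

    def test_nonpositive_calibrator_rejected(self, npanel):
        sim = _clean_run(npanel)
        table = sim.table.copy()
        table.loc[table["probe"] == "POS_A", "count"] = 0.0
        with pytest.raises(ValueError):
            nanostring_normalize(table, npanel)

    def test_null_fold_recovered_as_one(self, npanel):
        sim = _clean_run(npanel, fold=1.0)
        norm = nanostring_normalize(sim.table, npanel)
        res, _ = ifn_score_nanostring(norm, sim.truth["controls"], npanel)
        for s in sim.truth["patients"]:
            assert res[s].score == pytest.approx(1.0, rel=1e-9)


class TestNanoStringScore:
    def test_identical_controls_threshold_equals_score(self, npanel):
        sim = _clean_run(npanel, n_patients=1, n_controls=4)
        norm = nanostring_normalize(sim.table, npanel)
        res, threshold = ifn_score_nanostring(norm, sim.truth["controls"], npanel)
        assert threshold == pytest.approx(1.0)
        patient = res[sim.truth["patients"][0]]
        assert patient.score == pytest.approx(1.0) and not patient.positive

    def test_threshold_is_mean_plus_two_sample_sd(self, npanel, rng):
        spec = ExpressionSimSpec(
            n_patients=1, n_controls=27, injected_fold=4.0, ct_noise_sd=0.2, seed=9
        )
        sim = simulate_nanostring(spec, npanel)
        norm = nanostring_normalize(sim.table, npanel)
        res, threshold = ifn_score_nanostring(norm, sim.truth["controls"], npanel)
        ctrl_scores = np.array([res[s].score for s in sim.truth["controls"]])
        assert threshold == pytest.approx(
            ctrl_scores.mean() + 2 * ctrl_scores.std(ddof=1), rel=1e-12
        )

    def test_distorted_run_recovers_injected_fold(self, npanel):
        spec = ExpressionSimSpec(
            n_patients=20, n_controls=27, injected_fold=5.0, ct_noise_sd=0.15, seed=10
        )
        sim = simulate_nanostring(spec, npanel, lane_cv=0.3, background_mean=12.0)
        norm = nanostring_normalize(sim.table, npanel)
        res, _ = ifn_score_nanostring(norm, sim.truth["controls"], npanel)
        mean_score = np.mean([res[s].score for s in sim.truth["patients"]])
        assert mean_score == pytest.approx(5.0, rel=0.2)

    def test_fewer_than_two_controls_rejected(self, npanel):
        sim = _clean_run(npanel, n_controls=2)
        norm = nanostring_normalize(sim.table, npanel)
        with pytest.raises(ValueError):
            ifn_score_nanostring(norm, ["C01"], npanel)


def test_panels_match_published_layout(qpanel, npanel):
    assert len(qpanel.isgs) == 6 and len(qpanel.housekeeping) == 2
    assert qpanel.threshold == 2.46
    assert len(npanel.probes) == 24 and len(npanel.reference_probes) == 3
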