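"""Metric semantics, undefined-value accounting, and brute-force oracle agreement."""

import math

import numpy as np
import pandas as pd
import pytest

from drpbench import (
    FormatError,
    MetricReport,
    PredictionTable,
    ResponseTable,
    Stratification,
    ValueKind,
    aggregate_over_seeds,
    metric_stratified,
    metric_unstratified,
    read_report,
    summarize_reports,
    write_report,
)

# ---------------------------------------------------------------------------
# brute-force reference implementations (explicit loops, rank counting)
# ---------------------------------------------------------------------------

def brute_mse(y, p):
    return sum((yi - pi) ** 2 for yi, pi in zip(y, p)) / len(y)


def brute_pearson(y, p):
    n = len(y)
    if n < 2:
        return None
    my, mp = sum(y) / n, sum(p) / n
    sy = math.sqrt(sum((v - my) ** 2 for v in y))
    sp = math.sqrt(sum((v - mp) ** 2 for v in p))
    if sy == 0 or sp == 0:
        return None
    cov = sum((a - my) * (b - mp) for a, b in zip(y, p))
    return cov / (sy * sp)


def brute_r2(y, p):
    n = len(y)
    if n < 2:
        return None
    my = sum(y) / n
    ss_tot = sum((v - my) ** 2 for v in y)
    if ss_tot == 0:
        return None
    ss_res = sum((a - b) ** 2 for a, b in zip(y, p))
    return 1 - ss_res / ss_tot


def brute_auc(y, p):
    """Mann-Whitney over all (positive, negative) pairs; ties count 1/2."""
    pos = [s for yi, s in zip(y, p) if yi == 1]
    neg = [s for yi, s in zip(y, p) if yi == 0]
    if not pos or not neg:
        return None
    wins = 0.0
    for sp_ in pos:
        for sn in neg:
            wins += 1.0 if sp_ > sn else (0.5 if sp_ == sn else 0.0)
    return wins / (len(pos) * len(neg))


def brute_aupr(y, p):
    """Step-wise PR integration over unique score thresholds, no interpolation."""
    if sum(y) == 0 or sum(y) == len(y):
        return None
    thresholds = sorted(set(p), reverse=True)
    n_pos = sum(y)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        selected = [yi for yi, pi in zip(y, p) if pi >= t]
        tp = sum(selected)
        precision = tp / len(selected)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_bce(y, p):
    # same clipping convention as the implementation: q in [eps, 1-eps]
    eps = 1e-12
    total = 0.0
    for yi, pi in zip(y, p):
        q = min(max(pi, eps), 1 - eps)
        total += yi * math.log(q) + (1 - yi) * math.log(1 - q)
    return -total / len(y)


BRUTE = {"mse": brute_mse, "pearson": brute_pearson, "r2": brute_r2,
         "auc": brute_auc, "aupr": brute_aupr, "bce": brute_bce}


def tables_from_arrays(cells, drugs, y, p, binary=False):
    kind = ValueKind.binary if binary else ValueKind.continuous_lnIC50
    truth = ResponseTable.from_records(
        [(c, d, float(v)) for c, d, v in zip(cells, drugs, y)], value_kind=kind
    )
    pred = PredictionTable.from_records(
        [(c, d, float(v)) for c, d, v in zip(cells, drugs, p)]
    )
    return pred, truth


def random_instance(rng, binary, max_pairs=60):
    n_cells = int(rng.integers(2, 9))
    n_drugs = int(rng.integers(2, 9))
    keys = [(f"c{i}", f"d{j}") for i in range(n_cells) for j in range(n_drugs)]
    rng.shuffle(keys)
    keys = keys[: int(rng.integers(4, min(max_pairs, len(keys)) + 1))]
    cells = [c for c, _ in keys]
    drugs = [d for _, d in keys]
    if binary:
        y = (rng.random(len(keys)) < 0.4).astype(float)
        # probability-scale scores, rounded to force ties
        p = np.round(rng.random(len(keys)), 1)
    else:
        y = rng.normal(size=len(keys))
        # continuous scores with deliberate ties to exercise tie handling
        p = np.round(rng.normal(size=len(keys)), 1)
    return tables_from_arrays(cells, drugs, y, p, binary=binary)


class TestAgainstBruteForce:
    @pytest.mark.parametrize("metric", ["mse", "pearson", "r2", "auc", "aupr", "bce"])
    def test_all_stratifications_match_naive_loops(self, metric):
        binary = metric in ("auc", "aupr", "bce")
        rng = np.random.default_rng(hash(metric) % 2**31)
        for _ in range(30):
            pred, truth = random_instance(rng, binary)
            df = truth.records.copy()
            pmap = pred.prediction_map()
            df["prediction"] = [pmap[k] for k in truth.keys]
            # unstratified
            expected = BRUTE[metric](df["value"].tolist(), df["prediction"].tolist())
            got = metric_unstratified(pred, truth, metric)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-10)
            # stratified, both ways
            for strat, col in [(Stratification.by_cell_line, "cell_line"),
                               (Stratification.by_drug, "drug")]:
                report = metric_stratified(pred, truth, metric, strat)
                vals = []
                for name, g in df.groupby(col):
                    e = BRUTE[metric](g["value"].tolist(), g["prediction"].tolist())
                    assert report.per_stratum[str(name)] == (
                        pytest.approx(e, abs=1e-10) if e is not None else None
                    )
                    if e is not None:
                        vals.append(e)
                if vals:
                    assert report.aggregate == pytest.approx(np.mean(vals), abs=1e-10)
                else:
                    assert report.aggregate is None


class TestUnstratified:
    def test_perfect_prediction(self):
        pred, truth = tables_from_arrays(["c1", "c2", "c3"], ["d"] * 3,
                                         [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert metric_unstratified(pred, truth, "mse") == 0.0
        assert metric_unstratified(pred, truth, "pearson") == pytest.approx(1.0)
        assert metric_unstratified(pred, truth, "r2") == pytest.approx(1.0)

    def test_constant_prediction_on_binary_truth(self):
        # constant scorer: AUC exactly 1/2 (tie convention), AUPR = prevalence
        pred, truth = tables_from_arrays(
            [f"c{i}" for i in range(10)], ["d"] * 10,
            [1, 1, 1, 0, 0, 0, 0, 0, 0, 0], [0.4] * 10, binary=True,
        )
        assert metric_unstratified(pred, truth, "auc") == 0.5
        assert metric_unstratified(pred, truth, "aupr") == pytest.approx(0.3)

    def test_anticorrelated_hand_computed(self):
        # SS_res = 8, SS_tot = 2: r = -1, R^2 = -3
        pred, truth = tables_from_arrays(["c1", "c2", "c3"], ["d"] * 3,
                                         [1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert metric_unstratified(pred, truth, "pearson") == pytest.approx(-1.0)
        assert metric_unstratified(pred, truth, "r2") == pytest.approx(-3.0)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        y = (rng.random(50) < 0.5).astype(float)
        p = rng.normal(size=50)
        pred1, truth = tables_from_arrays([f"c{i}" for i in range(50)], ["d"] * 50,
                                          y, p, binary=True)
        pred2, _ = tables_from_arrays([f"c{i}" for i in range(50)], ["d"] * 50,
                                      y, np.exp(3 * p), binary=True)
        assert metric_unstratified(pred1, truth, "auc") == pytest.approx(
            metric_unstratified(pred2, truth, "auc"), abs=1e-12
        )

    def test_zero_variance_truth_is_undefined_not_an_exception(self):
        pred, truth = tables_from_arrays(["c1", "c2"], ["d"] * 2, [2.0, 2.0], [1.0, 3.0])
        assert metric_unstratified(pred, truth, "pearson") is None
        assert metric_unstratified(pred, truth, "r2") is None

    def test_single_class_auc_undefined(self):
        pred, truth = tables_from_arrays(["c1", "c2"], ["d"] * 2, [1, 1], [0.2, 0.8],
                                         binary=True)
        assert metric_unstratified(pred, truth, "auc") is None
        assert metric_unstratified(pred, truth, "aupr") is None

    def test_metric_value_kind_compatibility_enforced(self, tiny_table):
        pred = PredictionTable.from_records([(c, d, 0.0) for c, d in tiny_table.keys])
        with pytest.raises(FormatError, match="binary"):
            metric_unstratified(pred, tiny_table, "auc")

    def test_key_mismatch_rejected(self, tiny_table):
        pred = PredictionTable.from_records([("c1", "d1", 0.0)])
        with pytest.raises(FormatError, match="mismatch"):
            metric_unstratified(pred, tiny_table, "mse")


class TestStratified:
    def test_constant_per_drug_pearson_all_undefined(self, tiny_table):
        # the drug-average baseline predicts one value per drug: within every
        # drug stratum the prediction vector is constant, Pearson undefined
        per_drug = {"d1": 1.0, "d2": 2.0}
        pred = PredictionTable.from_records(
            [(c, d, per_drug[d]) for c, d in tiny_table.keys]
        )
        report = metric_stratified(pred, tiny_table, "pearson", "by_drug")
        assert report.n_undefined == report.n_strata == 2
        assert report.aggregate is None

    def test_r2_exactly_zero_when_prediction_is_stratum_mean(self, tiny_table):
        means = tiny_table.records.groupby("drug")["value"].mean()
        pred = PredictionTable.from_records(
            [(c, d, float(means[d])) for c, d in tiny_table.keys]
        )
        report = metric_stratified(pred, tiny_table, "r2", "by_drug")
        assert report.aggregate == pytest.approx(0.0, abs=1e-12)

    def test_unweighted_mean_over_strata(self):
        cells = ["c1", "c2", "c1", "c2", "c3"]
        drugs = ["d1", "d1", "d2", "d2", "d2"]
        y = [0.0, 1.0, 0.0, 1.0, 2.0]
        p = [0.0, 1.0, 1.0, 2.0, 3.0]  # d1: mse 0, d2: mse 1
        pred, truth = tables_from_arrays(cells, drugs, y, p)
        report = metric_stratified(pred, truth, "mse", "by_drug")
        assert report.per_stratum == {"d1": 0.0, "d2": 1.0}
        assert report.aggregate == pytest.approx(0.5)

    def test_single_stratum_equals_unstratified(self, tiny_table):
        pred = PredictionTable.from_records(
            [(c, d, i * 0.5) for i, (c, d) in enumerate(tiny_table.keys)]
        )
        for metric in ("mse", "pearson", "r2"):
            report = metric_stratified(pred, tiny_table, metric, Stratification.none)
            assert report.n_strata == 1
            assert report.aggregate == pytest.approx(
                metric_unstratified(pred, tiny_table, metric)
            )

    def test_mse_decomposition_over_strata(self):
        rng = np.random.default_rng(3)
        n = 40
        cells = [f"c{rng.integers(5)}" for _ in range(n)]
        drugs = [f"d{i}" for i in range(n)]
        y, p = rng.normal(size=n), rng.normal(size=n)
        pred, truth = tables_from_arrays(cells, drugs, y, p)
        report = metric_stratified(pred, truth, "mse", "by_cell_line")
        df = truth.records
        weighted = sum(
            report.per_stratum[c] * len(g) for c, g in df.groupby("cell_line")
        ) / len(df)
        assert metric_unstratified(pred, truth, "mse") == pytest.approx(weighted, abs=1e-12)

    def test_small_strata_undefined_for_correlations_defined_for_mse(self):
        pred, truth = tables_from_arrays(["c1"], ["d1"], [2.0], [1.0])
        assert metric_stratified(pred, truth, "pearson", "by_drug").n_undefined == 1
        rep = metric_stratified(pred, truth, "mse", "by_drug")
        assert rep.per_stratum["d1"] == pytest.approx(1.0)


class TestAggregationAndIO:
    @staticmethod
    def report_with(aggregate, seed, metric="mse", strat=Stratification.by_drug):
        return MetricReport(
            metric=metric, stratification=strat,
            per_stratum={"d1": aggregate}, aggregate=aggregate,
            n_strata=1, n_undefined=0 if aggregate is not None else 1,
            regime="cancer_blind", method="m", split_seed=0, model_seed=seed,
        )

    def test_identical_seeds_zero_std(self):
        out = aggregate_over_seeds([self.report_with(1.0, s) for s in range(3)])
        assert out["mean"] == 1.0 and out["std"] == 0.0

    def test_sample_std_formula(self):
        out = aggregate_over_seeds(
            [self.report_with(v, s) for s, v in enumerate([0.74, 0.75, 0.76])]
        )
        assert out["mean"] == pytest.approx(0.75)
        assert out["std"] == pytest.approx(0.01, abs=1e-12)

    def test_single_report_std_undefined(self):
        assert aggregate_over_seeds([self.report_with(0.5, 0)])["std"] is None

    def test_mixed_stratifications_rejected(self):
        reports = [
            self.report_with(0.5, 0, strat=Stratification.by_drug),
            self.report_with(0.5, 1, strat=Stratification.by_cell_line),
        ]
        with pytest.raises(ValueError):
            aggregate_over_seeds(reports)

    def test_write_read_round_trip_exact(self, tmp_path):
        reports = [self.report_with(v, s) for s, v in enumerate([0.123456789012345, 0.2, 0.3])]
        reports += [
            MetricReport(
                metric="pearson", stratification=Stratification.by_drug,
                per_stratum={"d1": None}, aggregate=None, n_strata=1, n_undefined=1,
                regime="cancer_blind", method="m", split_seed=0, model_seed=s,
            )
            for s in range(2)
        ]
        summary = summarize_reports(reports)
        p = tmp_path / "report.csv"
        write_report(summary, p)
        text = p.read_text()
        assert "N/A" in text  # fully-undefined aggregate is printed N/A, never 0
        back = read_report(p)
        for col in ("mean", "std"):
            for a, b in zip(summary[col], back[col]):
                if a is None or (isinstance(a, float) and math.isnan(a)):
                    assert b is None
                else:
                    assert b == pytest.approx(a, abs=1e-12)

    def test_undefined_count_written(self, tmp_path):
        reports = [
            MetricReport(
                metric="pearson", stratification=Stratification.by_drug,
                per_stratum={f"d{i}": None for i in range(5)}, aggregate=None,
                n_strata=5, n_undefined=5, regime="r", method="m",
                split_seed=0, model_seed=0,
            )
        ]
        summary = summarize_reports(reports)
        p = tmp_path / "r.csv"
        write_report(summary, p)
        assert read_report(p)["n_undefined"].iloc[0] == 5

    def test_fully_undefined_report_cannot_claim_a_value(self):
        with pytest.raises(ValueError):
            MetricReport(
                metric="pearson", stratification=Stratification.by_drug,
                per_stratum={"d1": None}, aggregate=0.0, n_strata=1, n_undefined=1,
            )
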