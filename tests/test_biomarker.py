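import numpy as np
import pandas as pd
import pytest

from viromefmt.biomarker import (fit_rd_model, flag_high_hv, prevalence_table,
                                 roc_auc, score_contigs,
                                 select_discriminant_hvs)
from viromefmt.evaluation import auc_pair_oracle
from viromefmt.io import AbundanceMatrix, StudyDesign


def _simper_frame(rows):
    return pd.DataFrame(rows, columns=["virus_id", "contribution", "fraction",
                                       "cumulative", "p"])


class TestSelect:
    def test_all_insignificant_empty(self):
        records = _simper_frame([("h1", .5, .5, .5, 1.0), ("h2", .5, .5, 1.0, 1.0)])
        assert select_discriminant_hvs(records) == []

    def test_first_hv_selected(self):
        records = _simper_frame([("h1", .4, .4, .4, .01), ("h2", .3, .3, .7, .01)])
        assert select_discriminant_hvs(records) == ["h1"]  # h2 at cum = 0.7 excluded

    def test_both_thresholds_strict(self):
        records = _simper_frame([("h1", .2, .2, .2, .05)])
        assert select_discriminant_hvs(records) == []     # p = 0.05 excluded
        records = _simper_frame([("h1", .2, .2, .2, .049)])
        assert select_discriminant_hvs(records) == ["h1"]


def _scoring_setup(contig_values, presence_threshold=0.5):
    """Two responders, one donor, one non-responder, one sample each."""
    rows = [("R1_W0", "R1", "responder", "D1", 0),
            ("R2_W0", "R2", "responder", "D1", 0),
            ("D1_W0", "D1", "donor", None, 0),
            ("N1_W0", "N1", "non_responder", "D1", 0)]
    design = StudyDesign(pd.DataFrame(rows, columns=[
        "sample_id", "subject_id", "role", "paired_donor_id", "week"]))
    samples = ["R1_W0", "R2_W0", "D1_W0", "N1_W0"]
    values = pd.DataFrame(contig_values, columns=samples,
                          index=[f"c{i}" for i in range(len(contig_values))])
    rpkm = AbundanceMatrix(values, "rpkm")
    presence = values > presence_threshold
    return rpkm, presence, design


class TestScoreContigs:
    def test_worked_example(self):
        # r_total 10, present in 2 responder/donor subjects, absent from all
        # non-responders, median of present abundances 4 -> 10*2/(0+1)*4 = 80
        rpkm, presence, design = _scoring_setup([[4.0, 6.0, 0.0, 0.0]])
        out = score_contigs(rpkm, presence, design, {"hv1": frozenset({"c0"})})
        row = out.iloc[0]
        assert row.r_score == pytest.approx(20.0)
        assert row.n_score == 0.0
        assert row.median_r == pytest.approx(5.0)
        assert row.score == pytest.approx(100.0)

    def test_worked_example_multiweek(self):
        # total RPKM 10 over present responder samples (4, 2, 4), present in
        # 2 responder/donor subjects, absent from non-responders:
        # score = 10 * 2 / (0 + 1) * median(4, 2, 4) = 80
        rows = [("R1_W0", "R1", "responder", "D1", 0),
                ("R2_W0", "R2", "responder", "D1", 0),
                ("R2_W6", "R2", "responder", "D1", 6),
                ("D1_W0", "D1", "donor", None, 0),
                ("N1_W0", "N1", "non_responder", "D1", 0)]
        design = StudyDesign(pd.DataFrame(rows, columns=[
            "sample_id", "subject_id", "role", "paired_donor_id", "week"]))
        samples = [r[0] for r in rows]
        values = pd.DataFrame([[4.0, 2.0, 4.0, 0.0, 0.0]], index=["c0"],
                              columns=samples)
        rpkm = AbundanceMatrix(values, "rpkm")
        out = score_contigs(rpkm, values > 0.5, design, {"hv1": frozenset({"c0"})})
        assert out.iloc[0].score == pytest.approx(80.0)

    def test_absent_everywhere_scores_zero(self):
        rpkm, presence, design = _scoring_setup([[0.0, 0.0, 0.0, 0.0]])
        out = score_contigs(rpkm, presence, design, {"hv1": frozenset({"c0"})})
        assert out.iloc[0].score == 0.0

    def test_non_responder_presence_penalizes(self):
        rpkm, presence, design = _scoring_setup([
            [4.0, 6.0, 0.0, 0.0],
            [4.0, 6.0, 0.0, 3.0],
        ])
        out = score_contigs(rpkm, presence, design,
                            {"hv1": frozenset({"c0", "c1"})}).set_index("contig_id")
        assert out.loc["c1", "score"] < out.loc["c0", "score"]
        assert out.loc["c0", "rank_in_hv"] == 1

    def test_monotone_in_responder_abundance(self):
        rpkm, presence, design = _scoring_setup([[4.0, 6.0, 0.0, 0.0],
                                                 [4.0, 9.0, 0.0, 0.0]])
        out = score_contigs(rpkm, presence, design,
                            {"hv1": frozenset({"c0", "c1"})}).set_index("contig_id")
        assert out.loc["c1", "score"] >= out.loc["c0", "score"]


class TestRdModel:
    def test_perfect_linear_relation(self):
        x = pd.Series({f"s{i}": float(i) for i in range(6)})
        model = fit_rd_model(x, 3.0 * x + 2.0)
        assert model.adjusted_r2 == pytest.approx(1.0)
        assert model.p < 1e-6
        assert model.slope == pytest.approx(3.0)

    def test_exclusions_applied(self):
        x = pd.Series({f"s{i}": float(i) for i in range(6)})
        y = 2.0 * x
        y["s5"] = 100.0  # outlier
        full = fit_rd_model(x, y)
        trimmed = fit_rd_model(x, y, exclusions=("s5",))
        assert trimmed.adjusted_r2 > full.adjusted_r2
        assert trimmed.adjusted_r2 == pytest.approx(1.0)

    def test_too_few_subjects(self):
        x = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError):
            fit_rd_model(x, x)

    def test_zero_variance_predictor(self):
        x = pd.Series({f"s{i}": 1.0 for i in range(5)})
        with pytest.raises(ValueError):
            fit_rd_model(x, x + 1)

    def test_null_calibration_small(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(8)]
        rejections = sum(
            fit_rd_model(pd.Series(rng.normal(size=8), index=idx),
                         pd.Series(rng.normal(size=8), index=idx)).p <= 0.05
            for _ in range(200))
        assert 2 <= rejections <= 22  # 99% binomial band around 10/200


class TestRoc:
    def test_perfect_separation(self):
        abund = pd.Series({"a": 10.0, "b": 9.0, "c": 1.0, "d": 0.5})
        flags = pd.Series({"a": True, "b": True, "c": False, "d": False})
        auc, p = roc_auc(abund, flags)
        assert auc == 1.0

    def test_all_tied_gives_half(self):
        abund = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        flags = pd.Series({"a": True, "b": True, "c": False, "d": False})
        auc, _ = roc_auc(abund, flags)
        assert auc == 0.5

    def test_single_class_rejected(self):
        abund = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            roc_auc(abund, pd.Series({"a": True, "b": True}))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        values = np.round(rng.normal(size=n), 1)
        flags = np.zeros(n, bool)
        flags[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
        abund = pd.Series(values, index=[f"s{i}" for i in range(n)])
        auc, _ = roc_auc(abund, pd.Series(flags, index=abund.index))
        assert auc == pytest.approx(auc_pair_oracle(values[flags], values[~flags]))


class TestPrevalence:
    def test_flag_high_rules(self):
        abund = pd.DataFrame({"m1": [5.0, 5.0, 0.0], "m2": [5.0, 0.0, 0.0],
                              "m3": [0.0, 0.0, 0.0]}, index=["a", "b", "c"])
        flags = flag_high_hv(abund, threshold=1.0, min_markers=2)
        assert list(flags) == [True, False, False]
        assert flag_high_hv(abund, threshold=1.0, min_markers=0).all()

    def test_marginals_match_totals(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(30)]
        high = pd.Series(rng.random(30) > 0.5, index=idx)
        resp = pd.Series(rng.random(30) > 0.4, index=idx)
        table = prevalence_table(high, resp)
        assert table["n_high"] + table["n_low"] == table["n_total"] == 30
        assert (table["responders_high"] + table["responders_low"]
                == table["responders_total"] == int(resp.sum()))
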