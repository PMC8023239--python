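import numpy as np
import pandas as pd
import pytest

from viromefmt.io import AbundanceMatrix, StudyDesign
from viromefmt.transfer import (category_trajectories, classify_categories,
                                donor_recipient_abundance_fit,
                                invading_dynamics)


def _design(weeks=(0, 6), with_control=True):
    rows = [("D1_W0", "D1", "donor", None, 0)]
    for w in weeks:
        rows.append((f"R1_W{w}", "R1", "responder", "D1", w))
    if with_control:
        for w in weeks:
            rows.append((f"C1_W{w}", "C1", "control", None, w))
    return StudyDesign(pd.DataFrame(rows, columns=[
        "sample_id", "subject_id", "role", "paired_donor_id", "week"]))


def _presence(sets, samples, viruses):
    frame = pd.DataFrame(False, index=viruses, columns=samples)
    for sample, present in sets.items():
        frame.loc[sorted(present), sample] = True
    return frame


VIRUSES = list("ABCDE")


class TestClassify:
    def test_set_definitions(self):
        design = _design(with_control=False)
        presence = _presence({
            "R1_W0": {"A", "B"}, "D1_W0": {"B", "C"}, "R1_W6": {"B", "C", "D"},
        }, ["D1_W0", "R1_W0", "R1_W6"], VIRUSES)
        got = classify_categories(presence, design)
        expect = {("R1", "A"): "unique_preFMT", ("R1", "B"): "shared_preFMT",
                  ("R1", "C"): "invading", ("R1", "D"): "new"}
        assert {(r, v): c for r, v, c in got.itertuples(index=False)} == expect

    def test_control_has_no_donor_baseline(self):
        design = _design()
        presence = _presence({
            "C1_W0": {"A"}, "C1_W6": {"A", "E"},
            "R1_W0": set(), "R1_W6": set(), "D1_W0": {"A", "E"},
        }, ["D1_W0", "R1_W0", "R1_W6", "C1_W0", "C1_W6"], VIRUSES)
        got = classify_categories(presence, design)
        ctrl = {(v, c) for r, v, c in got.itertuples(index=False) if r == "C1"}
        # donor presence is irrelevant to controls: A unique, E new
        assert ctrl == {("A", "unique_preFMT"), ("E", "new")}

    def test_donor_virus_never_in_recipient_gets_no_label(self):
        design = _design(with_control=False)
        presence = _presence({
            "R1_W0": {"A"}, "D1_W0": {"A", "C"}, "R1_W6": {"A"},
        }, ["D1_W0", "R1_W0", "R1_W6"], VIRUSES)
        got = classify_categories(presence, design)
        assert "C" not in set(got["virus"])

    def test_missing_week0_raises(self):
        rows = [("D1_W0", "D1", "donor", None, 0),
                ("R1_W6", "R1", "responder", "D1", 6)]
        design = StudyDesign(pd.DataFrame(rows, columns=[
            "sample_id", "subject_id", "role", "paired_donor_id", "week"]))
        presence = _presence({}, ["D1_W0", "R1_W6"], VIRUSES)
        with pytest.raises(ValueError, match="R1"):
            classify_categories(presence, design)

    def test_category_fixed_at_baseline(self, default_study):
        # every ever-present virus of each recipient receives exactly one label
        from viromefmt import evaluation as ev
        _, rpkm_hv, presence_hv = ev._analyze(default_study)
        got = classify_categories(presence_hv, default_study.design)
        assert not got.duplicated(["recipient", "virus"]).any()
        ctrl_rows = got[got["recipient"].str.startswith("C")]
        assert set(ctrl_rows["category"]) <= {"unique_preFMT", "new"}


class TestTrajectories:
    def _setup(self):
        design = _design(with_control=False)
        samples = ["D1_W0", "R1_W0", "R1_W6"]
        presence = _presence({
            "R1_W0": {"A", "B"}, "D1_W0": {"B", "C"}, "R1_W6": {"B", "C", "D"},
        }, samples, VIRUSES)
        values = pd.DataFrame(10.0, index=VIRUSES, columns=samples)
        values.loc["C", "R1_W6"] = 30.0
        rpkm = AbundanceMatrix(values.where(presence, 0.0), "rpkm")
        return design, presence, rpkm

    def test_fractions_partition_each_week(self):
        design, presence, rpkm = self._setup()
        assignment = classify_categories(presence, design)
        traj = category_trajectories(rpkm, presence, assignment, design)
        sums = traj.groupby(["recipient", "week"])["fraction"].sum()
        assert np.allclose(sums, 1.0)
        w6 = traj[(traj.week == 6) & (traj.category == "invading")]["fraction"]
        assert w6.iloc[0] == pytest.approx(30.0 / 50.0)

    def test_only_unique_present_gives_fraction_one(self):
        design = _design(with_control=False)
        samples = ["D1_W0", "R1_W0", "R1_W6"]
        presence = _presence({"R1_W0": {"A"}, "R1_W6": {"A"}}, samples, VIRUSES)
        rpkm = AbundanceMatrix(
            pd.DataFrame(5.0, index=VIRUSES, columns=samples).where(presence, 0.0),
            "rpkm")
        assignment = classify_categories(presence, design)
        traj = category_trajectories(rpkm, presence, assignment, design)
        unique = traj[traj.category == "unique_preFMT"]["fraction"]
        assert (unique == 1.0).all()

    def test_empty_week_emitted_as_missing(self):
        design, presence, rpkm = self._setup()
        presence["R1_W6"] = False
        assignment = classify_categories(presence, design)
        traj = category_trajectories(rpkm, presence, assignment, design)
        assert traj[traj.week == 6]["fraction"].isna().all()


class TestInvading:
    def test_counts_and_distinct_totals(self):
        design = _design(weeks=(0, 6, 12), with_control=False)
        samples = ["D1_W0", "R1_W0", "R1_W6", "R1_W12"]
        presence = _presence({
            "D1_W0": {"C"}, "R1_W0": {"A"}, "R1_W6": {"A"}, "R1_W12": {"A", "C"},
        }, samples, VIRUSES)
        rpkm = AbundanceMatrix(
            pd.DataFrame(8.0, index=VIRUSES, columns=samples).where(presence, 0.0),
            "rpkm")
        assignment = classify_categories(presence, design)
        per_week, totals = invading_dynamics(rpkm, presence, assignment, design)
        by_week = per_week.set_index("week")["n_invading"]
        assert by_week[6] == 0 and by_week[12] == 1
        assert totals["R1"] == 1

    def test_no_invaders_all_zero(self):
        design = _design(with_control=False)
        samples = ["D1_W0", "R1_W0", "R1_W6"]
        presence = _presence({"R1_W0": {"A"}, "R1_W6": {"A"}}, samples, VIRUSES)
        rpkm = AbundanceMatrix(
            pd.DataFrame(1.0, index=VIRUSES, columns=samples).where(presence, 0.0),
            "rpkm")
        assignment = classify_categories(presence, design)
        per_week, totals = invading_dynamics(rpkm, presence, assignment, design)
        assert (per_week["n_invading"] == 0).all()
        assert totals["R1"] == 0


class TestDonorRecipientFit:
    def _study(self, recipient_values):
        design = _design(with_control=False)
        samples = ["D1_W0", "R1_W0", "R1_W6"]
        viruses = [f"v{i}" for i in range(len(recipient_values))] + ["base"]
        presence = _presence({
            "D1_W0": set(viruses[:-1]), "R1_W0": {"base"},
            "R1_W6": set(viruses),
        }, samples, viruses)
        values = pd.DataFrame(0.0, index=viruses, columns=samples)
        values.loc[viruses[:-1], "D1_W0"] = np.arange(1.0, len(viruses))
        values.loc[viruses[:-1], "R1_W6"] = recipient_values
        values.loc["base", ["R1_W0", "R1_W6"]] = 5.0
        rpkm = AbundanceMatrix(values, "rpkm")
        assignment = classify_categories(presence, design)
        return rpkm, assignment, design

    def test_proportional_gives_r2_one(self):
        donor = np.arange(1.0, 6.0)
        rpkm, assignment, design = self._study(3.0 * donor)
        fits = donor_recipient_abundance_fit(rpkm, assignment, design)
        assert fits["R1"] == pytest.approx(1.0)

    def test_too_few_invaders_skipped(self):
        rpkm, assignment, design = self._study(np.array([1.0, 2.0]))
        fits = donor_recipient_abundance_fit(rpkm, assignment, design)
        assert np.isnan(fits["R1"])

    def test_null_mean_near_zero(self):
        # adjusted R^2 is centered at 0 when recipient abundances are
        # independent of donor abundances (20 invading viruses per replicate)
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(100):
            rpkm, assignment, design = self._study(rng.lognormal(0, 1, 20))
            vals.append(donor_recipient_abundance_fit(rpkm, assignment, design)["R1"])
        assert abs(np.mean(vals)) < 0.05
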