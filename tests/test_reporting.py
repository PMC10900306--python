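import json

import numpy as np
import pandas as pd
import pytest

from resptraj import (
    RunConfig,
    baseline_table,
    charlson_index,
    count_trajectories,
    first_line_distribution,
    render_sunburst,
    to_sunburst,
)
from tests._oracles import prefix_counts


class TestRetentionThreshold:
    def _frame(self, traj_frame, n_with, n_without, n_untreated):
        return traj_frame(
            [("SABA",)] * n_with + [("ICS", "LTRA")] * n_without + [()] * n_untreated
        )

    def test_half_percent_retained_and_below_pooled(self, config, traj_frame):
        # population 1000: a 5-patient trajectory (exactly 0.5%) is retained,
        # a 4-patient one is pooled
        df = self._frame(traj_frame, 5, 4, 991)
        retained, other, untreated = count_trajectories(df, config)
        assert retained == {("SABA",): 5}
        assert other == 4 and untreated == 991

    def test_single_shared_trajectory(self, config, traj_frame):
        df = traj_frame([("SABA", "ICS")] * 20)
        retained, other, untreated = count_trajectories(df, config)
        assert retained == {("SABA", "ICS"): 20} and other == 0 and untreated == 0

    def test_conservation(self, config, traj_frame):
        rng = np.random.default_rng(5)
        pool = [("SABA",), ("ICS",), ("SABA", "ICS"), ("LTRA", "SABA", "ICS"), ()]
        df = traj_frame([pool[i] for i in rng.integers(0, len(pool), 400)])
        retained, other, untreated = count_trajectories(df, config)
        assert sum(retained.values()) + other + untreated == len(df)

    def test_treated_only_population_switch(self, traj_frame):
        cfg = RunConfig(population_includes_untreated=False)
        df = self._frame(traj_frame, 5, 4, 991)
        retained, other, _ = count_trajectories(df, cfg)
        # population is now 9 -> threshold 0.045 patients -> both retained
        assert set(retained) == {("SABA",), ("ICS", "LTRA")}


class TestSunburstTree:
    def test_prefix_sums(self):
        tree = to_sunburst({("SABA",): 10, ("SABA", "ICS"): 5})
        assert len(tree) == 1
        root = tree[0]
        assert (root.label, root.depth, root.patient_count) == ("SABA", 1, 15)
        assert [(c.label, c.depth, c.patient_count) for c in root.children] == [("ICS", 2, 5)]

    def test_empty(self):
        assert to_sunburst({}) == []

    def test_other_wedge(self, config):
        tree = to_sunburst({("SABA",): 10}, other_count=3, config=config)
        assert [(n.label, n.patient_count) for n in tree] == [("SABA", 10), ("other", 3)]
        cfg = RunConfig(other_wedge=False)
        assert [n.label for n in to_sunburst({("SABA",): 10}, other_count=3, config=cfg)] == ["SABA"]

    def test_random_multiset_matches_prefix_oracle(self):
        rng = np.random.default_rng(11)
        labels = ["SABA", "ICS", "LTRA", "LABA-ICS"]
        trajectories = [
            tuple(rng.choice(labels, size=rng.integers(1, 6), replace=True))
            for _ in range(200)
        ]
        counts: dict[tuple[str, ...], int] = {}
        for t in trajectories:
            counts[t] = counts.get(t, 0) + 1
        tree = to_sunburst(counts)
        want = prefix_counts(trajectories)

        def walk(nodes, prefix):
            for nd in nodes:
                p = prefix + (nd.label,)
                assert nd.patient_count == want[p]
                assert all(c.depth == nd.depth + 1 for c in nd.children)
                assert sum(c.patient_count for c in nd.children) <= nd.patient_count
                walk(nd.children, p)

        walk(tree, ())
        assert sum(nd.patient_count for nd in tree) == 200


class TestRenderSunburst:
    def test_html_contains_labels_and_payload_depth(self, tmp_path):
        tree = to_sunburst({("SABA", "ICS", "LTRA", "LABA", "LAMA"): 10, ("SABA",): 5})
        path = render_sunburst(tree, tmp_path / "s.html", n=15, pct_treated=80.0)
        text = path.read_text()
        assert "SABA" in text and "LTRA" in text and "N=15" in text

        payload = text.split('id="sunburst-data">')[1].split("</script>")[0]
        nodes = json.loads(payload)

        def max_depth(ns):
            return max((max(nd["depth"], max_depth(nd["children"])) for nd in ns), default=0)

        assert max_depth(nodes) == 5

    def test_rerender_is_byte_identical(self, tmp_path):
        tree = to_sunburst({("SABA", "ICS"): 3, ("LTRA",): 2})
        p1 = render_sunburst(tree, tmp_path / "a.html")
        p2 = render_sunburst(tree, tmp_path / "b.html")
        assert p1.read_bytes() == p2.read_bytes()


class TestBaseline:
    def _cohort(self, ids, index_day=500):
        return pd.DataFrame(
            [(pid, "asthma", index_day, 2000, 30) for pid in ids],
            columns=["person_id", "disease", "index_day", "followup_end_day", "age_at_index"],
        )

    def _person(self, ids, sex="female"):
        return pd.DataFrame([(pid, 1980, sex) for pid in ids], columns=["person_id", "birth_year", "sex"])

    def test_comorbidity_percentages(self):
        cond = pd.DataFrame(
            [("P1", "anxiety", 100), ("P1", "asthma", 500), ("P2", "asthma", 500)],
            columns=["person_id", "concept", "day"],
        )
        table = baseline_table(self._cohort(["P1", "P2"]), self._person(["P1", "P2"]), cond, {})
        got = dict(zip(table["characteristic"], table["value"]))
        assert got["pct_anxiety"] == 50.0

    def test_no_comorbidities_all_zero(self):
        cond = pd.DataFrame([("P1", "asthma", 500)], columns=["person_id", "concept", "day"])
        table = baseline_table(self._cohort(["P1"]), self._person(["P1"]), cond, {}, comorbidities=["anxiety"])
        got = dict(zip(table["characteristic"], table["value"]))
        assert got["pct_anxiety"] == 0.0 and got["mean_charlson"] == 0.0

    def test_charlson_sums_configured_weights(self):
        weights = {"diabetes_mellitus": 1, "heart_failure": 1}
        assert charlson_index({"diabetes_mellitus", "heart_failure"}, weights) == 2
        with pytest.raises(KeyError):
            charlson_index({"renal_disease"}, weights)
        cond = pd.DataFrame(
            [("P1", "diabetes_mellitus", 100), ("P1", "heart_failure", 200)],
            columns=["person_id", "concept", "day"],
        )
        table = baseline_table(self._cohort(["P1"]), self._person(["P1"]), cond, weights)
        got = dict(zip(table["characteristic"], table["value"]))
        assert got["mean_charlson"] == 2.0

    def test_lrti_lookback_restricted_to_previous_year(self):
        cond = pd.DataFrame(
            [("P1", "lower_respiratory_tract_infection", 50),
             ("P2", "lower_respiratory_tract_infection", 400)],
            columns=["person_id", "concept", "day"],
        )
        table = baseline_table(self._cohort(["P1", "P2"], index_day=500), self._person(["P1", "P2"]), cond, {})
        got = dict(zip(table["characteristic"], table["value"]))
        # day 50 is 450 days before index -> outside the 365-day window
        assert got["pct_lower_respiratory_tract_infection"] == 50.0


class TestFirstLine:
    def test_percentages(self, traj_frame):
        df = traj_frame([("SABA",), ("SABA", "ICS"), ("ICS",), ("LTRA", "SABA")])
        table = first_line_distribution(df)
        got = dict(zip(table["label"], table["percent"]))
        assert got == {"SABA": 50.0, "ICS": 25.0, "LTRA": 25.0}
        assert abs(table["percent"].sum() - 100.0) <= 0.2

    def test_single_patient(self, traj_frame):
        table = first_line_distribution(traj_frame([("LABA-ICS", "SABA")]))
        assert list(table["percent"]) == [100.0]
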