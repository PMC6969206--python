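import numpy as np
import pandas as pd
import pytest

import oracles
from achconnect import (
    ACHVerdict,
    CoverRecord,
    compare_clusterings,
    default_scenario,
    evaluate_ach,
    overall_verdict,
    partition_cover_by_lineage,
    quadrats_with_mean,
    round_down,
    summarize_cover,
)
from achconnect.connectivity import ClusterPartition
from achconnect.popgen import DiffMatrix, DiversityEstimate


def records_from_site_means(entries):
    return [
        CoverRecord(
            site=code,
            values=quadrats_with_mean(mean, n=20),
            category=cat,
            lineage=lin,
        )
        for code, lin, cat, mean in entries
    ]


WEST_TABLE = [
    ("P1", "west", "edge", 0.14),
    ("P2", "west", "edge", 0.12),
    ("P3", "west", "centre", 57.49),
    ("P4", "west", "centre", 59.46),
]
EAST_TABLE = [
    ("P7", "east", "centre", 71.65),
    ("P8", "east", "centre", 73.53),
]


class TestCover:
    def test_western_edge_mean(self):
        out = summarize_cover(records_from_site_means(WEST_TABLE))
        assert out.loc[("west", "edge"), "mean_2dp"] == 0.13

    def test_western_centre_mean(self):
        out = summarize_cover(records_from_site_means(WEST_TABLE))
        assert out.loc[("west", "centre"), "mean_2dp"] == 58.47

    def test_eastern_centre_mean(self):
        out = summarize_cover(records_from_site_means(EAST_TABLE))
        assert out.loc[("east", "centre"), "mean_2dp"] == 72.59

    def test_single_site_group_is_site_mean(self):
        recs = records_from_site_means([("P7", "east", "centre", 71.65)])
        out = summarize_cover(recs)
        assert out.loc[("east", "centre"), "mean"] == pytest.approx(71.65)

    def test_invariant_to_quadrat_order(self):
        rng = np.random.default_rng(0)
        vals = quadrats_with_mean(40.0, 20)
        a = CoverRecord("s", vals, "centre", "west")
        b = CoverRecord("s", rng.permutation(vals), "centre", "west")
        assert a.site_mean == pytest.approx(b.site_mean)

    def test_quadrat_values_validated(self):
        with pytest.raises(ValueError, match="0, 100"):
            CoverRecord("s", [-1.0, 5.0], "edge")


class TestLineagePartition:
    def test_even_split(self):
        w, e = partition_cover_by_lineage(66.2, 0.50)
        assert round_down(w, 1) == 33.1 and round_down(e, 1) == 33.1

    def test_thirty_seventy_split_truncates_like_printed_tables(self):
        w, e = partition_cover_by_lineage(52.1, 0.30)
        assert w == pytest.approx(15.63)
        assert round_down(w, 1) == 15.6
        assert round_down(e, 1) == 36.4

    def test_zero_fraction(self):
        assert partition_cover_by_lineage(40.0, 0.0) == (0.0, 40.0)

    def test_partition_conserves_total(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            total = float(rng.uniform(0, 100))
            f = float(rng.uniform(0, 1))
            w, e = partition_cover_by_lineage(total, f)
            assert w + e == pytest.approx(total, abs=1e-12)


def _est(site, stat, value, ci=None, sd=None):
    return DiversityEstimate(site=site, statistic=stat, value=value, ci=ci, sd=sd, n=40)


def _sites(rows):
    return pd.DataFrame(rows, columns=["code", "lineage", "category"])


class TestEvaluateACH:
    def _diff(self, ids, edge_high=True):
        n = len(ids)
        vals = np.full((n, n), 0.05)
        np.fill_diagonal(vals, 0.0)
        if edge_high:
            vals[0, :] = vals[:, 0] = 0.3  # first id is the edge site
            vals[0, 0] = 0.0
        return DiffMatrix(statistic="G''st", ids=list(ids), values=vals)

    def test_clear_effect_supported(self):
        sites = _sites([("E1", "w", "edge"), ("C1", "w", "centre"), ("C2", "w", "centre")])
        div = [
            _est("E1", "A_r", 4.0, ci=(3.8, 4.2)),
            _est("C1", "A_r", 8.0, ci=(7.7, 8.3)),
            _est("C2", "A_r", 8.1, ci=(7.8, 8.4)),
        ]
        verdicts = evaluate_ach(div, [self._diff(["E1", "C1", "C2"])], sites)
        assert len(verdicts) == 1
        assert verdicts[0].conclusion == "supported"
        assert overall_verdict(verdicts)

    def test_overlapping_cis_rejected(self):
        sites = _sites([("E1", "w", "edge"), ("C1", "w", "centre"), ("C2", "w", "centre")])
        div = [
            _est("E1", "A_r", 7.6, ci=(7.0, 8.2)),
            _est("C1", "A_r", 8.0, ci=(7.4, 8.6)),
            _est("C2", "A_r", 8.1, ci=(7.5, 8.7)),
        ]
        verdicts = evaluate_ach(div, [self._diff(["E1", "C1", "C2"])], sites)
        assert verdicts[0].conclusion == "rejected"
        assert verdicts[0].n_edge_lower == 0

    def test_lower_diversity_without_elevated_divergence_rejected(self):
        sites = _sites([("E1", "w", "edge"), ("C1", "w", "centre"), ("C2", "w", "centre")])
        div = [
            _est("E1", "A_r", 4.0, ci=(3.8, 4.2)),
            _est("C1", "A_r", 8.0, ci=(7.7, 8.3)),
            _est("C2", "A_r", 8.1, ci=(7.8, 8.4)),
        ]
        dm = self._diff(["E1", "C1", "C2"], edge_high=False)
        verdicts = evaluate_ach(div, [dm], sites)
        assert verdicts[0].conclusion == "rejected"

    def test_permutation_pvalues_take_precedence(self):
        sites = _sites([("E1", "w", "edge"), ("C1", "w", "centre")])
        div = [_est("E1", "h", 0.3, sd=0.2), _est("C1", "h", 0.9, sd=0.2)]
        dm = DiffMatrix(
            statistic="PhiPT", ids=["E1", "C1"], values=np.array([[0, 0.2], [0.2, 0]])
        )
        tests = {("h", "E1", "C1"): 0.01}
        verdicts = evaluate_ach(div, [dm], sites, diversity_tests=tests)
        # edge divergence condition lacks a centre-centre pair -> inconclusive
        assert verdicts[0].n_edge_lower == 1
        assert verdicts[0].conclusion == "inconclusive"

    def test_group_without_edges_skipped(self):
        sites = _sites([("C1", "w", "centre"), ("C2", "w", "centre")])
        div = [_est("C1", "h", 0.8, sd=0.1), _est("C2", "h", 0.9, sd=0.1)]
        assert evaluate_ach(div, [], sites) == []

    def test_null_scenario_rarely_supported(self):
        # shuffled labels on effect-free synthetic data: support stays at or
        # below the nominal level
        from achconnect.pipeline import genetics_study

        hits = 0
        for seed in range(20):
            study = genetics_study(
                default_scenario(ach_effect=False),
                seed=seed,
                test_iterations=200,
                bootstraps=200,
            )
            hits += study.supported
        assert hits <= 1


class TestVerdictReport:
    def test_report_serialises_and_tabulates(self):
        import json

        from achconnect.ach import verdict_report

        v = ACHVerdict(
            statistic="A_r",
            group="all",
            centre_mean=8.0,
            edge_mean=4.0,
            n_edge=2,
            n_edge_lower=2,
            divergence_edge=0.3,
            divergence_centre=0.1,
            supported=True,
            conclusion="supported",
        )
        payload, md = verdict_report([v])
        assert payload["overall_supported"] is True
        json.dumps(payload)  # JSON-ready
        assert "| A_r |" in md and "supported" in md


class TestCompareClusterings:
    def test_identical_partitions_ari_one(self):
        gen = {"a": 0, "b": 0, "c": 1, "d": 1}
        assert compare_clusterings(gen, dict(gen))["ari"] == pytest.approx(1.0)

    def test_all_in_one_vs_split_ari_zero(self):
        gen = {"a": 0, "b": 0, "c": 0, "d": 0}
        conn = {"a": 0, "b": 0, "c": 1, "d": 1}
        assert compare_clusterings(gen, conn)["ari"] == pytest.approx(0.0)

    def test_one_site_moved_matches_bruteforce_formula(self):
        sites = [f"s{k}" for k in range(9)]
        gen = {s: k // 3 for k, s in enumerate(sites)}
        conn = dict(gen)
        conn["s8"] = 0  # move one site across clusters
        got = compare_clusterings(gen, conn)["ari"]
        expect = oracles.naive_ari(
            [gen[s] for s in sites], [conn[s] for s in sites]
        )
        assert got == pytest.approx(expect, abs=1e-12)

    def test_accepts_cluster_partition_object(self):
        part = ClusterPartition(
            ids=np.array(["a", "b"]), labels=np.array([0, 1]), Q=0.1, method="exhaustive"
        )
        out = compare_clusterings({"a": 0, "b": 1}, part)
        assert out["ari"] == pytest.approx(1.0)

    def test_disjoint_site_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            compare_clusterings({"a": 0}, {"b": 0})
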