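import json
import shutil

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from trialnet.cohort import CohortConfig, TrialCohort, generate_cohort
from trialnet.discovery import (
    hr_vs_measure_trend,
    run_full_study,
    spearman_permutation,
    top_central_profile,
)
from trialnet.exceptions import StageError
from trialnet.io import StudyConfig, write_trials_csv
from trialnet.networks import PAConfig, build_shared_attribute_network

from conftest import make_trial


def chain_cohort(hrs, **kw):
    return TrialCohort([
        make_trial(f"T{i}", year=1990 + i, hr=h, **kw)
        for i, h in enumerate(hrs)
    ])


def small_study_config(tmp_path, **overrides):
    kw = dict(
        cohort=CohortConfig(n_trials=60),
        pa=PAConfig(m0=5, m=4),
        er_replicates=2,
        bootstrap_replicates=120,
        n_bins=5,
        n_permutations=200,
        master_seed=7,
        output_dir=str(tmp_path / "study"),
    )
    kw.update(overrides)
    return StudyConfig(**kw)


class TestSpearmanPermutation:
    def test_matches_scipy_rho(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=80), rng.normal(size=80)
        rho, _ = spearman_permutation(x, y, n_perm=500, seed=0)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_detects_monotone_signal(self):
        x = np.arange(60.0)
        y = x + np.random.default_rng(1).normal(0, 5, 60)
        rho, p = spearman_permutation(x, y, n_perm=2000, seed=0)
        assert rho > 0.8 and p < 0.01


class TestTrend:
    def test_constant_hr_gives_flat_bins_and_zero_rho(self):
        cohort = chain_cohort([1.3] * 12)
        g = nx.path_graph([t.trial_id for t in cohort])
        trend = hr_vs_measure_trend(cohort, g, "degree", n_bins=3, n_perm=100)
        filled = trend.bin_mean_hr[trend.bin_count > 0]
        assert np.allclose(filled, 1.3)
        assert trend.trend_rho == 0.0 and trend.trend_p == 1.0

    def test_constant_measure_flagged_degenerate(self):
        cohort = chain_cohort(np.linspace(0.8, 2.0, 8))
        g = nx.complete_graph([t.trial_id for t in cohort])
        trend = hr_vs_measure_trend(cohort, g, "degree", n_perm=100)
        assert trend.degenerate is not None
        assert trend.trend_rho is None

    def test_perfect_monotone_link_gives_rho_one(self):
        # star-of-stars: node i has degree i+1 and hr increasing in degree
        g = nx.Graph()
        ids = [f"T{i}" for i in range(6)]
        for i, v in enumerate(ids):
            for j in range(i + 1):
                g.add_edge(v, f"leaf_{v}_{j}")
        hrs = [1.0 + 0.2 * i for i in range(6)]
        cohort = TrialCohort(
            [make_trial(v, year=1990 + i, hr=hrs[i]) for i, v in enumerate(ids)]
            + [make_trial(f"leaf_{v}_{j}", year=2000, hr=1.0)
               for i, v in enumerate(ids) for j in range(i + 1)]
        )
        trend = hr_vs_measure_trend(cohort, g, "degree", n_perm=500, seed=0)
        sub = trend.per_value[trend.per_value["value"] > 1]
        assert (np.diff(sub["mean_hr"]) > 0).all()

    def test_rho_independent_of_bin_count(self, default_cohort):
        g = build_shared_attribute_network(default_cohort, ["group", "disease"])
        t1 = hr_vs_measure_trend(default_cohort, g, "degree", n_bins=5,
                                 n_perm=300, seed=1)
        t2 = hr_vs_measure_trend(default_cohort, g, "degree", n_bins=40,
                                 n_perm=300, seed=1)
        assert t1.trend_rho == pytest.approx(t2.trend_rho)

    def test_bin_counts_partition_nodes(self, default_cohort):
        g = build_shared_attribute_network(default_cohort, ["group"])
        trend = hr_vs_measure_trend(default_cohort, g, "degree", n_perm=100)
        assert trend.bin_count.sum() == g.number_of_nodes()

    def test_invalid_inputs(self, default_cohort):
        g = build_shared_attribute_network(default_cohort, ["group"])
        with pytest.raises(ValueError, match="n_bins"):
            hr_vs_measure_trend(default_cohort, g, "degree", n_bins=1)
        with pytest.raises(ValueError, match="unknown measure"):
            hr_vs_measure_trend(default_cohort, g, "pagerank")


class TestCentralProfile:
    def test_dominant_node_profile(self):
        cohort = chain_cohort([1.0, 1.0, 2.5], group="SWOG")
        g = nx.star_graph(["T2", "T0", "T1"])  # T2 is the center
        prof = top_central_profile(cohort, g, "closeness", k=1)
        assert prof.top_nodes == ("T2",)
        assert prof.modal_group == "SWOG"
        assert prof.attribute_counts["group"] == {"SWOG": 1}
        assert prof.avg_hr_top == pytest.approx(2.5)

    def test_planted_high_score_attributes_recovered(self):
        # make every ECOG/definitive trial an extreme success; the growth
        # network's most central trials should be dominated by them
        rng = np.random.default_rng(0)
        trials = []
        for i in range(80):
            planted = i % 4 == 0
            trials.append(make_trial(
                f"T{i:03d}", year=1950 + i,
                group="ECOG" if planted else "SWOG",
                treatment="definitive" if planted else "adjuvant",
                hr=4.0 if planted else float(rng.uniform(0.8, 1.2)),
                p_value=0.01 if planted else 0.5,
            ))
        cohort = TrialCohort(trials)
        from trialnet.networks import build_preferential_attachment_network

        g = build_preferential_attachment_network(cohort, PAConfig(m0=5, m=4, seed=2))
        prof = top_central_profile(cohort, g, "closeness", k=10)
        assert prof.modal_group == "ECOG"
        assert prof.modal_treatment == "definitive"
        assert sum(prof.attribute_counts["group"].values()) == 10
        assert prof.avg_hr_top > cohort.hr.mean()

    def test_k_exceeding_node_count_rejected(self):
        cohort = chain_cohort([1.0, 1.1])
        g = nx.path_graph(["T0", "T1"])
        with pytest.raises(ValueError, match="k="):
            top_central_profile(cohort, g, "closeness", k=5)


class TestSingleAttributeNetworksAreCliqueUnions:
    def test_disjoint_clique_structure(self, default_cohort):
        # networks on one attribute decompose into one clique per label,
        # which is why they are excluded from the analysis set
        for attr in ("group", "disease", "treatment"):
            g = build_shared_attribute_network(default_cohort, [attr])
            for comp in nx.connected_components(g):
                sub = g.subgraph(comp)
                n = len(comp)
                assert sub.number_of_edges() == n * (n - 1) // 2
                labels = {getattr(default_cohort.record(v), attr) for v in comp}
                assert len(labels) == 1


class TestFullStudy:
    def test_artifact_layout_and_network_count(self, tmp_path):
        report = run_full_study(small_study_config(tmp_path))
        assert len(report.networks) == 5  # 4 shared + 1 growth network
        assert len(report.er_ensembles) == 5
        out = report.output_dir
        assert (out / "trials.csv").exists()
        assert len(list((out / "networks").glob("*.graphml"))) == 5
        assert (out / "topology.csv").exists()
        assert len(list((out / "fits").glob("*.json"))) == 5
        assert (out / "manifest.json").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["master_seed"] == 7
        assert set(manifest["outputs"]) >= {"trials.csv", "topology.csv"}

    def test_rerun_reproduces_byte_identical_outputs(self, tmp_path):
        cfg = small_study_config(tmp_path)
        report = run_full_study(cfg)
        first = {p.relative_to(report.output_dir): p.read_bytes()
                 for p in sorted(report.output_dir.rglob("*")) if p.is_file()}
        shutil.rmtree(report.output_dir)
        report2 = run_full_study(cfg)
        second = {p.relative_to(report2.output_dir): p.read_bytes()
                  for p in sorted(report2.output_dir.rglob("*")) if p.is_file()}
        assert first == second

    def test_deleting_a_trial_shifts_node_counts_by_one(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_trials=40, seed=1))
        full_csv = tmp_path / "full.csv"
        write_trials_csv(cohort, full_csv)
        smaller = TrialCohort(list(cohort)[:-1])
        small_csv = tmp_path / "small.csv"
        write_trials_csv(smaller, small_csv)
        r1 = run_full_study(small_study_config(
            tmp_path, trials_csv=str(full_csv), pa=PAConfig(m0=4, m=3),
            output_dir=str(tmp_path / "a")))
        r2 = run_full_study(small_study_config(
            tmp_path, trials_csv=str(small_csv), pa=PAConfig(m0=4, m=3),
            output_dir=str(tmp_path / "b")))
        assert (r1.topology["n_nodes"] - r2.topology["n_nodes"] == 1).all()

    def test_failed_stage_is_named(self, tmp_path):
        cfg = small_study_config(tmp_path, trials_csv=str(tmp_path / "nope.csv"))
        with pytest.raises(StageError, match="cohort"):
            run_full_study(cfg)
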