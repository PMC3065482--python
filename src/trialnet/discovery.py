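"""Treatment success as a function of network position.

Relates the survival hazard ratio of each trial to where the trial sits in
an interaction network: binned mean-HR trends against degree and the
centrality measures (with a permutation-tested Spearman rank correlation
as the headline, bin-free statistic), profiles of the most central trials
(their modal group/disease/treatment and mean HR), and the orchestration
of the full study — cohort, networks, random ensembles, topology table,
degree-distribution fits, trend tables and central profiles, all
serialized reproducibly under one master seed.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import metrics as gm
from ._seeds import child_seed
from .cohort import ATTRIBUTES, TrialCohort, generate_cohort
from .exceptions import StageError
from .networks import PAConfig, build_er_ensemble, build_preferential_attachment_network, \
    build_shared_attribute_network
from .powerlaw import classify_connectivity

__all__ = [
    "MEASURES",
    "node_measure",
    "spearman_permutation",
    "BinnedTrend",
    "hr_vs_measure_trend",
    "CentralProfile",
    "top_central_profile",
    "StudyReport",
    "run_full_study",
]

logger = logging.getLogger(__name__)

MEASURES = ("degree", "closeness", "betweenness", "authority", "hub",
            "local_clustering")


def node_measure(g: nx.Graph, measure: str) -> dict:
    """One per-node measure as a node -> value mapping."""
    if measure == "degree":
        return {v: float(d) for v, d in g.degree()}
    if measure == "closeness":
        return gm.closeness_centrality(g)
    if measure == "betweenness":
        return gm.betweenness_centrality(g)
    if measure in ("authority", "hub"):
        auth, hub = gm.hits_scores(g)
        return auth if measure == "authority" else hub
    if measure == "local_clustering":
        return {v: float(c) for v, c in nx.clustering(g).items()}
    raise ValueError(f"unknown measure {measure!r}; known: {MEASURES}")


def spearman_permutation(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Spearman rho with a two-sided permutation p-value.

    The p-value is ``(1 + #{|rho_perm| >= |rho|}) / (n_perm + 1)``, with
    the permutations of ``y`` drawn from a generator seeded by ``seed``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        raise ValueError("constant input; rank correlation undefined")
    rho = float((rxc * ryc).sum() / denom)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(ryc, (n_perm, 1)), axis=1)
    rho_perm = perm @ rxc / denom
    p = float((1 + np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (n_perm + 1))
    return rho, p


@dataclass
class BinnedTrend:
    """Mean HR as a function of a binned network measure.

    ``trend_rho`` / ``trend_p`` are the unbinned node-level Spearman rank
    correlation and its permutation p-value; both are None when the
    measure is constant across nodes (``degenerate`` says why). For
    integer-valued measures ``per_value`` additionally averages HR within
    each distinct measure value.
    """

    measure_name: str
    bin_edges: np.ndarray
    bin_mean_hr: np.ndarray
    bin_count: np.ndarray
    trend_rho: float | None
    trend_p: float | None
    n_permutations: int
    degenerate: str | None = None
    per_value: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "mean_hr": self.bin_mean_hr,
            "count": self.bin_count,
        })


def hr_vs_measure_trend(
    cohort: TrialCohort,
    g: nx.Graph,
    measure: str = "degree",
    n_bins: int = 20,
    n_perm: int = 10_000,
    seed: int = 0,
    log_mean: bool = False,
) -> BinnedTrend:
    """Trend of treatment success (HR) against a network measure.

    Equal-width bins over the observed measure range carry per-bin mean HR
    (arithmetic by default, geometric with ``log_mean``); the headline
    statistic is the bin-free Spearman rho over node-level (measure, HR)
    pairs with a seeded permutation p-value.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = node_measure(g, measure)
    nodes = [t.trial_id for t in cohort if t.trial_id in values]
    if len(nodes) != g.number_of_nodes():
        missing = g.number_of_nodes() - len(nodes)
        raise ValueError(f"{missing} graph node(s) missing from cohort")
    x = np.array([values[v] for v in nodes])
    hr = np.array([cohort.record(v).hr for v in nodes])

    lo, hi = float(x.min()), float(x.max())
    degenerate = None
    if lo == hi:
        degenerate = f"measure {measure!r} constant across nodes"
        edges = np.array([lo, hi], float)
        mean_hr = np.array([_mean_hr(hr, log_mean)])
        counts = np.array([x.size])
        rho = p = None
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.digitize(x, edges[1:-1], right=False), 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        mean_hr = np.full(n_bins, np.nan)
        for b in range(n_bins):
            if counts[b]:
                mean_hr[b] = _mean_hr(hr[idx == b], log_mean)
        if np.ptp(hr) == 0:
            # constant outcome: correlation 0 by convention
            rho, p = 0.0, 1.0
        else:
            rho, p = spearman_permutation(x, hr, n_perm=n_perm, seed=seed)

    per_value = None
    if measure == "degree":
        df = pd.DataFrame({"value": x, "hr": hr})
        per_value = (df.groupby("value")["hr"]
                       .agg(mean_hr="mean", count="size").reset_index())
    return BinnedTrend(
        measure_name=measure, bin_edges=edges, bin_mean_hr=mean_hr,
        bin_count=counts, trend_rho=rho, trend_p=p, n_permutations=n_perm,
        degenerate=degenerate, per_value=per_value,
    )


def _mean_hr(hr: np.ndarray, log_mean: bool) -> float:
    return float(np.exp(np.log(hr).mean())) if log_mean else float(hr.mean())


@dataclass(frozen=True)
class CentralProfile:
    """Characteristics of the k most central trials under one measure.

    ``attribute_counts`` holds the membership counts per label among the
    top-k (the "(8/10)" style tallies); modal_* are the most frequent
    labels (ties broken alphabetically).
    """

    measure_name: str
    k: int
    max_value: float
    top_nodes: tuple[str, ...]
    attribute_counts: dict
    modal_group: str
    modal_disease: str
    modal_treatment: str
    avg_hr_top: float


def top_central_profile(
    cohort: TrialCohort, g: nx.Graph, measure: str, k: int = 10
) -> CentralProfile:
    """Profile the top-k nodes by a measure (ties broken by trial_id)."""
    if k > g.number_of_nodes():
        raise ValueError(f"k={k} exceeds node count {g.number_of_nodes()}")
    values = node_measure(g, measure)
    ranked = sorted(values, key=lambda v: (-values[v], v))
    top = ranked[:k]
    counts = {
        attr: dict(Counter(getattr(cohort.record(v), attr) for v in top))
        for attr in ATTRIBUTES
    }
    modal = {
        attr: min(counts[attr], key=lambda lbl: (-counts[attr][lbl], lbl))
        for attr in ATTRIBUTES
    }
    return CentralProfile(
        measure_name=measure,
        k=k,
        max_value=float(values[top[0]]),
        top_nodes=tuple(top),
        attribute_counts=counts,
        modal_group=modal["group"],
        modal_disease=modal["disease"],
        modal_treatment=modal["treatment"],
        avg_hr_top=float(np.mean([cohort.record(v).hr for v in top])),
    )


# --- full-study orchestration ----------------------------------------------

_TREND_MEASURES = ("degree", "closeness", "betweenness", "local_clustering")
_PROFILE_MEASURES = ("closeness", "betweenness", "authority", "hub")


@dataclass
class StudyReport:
    """In-memory handle to everything a study run produced."""

    output_dir: Path
    cohort: TrialCohort
    networks: dict
    er_ensembles: dict
    topology: pd.DataFrame
    fits: dict
    trends: dict
    profiles: dict
    manifest: dict


def run_full_study(config) -> "StudyReport":
    """Execute the full pipeline and serialize it under one master seed.

    Stages: cohort synthesis (or CSV ingest) -> four shared-characteristics
    networks + one success-biased growth network -> matched random
    ensembles -> topology table -> degree-distribution classification ->
    HR-vs-measure trend tables -> top-central profiles -> manifest.
    Re-running with the same config reproduces byte-identical outputs; any
    stage failure raises :class:`StageError` naming the stage, with
    already-written outputs preserved.
    """
    from . import __version__
    from .io import write_graph, write_trials_csv, read_trials_csv

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.master_seed
    manifest: dict = {
        "package": "trialnet",
        "version": __version__,
        "master_seed": master,
        "config": config.to_dict(),
        "derived_seeds": {},
        "outputs": [],
    }

    def _record(path: Path):
        manifest["outputs"].append(str(path.relative_to(out)))

    stage = "cohort"
    try:
        if config.trials_csv:
            cohort = read_trials_csv(config.trials_csv)
        else:
            cseed = child_seed(master, "cohort")
            manifest["derived_seeds"]["cohort"] = cseed
            cohort = generate_cohort(config.cohort.with_seed(cseed))
        p = out / "trials.csv"
        write_trials_csv(cohort, p)
        _record(p)

        stage = "networks"
        (out / "networks").mkdir(exist_ok=True)
        networks: dict[str, nx.Graph] = {}
        for attrs in config.attribute_subsets:
            name = "shared_" + "_".join(attrs)
            networks[name] = build_shared_attribute_network(cohort, attrs)
        pa_seed = child_seed(master, "pa")
        manifest["derived_seeds"]["pa"] = pa_seed
        pa_cfg = PAConfig(m0=config.pa.m0, m=config.pa.m,
                          score_rule=config.pa.score_rule, seed=pa_seed,
                          degree_weighted=config.pa.degree_weighted)
        networks["preferential_attachment"] = build_preferential_attachment_network(
            cohort, pa_cfg)
        for name, g in networks.items():
            p = out / "networks" / f"{name}.graphml"
            write_graph(g, p, fmt="graphml")
            _record(p)

        stage = "er_ensembles"
        ensembles: dict[str, list[nx.Graph]] = {}
        for name, g in networks.items():
            n = g.number_of_nodes()
            avg_deg = 2 * g.number_of_edges() / n
            s = child_seed(master, "er", len(ensembles))
            manifest["derived_seeds"][f"er_{name}"] = s
            ensembles[name] = build_er_ensemble(n, avg_deg, config.er_replicates, s)

        stage = "topology"
        rows = []
        for name, g in networks.items():
            sw = gm.small_world_assessment(g, ensembles[name])
            rows.append({
                "network": name,
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
                "mean_degree": 2 * g.number_of_edges() / g.number_of_nodes(),
                "avg_shortest_path": sw.observed_path,
                "global_clustering": sw.observed_clustering,
                "er_avg_shortest_path": sw.ensemble_path,
                "er_global_clustering": sw.ensemble_clustering,
                "path_ratio": sw.path_ratio,
                "clustering_ratio": sw.clustering_ratio,
                "small_world": sw.is_small_world,
            })
        topology = pd.DataFrame(rows)
        p = out / "topology.csv"
        topology.to_csv(p, index=False, float_format="%.6g")
        _record(p)

        stage = "degree_fits"
        (out / "fits").mkdir(exist_ok=True)
        fits = {}
        for i, (name, g) in enumerate(networks.items()):
            s = child_seed(master, "gof", i)
            manifest["derived_seeds"][f"gof_{name}"] = s
            cls = classify_connectivity(
                gm.degree_distribution(g),
                n_boot=config.bootstrap_replicates, seed=s,
                tail_min=config.tail_min, return_details=True,
            )
            fits[name] = cls
            fit = cls.power_law
            payload = {
                "network": name, "label": cls.label, "alpha": fit.alpha,
                "x_min": fit.x_min, "ks_stat": fit.ks_stat,
                "n_tail": fit.n_tail, "gof_p": fit.gof_p,
                "n_boot": fit.n_boot, "seed": s,
                "geometric_ks": cls.geometric_ks,
            }
            p = out / "fits" / f"{name}.json"
            p.write_text(json.dumps(payload, sort_keys=True, indent=2))
            _record(p)

        stage = "trends"
        (out / "trends").mkdir(exist_ok=True)
        trends = {}
        trend_nets = dict(networks)
        for name in list(networks):
            trend_nets[f"er_matched_{name}"] = ensembles[name][0]
        summary_rows = []
        for i, (name, g) in enumerate(trend_nets.items()):
            gg = _with_cohort_labels(g, cohort)
            for j, measure in enumerate(_TREND_MEASURES):
                s = child_seed(master, "trend", i, j)
                trend = hr_vs_measure_trend(
                    cohort, gg, measure=measure, n_bins=config.n_bins,
                    n_perm=config.n_permutations, seed=s,
                )
                trends[(name, measure)] = trend
                p = out / "trends" / f"{name}__{measure}.csv"
                trend.to_frame().to_csv(p, index=False, float_format="%.6g")
                _record(p)
                summary_rows.append({
                    "network": name, "measure": measure,
                    "rho": trend.trend_rho, "p": trend.trend_p,
                    "degenerate": trend.degenerate or "",
                })
        p = out / "trends" / "summary.csv"
        pd.DataFrame(summary_rows).to_csv(p, index=False, float_format="%.6g")
        _record(p)

        stage = "profiles"
        (out / "profiles").mkdir(exist_ok=True)
        profiles = {}
        for name, g in trend_nets.items():
            gg = _with_cohort_labels(g, cohort)
            payload = {}
            for measure in _PROFILE_MEASURES:
                prof = top_central_profile(cohort, gg, measure,
                                           k=min(config.top_k, len(cohort)))
                profiles[(name, measure)] = prof
                payload[measure] = {
                    "max_value": prof.max_value,
                    "top_nodes": list(prof.top_nodes),
                    "attribute_counts": prof.attribute_counts,
                    "modal_group": prof.modal_group,
                    "modal_disease": prof.modal_disease,
                    "modal_treatment": prof.modal_treatment,
                    "avg_hr_top": prof.avg_hr_top,
                    "k": prof.k,
                }
            p = out / "profiles" / f"{name}.json"
            p.write_text(json.dumps(payload, sort_keys=True, indent=2))
            _record(p)

        stage = "manifest"
        manifest["outputs"] = sorted(manifest["outputs"])
        p = out / "manifest.json"
        p.write_text(json.dumps(manifest, sort_keys=True, indent=2))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage name is the useful context
        raise StageError(stage, str(e)) from e

    logger.info("study complete: %d networks, outputs in %s", len(networks), out)
    return StudyReport(
        output_dir=out, cohort=cohort, networks=networks,
        er_ensembles=ensembles, topology=topology, fits=fits,
        trends=trends, profiles=profiles, manifest=manifest,
    )


def _with_cohort_labels(g: nx.Graph, cohort: TrialCohort) -> nx.Graph:
    """Relabel integer-node graphs (ER members) onto cohort trial ids."""
    if set(g.nodes()) == set(cohort.trial_ids):
        return g
    mapping = dict(zip(sorted(g.nodes()), cohort.trial_ids))
    return nx.relabel_nodes(g, mapping, copy=True)
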