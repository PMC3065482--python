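"""Construction of RCT interaction networks.

Three families of undirected simple graphs over the trials of a cohort:

* shared-characteristics networks — an edge joins two trials that share a
  label on at least one of the chosen attributes (cooperative group,
  disease, treatment type);
* success-biased growth (preferential attachment by fitness) — trials
  enter in chronological order and attach to existing trials with
  probability proportional to their success score, not their degree;
* Erdős–Rényi ensembles matched on node count and average degree, the
  random null against which the first two are compared.

Every builder stamps provenance (model identifier, parameters, seed) into
``graph.graph`` so serialized graphs are self-describing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from ._seeds import spawn_seeds
from .cohort import ATTRIBUTES, TrialCohort, success_scores
from .exceptions import ConfigurationError

__all__ = [
    "PAConfig",
    "build_shared_attribute_network",
    "build_preferential_attachment_network",
    "build_er_ensemble",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PAConfig:
    """Parameters of the success-biased growth model.

    The earliest ``m0`` trials form a fully connected seed network; each
    later trial adds exactly ``m`` ties. Defaults give average degree
    ``~2m = 36``, the scale of the observed growth network.
    """

    m0: int = 19
    m: int = 18
    score_rule: str = "hr_times_one_minus_p"
    seed: int = 0
    degree_weighted: bool = False  # if True, bias by score * (degree + 1)

    def validate(self):
        if not 1 <= self.m <= self.m0:
            raise ConfigurationError(f"need 1 <= m <= m0, got m={self.m}, m0={self.m0}")


def _provenance(model: str, **params) -> dict:
    return {"model": model, **{k: v for k, v in params.items() if v is not None}}


def build_shared_attribute_network(cohort: TrialCohort, attrs) -> nx.Graph:
    """Network of trials sharing at least one attribute label.

    ``attrs`` is a non-empty subset of ``{"group", "disease", "treatment"}``.
    OR semantics: an edge joins two distinct trials iff they carry the same
    label on *at least one* attribute in ``attrs``, so adding attributes can
    only add edges and multi-attribute networks are denser than
    single-attribute ones (which are disjoint unions of cliques).
    Deterministic; edge direction (later trial cites earlier) is a
    time-flow gloss that does not affect the undirected structure.
    """
    attrs = tuple(attrs)
    if not attrs:
        raise ValueError("attrs must be a non-empty subset of group/disease/treatment")
    unknown = set(attrs) - set(ATTRIBUTES)
    if unknown:
        raise ValueError(f"unknown attribute(s) {sorted(unknown)}; known: {ATTRIBUTES}")

    g = nx.Graph(**_provenance("shared_attributes", attrs=",".join(sorted(set(attrs)))))
    g.add_nodes_from(t.trial_id for t in cohort)
    for attr in attrs:
        by_label: dict[str, list[str]] = {}
        for t in cohort:
            by_label.setdefault(getattr(t, attr), []).append(t.trial_id)
        for members in by_label.values():
            g.add_edges_from(combinations(members, 2))
    return g


def build_preferential_attachment_network(
    cohort: TrialCohort, config: PAConfig | None = None
) -> nx.Graph:
    """Grow a network by success-biased attachment.

    Trials enter in chronological order. The earliest ``m0`` form a
    complete seed graph; each subsequent trial draws ``m`` distinct
    existing trials without replacement, with probability proportional to
    the success score (renormalized after each draw). If every existing
    score is zero at some step the draw falls back to uniform sampling
    (logged at warning level). The result is connected by construction.
    """
    config = config or PAConfig()
    config.validate()
    n = len(cohort)
    if n < config.m0:
        raise ValueError(f"cohort size {n} < m0 = {config.m0}")

    ids = cohort.trial_ids
    scores = success_scores(cohort, config.score_rule)
    rng = np.random.default_rng(config.seed)

    g = nx.Graph(**_provenance(
        "preferential_attachment",
        m0=config.m0, m=config.m, score_rule=config.score_rule,
        seed=config.seed, degree_weighted=config.degree_weighted,
    ))
    g.add_nodes_from(ids[: config.m0])
    g.add_edges_from(combinations(ids[: config.m0], 2))

    fallbacks = 0
    for i in range(config.m0, n):
        w = scores[:i].astype(float).copy()
        if config.degree_weighted:
            w *= np.array([g.degree(v) + 1 for v in ids[:i]], float)
        total = w.sum()
        if total <= 0:
            fallbacks += 1
            targets = rng.choice(i, size=config.m, replace=False)
        else:
            # sequential weighted draws without replacement (renormalizing)
            targets = rng.choice(i, size=config.m, replace=False, p=w / total)
        g.add_node(ids[i])
        g.add_edges_from((ids[i], ids[j]) for j in targets)
    if fallbacks:
        logger.warning(
            "preferential attachment: %d step(s) had all-zero scores; "
            "fell back to uniform sampling", fallbacks,
        )
    return g


def build_er_ensemble(
    n_nodes: int, avg_degree: float, n_graphs: int, seed: int
) -> list[nx.Graph]:
    """An ensemble of G(n, p) graphs with ``p = avg_degree / (n_nodes - 1)``.

    Each graph gets its own seed derived deterministically from ``seed``.
    """
    if n_graphs < 1:
        raise ValueError(f"n_graphs must be >= 1, got {n_graphs}")
    if not 0 <= avg_degree <= n_nodes - 1:
        raise ValueError(
            f"avg_degree must be in [0, n_nodes - 1] = [0, {n_nodes - 1}], "
            f"got {avg_degree}"
        )
    p = avg_degree / (n_nodes - 1)
    graphs = []
    for i, s in enumerate(spawn_seeds(seed, "er_ensemble", n_graphs)):
        g = nx.gnp_random_graph(n_nodes, p, seed=np.random.default_rng(s))
        g.graph.update(_provenance(
            "erdos_renyi", n=n_nodes, avg_degree=avg_degree, p=p,
            seed=seed, member=i, member_seed=s,
        ))
        graphs.append(g)
    return graphs
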