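import networkx as nx
import numpy as np
import pytest

from trialnet.cohort import CohortConfig, TrialCohort, TrialRecord, generate_cohort


def make_trial(trial_id, year=2000, group="ECOG", disease="GI",
               treatment="definitive", hr=1.0, p_value=0.5):
    return TrialRecord(trial_id=trial_id, year=year, group=group,
                       disease=disease, treatment=treatment, hr=hr,
                       p_value=p_value)


@pytest.fixture(scope="session")
def default_cohort():
    """A study-scale synthetic cohort (280 trials, fixed seed)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture()
def toy_cohort():
    """Five trials with labels (A,x),(A,y),(B,y),(B,z),(C,z) on
    (group, disease), entering in consecutive years."""
    labels = [("A", "x"), ("A", "y"), ("B", "y"), ("B", "z"), ("C", "z")]
    return TrialCohort([
        make_trial(f"T{i}", year=1990 + i, group=g, disease=d, treatment="other")
        for i, (g, d) in enumerate(labels)
    ])


def random_small_graphs(n_graphs, max_nodes=7, seed=0):
    """Random graphs on <= max_nodes nodes (connected or not), with at
    least one edge each."""
    rng = np.random.default_rng(seed)
    graphs = []
    while len(graphs) < n_graphs:
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.2, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            continue
        graphs.append(g)
    return graphs
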