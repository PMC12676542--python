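import numpy as np
import pytest

import epiparc as ep
from epiparc import mshbm


@pytest.fixture(scope="session")
def ring_graph():
    return ep.build_cortical_graph(20, "ring")


@pytest.fixture(scope="session")
def grid_graph():
    return ep.build_cortical_graph(36, "grid")


@pytest.fixture(scope="session")
def tiny_cohort():
    """K=3 cohort on a 40-vertex ring: 4 subjects x 2 runs, T=100."""
    graph = ep.build_cortical_graph(20, "ring")
    truth, runs = ep.generate_cohort(graph, K=3, R=20, n_subjects=4,
                                     n_runs=2, T=100, snr=4.0,
                                     deviation_rate=0.1, seed=11)
    return graph, truth, runs


def fit_group_and_train(graph, truth, runs, n_subjects, n_runs, c=1.0,
                        max_iter=10, n_init=2, seed=0):
    """Group vMF fit aligned to the planted networks, then MS-HBM training."""
    profs = {s: [ep.compute_profile(runs[(s, t)]) for t in range(n_runs)]
             for s in range(n_subjects)}
    rows = np.concatenate([p.matrix for ps in profs.values() for p in ps])
    vidx = np.tile(np.arange(graph.n_vertices), n_subjects * n_runs)
    mix, parc = ep.fit_vmf_mixture(rows, truth.K, vertex_index=vidx,
                                   n_vertices=graph.n_vertices,
                                   mask=graph.cortex_mask,
                                   n_init=n_init, seed=seed)
    perm = mshbm.match_networks(parc.labels, truth.group_labels, truth.K)
    parc.labels = mshbm.relabel(parc.labels, perm)
    order = np.argsort(perm)
    mix.mu, mix.kappa, mix.weights = mix.mu[order], mix.kappa[order], mix.weights[order]
    params = ep.train_mshbm([profs[s] for s in range(n_subjects)], graph,
                            parc, mix, c=c, max_iter=max_iter, seed=seed)
    return profs, mix, parc, params


@pytest.fixture(scope="session")
def trained_model():
    """Mid-size trained MS-HBM shared across inference tests:
    K=4 on a 160-vertex grid, 10 subjects x 2 runs."""
    graph = ep.build_cortical_graph(80, "grid")
    truth, runs = ep.generate_cohort(graph, K=4, R=32, n_subjects=10,
                                     n_runs=2, T=150, snr=4.0,
                                     deviation_rate=0.1, seed=5)
    profs, mix, parc, params = fit_group_and_train(graph, truth, runs, 10, 2)
    return graph, truth, runs, profs, parc, params
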