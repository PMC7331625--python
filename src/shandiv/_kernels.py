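"""Numba kernels: bounded-SMM coalescent and batched subset sampling.

The simulator samples whole populations (20,000 gene copies per locus), so
the coalescent loop and the mutation walk are compiled.  Each kernel seeds
numba's own Mersenne Twister from an explicit 32-bit seed, which makes every
(replicate, scenario, locus) simulation reproducible in isolation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_locus_states", "draw_subsamples"]


@njit(cache=True)
def simulate_locus_states(
    n_copies, epoch_ends, epoch_sizes, mu, k_max, root_state, seed, reflect
):
    """Simulate one locus: tip allele states under a bounded stepwise model.

    Runs a Kingman coalescent on ``n_copies`` lineages through a
    piecewise-constant demography (``epoch_ends`` are cumulative boundary
    times backward from sampling, last entry inf; ``epoch_sizes`` diploid
    N per epoch), then drops Poisson(mu * branch length) mutations on every
    branch.  Each mutation steps the allele state +/-1 with equal
    probability; a step leaving ``[0, k_max - 1]`` is either discarded
    (state unchanged, ``reflect`` false) or bounced off the range wall
    (``reflect`` true).  Returns the ``n_copies`` tip states.
    """
    np.random.seed(seed)
    total = 2 * n_copies - 1
    parent = np.full(total, -1, dtype=np.int64)
    node_time = np.zeros(total, dtype=np.float64)

    active = np.empty(n_copies, dtype=np.int64)
    for i in range(n_copies):
        active[i] = i
    k = n_copies
    t = 0.0
    epoch = 0
    next_node = n_copies
    n_epochs = epoch_ends.shape[0]

    while k > 1:
        pop_n = epoch_sizes[epoch]
        rate = k * (k - 1.0) / (4.0 * pop_n)  # C(k,2) / (2N) per generation
        wait = np.random.exponential(1.0 / rate)
        if epoch < n_epochs - 1 and t + wait > epoch_ends[epoch]:
            t = epoch_ends[epoch]
            epoch += 1
            continue
        t += wait
        i = np.random.randint(0, k)
        j = np.random.randint(0, k - 1)
        if j >= i:
            j += 1
        a = active[i]
        b = active[j]
        parent[a] = next_node
        parent[b] = next_node
        node_time[next_node] = t
        active[i] = next_node
        active[j] = active[k - 1]
        k -= 1
        next_node += 1

    # states top-down: every parent has a larger node index than its children
    state = np.empty(total, dtype=np.int64)
    state[total - 1] = root_state
    for node in range(total - 2, -1, -1):
        branch = node_time[parent[node]] - node_time[node]
        n_mut = np.random.poisson(mu * branch)
        s = state[parent[node]]
        for _ in range(n_mut):
            if np.random.randint(0, 2) == 1:
                step = 1
            else:
                step = -1
            moved = s + step
            if 0 <= moved < k_max:
                s = moved
            elif reflect:
                s = s - step
        state[node] = s
    return state[:n_copies]


@njit(cache=True)
def pairwise_coalescence_times(epoch_ends, epoch_sizes, n_runs, seed):
    """Coalescence times of a sample of two lineages through a
    piecewise-constant demography; used to validate epoch handling against
    closed-form expectations."""
    np.random.seed(seed)
    out = np.empty(n_runs, dtype=np.float64)
    n_epochs = epoch_ends.shape[0]
    for r in range(n_runs):
        t = 0.0
        epoch = 0
        while True:
            wait = np.random.exponential(2.0 * epoch_sizes[epoch])
            if epoch < n_epochs - 1 and t + wait > epoch_ends[epoch]:
                t = epoch_ends[epoch]
                epoch += 1
                continue
            out[r] = t + wait
            break
    return out


@njit(cache=True)
def draw_subsamples(n_pop, ns, n_draws, seed):
    """Draw ``n_draws`` independent uniform subsets of ``ns`` indices from
    ``range(n_pop)`` without replacement (Floyd's algorithm)."""
    np.random.seed(seed)
    out = np.empty((n_draws, ns), dtype=np.int64)
    chosen = np.zeros(n_pop, dtype=np.bool_)
    for d in range(n_draws):
        c = 0
        for j in range(n_pop - ns, n_pop):
            candidate = np.random.randint(0, j + 1)
            if chosen[candidate]:
                out[d, c] = j
                chosen[j] = True
            else:
                out[d, c] = candidate
                chosen[candidate] = True
            c += 1
        for j in range(ns):
            chosen[out[d, j]] = False
    return out
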