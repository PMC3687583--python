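"""Independent oracle for the linkage HMM: exhaustive path enumeration.

Builds the full transition matrices explicitly and sums the joint
probability of every one of the 3^L state paths, marginalising per marker.
Tractable only for short chromosomes; independent of the forward-backward
implementation it checks.
"""

import itertools

import numpy as np
from scipy import stats


def enumerate_posteriors(k, n, pos, params):
    k = np.asarray(k)
    n = np.asarray(n)
    pos = np.asarray(pos)
    L = len(k)
    pi = np.asarray(params.priors, dtype=float)
    p_states = np.array([0.5, params.p_link, 1.0 - params.p_link])
    emis = stats.binom.pmf(k[:, None], n[:, None], p_states[None, :])
    trans = []
    for i in range(L - 1):
        stay = np.exp(-(pos[i + 1] - pos[i]) / params.persistence_bp)
        trans.append(stay * np.eye(3) + (1.0 - stay) * np.tile(pi, (3, 1)))
    joint = np.zeros((L, 3))
    total = 0.0
    for path in itertools.product(range(3), repeat=L):
        p = pi[path[0]] * emis[0, path[0]]
        for i in range(1, L):
            p *= trans[i - 1][path[i - 1], path[i]] * emis[i, path[i]]
        total += p
        for i, s in enumerate(path):
            joint[i, s] += p
    return joint / total


def random_instance(rng, max_markers=8):
    L = int(rng.integers(2, max_markers + 1))
    pos = np.sort(rng.choice(200_000, size=L, replace=False)) + 1
    n = rng.integers(0, 31, size=L)
    k = rng.binomial(n, rng.uniform(0.05, 0.95))
    return k, n, pos
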