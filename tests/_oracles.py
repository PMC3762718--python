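"""Independent brute-force oracles used to cross-check the fast paths.

Everything here is written from the model definition alone (explicit
enumeration / sorted-window scans) and deliberately shares no code with the
package implementation.
"""

from itertools import product

import numpy as np

NA = -1


def enum_within_year(row, p, z):
    """Direct product over non-NA entries of one year's history."""
    pr = 1.0
    for y in row:
        if y == NA:
            continue
        if z == 0:
            pr *= 0.0 if y == 1 else 1.0
        else:
            pr *= p if y == 1 else (1.0 - p)
    return pr


def enum_site_likelihood(histories, psi1, phi, gamma, p):
    """Sum over all 2^T latent occupancy configurations."""
    T = len(histories)
    phi = np.broadcast_to(np.asarray(phi, float), (max(T - 1, 1),))
    gamma = np.broadcast_to(np.asarray(gamma, float), (max(T - 1, 1),))
    p = np.broadcast_to(np.asarray(p, float), (T,))
    total = 0.0
    for zs in product((0, 1), repeat=T):
        pr = psi1 if zs[0] == 1 else 1.0 - psi1
        for t in range(1, T):
            if zs[t - 1] == 1:
                pr *= phi[t - 1] if zs[t] == 1 else 1.0 - phi[t - 1]
            else:
                pr *= gamma[t - 1] if zs[t] == 1 else 1.0 - gamma[t - 1]
        for t in range(T):
            pr *= enum_within_year(histories[t], p[t], zs[t])
        total += pr
    return total


def enum_dataset_loglik(data, psi1_per_site, phi, gamma, p):
    """Sum of per-site enumeration log-likelihoods for (S, T, K) data."""
    ll = 0.0
    for j in range(data.shape[0]):
        histories = [data[j, t, :] for t in range(data.shape[1])]
        ll += np.log(enum_site_likelihood(histories, psi1_per_site[j], phi, gamma, p))
    return ll


def scan_hpdi(draws, level=0.95):
    """Exhaustive shortest-window search over the sorted draws."""
    x = np.sort(np.asarray(draws, float))
    n = x.size
    m = int(np.ceil(level * n))
    best = (np.inf, None)
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if w < best[0]:
            best = (w, (x[i], x[i + m - 1]))
    return best[1]
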