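"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths (and where possible the libraries)
they check: the Cox oracle maximizes the partial likelihood on a dense
grid, the Fisher oracle enumerates hypergeometric tables with exact
integer arithmetic, the cutoff oracle rescans every candidate threshold,
and the dilation oracle computes voxel-to-mask distances pairwise.
"""

import math

import numpy as np


def cox_grid_coefficient(times, events, covariate, lo=-5.0, hi=5.0, step=1e-4):
    """Grid-search maximizer of the Cox partial likelihood (tie-free data)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(covariate, float)
    assert len(np.unique(times)) == len(times), "oracle assumes tie-free times"
    betas = np.arange(lo, hi + step / 2, step)
    loglik = np.zeros_like(betas)
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    n = len(times)
    for i in range(n):
        if not events[i]:
            continue
        risk = x[i:]  # all subjects with time >= t_i
        terms = np.exp(betas[:, None] * risk[None, :]).sum(axis=1)
        loglik += betas * x[i] - np.log(terms)
    return float(betas[np.argmax(loglik)])


def fisher_exact_two_sided(table):
    """Two-sided Fisher p by exact enumeration of tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def weight(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0
        return math.comb(r1, k) * math.comb(r2, c1 - k)

    w_obs = weight(a)
    total = math.comb(n, c1)
    acc = sum(w for k in range(0, c1 + 1) if (w := weight(k)) <= w_obs)
    return acc / total


def youden_scan(scores, labels):
    """Exhaustive midpoint-threshold scan maximizing sensitivity+specificity-1."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    uniq = np.unique(scores)
    best_thr, best_j, best = None, -np.inf, None
    for thr in (uniq[:-1] + uniq[1:]) / 2.0:
        tp = np.sum(labels & (scores >= thr))
        fn = np.sum(labels & (scores < thr))
        tn = np.sum(~labels & (scores < thr))
        fp = np.sum(~labels & (scores >= thr))
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_thr, best_j, best = thr, j, (sens, spec)
    return best_thr, best_j, best


def dilate_bruteforce(mask, spacing, margin):
    """World-mm dilation by pairwise voxel-center distances (small grids only)."""
    mask = np.asarray(mask, bool)
    spacing = np.asarray(spacing, float)
    seeds = np.argwhere(mask) * spacing
    out = np.zeros(mask.shape, bool)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * spacing
        if np.min(np.linalg.norm(seeds - p, axis=1)) <= margin:
            out[idx] = True
    return out


def km_empirical_survivor(times):
    """Empirical survivor function S(t) = P(T > t) at each event time."""
    times = np.sort(np.asarray(times, float))
    n = len(times)
    return times, 1.0 - np.arange(1, n + 1) / n


def logrank_chi2(times, events, group):
    """Two-group log-rank chi-square from first principles."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group).astype(bool)
    obs_minus_exp, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_all, n_1 = at_risk.sum(), (at_risk & group).sum()
        d_all = ((times == t) & (events == 1)).sum()
        d_1 = ((times == t) & (events == 1) & group).sum()
        obs_minus_exp += d_1 - d_all * n_1 / n_all
        if n_all > 1:
            var += (
                d_all * (n_1 / n_all) * (1 - n_1 / n_all) * (n_all - d_all) / (n_all - 1)
            )
    return obs_minus_exp**2 / var
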