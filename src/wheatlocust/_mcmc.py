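"""JIT-compiled component-wise random-walk Metropolis core for the BS model.

The likelihood depends on the choice trials only through per-pair sufficient
statistics (number of trials, number of wild wins), so a chain update for one
accession touches only the pairs that involve it.  The sampler stores those
pairs in CSR-style index arrays and runs the whole chain inside one
``numba.njit`` function.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

P_CLAMP = 1e-6


@njit(cache=True)
def _log_prior(bs: float) -> float:
    # shifted Beta(2,2): density ∝ (bs+0.5)(0.5−bs) on (−0.5, 0.5)
    x = bs + 0.5
    if x <= 0.0 or x >= 1.0:
        return -np.inf
    return math.log(x) + math.log(1.0 - x)


@njit(cache=True)
def _pair_loglik(bs_j: float, bs_k: float, wins: float, tot: float) -> float:
    p = 0.5 + bs_j - bs_k
    if p < P_CLAMP:
        p = P_CLAMP
    elif p > 1.0 - P_CLAMP:
        p = 1.0 - P_CLAMP
    return wins * math.log(p) + (tot - wins) * math.log(1.0 - p)


@njit(cache=True)
def run_chain(
    n_acc: int,
    pair_j: np.ndarray,  # wild accession index per pair
    pair_k: np.ndarray,  # modern accession index per pair
    wins: np.ndarray,  # wild wins per pair (float)
    tot: np.ndarray,  # trials per pair (float)
    acc_ptr: np.ndarray,  # CSR pointers into acc_pairs, len n_acc+1
    acc_pairs: np.ndarray,  # pair indices grouped by accession
    n_steps: int,
    burn_in: int,
    thin: int,
    proposal_sd: float,
    seed: int,
    adapt: bool,
):
    """One Metropolis chain; returns (draws, acceptance_rate, tuned_sd).

    A step is one sweep of single-component random-walk proposals over all
    ``n_acc`` scores.  Proposal scales are tuned multiplicatively during
    burn-in only (targeting ~35% acceptance), keeping the post-burn-in kernel
    fixed.  Draws are retained every ``thin`` steps after burn-in:
    ``n_kept = (n_steps − burn_in) // thin``.
    """
    np.random.seed(seed)
    bs = np.zeros(n_acc)
    sd = np.full(n_acc, proposal_sd)
    pair_ll = np.empty(len(pair_j))
    for p in range(len(pair_j)):
        pair_ll[p] = _pair_loglik(bs[pair_j[p]], bs[pair_k[p]], wins[p], tot[p])
    prior = np.empty(n_acc)
    for a in range(n_acc):
        prior[a] = _log_prior(bs[a])

    n_keep = (n_steps - burn_in) // thin
    draws = np.empty((n_keep, n_acc))
    accepted = np.zeros(n_acc)
    attempted = np.zeros(n_acc)
    win_acc = np.zeros(n_acc)
    win_att = np.zeros(n_acc)
    kept = 0
    for step in range(n_steps):
        for a in range(n_acc):
            prop = bs[a] + sd[a] * np.random.normal()
            attempted[a] += 1.0
            win_att[a] += 1.0
            new_prior = _log_prior(prop)
            if new_prior == -np.inf:
                continue
            delta = new_prior - prior[a]
            for idx in range(acc_ptr[a], acc_ptr[a + 1]):
                p = acc_pairs[idx]
                if pair_j[p] == a:
                    new_ll = _pair_loglik(prop, bs[pair_k[p]], wins[p], tot[p])
                else:
                    new_ll = _pair_loglik(bs[pair_j[p]], prop, wins[p], tot[p])
                delta += new_ll - pair_ll[p]
            if delta >= 0.0 or math.log(np.random.random()) < delta:
                bs[a] = prop
                prior[a] = new_prior
                for idx in range(acc_ptr[a], acc_ptr[a + 1]):
                    p = acc_pairs[idx]
                    if pair_j[p] == a:
                        pair_ll[p] = _pair_loglik(bs[a], bs[pair_k[p]], wins[p], tot[p])
                    else:
                        pair_ll[p] = _pair_loglik(bs[pair_j[p]], bs[a], wins[p], tot[p])
                accepted[a] += 1.0
                win_acc[a] += 1.0
        if adapt and step < burn_in and (step + 1) % 100 == 0:
            for a in range(n_acc):
                rate = win_acc[a] / win_att[a]
                sd[a] *= math.exp(rate - 0.35)
                if sd[a] < 1e-3:
                    sd[a] = 1e-3
                elif sd[a] > 0.5:
                    sd[a] = 0.5
                win_acc[a] = 0.0
                win_att[a] = 0.0
        if step >= burn_in and (step - burn_in) % thin == thin - 1 and kept < n_keep:
            draws[kept] = bs
            kept += 1
    return draws, accepted / attempted, sd
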