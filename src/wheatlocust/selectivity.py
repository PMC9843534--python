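"""Feeding selectivity: disk-area bookkeeping, paired tests and Bayesian scores.

In a paired-choice (cafeteria) trial a starved locust nymph faces leaf disks
of one wild (ancestral) and one modern wheat accession.  Consumed dry biomass
per side is the eaten disk area divided by that accession's specific leaf
area; the feeding-selectivity proportion FS of a side is its share of the
total consumed biomass (the two sides sum to 1).

The latent preference model treats the binary event "FS was higher for the
ancestral accession" as Bernoulli with

    P(choose wild) = 0.5 + BS_wild − BS_modern,

one score BS ∈ [−0.5, 0.5] per accession, with independent shifted-Beta(2,2)
priors centred on 0 (density vanishing at ±0.5).  Because the printed
probability equation can leave [0, 1] for extreme score pairs, P is clamped
to [1e−6, 1−1e−6] in both the likelihood and the simulator.  The posterior is
sampled by component-wise random-walk Metropolis (proposal scales auto-tuned
during burn-in to a 20–50% acceptance band), with a brute-force grid
posterior available as an independent oracle for problems of ≤ 3 accessions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._mcmc import P_CLAMP, run_chain

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feeding-selectivity proportions
# ---------------------------------------------------------------------------

def consumed_dry_biomass(
    control_area_cm2: float, uneaten_area_cm2: float, sla_cm2_g: float
) -> float:
    """Consumed dry biomass (g) from disk areas and specific leaf area.

    Negative area differences (climatic-control measurement noise) are
    clamped to zero; callers can count clamp events via the module logger.
    """
    if sla_cm2_g <= 0:
        raise ValueError(f"SLA must be positive, got {sla_cm2_g}")
    if control_area_cm2 < 0 or uneaten_area_cm2 < 0:
        raise ValueError("disk areas must be nonnegative")
    diff = control_area_cm2 - uneaten_area_cm2
    if diff < 0:
        logger.debug("consumed area clamped to 0 (uneaten > control by %.4g)", -diff)
        diff = 0.0
    return diff / sla_cm2_g


def feeding_selectivity(mass_wild_g: float, mass_modern_g: float) -> tuple[float, float]:
    """FS proportions of the two sides; (nan, nan) when nothing was eaten."""
    if mass_wild_g < 0 or mass_modern_g < 0:
        raise ValueError("consumed masses must be nonnegative")
    total = mass_wild_g + mass_modern_g
    if total == 0:
        return (float("nan"), float("nan"))
    fs_wild = mass_wild_g / total
    return (fs_wild, 1.0 - fs_wild)


def compute_fs_table(choice_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial FS proportions and choice indicators from a disk-area table.

    Expects the choice_trials.csv dialect (control/uneaten areas and SLA per
    side).  Adds ``mass_wild_g, mass_modern_g, fs_wild, fs_modern,
    wild_chosen, informative``.  Trials with zero total consumption are
    flagged uninformative; exact FS ties (0.5) keep their FS values for the
    paired test but get ``wild_chosen = NaN`` so they drop out of the
    Bernoulli likelihood.
    """
    n_clamped = 0
    rows = []
    for t in choice_trials.itertuples(index=False):
        if t.uneaten_area_wild_cm2 > t.control_area_wild_cm2:
            n_clamped += 1
        if t.uneaten_area_modern_cm2 > t.control_area_modern_cm2:
            n_clamped += 1
        mw = consumed_dry_biomass(
            t.control_area_wild_cm2, t.uneaten_area_wild_cm2, t.sla_wild_cm2_g
        )
        mm = consumed_dry_biomass(
            t.control_area_modern_cm2, t.uneaten_area_modern_cm2, t.sla_modern_cm2_g
        )
        fsw, fsm = feeding_selectivity(mw, mm)
        informative = not math.isnan(fsw)
        if not informative or fsw == 0.5:
            chosen = float("nan")
        else:
            chosen = float(fsw > 0.5)
        rows.append((mw, mm, fsw, fsm, chosen, informative))
    if n_clamped:
        logger.info("compute_fs_table: clamped %d negative consumed areas", n_clamped)
    extra = pd.DataFrame(
        rows,
        columns=["mass_wild_g", "mass_modern_g", "fs_wild", "fs_modern",
                 "wild_chosen", "informative"],
        index=choice_trials.index,
    )
    return pd.concat([choice_trials, extra], axis=1)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_difference_pct: float  # mean (fs_wild − fs_modern), percentage points
    n: int


def paired_t_test(fs_wild: np.ndarray, mu0: float = 0.5) -> PairedTestResult:
    """Paired t-test of wild vs modern FS (one-sample t on the differences).

    Because the proportions sum to one, the paired difference is
    ``2·fs_wild − 1`` and the test is a one-sample t of ``fs_wild`` against
    ``mu0 = 0.5``.  The mean difference is reported in percentage points.
    """
    fs = np.asarray(fs_wild, dtype=float)
    fs = fs[~np.isnan(fs)]
    if fs.size < 2:
        raise ValueError("paired t-test needs at least 2 informative trials")
    diffs = 2.0 * fs - 2.0 * mu0
    mean_diff = float(diffs.mean())
    if np.allclose(diffs.std(ddof=1), 0.0):
        if math.isclose(mean_diff, 0.0, abs_tol=1e-15):
            return PairedTestResult(0.0, fs.size - 1, 1.0, 0.0, fs.size)
        return PairedTestResult(math.inf, fs.size - 1, 0.0, 100 * mean_diff, fs.size)
    res = stats.ttest_1samp(diffs, 0.0)
    return PairedTestResult(
        float(res.statistic), fs.size - 1, float(res.pvalue), 100 * mean_diff, fs.size
    )


# ---------------------------------------------------------------------------
# Bayesian score model
# ---------------------------------------------------------------------------

def choice_probability(bs_wild: float, bs_modern: float) -> float:
    """P(choose wild) = 0.5 + BS_wild − BS_modern, clamped to (0, 1)."""
    for name, v in (("bs_wild", bs_wild), ("bs_modern", bs_modern)):
        if not -0.5 <= v <= 0.5:
            raise ValueError(f"{name} = {v} outside the score support [-0.5, 0.5]")
    return float(np.clip(0.5 + bs_wild - bs_modern, P_CLAMP, 1.0 - P_CLAMP))


@dataclass(frozen=True)
class PairStats:
    """Sufficient statistics of the Bernoulli likelihood, one row per pair."""

    accessions: list[str]
    pair_j: np.ndarray  # wild accession index
    pair_k: np.ndarray  # modern accession index
    wins: np.ndarray  # wild-chosen counts
    tot: np.ndarray  # informative trial counts

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)


def pair_statistics(
    fs_table: pd.DataFrame, accessions: list[str] | None = None
) -> PairStats:
    """Collapse an FS table to per-pair win/total counts.

    Uninformative trials and exact ties (``wild_chosen`` NaN) are excluded
    from the likelihood; their count is logged.
    """
    ok = fs_table["wild_chosen"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("pair_statistics: excluded %d tie/uninformative trials", n_dropped)
    sub = fs_table[ok]
    if accessions is None:
        accessions = sorted(
            set(fs_table["wild_accession"]) | set(fs_table["modern_accession"])
        )
    index = {a: i for i, a in enumerate(accessions)}
    grouped = sub.groupby(["wild_accession", "modern_accession"])["wild_chosen"].agg(
        ["sum", "count"]
    )
    pj, pk, wins, tot = [], [], [], []
    for (w, m), row in grouped.iterrows():
        pj.append(index[w])
        pk.append(index[m])
        wins.append(float(row["sum"]))
        tot.append(float(row["count"]))
    return PairStats(
        list(accessions),
        np.asarray(pj, dtype=np.int64),
        np.asarray(pk, dtype=np.int64),
        np.asarray(wins, dtype=np.float64),
        np.asarray(tot, dtype=np.float64),
    )


def log_posterior(bs: np.ndarray, pairs: PairStats) -> float:
    """Unnormalized log posterior: Bernoulli likelihood + shifted Beta(2,2) priors.

    Finite on the open support (−0.5, 0.5)ⁿ; −inf at the boundary where the
    prior density vanishes.
    """
    bs = np.asarray(bs, dtype=float)
    x = bs + 0.5
    if np.any(x <= 0) or np.any(x >= 1):
        return -math.inf
    lp = float(np.sum(np.log(x) + np.log(1.0 - x)))  # Beta(2,2) up to constants
    p = np.clip(0.5 + bs[pairs.pair_j] - bs[pairs.pair_k], P_CLAMP, 1 - P_CLAMP)
    lp += float(np.sum(pairs.wins * np.log(p) + (pairs.tot - pairs.wins) * np.log1p(-p)))
    return lp


@dataclass
class PosteriorSamples:
    """Retained MCMC draws of the accession scores.

    ``draws`` has shape (chains, n_samples, n_accessions); every draw lies in
    [−0.5, 0.5] and ``n_samples = (total_steps − burn_in) // thinning``.
    """

    accessions: list[str]
    draws: np.ndarray
    acceptance_rate: np.ndarray  # (chains, n_accessions)
    seed: int
    total_steps: int
    burn_in: int
    thinning: int
    tuned_proposal_sd: np.ndarray = field(default=None)

    @property
    def pooled(self) -> np.ndarray:
        """Draws pooled over chains, shape (chains·n_samples, n_accessions)."""
        return self.draws.reshape(-1, self.draws.shape[-1])


def _csr_pairs(pairs: PairStats) -> tuple[np.ndarray, np.ndarray]:
    lists: list[list[int]] = [[] for _ in range(pairs.n_accessions)]
    for p in range(len(pairs.pair_j)):
        lists[pairs.pair_j[p]].append(p)
        lists[pairs.pair_k[p]].append(p)
    ptr = np.zeros(pairs.n_accessions + 1, dtype=np.int64)
    flat: list[int] = []
    for a, lst in enumerate(lists):
        flat.extend(lst)
        ptr[a + 1] = len(flat)
    return ptr, np.asarray(flat, dtype=np.int64)


def run_mcmc(
    pairs: PairStats,
    total_steps: int = 100_000,
    burn_in: int = 10_000,
    thinning: int = 10,
    proposal_sd: float = 0.1,
    chains: int = 4,
    seed: int = 0,
    adapt: bool = True,
) -> PosteriorSamples:
    """Sample the BS posterior by component-wise random-walk Metropolis.

    One step is a sweep of single-score proposals; proposals outside
    [−0.5, 0.5] are rejected by the vanishing prior.  At the reference
    settings (100,000 steps, burn-in 10,000, thinning 10) each chain retains
    9,000 draws.  Deterministic given ``seed``; chains use sub-seeds derived
    from it.  A prior-only run (no informative trials) is allowed and can be
    used to check the sampler against the shifted-Beta(2,2) marginals.
    """
    if proposal_sd <= 0:
        raise ValueError("proposal_sd must be positive")
    if not 0 <= burn_in < total_steps:
        raise ValueError("need 0 <= burn_in < total_steps")
    ptr, flat = _csr_pairs(pairs)
    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(chains)]
    all_draws, rates, sds = [], [], []
    for cseed in chain_seeds:
        draws, rate, sd = run_chain(
            pairs.n_accessions,
            pairs.pair_j,
            pairs.pair_k,
            pairs.wins,
            pairs.tot,
            ptr,
            flat,
            total_steps,
            burn_in,
            thinning,
            proposal_sd,
            cseed,
            adapt,
        )
        all_draws.append(draws)
        rates.append(rate)
        sds.append(sd)
    return PosteriorSamples(
        accessions=pairs.accessions,
        draws=np.stack(all_draws),
        acceptance_rate=np.stack(rates),
        seed=seed,
        total_steps=total_steps,
        burn_in=burn_in,
        thinning=thinning,
        tuned_proposal_sd=np.stack(sds),
    )


def split_rhat(chain_draws: np.ndarray) -> float:
    """Split-R̂ convergence diagnostic for one parameter, draws (chains, n)."""
    import arviz as az

    return float(az.rhat(np.asarray(chain_draws, dtype=float)))


def posterior_summary(samples: PosteriorSamples, ci: float = 0.95) -> pd.DataFrame:
    """Median, central credible interval and split-R̂ per accession.

    With a single chain R̂ is omitted (NaN) with a warning; the
    ``rhat_warning`` column flags any R̂ > 1.1.
    """
    alpha = (1.0 - ci) / 2.0
    pooled = samples.pooled
    rows = []
    single_chain = samples.draws.shape[0] < 2
    if single_chain:
        logger.warning("posterior_summary: single chain, R-hat omitted")
    for i, acc in enumerate(samples.accessions):
        rhat = float("nan") if single_chain else split_rhat(samples.draws[:, :, i])
        rows.append(
            {
                "accession_id": acc,
                "bs_median": float(np.median(pooled[:, i])),
                "bs_mean": float(np.mean(pooled[:, i])),
                f"ci_{100*alpha:g}": float(np.quantile(pooled[:, i], alpha)),
                f"ci_{100*(1-alpha):g}": float(np.quantile(pooled[:, i], 1 - alpha)),
                "rhat": rhat,
                "acceptance_rate": float(samples.acceptance_rate[:, i].mean()),
            }
        )
    out = pd.DataFrame(rows)
    out["rhat_warning"] = out["rhat"] > 1.1
    return out


# ---------------------------------------------------------------------------
# brute-force grid oracle (≤ 3 accessions)
# ---------------------------------------------------------------------------

def grid_oracle_posterior(pairs: PairStats, grid_resolution: int = 201) -> pd.DataFrame:
    """Posterior moments by brute-force summation on a dense grid.

    Independent of the MCMC code path: evaluates the same unnormalized
    posterior on a regular grid of cell midpoints over [−0.5, 0.5] per
    dimension and sums.  Only feasible for ≤ 3 accessions; larger problems
    must use :func:`run_mcmc`.
    """
    n = pairs.n_accessions
    if n > 3:
        raise ValueError(f"grid oracle supports <= 3 accessions, got {n}; use run_mcmc")
    edges = np.linspace(-0.5, 0.5, grid_resolution + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    grids = np.meshgrid(*([centers] * n), indexing="ij")
    flat = np.stack([g.ravel() for g in grids], axis=1)
    x = flat + 0.5
    logpost = np.sum(np.log(x) + np.log(1.0 - x), axis=1)
    for pj, pk, w, t in zip(pairs.pair_j, pairs.pair_k, pairs.wins, pairs.tot):
        p = np.clip(0.5 + flat[:, pj] - flat[:, pk], P_CLAMP, 1 - P_CLAMP)
        logpost += w * np.log(p) + (t - w) * np.log1p(-p)
    logpost -= logpost.max()
    weight = np.exp(logpost)
    weight /= weight.sum()
    rows = []
    for i, acc in enumerate(pairs.accessions):
        marg = np.zeros(len(centers))
        np.add.at(marg, np.searchsorted(centers, flat[:, i]), weight)
        cum = np.cumsum(marg)
        median = float(centers[np.searchsorted(cum, 0.5)])
        mean = float(np.dot(flat[:, i], weight))
        var = float(np.dot((flat[:, i] - mean) ** 2, weight))
        rows.append(
            {"accession_id": acc, "bs_mean": mean, "bs_median": median, "bs_var": var}
        )
    return pd.DataFrame(rows)
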