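"""Synthetic wheat–locust experiment generator with known ground truth.

Emulates the structure of the study design this package analyses:

* 10 ancestral (wild emmer, ``A1..A10``) and 10 modern (durum, ``M1..M10``)
  wheat accessions, with five herbivory-related leaf traits drawn
  multivariate-normally around subspecies means (the domestication shift is
  concentrated on leaf nitrogen content and toughness);
* six leaf replicates per accession from control cages;
* 100 bipartite wild × modern paired-choice trials (all pairs once), whose
  binary outcome follows ``P(choose wild) = 0.5 + BS_wild − BS_modern`` for
  latent per-accession scores BS ∈ [−0.5, 0.5];
* a 5-level ordinal feeding-damage score for 12 herbivory cages × 20 plants,
  generated from a cumulative-logit model with a subspecies fixed effect and
  accession random intercepts.

Every stage is deterministic given the master seed; per-component generator
streams are derived from fixed spawn keys so stages can be re-run
independently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# fixed spawn keys: one independent stream per simulation component
_STREAMS = {"accessions": 0, "bs": 1, "trials": 2, "disks": 3, "damage": 4, "raw": 5}

#: single 6 mm leaf disk area (cm²)
DISK_DIAMETER_MM = 6.0


def _disk_area_cm2(diameter_mm: float) -> float:
    r_cm = diameter_mm / 20.0
    return math.pi * r_cm * r_cm


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic experiment.

    Trait means/covariance are in the analysis-trait order
    ``[lt_um, sws, lnc_pct, lprc_pct, lchc_pct]`` (thickness μm, toughness
    J m⁻¹ mm⁻¹, then % of dry mass).  Defaults encode the study conditions:
    equal thickness between subspecies, higher toughness and nitrogen in the
    modern subspecies, protein-biased macronutrient ratios around 3, and a
    feeding preference for the ancestral subspecies (positive ancestral /
    negative modern mean BS, damage fixed effect pushing modern plants toward
    lower damage levels).
    """

    n_ancestral: int = 10
    n_modern: int = 10
    trait_means_ancestral: tuple[float, ...] = (220.0, 1.1, 3.9, 15.5, 5.0)
    trait_means_modern: tuple[float, ...] = (220.0, 1.5, 4.9, 17.5, 5.0)
    trait_covariance: np.ndarray = field(
        default_factory=lambda: _default_trait_covariance()
    )
    accession_scale: float = 0.7  # accession offsets ~ MVN(0, scale² Σ)
    replicates_per_accession: int = 6
    # feeding-selectivity ground truth
    bs_subspecies_shift: float = 0.07  # +shift ancestral, −shift modern
    bs_accession_sd: float = 0.08
    trials_per_pair: int = 1
    fs_concentration: float = 2.0  # Beta(c, c) spread of FS within the chosen half
    disk_noise_sd: float = 0.02  # multiplicative measurement noise on areas
    # ordinal damage ground truth
    damage_cutpoints: tuple[float, ...] = (-2.0, -0.5, 0.5, 2.0)
    damage_subspecies_effect: float = -1.5  # log-odds shift for modern plants
    damage_accession_sd: float = 0.3
    herbivory_cages_per_subspecies: int = 6
    plants_per_accession_per_cage: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.trait_covariance, dtype=float)
        if cov.shape != (5, 5) or not np.allclose(cov, cov.T):
            raise ValueError(f"trait covariance must be a symmetric 5x5 matrix, got\n{cov}")
        eigs = np.linalg.eigvalsh(cov)
        if eigs.min() < -1e-10:
            raise ValueError(
                f"trait covariance is not positive semi-definite "
                f"(min eigenvalue {eigs.min():.3g}):\n{cov}"
            )
        self.trait_covariance = cov
        cuts = np.asarray(self.damage_cutpoints, dtype=float)
        if np.any(np.diff(cuts) <= 0):
            raise ValueError(f"damage cutpoints must be strictly increasing, got {cuts}")
        if abs(self.bs_subspecies_shift) > 0.5:
            raise ValueError("bs subspecies shift must lie in [-0.5, 0.5]")

    # -- helpers -----------------------------------------------------------
    @property
    def ancestral_ids(self) -> list[str]:
        return [f"A{i+1}" for i in range(self.n_ancestral)]

    @property
    def modern_ids(self) -> list[str]:
        return [f"M{i+1}" for i in range(self.n_modern)]

    @property
    def accession_ids(self) -> list[str]:
        return self.ancestral_ids + self.modern_ids

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component stream derived from the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[component],))
        )


def _default_trait_covariance() -> np.ndarray:
    sd = np.array([15.0, 0.18, 0.35, 2.0, 1.2])
    corr = np.eye(5)
    corr[2, 3] = corr[3, 2] = 0.5  # LNC–LPrC
    corr[3, 4] = corr[4, 3] = -0.2  # LPrC–LChC
    corr[0, 1] = corr[1, 0] = 0.2  # thicker leaves slightly tougher
    return corr * np.outer(sd, sd)


# ---------------------------------------------------------------------------
# accessions and traits
# ---------------------------------------------------------------------------

def simulate_accessions(config: SimulationConfig) -> pd.DataFrame:
    """Replicate-level draws of the five traits for every accession.

    Each accession gets a single multivariate-normal offset (covariance
    ``accession_scale² · Σ``) around its subspecies mean; replicates add
    independent MVN(0, Σ) noise, so replicates within an accession are
    correlated.  Returns columns ``accession_id, subspecies, replicate`` plus
    ``lt_um, sws, lnc_pct, lprc_pct, lchc_pct`` (clipped below at a small
    positive floor — leaf traits are physical quantities).
    """
    rng = config.rng("accessions")
    cov = config.trait_covariance
    acc_cov = (config.accession_scale ** 2) * cov
    rows = []
    for subspecies, ids, mean in (
        ("ancestral", config.ancestral_ids, config.trait_means_ancestral),
        ("modern", config.modern_ids, config.trait_means_modern),
    ):
        mean = np.asarray(mean, dtype=float)
        for acc in ids:
            offset = rng.multivariate_normal(np.zeros(5), acc_cov, method="svd")
            reps = rng.multivariate_normal(
                mean + offset, cov, size=config.replicates_per_accession, method="svd"
            )
            for r in range(config.replicates_per_accession):
                rows.append((acc, subspecies, r + 1, *reps[r]))
    df = pd.DataFrame(
        rows,
        columns=["accession_id", "subspecies", "replicate",
                 "lt_um", "sws", "lnc_pct", "lprc_pct", "lchc_pct"],
    )
    floor = {"lt_um": 10.0, "sws": 0.01, "lnc_pct": 0.1, "lprc_pct": 0.1, "lchc_pct": 0.1}
    for col, lo in floor.items():
        df[col] = df[col].clip(lower=lo)
    return df


def accession_trait_means(replicates: pd.DataFrame) -> pd.DataFrame:
    """Accession-level means of the simulated replicate traits."""
    value_cols = ["lt_um", "sws", "lnc_pct", "lprc_pct", "lchc_pct"]
    return (
        replicates.groupby(["accession_id", "subspecies"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )


def raw_trait_tables(
    config: SimulationConfig, replicates: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Back-derive raw measurement tables consistent with the planted traits.

    Returns ``(leaf_samples, shear_traces, nutrients)`` in the CSV dialects
    the analysis reads.  Leaf area and SLA are drawn around nominal values;
    dry and fresh masses are then solved from SLA and LDMC = 10⁴/(SLA·LT) so
    the traits pipeline recovers the planted replicate values exactly.  Shear
    traces are constant-force cuts whose force reproduces the planted SWS at
    the replicate's thickness.
    """
    rng = config.rng("raw")
    leaf_rows, shear_rows, nutrient_rows = [], [], []
    # the analysis standardizes shear work by the accession-mean thickness, so
    # invert the SWS formula with that same thickness for an exact round trip
    lt_mean = replicates.groupby("accession_id")["lt_um"].mean()
    for row in replicates.itertuples(index=False):
        sla = float(rng.normal(220.0, 10.0))
        sla = max(sla, 50.0)
        ldmc = 1e4 / (sla * row.lt_um / 1000.0)  # mg g⁻¹ consistent with LT
        area = float(rng.normal(20.0, 2.0))
        area = max(area, 5.0)
        dry = area / sla
        fresh = 1000.0 * dry / ldmc
        leaf_rows.append(
            (row.accession_id, row.subspecies, row.replicate, area, dry, fresh)
        )
        # constant force F gives work-to-shear = F·tan(angle); invert for sws
        wts = row.sws * (lt_mean[row.accession_id] / 1000.0)
        force = wts / math.tan(math.radians(30.0))
        for i, z in enumerate(np.linspace(0.0, 0.01, 5)):
            shear_rows.append((row.accession_id, row.replicate, z, force))
    acc = accession_trait_means(replicates)
    for r in acc.itertuples(index=False):
        nutrient_rows.append((r.accession_id, r.lnc_pct, r.lprc_pct, r.lchc_pct))
    leaf = pd.DataFrame(
        leaf_rows,
        columns=["accession_id", "subspecies", "replicate",
                 "leaf_area_cm2", "dry_mass_g", "fresh_mass_g"],
    )
    shear = pd.DataFrame(
        shear_rows, columns=["accession_id", "replicate", "displacement_m", "force_N"]
    )
    nutrients = pd.DataFrame(
        nutrient_rows, columns=["accession_id", "lnc_pct", "lprc_pct", "lchc_pct"]
    )
    return leaf, shear, nutrients


# ---------------------------------------------------------------------------
# feeding-selectivity ground truth and choice trials
# ---------------------------------------------------------------------------

def draw_bs_true(config: SimulationConfig) -> dict[str, float]:
    """Ground-truth Bayesian scores: subspecies shift ± accession scatter.

    Ancestral accessions centre at ``+bs_subspecies_shift``, modern at the
    negative; accession-level normal scatter is truncated to [−0.45, 0.45] so
    every pairwise choice probability stays inside (0, 1).
    """
    rng = config.rng("bs")
    bs = {}
    for acc in config.ancestral_ids:
        bs[acc] = float(np.clip(
            rng.normal(config.bs_subspecies_shift, config.bs_accession_sd), -0.45, 0.45))
    for acc in config.modern_ids:
        bs[acc] = float(np.clip(
            rng.normal(-config.bs_subspecies_shift, config.bs_accession_sd), -0.45, 0.45))
    return bs


def simulate_choice_trials(
    config: SimulationConfig, bs_true: dict[str, float] | None = None
) -> pd.DataFrame:
    """Paired-choice trials for every wild × modern accession pair.

    Each of the ``n_ancestral × n_modern`` pairs is tested
    ``trials_per_pair`` times.  The binary outcome ``wild_chosen`` is
    Bernoulli with ``P = clamp(0.5 + BS_wild − BS_modern, 1e−6, 1−1e−6)``;
    the continuous feeding-selectivity proportion ``fs_wild`` is drawn from a
    Beta(c, c) rescaled to (0.5, 1] when wild is chosen and (0, 0.5]
    otherwise, so that ``fs_wild > 0.5 ⇔ wild_chosen`` and
    ``fs_wild + fs_modern = 1``.
    """
    if bs_true is None:
        bs_true = draw_bs_true(config)
    for acc in config.accession_ids:
        if acc not in bs_true:
            raise KeyError(f"accession {acc!r} has no ground-truth BS value")
        if not -0.5 <= bs_true[acc] <= 0.5:
            raise ValueError(f"bs_true[{acc!r}] = {bs_true[acc]} outside [-0.5, 0.5]")
    rng = config.rng("trials")
    c = config.fs_concentration
    rows = []
    trial = 0
    for wild in config.ancestral_ids:
        for modern in config.modern_ids:
            p = float(np.clip(0.5 + bs_true[wild] - bs_true[modern], 1e-6, 1 - 1e-6))
            for _ in range(config.trials_per_pair):
                trial += 1
                chosen = int(rng.random() < p)
                b = rng.beta(c, c)
                fs_wild = 0.5 + 0.5 * b if chosen else 0.5 - 0.5 * b
                rows.append((trial, wild, modern, p, chosen, fs_wild, 1.0 - fs_wild))
    return pd.DataFrame(
        rows,
        columns=["trial_id", "wild_accession", "modern_accession",
                 "p_wild_true", "wild_chosen", "fs_wild_true", "fs_modern_true"],
    )


def simulate_leaf_disks(
    sla_by_accession: pd.Series,
    consumption_fractions: pd.DataFrame,
    disk_diameter_mm: float = DISK_DIAMETER_MM,
    n_disks: int = 6,
    noise_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Control and uneaten leaf-disk areas for given consumption fractions.

    ``consumption_fractions`` has columns ``trial_id, accession_id, role,
    consumed_fraction`` (role in {wild, modern}).  Control areas are
    ``n_disks`` × single-disk area with multiplicative Gaussian measurement
    noise; uneaten areas are ``control × (1 − fraction)`` with independent
    noise.  With ``noise_sd = 0`` the selectivity pipeline recovers planted
    FS proportions exactly.
    """
    if disk_diameter_mm <= 0:
        raise ValueError("disk diameter must be positive")
    fr = consumption_fractions["consumed_fraction"].to_numpy(dtype=float)
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("consumption fractions must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = n_disks * _disk_area_cm2(disk_diameter_mm)
    out = consumption_fractions.copy()
    n = len(out)
    control = base * (1.0 + noise_sd * rng.standard_normal(n))
    uneaten = control * (1.0 - fr) * (1.0 + noise_sd * rng.standard_normal(n))
    out["control_area_cm2"] = control
    out["uneaten_area_cm2"] = np.clip(uneaten, 0.0, None)
    out["sla_cm2_g"] = out["accession_id"].map(sla_by_accession).to_numpy()
    if out["sla_cm2_g"].isna().any():
        missing = out.loc[out["sla_cm2_g"].isna(), "accession_id"].unique()
        raise KeyError(f"no SLA for accessions {list(missing)}")
    return out


def choice_trials_to_disk_table(
    config: SimulationConfig,
    trials: pd.DataFrame,
    sla_by_accession: pd.Series,
) -> pd.DataFrame:
    """Wide per-trial disk-area table (the choice_trials.csv dialect).

    Chooses a total consumed dry biomass per trial (uniform fraction of the
    offered disks) and splits it by the planted FS proportions, then converts
    to per-side consumed areas and noisy control/uneaten areas.
    """
    rng = config.rng("disks")
    base = 6 * _disk_area_cm2(DISK_DIAMETER_MM)
    long_rows = []
    for t in trials.itertuples(index=False):
        sla_w = float(sla_by_accession[t.wild_accession])
        sla_m = float(sla_by_accession[t.modern_accession])
        offered_mass = base / sla_w + base / sla_m
        total = float(rng.uniform(0.25, 0.45)) * offered_mass
        mass_w = t.fs_wild_true * total
        mass_m = (1.0 - t.fs_wild_true) * total
        frac_w = min(mass_w * sla_w / base, 0.95)
        frac_m = min(mass_m * sla_m / base, 0.95)
        long_rows.append((t.trial_id, t.wild_accession, "wild", frac_w))
        long_rows.append((t.trial_id, t.modern_accession, "modern", frac_m))
    fractions = pd.DataFrame(
        long_rows, columns=["trial_id", "accession_id", "role", "consumed_fraction"]
    )
    disks = simulate_leaf_disks(
        sla_by_accession, fractions, noise_sd=config.disk_noise_sd, seed=rng
    )
    wide = disks.pivot(index="trial_id", columns="role")
    out = pd.DataFrame(
        {
            "trial_id": wide.index,
            "wild_accession": wide[("accession_id", "wild")].to_numpy(),
            "modern_accession": wide[("accession_id", "modern")].to_numpy(),
            "control_area_wild_cm2": wide[("control_area_cm2", "wild")].to_numpy(),
            "uneaten_area_wild_cm2": wide[("uneaten_area_cm2", "wild")].to_numpy(),
            "control_area_modern_cm2": wide[("control_area_cm2", "modern")].to_numpy(),
            "uneaten_area_modern_cm2": wide[("uneaten_area_cm2", "modern")].to_numpy(),
            "sla_wild_cm2_g": wide[("sla_cm2_g", "wild")].to_numpy(),
            "sla_modern_cm2_g": wide[("sla_cm2_g", "modern")].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# ordinal feeding damage
# ---------------------------------------------------------------------------

def cumulative_logit_probabilities(
    cutpoints: np.ndarray, eta: float | np.ndarray
) -> np.ndarray:
    """Category probabilities P(Y = c) under P(Y ≤ c) = logistic(θ_c − η)."""
    cuts = np.asarray(cutpoints, dtype=float)
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    cum = 1.0 / (1.0 + np.exp(-(cuts[None, :] - eta[:, None])))
    cum = np.concatenate([cum, np.ones((eta.size, 1))], axis=1)
    probs = np.diff(np.concatenate([np.zeros((eta.size, 1)), cum], axis=1), axis=1)
    return probs.squeeze()


def simulate_damage(
    config: SimulationConfig, accession_effects: dict[str, float] | None = None
) -> pd.DataFrame:
    """Per-plant ordinal feeding-damage scores for the herbivory cages.

    Each subspecies gets ``herbivory_cages_per_subspecies`` single-subspecies
    cages holding ``plants_per_accession_per_cage`` plants of each of its
    accessions (the field layout: 12 cages × 20 plants at the defaults).
    Damage level ~ cumulative-logit(cutpoints; η = β·modern + u_accession)
    with accession intercepts u ~ N(0, damage_accession_sd²) drawn once.
    """
    rng = config.rng("damage")
    cuts = np.asarray(config.damage_cutpoints, dtype=float)
    probs_at_zero = cumulative_logit_probabilities(cuts, 0.0)
    if np.max(probs_at_zero) > 0.999:
        warnings.warn(
            "damage cutpoints concentrate virtually all mass on one level",
            stacklevel=2,
        )
    if accession_effects is None:
        accession_effects = {
            acc: float(rng.normal(0.0, config.damage_accession_sd))
            for acc in config.accession_ids
        }
    rows = []
    cage = 0
    for subspecies, ids in (
        ("ancestral", config.ancestral_ids),
        ("modern", config.modern_ids),
    ):
        beta = config.damage_subspecies_effect if subspecies == "modern" else 0.0
        for _ in range(config.herbivory_cages_per_subspecies):
            cage += 1
            for acc in ids:
                eta = beta + accession_effects[acc]
                probs = cumulative_logit_probabilities(cuts, eta)
                for plant in range(config.plants_per_accession_per_cage):
                    level = int(rng.choice(len(probs), p=probs))
                    rows.append((f"H{cage}", subspecies, acc, plant + 1, level))
    return pd.DataFrame(
        rows, columns=["cage_id", "subspecies", "accession_id", "plant_id", "fd_level"]
    )


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> dict[str, pd.DataFrame | dict]:
    """Generate every table of a synthetic experiment plus its ground truth."""
    replicates = simulate_accessions(config)
    leaf, shear, nutrients = raw_trait_tables(config, replicates)
    bs_true = draw_bs_true(config)
    trials = simulate_choice_trials(config, bs_true)
    # SLA consistent with the raw leaf samples (accession means)
    from .traits import replicate_trait_table

    sla = (
        replicate_trait_table(leaf).groupby("accession_id")["sla_cm2_g"].mean()
    )
    choice = choice_trials_to_disk_table(config, trials, sla)
    damage = simulate_damage(config)
    return {
        "leaf_samples": leaf,
        "shear_traces": shear,
        "nutrients": nutrients,
        "choice_trials": choice,
        "damage": damage,
        "trait_replicates_true": replicates,
        "choice_trials_true": trials,
        "bs_true": bs_true,
    }
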