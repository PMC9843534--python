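"""Herbivory-related leaf traits from raw morphology, mechanics and chemistry.

Five traits enter the downstream analyses, per wheat accession:

* ``lt_um`` — leaf thickness (μm), estimated indirectly as ``(SLA × LDMC)⁻¹``
  following the Vile et al. allometry, with SLA in cm² g⁻¹ and LDMC converted
  to g g⁻¹ (so ``LT[μm] = 10⁴ / (SLA × LDMC[mg g⁻¹] / 1000)``).
* ``sws`` — specific work to shear, a leaf-toughness proxy: the work done by a
  cutting blade per unit horizontal cut length, standardized by leaf
  thickness.  Work-to-shear itself is in J m⁻¹; the thickness-standardized
  trait divides by thickness in mm and is therefore reported as J m⁻¹ mm⁻¹
  (column ``sws_J_per_m_mm``), alongside the raw work-to-shear.
* ``lnc_pct`` — leaf nitrogen content, % of dry mass (spectroscopy output).
* ``lprc_pct`` / ``lchc_pct`` — soluble protein and digestible carbohydrate
  contents, % of dry mass (enzymatic assay outputs), plus their sum
  (``macronutrient_sum``) and ratio (``macronutrient_ratio``).

Raw assay chemistry and spectral calibration are out of scope: nutrient
contents enter this module as numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Names of the five analysis traits, in canonical order.
TRAIT_COLUMNS = ["lt_um", "sws", "lnc_pct", "macronutrient_sum", "macronutrient_ratio"]


# ---------------------------------------------------------------------------
# scalar trait formulas
# ---------------------------------------------------------------------------

def compute_sla(leaf_area_cm2: float, dry_mass_g: float) -> float:
    """Specific leaf area (cm² g⁻¹): leaf area over oven-dry mass."""
    if dry_mass_g <= 0:
        raise ValueError(f"dry mass must be positive, got {dry_mass_g}")
    if leaf_area_cm2 < 0:
        raise ValueError(f"leaf area must be nonnegative, got {leaf_area_cm2}")
    return leaf_area_cm2 / dry_mass_g


def compute_ldmc(dry_mass_g: float, fresh_saturated_mass_g: float) -> float:
    """Leaf dry matter content (mg g⁻¹): dry mass (mg) over water-saturated fresh mass (g)."""
    if fresh_saturated_mass_g <= 0:
        raise ValueError(f"fresh mass must be positive, got {fresh_saturated_mass_g}")
    if dry_mass_g < 0:
        raise ValueError(f"dry mass must be nonnegative, got {dry_mass_g}")
    if dry_mass_g > fresh_saturated_mass_g:
        raise ValueError(
            f"dry mass {dry_mass_g} g exceeds water-saturated fresh mass "
            f"{fresh_saturated_mass_g} g"
        )
    return 1000.0 * dry_mass_g / fresh_saturated_mass_g


def compute_leaf_thickness(sla_cm2_g: float, ldmc_mg_g: float) -> float:
    """Indirect leaf thickness (μm) as ``(SLA × LDMC)⁻¹``.

    With SLA in cm² g⁻¹ and LDMC converted to g g⁻¹ the reciprocal product is
    a length in cm; multiplied by 10⁴ to express μm.  The exact identity
    ``LT · SLA · LDMC = 10⁴`` (in these units) holds for every row.
    """
    if sla_cm2_g <= 0 or ldmc_mg_g <= 0:
        raise ValueError("SLA and LDMC must be positive to estimate thickness")
    return 1e4 / (sla_cm2_g * (ldmc_mg_g / 1000.0))


@dataclass(frozen=True)
class ShearResult:
    """Breakdown of a force–displacement shear trace into toughness quantities."""

    work_J: float
    cut_length_m: float
    work_to_shear_J_per_m: float
    sws_J_per_m_mm: float


def compute_sws(
    displacement_m: np.ndarray,
    force_N: np.ndarray,
    blade_angle_deg: float = 30.0,
    leaf_thickness_um: float | None = None,
) -> ShearResult:
    """Work to shear from a cutting-test trace, standardized by leaf thickness.

    The blade moves vertically; the work is the trapezoidal integral of force
    over vertical displacement.  The horizontal cut length is recovered from
    the vertical travel and the blade angle (measured from the horizontal):
    ``L = Δz / tan(angle)``.  Work-to-shear = W / L (J m⁻¹); the
    thickness-standardized trait divides by thickness in mm.

    Parameters
    ----------
    displacement_m
        Strictly increasing vertical blade positions (m).
    force_N
        Force samples (N) aligned with ``displacement_m``.
    blade_angle_deg
        Blade angle from the horizontal, 0 < angle < 90 (default 30°).
    leaf_thickness_um
        Leaf thickness (μm) for standardization; if None the standardized
        value is NaN and only work-to-shear is meaningful.
    """
    z = np.asarray(displacement_m, dtype=float)
    f = np.asarray(force_N, dtype=float)
    if z.ndim != 1 or z.shape != f.shape or z.size < 2:
        raise ValueError("displacement and force must be 1-D arrays of equal length >= 2")
    if np.any(np.diff(z) <= 0):
        raise ValueError("vertical displacement must be strictly increasing")
    if not 0.0 < blade_angle_deg < 90.0:
        raise ValueError(f"blade angle must be in (0, 90) degrees, got {blade_angle_deg}")
    work = float(np.trapezoid(f, z))
    vertical_travel = float(z[-1] - z[0])
    cut_length = vertical_travel / math.tan(math.radians(blade_angle_deg))
    if cut_length <= 0:
        raise ValueError("zero horizontal cut length")
    wts = work / cut_length
    if leaf_thickness_um is None:
        sws = float("nan")
    else:
        if leaf_thickness_um <= 0:
            raise ValueError("leaf thickness must be positive")
        sws = wts / (leaf_thickness_um / 1000.0)
    return ShearResult(work, cut_length, wts, sws)


# ---------------------------------------------------------------------------
# table-level derivations
# ---------------------------------------------------------------------------

def replicate_trait_table(leaf_samples: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate SLA, LDMC and LT from a leaf-sample table.

    Expects columns ``accession_id, subspecies, replicate, leaf_area_cm2,
    dry_mass_g, fresh_mass_g``; returns the same keys plus ``sla_cm2_g,
    ldmc_mg_g, lt_um``.
    """
    out = leaf_samples.copy()
    out["sla_cm2_g"] = [
        compute_sla(a, d) for a, d in zip(out["leaf_area_cm2"], out["dry_mass_g"])
    ]
    out["ldmc_mg_g"] = [
        compute_ldmc(d, f) for d, f in zip(out["dry_mass_g"], out["fresh_mass_g"])
    ]
    out["lt_um"] = [
        compute_leaf_thickness(s, l) for s, l in zip(out["sla_cm2_g"], out["ldmc_mg_g"])
    ]
    return out


def sws_per_replicate(
    shear_traces: pd.DataFrame,
    thickness_um_by_accession: pd.Series,
    blade_angle_deg: float = 30.0,
) -> pd.DataFrame:
    """Work-to-shear and SWS per (accession, replicate) from long-format traces."""
    rows = []
    for (acc, rep), grp in shear_traces.groupby(["accession_id", "replicate"], sort=True):
        grp = grp.sort_values("displacement_m")
        if acc not in thickness_um_by_accession.index:
            raise KeyError(f"no leaf thickness available for accession {acc!r}")
        res = compute_sws(
            grp["displacement_m"].to_numpy(),
            grp["force_N"].to_numpy(),
            blade_angle_deg=blade_angle_deg,
            leaf_thickness_um=float(thickness_um_by_accession.loc[acc]),
        )
        rows.append(
            {
                "accession_id": acc,
                "replicate": rep,
                "work_J": res.work_J,
                "work_to_shear_J_per_m": res.work_to_shear_J_per_m,
                "sws_J_per_m_mm": res.sws_J_per_m_mm,
            }
        )
    return pd.DataFrame(rows)


def aggregate_traits(replicates: pd.DataFrame, value_columns: list[str]) -> pd.DataFrame:
    """Accession-level arithmetic means of replicate trait values.

    Missing replicates are NaN-skipped; the number skipped is logged.
    """
    n_missing = int(replicates[value_columns].isna().sum().sum())
    if n_missing:
        logger.info("aggregate_traits: skipped %d missing replicate values", n_missing)
    keys = ["accession_id"] + (
        ["subspecies"] if "subspecies" in replicates.columns else []
    )
    return replicates.groupby(keys, sort=True)[value_columns].mean().reset_index()


def build_trait_table(
    leaf_samples: pd.DataFrame,
    shear_traces: pd.DataFrame,
    nutrients: pd.DataFrame,
    blade_angle_deg: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-accession analysis trait table.

    Returns ``(accession_table, replicate_table)``.  The accession table has
    one row per accession with the five analysis traits (``TRAIT_COLUMNS``,
    where ``sws`` is the thickness-standardized work to shear) plus SLA, LDMC
    and the raw nutrient contents.
    """
    reps = replicate_trait_table(leaf_samples)
    morph = aggregate_traits(reps, ["sla_cm2_g", "ldmc_mg_g", "lt_um"])
    thick = morph.set_index("accession_id")["lt_um"]
    shear = sws_per_replicate(shear_traces, thick, blade_angle_deg=blade_angle_deg)
    shear_acc = aggregate_traits(shear, ["work_to_shear_J_per_m", "sws_J_per_m_mm"])
    table = morph.merge(shear_acc, on="accession_id", how="left")
    table = table.merge(nutrients, on="accession_id", how="left")
    table["sws"] = table["sws_J_per_m_mm"]
    table["macronutrient_sum"] = table["lprc_pct"] + table["lchc_pct"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = table["lprc_pct"] / table["lchc_pct"]
    ratio[table["lchc_pct"] <= 0] = np.nan
    table["macronutrient_ratio"] = ratio
    n_undef = int(table["macronutrient_ratio"].isna().sum())
    if n_undef:
        logger.warning("build_trait_table: %d accessions with undefined P:C ratio", n_undef)
    return table, reps


# ---------------------------------------------------------------------------
# nutrient-balance comparisons
# ---------------------------------------------------------------------------

def nutrient_balance(
    table: pd.DataFrame, intake_ratio_targets: tuple[float, ...] = (1.0, 0.7)
) -> pd.DataFrame:
    """Protein:carbohydrate balance of each accession against herbivore intake targets.

    The migratory locust nymph performs best near a protein:carbohydrate
    intake ratio of roughly 0.7–1.0; an accession whose leaf LPrC:LChC ratio
    exceeds a target is flagged ``protein_biased_at_<target>``.  Accessions
    with zero carbohydrate content have an undefined ratio and are excluded
    from the summary mean.
    """
    out = table[["accession_id", "lprc_pct", "lchc_pct"]].copy()
    out["macronutrient_sum"] = out["lprc_pct"] + out["lchc_pct"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["macronutrient_ratio"] = np.where(
            out["lchc_pct"] > 0, out["lprc_pct"] / out["lchc_pct"], np.nan
        )
    for target in intake_ratio_targets:
        out[f"protein_biased_at_{target:g}"] = out["macronutrient_ratio"] > target
    return out


def nutrient_balance_summary(balance: pd.DataFrame) -> dict:
    """Mean / min / max of defined P:C ratios, with the undefined count."""
    ratios = balance["macronutrient_ratio"].dropna()
    return {
        "ratio_mean": float(ratios.mean()),
        "ratio_min": float(ratios.min()),
        "ratio_max": float(ratios.max()),
        "n_defined": int(ratios.size),
        "n_undefined": int(balance["macronutrient_ratio"].isna().sum()),
    }


def nitrogen_to_protein_factor(table: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Per-accession LPrC/LNC conversion factor, its mean, and corr(LNC, LPrC).

    A low factor (well below the classic 6.25 food-protein convention) means
    much of the leaf nitrogen is not in soluble protein.  Accessions with
    nonpositive LNC are excluded with a warning.
    """
    ok = table["lnc_pct"] > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("nitrogen_to_protein_factor: excluded %d accessions with LNC <= 0", n_bad)
    sub = table[ok]
    factor = (sub["lprc_pct"] / sub["lnc_pct"]).rename("n_to_protein_factor")
    factor.index = sub["accession_id"].to_numpy()
    if len(sub) >= 2 and sub["lnc_pct"].std() > 0 and sub["lprc_pct"].std() > 0:
        corr = float(np.corrcoef(sub["lnc_pct"], sub["lprc_pct"])[0, 1])
    else:
        corr = float("nan")
    return factor, float(factor.mean()), corr
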