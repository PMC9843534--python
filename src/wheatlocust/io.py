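"""Readers, writers, run configuration and the end-to-end pipeline.

All tables are plain UTF-8 CSV with a mandatory header and dot decimal
separator; units are encoded in column names (``leaf_area_cm2`` etc.).  Each
named schema lists required columns with dtypes and row validators; unknown
columns are preserved but ignored.  A pipeline run writes a machine-readable
``manifest.json`` recording the seed, settings, package version, per-stage
row counts and SHA-256 hashes of the inputs each output was computed from.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import damage as damage_mod
from . import multivariate as mv
from . import selectivity as sel
from . import synthetic_data as synth
from . import traits as traits_mod

logger = logging.getLogger(__name__)

SCHEMAS: dict[str, dict] = {
    "leaf_samples": {
        "columns": {
            "accession_id": str, "subspecies": str, "replicate": int,
            "leaf_area_cm2": float, "dry_mass_g": float, "fresh_mass_g": float,
        },
    },
    "shear_traces": {
        "columns": {
            "accession_id": str, "replicate": int,
            "displacement_m": float, "force_N": float,
        },
    },
    "nutrients": {
        "columns": {
            "accession_id": str, "lnc_pct": float, "lprc_pct": float, "lchc_pct": float,
        },
    },
    "choice_trials": {
        "columns": {
            "trial_id": int, "wild_accession": str, "modern_accession": str,
            "control_area_wild_cm2": float, "uneaten_area_wild_cm2": float,
            "control_area_modern_cm2": float, "uneaten_area_modern_cm2": float,
            "sla_wild_cm2_g": float, "sla_modern_cm2_g": float,
        },
    },
    "damage": {
        "columns": {
            "cage_id": str, "subspecies": str, "accession_id": str,
            "plant_id": int, "fd_level": int,
        },
        "validators": {"fd_level": lambda v: 0 <= v <= 4},
    },
}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises on missing columns (naming them), unparseable cells (with the row
    number) and validator failures (with the row index); warns on an empty
    table.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; have {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col, dtype in schema["columns"].items():
        if dtype is str:
            df[col] = df[col].astype(str)
            continue
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as err:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            row = int(np.argmax(bad.to_numpy())) if bad.any() else "?"
            raise ValueError(
                f"{path.name}: column {col!r} has an unparseable cell at row {row}"
            ) from err
    for col, check in schema.get("validators", {}).items():
        ok = df[col].map(check)
        if not ok.all():
            bad_rows = list(df.index[~ok][:5])
            raise ValueError(
                f"{path.name}: column {col!r} fails validation at row(s) {bad_rows}"
            )
    if df.empty:
        logger.warning("%s: valid header but no rows", path.name)
    logger.info("read %s: %d rows (%s)", path.name, len(df), schema_name)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunConfig:
    """Settings of an end-to-end pipeline run."""

    input_dir: str | Path
    output_dir: str | Path
    seed: int = 0
    simulate: bool = False  # generate synthetic inputs into input_dir first
    mcmc_total_steps: int = 100_000
    mcmc_burn_in: int = 10_000
    mcmc_thinning: int = 10
    mcmc_chains: int = 4
    mcmc_proposal_sd: float = 0.1
    min_eigenvalue: float = 1.0
    n_permutations: int = 999
    manova_gate_alpha: float = 0.05
    force_lda: bool = False  # run the LDA even when the MANOVA gate fails
    blade_angle_deg: float = 30.0
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self) -> None:
        if Path(self.input_dir).resolve() == Path(self.output_dir).resolve():
            raise ValueError("input and output directories must be distinct")
        if not 0 <= self.mcmc_burn_in < self.mcmc_total_steps:
            raise ValueError("need 0 <= burn_in < total_steps")
        for name in ("mcmc_total_steps", "mcmc_thinning", "mcmc_chains", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def write_synthetic_inputs(config: synth.SimulationConfig, outdir: str | Path) -> dict:
    """Generate a synthetic dataset and write the raw input CSVs."""
    outdir = Path(outdir)
    data = synth.simulate_dataset(config)
    paths = {}
    for name in ("leaf_samples", "shear_traces", "nutrients", "choice_trials", "damage"):
        paths[name] = str(write_table(data[name], outdir / f"{name}.csv"))
    bs = pd.DataFrame(
        {"accession_id": list(data["bs_true"]), "bs_true": list(data["bs_true"].values())}
    )
    paths["bs_true"] = str(write_table(bs, outdir / "bs_true.csv"))
    logger.info("synthetic inputs written to %s", outdir)
    return {"paths": paths, "data": data}


def run_pipeline(config: RunConfig) -> dict:
    """Execute traits → selectivity → damage → multivariate on the input tables.

    Returns a dict of in-memory results; writes every output table plus
    ``manifest.json`` and a plain-text report under ``config.output_dir``.
    Identical config + seed yields identical outputs.
    """
    indir, outdir = Path(config.input_dir), Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        sim_cfg = synth.SimulationConfig(seed=config.seed, **config.simulation)
        write_synthetic_inputs(sim_cfg, indir)

    stage = "read"
    try:
        leaf = read_table(indir / "leaf_samples.csv", "leaf_samples")
        shear = read_table(indir / "shear_traces.csv", "shear_traces")
        nutrients = read_table(indir / "nutrients.csv", "nutrients")
        choice = read_table(indir / "choice_trials.csv", "choice_trials")
        dmg = read_table(indir / "damage.csv", "damage")
        input_hashes = {
            f.name: sha256_file(indir / f.name)
            for f in sorted(indir.glob("*.csv"))
        }

        stage = "traits"
        trait_table, trait_reps = traits_mod.build_trait_table(
            leaf, shear, nutrients, blade_angle_deg=config.blade_angle_deg
        )
        balance = traits_mod.nutrient_balance(trait_table)
        balance_summary = traits_mod.nutrient_balance_summary(balance)
        _, npf_mean, npf_corr = traits_mod.nitrogen_to_protein_factor(trait_table)

        stage = "selectivity"
        fs_table = sel.compute_fs_table(choice)
        ttest = sel.paired_t_test(fs_table.loc[fs_table["informative"], "fs_wild"].to_numpy())
        pairs = sel.pair_statistics(fs_table)
        samples = sel.run_mcmc(
            pairs,
            total_steps=config.mcmc_total_steps,
            burn_in=config.mcmc_burn_in,
            thinning=config.mcmc_thinning,
            proposal_sd=config.mcmc_proposal_sd,
            chains=config.mcmc_chains,
            seed=config.seed,
        )
        bs_summary = sel.posterior_summary(samples)

        stage = "damage"
        dmg_analysis = damage_mod.subspecies_damage_analysis(dmg)
        fd_means = damage_mod.mean_damage_by_accession(dmg)

        stage = "multivariate"
        order = trait_table.sort_values("accession_id").reset_index(drop=True)
        X = order[traits_mod.TRAIT_COLUMNS].to_numpy()
        labels = order["subspecies"].to_numpy()
        acc_ids = order["accession_id"].tolist()
        pca = mv.pca_standardized(X, trait_names=traits_mod.TRAIT_COLUMNS)
        manova = mv.manova_two_group(X, labels)
        lda = None
        if manova.p < config.manova_gate_alpha or config.force_lda:
            lda = mv.lda_two_group(X, labels, traits_mod.TRAIT_COLUMNS, acc_ids)
        else:
            logger.warning(
                "MANOVA p = %.3g >= %.2g: LDA gated off", manova.p, config.manova_gate_alpha
            )
        bs_by_acc = bs_summary.set_index("accession_id")["bs_median"].reindex(acc_ids)
        fd_by_acc = fd_means.set_index("accession_id")["fd_mean"].reindex(acc_ids)
        fits = {}
        regressions = {}
        for name, resp in (("BS", bs_by_acc), ("FD", fd_by_acc)):
            fits[name] = mv.vector_fit(
                resp.to_numpy(), pca, min_eigenvalue=config.min_eigenvalue,
                n_permutations=config.n_permutations, response_name=name,
                seed=config.seed,
            )
            if lda is not None:
                regressions[name] = mv.regress_response_on_df(
                    lda.df_scores.to_numpy(), resp.to_numpy()
                )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # ---- outputs ---------------------------------------------------------
    write_table(trait_table, outdir / "trait_table.csv")
    write_table(trait_reps, outdir / "trait_replicates.csv")
    write_table(fs_table, outdir / "fs_table.csv")
    write_table(bs_summary, outdir / "bs_posterior_summary.csv")
    draws = pd.DataFrame(samples.pooled, columns=samples.accessions)
    write_table(draws, outdir / "bs_draws.csv")
    full = dmg_analysis["full"]
    clmm_rows = [
        {"parameter": f"threshold_{i}", "estimate": t, "se": np.nan}
        for i, t in enumerate(full.thresholds)
    ]
    clmm_rows += [
        {"parameter": "subspecies_modern", "estimate": full.subspecies_effect,
         "se": full.se_subspecies_effect},
        {"parameter": "accession_sd", "estimate": full.accession_sd, "se": np.nan},
        {"parameter": "lrt_statistic", "estimate": dmg_analysis["lrt"].statistic, "se": np.nan},
        {"parameter": "lrt_p", "estimate": dmg_analysis["lrt"].p, "se": np.nan},
        {"parameter": "s_value_bits", "estimate": dmg_analysis["s_value_bits"], "se": np.nan},
    ]
    write_table(pd.DataFrame(clmm_rows), outdir / "clmm_fit.csv")
    ordination = pd.DataFrame(
        pca.scores[:, :2], columns=["pc1", "pc2"]
    ).assign(accession_id=acc_ids, subspecies=labels)
    write_table(ordination, outdir / "ordination.csv")
    if lda is not None:
        write_table(
            lda.coefficients.rename_axis("trait").reset_index(), outdir / "discriminant.csv"
        )
    vf_rows = []
    for name, fit in fits.items():
        row = {"response": name, "r_squared": fit.r_squared,
               "permutation_p": fit.permutation_p}
        for j, comp in enumerate(fit.retained_components):
            row[f"cos_pc{comp + 1}"] = fit.direction[j]
        vf_rows.append(row)
    write_table(pd.DataFrame(vf_rows), outdir / "vector_fits.csv")
    if regressions:
        reg_df = pd.DataFrame(
            [{"response": k, **dataclasses.asdict(v)} for k, v in regressions.items()]
        )
        write_table(reg_df, outdir / "df_regressions.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "settings": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "simulation"
        },
        "input_hashes": input_hashes,
        "row_counts": {
            "leaf_samples": len(leaf), "shear_traces": len(shear),
            "nutrients": len(nutrients), "choice_trials": len(choice),
            "damage": len(dmg), "trait_table": len(trait_table),
            "fs_table": len(fs_table),
        },
        "summary": {
            "fs_mean_difference_pct": ttest.mean_difference_pct,
            "fs_paired_t_p": ttest.p,
            "clmm_subspecies_p": dmg_analysis["lrt"].p,
            "clmm_s_value_bits": dmg_analysis["s_value_whole_bits"],
            "pca_pc1_pc2_variance_pct": 100 * float(pca.variance_explained[:2].sum()),
            "manova_p": manova.p,
            "nutrient_ratio_mean": balance_summary["ratio_mean"],
            "nitrogen_to_protein_factor_mean": npf_mean,
            "nitrogen_protein_correlation": npf_corr,
        },
    }
    manifest["settings"]["input_dir"] = str(config.input_dir)
    manifest["settings"]["output_dir"] = str(config.output_dir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _write_report(outdir / "report.txt", manifest, fits, regressions, lda, pca, manova)
    logger.info("pipeline complete: outputs in %s", outdir)
    return {
        "trait_table": trait_table,
        "fs_table": fs_table,
        "ttest": ttest,
        "bs_summary": bs_summary,
        "samples": samples,
        "damage_analysis": dmg_analysis,
        "fd_means": fd_means,
        "pca": pca,
        "manova": manova,
        "lda": lda,
        "vector_fits": fits,
        "df_regressions": regressions,
        "manifest": manifest,
    }


def _write_report(path, manifest, fits, regressions, lda, pca, manova) -> None:
    lines = ["wheat-locust pipeline report", "=" * 32, ""]
    s = manifest["summary"]
    lines.append(f"feeding selectivity: mean wild-modern FS difference "
                 f"{s['fs_mean_difference_pct']:.1f} pp (paired t p = {s['fs_paired_t_p']:.3g})")
    lines.append(f"feeding damage: CLMM subspecies LRT p = {s['clmm_subspecies_p']:.3g} "
                 f"(S = {s['clmm_s_value_bits']} bits)")
    lines.append(f"PCA: PC1+PC2 explain {s['pca_pc1_pc2_variance_pct']:.1f}% of trait variance "
                 f"(eigenvalues {pca.eigenvalues[0]:.2f}, {pca.eigenvalues[1]:.2f})")
    lines.append(f"MANOVA (subspecies): Wilks lambda = {manova.wilks_lambda:.3f}, "
                 f"p = {manova.p:.3g}")
    if lda is not None:
        coeff = ", ".join(f"{t} {c:+.3f}" for t, c in lda.coefficients.items())
        lines.append(f"discriminant function: {coeff}")
    for name, fit in fits.items():
        lines.append(f"vector fit {name}: r2 = {fit.r_squared:.3f}, "
                     f"perm p = {fit.permutation_p}")
    for name, reg in regressions.items():
        lines.append(f"DF -> {name}: slope {reg.slope:+.3f} (p = {reg.p:.3g}, "
                     f"S = {reg.s_value_whole_bits} bits)")
    lines.append("")
    lines.append(f"P:C ratio mean {s['nutrient_ratio_mean']:.2f}; "
                 f"N-to-protein factor {s['nitrogen_to_protein_factor_mean']:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")
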