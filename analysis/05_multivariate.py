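#!/usr/bin/env python
"""Domestication syndrome: PCA, MANOVA, discriminant function, vector fits.

Standardized PCA of the five leaf traits over the 20 accessions; two-group
MANOVA on subspecies; if significant, the linear discriminant function
(unit-norm coefficients, leaf nitrogen positive); vector fitting of the two
herbivore responses (median BS, mean FD) onto the PCs with eigenvalue >= 1;
and linear regressions of both responses on the discriminant scores.
Requires the outputs of steps 02-04.  Writes ordination.csv,
discriminant.csv, vector_fits.csv and df_regressions.csv to results/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from wheatlocust import io as io_mod
from wheatlocust import multivariate as mv
from wheatlocust.traits import TRAIT_COLUMNS

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20230117


def main() -> None:
    table = pd.read_csv(ROOT / "trait_table.csv").sort_values("accession_id")
    bs = pd.read_csv(ROOT / "bs_posterior_summary.csv").set_index("accession_id")
    fd = pd.read_csv(ROOT / "fd_means.csv").set_index("accession_id")
    acc = table["accession_id"].tolist()
    X = table[TRAIT_COLUMNS].to_numpy()
    labels = table["subspecies"].to_numpy()

    pca = mv.pca_standardized(X, trait_names=TRAIT_COLUMNS)
    print(f"PCA: PC1+PC2 explain {100 * pca.variance_explained[:2].sum():.1f}% "
          f"(eigenvalues {pca.eigenvalues[0]:.2f}, {pca.eigenvalues[1]:.2f})")
    io_mod.write_table(
        pd.DataFrame(pca.scores[:, :2], columns=["pc1", "pc2"]).assign(
            accession_id=acc, subspecies=labels
        ),
        ROOT / "ordination.csv",
    )

    manova = mv.manova_two_group(X, labels)
    print(f"MANOVA: Wilks lambda = {manova.wilks_lambda:.3f}, "
          f"F({manova.df1},{manova.df2}) = {manova.F:.2f}, p = {manova.p:.2g}")
    if manova.p >= 0.05:
        print("subspecies not separated; skipping the discriminant analysis")
        return

    lda = mv.lda_two_group(X, labels, TRAIT_COLUMNS, acc)
    io_mod.write_table(
        lda.coefficients.rename_axis("trait").reset_index(), ROOT / "discriminant.csv"
    )
    terms = " ".join(f"{c:+.3f} {t}" for t, c in lda.coefficients.items())
    print(f"discriminant function: DF = {terms}")

    rows_vf, rows_reg = [], []
    for name, resp in (
        ("BS", bs["bs_median"].reindex(acc)),
        ("FD", fd["fd_mean"].reindex(acc)),
    ):
        fit = mv.vector_fit(resp.to_numpy(), pca, n_permutations=999,
                            response_name=name, seed=SEED)
        reg = mv.regress_response_on_df(lda.df_scores.to_numpy(), resp.to_numpy())
        row = {"response": name, "r_squared": fit.r_squared,
               "permutation_p": fit.permutation_p}
        for j, comp in enumerate(fit.retained_components):
            row[f"cos_pc{comp + 1}"] = fit.direction[j]
        rows_vf.append(row)
        rows_reg.append({"response": name, **dataclasses.asdict(reg)})
        print(f"{name}: vector fit r2 = {fit.r_squared:.2f} "
              f"(perm p = {fit.permutation_p:.3f}); DF slope {reg.slope:+.3f} "
              f"(p = {reg.p:.2g}, S = {reg.s_value_whole_bits} bits)")
    io_mod.write_table(pd.DataFrame(rows_vf), ROOT / "vector_fits.csv")
    io_mod.write_table(pd.DataFrame(rows_reg), ROOT / "df_regressions.csv")


if __name__ == "__main__":
    main()
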