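"""Multivariate characterization of the wheat domestication syndrome.

Given the per-accession table of the five herbivory-related leaf traits,
this module provides:

* standardized (correlation-matrix) PCA with deterministic component signs;
* a two-group MANOVA on subspecies (Wilks Λ with the exact F transform);
* a two-group linear discriminant function (LDA) on standardized traits,
  unit-norm with the leaf-nitrogen coefficient fixed positive, gated on the
  MANOVA being significant;
* vector fitting of herbivore feeding responses (BS medians, mean FD) onto
  the principal components with eigenvalue ≥ 1, with a permutation test;
* simple linear regressions of the feeding responses on the discriminant
  scores, reported with p- and S-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .damage import s_value

logger = logging.getLogger(__name__)


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Column z-scores (ddof=1); raises if any column is constant."""
    X = np.asarray(matrix, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(f"constant trait column(s) at index {np.where(sd == 0)[0]}")
    return (X - X.mean(axis=0)) / sd


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray  # nonincreasing, nonnegative
    variance_explained: np.ndarray  # proportions summing to 1
    scores: np.ndarray  # accessions × components
    loadings: np.ndarray  # traits × components, orthonormal columns
    trait_names: list[str] | None = None


def pca_standardized(
    trait_matrix: np.ndarray, trait_names: list[str] | None = None
) -> OrdinationResult:
    """PCA of the correlation matrix (traits have heterogeneous units).

    Components are sorted by decreasing eigenvalue; each loading column's
    sign is fixed so its largest-magnitude entry is positive, making output
    reproducible across linear-algebra backends.
    """
    X = np.asarray(trait_matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 accessions")
    Z = standardize(X)
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    return OrdinationResult(
        eigenvalues=eigval,
        variance_explained=eigval / eigval.sum(),
        scores=Z @ eigvec,
        loadings=eigvec,
        trait_names=trait_names,
    )


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    F: float
    df1: int
    df2: int
    p: float


def manova_two_group(trait_matrix: np.ndarray, labels: np.ndarray) -> ManovaResult:
    """Two-group MANOVA: Wilks Λ = det(E)/det(E+H) with the exact F transform.

    For two groups Wilks' Λ is equivalent to Hotelling's T²;
    F = ((n − p − 1)/p) · (1 − Λ)/Λ on (p, n − p − 1) degrees of freedom.
    """
    X = np.asarray(trait_matrix, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    n, p = X.shape
    grand = X.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for g in uniq:
        sub = X[labels == g]
        if len(sub) < p + 1:
            raise ValueError(
                f"group {g!r} has {len(sub)} members; need at least {p + 1} "
                "for the F approximation (consider removing traits)"
            )
        mean_g = sub.mean(axis=0)
        centered = sub - mean_g
        E += centered.T @ centered
        d = (mean_g - grand)[:, None]
        H += len(sub) * (d @ d.T)
    sign_E, logdet_E = np.linalg.slogdet(E)
    sign_T, logdet_T = np.linalg.slogdet(E + H)
    if sign_E <= 0 or sign_T <= 0:
        raise ValueError("singular within-group covariance; remove collinear traits")
    lam = math.exp(logdet_E - logdet_T)
    df1, df2 = p, n - p - 1
    F = (df2 / df1) * (1.0 - lam) / lam
    return ManovaResult(lam, F, df1, df2, float(stats.f.sf(F, df1, df2)))


@dataclass
class DiscriminantResult:
    coefficients: pd.Series  # unit-norm, on standardized traits
    raw_coefficients: pd.Series  # on the original trait scale
    df_scores: pd.Series  # per accession
    group_means: pd.DataFrame  # mean DF score per subspecies


def lda_two_group(
    trait_matrix: np.ndarray,
    labels: np.ndarray,
    trait_names: list[str],
    accession_ids: list[str],
    sign_trait: str = "lnc_pct",
) -> DiscriminantResult:
    """Two-group linear discriminant on standardized traits.

    Direction w ∝ W⁻¹(mean_modern − mean_ancestral) for pooled within-group
    covariance W, scaled to unit norm with the sign fixed so the coefficient
    of ``sign_trait`` (leaf nitrogen by default) is positive.
    """
    X = standardize(np.asarray(trait_matrix, dtype=float))
    labels = np.asarray(labels)
    uniq = sorted(np.unique(labels))
    if len(uniq) != 2:
        raise ValueError("LDA requires exactly two groups")
    a, b = uniq  # 'ancestral', 'modern' in the canonical labelling
    Xa, Xb = X[labels == a], X[labels == b]
    n = len(X)
    W = (
        (Xa - Xa.mean(axis=0)).T @ (Xa - Xa.mean(axis=0))
        + (Xb - Xb.mean(axis=0)).T @ (Xb - Xb.mean(axis=0))
    ) / (n - 2)
    try:
        w = np.linalg.solve(W, Xb.mean(axis=0) - Xa.mean(axis=0))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular pooled within-group covariance") from err
    w = w / np.linalg.norm(w)
    sign_ix = trait_names.index(sign_trait)
    if w[sign_ix] < 0:
        w = -w
    scores = X @ w
    # back-transform to the raw trait scale for transparency
    sd = np.asarray(trait_matrix, dtype=float).std(axis=0, ddof=1)
    raw = w / sd
    coeff = pd.Series(w, index=trait_names, name="df_coefficient")
    group_means = (
        pd.DataFrame({"subspecies": labels, "df_score": scores})
        .groupby("subspecies")["df_score"]
        .mean()
        .to_frame()
    )
    return DiscriminantResult(
        coefficients=coeff,
        raw_coefficients=pd.Series(raw, index=trait_names, name="df_raw_coefficient"),
        df_scores=pd.Series(scores, index=accession_ids, name="df_score"),
        group_means=group_means,
    )


@dataclass
class VectorFit:
    response: str
    direction: np.ndarray  # unit-norm cosines on the retained components
    r_squared: float
    retained_components: np.ndarray  # indices of components with eig >= threshold
    permutation_p: float | None = None


def vector_fit(
    response_values: np.ndarray,
    ordination: OrdinationResult,
    min_eigenvalue: float = 1.0,
    n_permutations: int = 0,
    response_name: str = "response",
    seed: int = 0,
) -> VectorFit:
    """Fit a response vector into the retained PC axes (the envfit operation).

    Ordinary least squares of the response on the component scores with
    eigenvalue ≥ ``min_eigenvalue``; the fitted arrow direction is the
    normalized coefficient vector, and r² the squared multiple correlation.
    An optional permutation test shuffles the response
    (p = (1 + #{r²_perm ≥ r²_obs}) / (1 + n_permutations)).
    """
    y = np.asarray(response_values, dtype=float)
    keep = np.where(ordination.eigenvalues >= min_eigenvalue)[0]
    if keep.size == 0:
        raise ValueError(f"no component has eigenvalue >= {min_eigenvalue}")
    S = ordination.scores[:, keep]
    if len(y) != S.shape[0]:
        raise ValueError("response must be defined for every accession with scores")

    def r2_of(yy: np.ndarray) -> tuple[float, np.ndarray]:
        A = np.column_stack([np.ones(len(yy)), S])
        coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
        fitted = A @ coef
        ss_res = float(np.sum((yy - fitted) ** 2))
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return r2, coef[1:]

    r2, beta = r2_of(y)
    norm = np.linalg.norm(beta)
    direction = beta / norm if norm > 0 else beta
    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            r2p, _ = r2_of(rng.permutation(y))
            if r2p >= r2:
                hits += 1
        perm_p = (1 + hits) / (1 + n_permutations)
    return VectorFit(response_name, direction, r2, keep, perm_p)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    se_slope: float
    t: float
    p: float
    s_value_bits: float
    s_value_whole_bits: int
    r_squared: float
    n: int


def regress_response_on_df(
    df_scores: np.ndarray, response_values: np.ndarray
) -> RegressionFit:
    """Simple linear regression of a feeding response on discriminant scores."""
    x = np.asarray(df_scores, dtype=float)
    y = np.asarray(response_values, dtype=float)
    if len(x) < 3:
        raise ValueError("regression needs at least 3 accessions")
    if np.allclose(x.std(ddof=1), 0):
        raise ValueError("zero variance in discriminant scores")
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    raw_bits, whole_bits = s_value(max(p, 1e-300))
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        t=float(res.slope / res.stderr) if res.stderr > 0 else math.inf,
        p=p,
        s_value_bits=raw_bits,
        s_value_whole_bits=whole_bits,
        r_squared=float(res.rvalue**2),
        n=len(x),
    )
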