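"""Bayesian GBLUP: Gibbs sampling of y = Xb + Zu + e with u ~ N(0, G sigma2_u).

The phenotype y is the untransformed proportional abundance of one taxon;
X holds the fixed effects (intercept, first two principal components of G,
contemporary-group indicators with the first level dropped); u is the vector
of additive genetic values with covariance proportional to the genomic
relationship matrix G.

Priors: flat on b; scaled inverse chi-squared on both variance components
with 5 degrees of freedom and scale factors chosen so that the prior mode
splits the phenotypic variance as R2 : (1 - R2) with R2 = 0.20 by default
(the BGLR default rule).  Under the chi^-2(df, S) parameterization used
here a variance draw is (sum of squares + S) / chi2_{df + n}.

Sampling is done in the eigenbasis of G: with G = U D U', u = U alpha and
the rotated model has independent normal full conditionals for each
alpha_i.  Components whose eigenvalue falls below a relative floor carry no
genetic variance (G from in-sample allele frequencies is singular by
construction) and are excluded from u' G^- u and its degrees of freedom.

Per-sample heritability is h2 = sigma2_u / (sigma2_u + sigma2_e); the
reported estimate is its posterior mean +/- posterior SD over the retained
(post-burn-in, thinned) samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

from .grm import (
    EIG_FLOOR_RATIO,
    GenomicRelationship,
    GenotypeMatrix,
    center_genotypes,
    grm_pca,
    impute_missing_mean,
    vanraden_grm,
)

__all__ = [
    "PriorSpec",
    "ChainSettings",
    "PosteriorChain",
    "default_priors",
    "build_design",
    "fit_gblup_gibbs",
    "blup_solve",
    "heritability_summary",
    "effective_sample_size",
    "GBLUPRegressor",
]


@dataclass
class PriorSpec:
    """Scaled inverse chi-squared priors for the two variance components."""

    scale_u: float
    scale_e: float
    df_u: float = 5.0
    df_e: float = 5.0
    r2: float = 0.20

    def __post_init__(self) -> None:
        if self.df_u <= 0 or self.df_e <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if self.scale_u <= 0 or self.scale_e <= 0:
            raise ValueError("prior scale factors must be positive")

    def prior_mode_u(self, mean_diag_g: float = 1.0) -> float:
        """Mode of the implied prior on sigma2_u, S * mean(diag G) / (df + 2)."""
        return self.scale_u * mean_diag_g / (self.df_u + 2.0)

    def prior_mode_e(self) -> float:
        return self.scale_e / (self.df_e + 2.0)


@dataclass
class ChainSettings:
    """MCMC chain bookkeeping; defaults are the analysis settings."""

    n_iter: int = 102_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorChain:
    """Retained samples of (b, u, sigma2_u, sigma2_e) and derived h2."""

    b: np.ndarray          # n_samples x p
    u: np.ndarray          # n_samples x n
    sigma2_u: np.ndarray   # n_samples
    sigma2_e: np.ndarray   # n_samples
    settings: ChainSettings
    animal_ids: list | None = None
    fixed_effect_names: list | None = None

    @property
    def h2(self) -> np.ndarray:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)

    @property
    def n_retained(self) -> int:
        return len(self.sigma2_u)

    def posterior_mean_u(self) -> np.ndarray:
        return self.u.mean(axis=0)

    def posterior_mean_b(self) -> np.ndarray:
        return self.b.mean(axis=0)

    def summary(self) -> pd.Series:
        h2_mean, h2_sd = heritability_summary(self)
        return pd.Series({
            "h2_mean": h2_mean,
            "h2_psd": h2_sd,
            "sigma2_u_mean": float(self.sigma2_u.mean()),
            "sigma2_e_mean": float(self.sigma2_e.mean()),
            "ess_h2": effective_sample_size(self.h2),
            "n_retained": self.n_retained,
        })


def default_priors(y, G: GenomicRelationship | np.ndarray, r2: float = 0.20,
                   df: float = 5.0) -> PriorSpec:
    """Prior scale factors from the assumed R2 split of var(y).

    scale_u = var(y) * R2 * (df + 2) / mean(diag G) and
    scale_e = var(y) * (1 - R2) * (df + 2), so each prior's mode returns the
    assumed share of the phenotypic variance.
    """
    y = np.asarray(y, dtype=float)
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise ValueError("phenotype is constant; cannot set priors (skip taxon)")
    if not 0 < r2 < 1:
        raise ValueError("r2 must lie strictly between 0 and 1")
    Gm = G.G if isinstance(G, GenomicRelationship) else np.asarray(G)
    mean_diag = float(np.mean(np.diag(Gm)))
    if mean_diag <= 0:
        raise ValueError("mean diagonal of G must be positive")
    return PriorSpec(
        scale_u=vy * r2 * (df + 2.0) / mean_diag,
        scale_e=vy * (1.0 - r2) * (df + 2.0),
        df_u=df, df_e=df, r2=r2,
    )


def build_design(n: int, pcs: pd.DataFrame | np.ndarray | None = None,
                 groups=None) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design: intercept, PC columns, reference-coded groups.

    The first contemporary-group level (sorted order) is the reference and
    is dropped so X stays full column rank under the flat prior on b.
    """
    cols, names = [np.ones((n, 1))], ["intercept"]
    if pcs is not None:
        arr = pcs.to_numpy() if isinstance(pcs, pd.DataFrame) else np.asarray(pcs)
        if arr.ndim == 1:
            arr = arr[:, None]
        cols.append(arr)
        if isinstance(pcs, pd.DataFrame):
            names += list(pcs.columns)
        else:
            names += [f"PC{i + 1}" for i in range(arr.shape[1])]
    if groups is not None:
        g = pd.Series(list(groups))
        levels = sorted(g.unique())
        for lev in levels[1:]:
            cols.append((g == lev).to_numpy(dtype=float)[:, None])
            names.append(f"group[{lev}]")
    X = np.hstack(cols)
    if X.shape[0] != n:
        raise ValueError("design rows do not match phenotype length")
    return X, names


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the gram matrix
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1])
               if abs(r[j, j]) < 1e-8 * max(abs(np.diag(r)).max(), 1.0)] if names else []
        raise ValueError(f"fixed-effects design is rank deficient; collinear: {bad}")


def _draw_scaled_inv_chi2(rng, df: float, ss: float) -> float:
    """One draw of (ss) / chi2_df — the chi^-2(df, ss) distribution."""
    return ss / rng.chisquare(df)


def fit_gblup_gibbs(y, X, G: GenomicRelationship | np.ndarray,
                    priors: PriorSpec | None = None,
                    settings: ChainSettings | None = None,
                    fixed_variances: tuple[float, float] | None = None,
                    eig_floor_ratio: float = EIG_FLOOR_RATIO,
                    fixed_effect_names: list | None = None) -> PosteriorChain:
    """Gibbs sampler for the GBLUP model; returns the retained chain.

    ``fixed_variances=(sigma2_u, sigma2_e)`` clamps the variance components
    (no scaled-inv-chi2 draws), which makes the retained mean of (b, u) an
    estimate of the exact BLUP solution — used for oracle validation.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    names = fixed_effect_names or [f"x{j}" for j in range(p)]
    _check_design(X, names)
    if isinstance(G, np.ndarray):
        G = GenomicRelationship(G=G, p=np.empty(0), denom=1.0)
    if priors is None:
        priors = default_priors(y, G)
    settings = settings or ChainSettings()
    rng = np.random.default_rng(settings.seed)

    d, U, keep = G.eigen(eig_floor_ratio)
    n_pos = int(keep.sum())
    d_pos = d[keep]
    yt = U.T @ y
    Xt = U.T @ X
    XtX = Xt.T @ Xt
    chol = cho_factor(XtX)
    L = np.linalg.cholesky(XtX)  # for drawing b ~ N(mean, (X'X)^-1 s2e)

    if fixed_variances is not None:
        s2u, s2e = map(float, fixed_variances)
        if s2u <= 0 or s2e <= 0:
            raise ValueError("clamped variance components must be positive")
    else:
        s2u = priors.prior_mode_u(float(np.mean(np.diag(G.G))))
        s2e = priors.prior_mode_e()

    alpha = np.zeros(n)
    b = cho_solve(chol, Xt.T @ yt)

    n_ret = settings.n_retained
    out_b = np.empty((n_ret, p))
    out_u = np.empty((n_ret, n))
    out_s2u = np.empty(n_ret)
    out_s2e = np.empty(n_ret)
    kept = 0

    for it in range(1, settings.n_iter + 1):
        # b | rest: flat prior, Gaussian conditional N(mean, (X'X)^-1 s2e)
        mean_b = cho_solve(chol, Xt.T @ (yt - alpha))
        z = rng.standard_normal(p)
        b = mean_b + np.sqrt(s2e) * np.linalg.solve(L.T, z)

        r = yt - Xt @ b
        # alpha | rest on the positive eigencomponents
        prec = 1.0 / (d_pos * s2u) + 1.0 / s2e
        mean_a = (r[keep] / s2e) / prec
        alpha[:] = 0.0
        alpha[keep] = mean_a + rng.standard_normal(n_pos) / np.sqrt(prec)

        if fixed_variances is None:
            ss_u = float(np.sum(alpha[keep] ** 2 / d_pos))
            s2u = _draw_scaled_inv_chi2(
                rng, priors.df_u + n_pos, ss_u + priors.scale_u
            )
            e = r - alpha
            s2e = _draw_scaled_inv_chi2(
                rng, priors.df_e + n, float(e @ e) + priors.scale_e
            )

        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            out_b[kept] = b
            out_u[kept] = U @ alpha
            out_s2u[kept] = s2u
            out_s2e[kept] = s2e
            kept += 1

    return PosteriorChain(
        b=out_b[:kept], u=out_u[:kept], sigma2_u=out_s2u[:kept],
        sigma2_e=out_s2e[:kept], settings=settings,
        animal_ids=G.animal_ids, fixed_effect_names=names,
    )


def blup_solve(y, X, G: GenomicRelationship | np.ndarray, sigma2_u: float,
               sigma2_e: float,
               eig_floor_ratio: float = EIG_FLOOR_RATIO):
    """Henderson mixed-model-equation BLUP at known variance components.

    Solved as GLS with V = sigma2_u G + sigma2_e I via the eigendecomposition
    of G: b_hat = (X'V^-1 X)^-1 X'V^-1 y, u_hat = sigma2_u G V^-1 (y - X b_hat).
    Deterministic oracle for the Gibbs sampler's conditional means.
    """
    if sigma2_u <= 0 or sigma2_e <= 0:
        raise ValueError("variance components must be positive")
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if isinstance(G, np.ndarray):
        G = GenomicRelationship(G=G, p=np.empty(0), denom=1.0)
    d, U, _ = G.eigen(eig_floor_ratio)
    v = sigma2_u * np.clip(d, 0.0, None) + sigma2_e  # eigenvalues of V
    yt, Xt = U.T @ y, U.T @ X
    XtVX = Xt.T @ (Xt / v[:, None])
    b_hat = np.linalg.solve(XtVX, Xt.T @ (yt / v))
    r = yt - Xt @ b_hat
    u_hat = U @ (sigma2_u * np.clip(d, 0.0, None) * r / v)
    return b_hat, u_hat


def heritability_summary(chain: PosteriorChain) -> tuple[float, float]:
    """Posterior mean and posterior SD of the per-sample h2 series."""
    h2 = chain.h2
    if len(h2) < 2:
        raise ValueError("need at least two retained samples")
    return float(h2.mean()), float(h2.std(ddof=1))


def effective_sample_size(series) -> float:
    """ESS = n / (1 + 2 sum rho_k) with Geyer's initial-positive-sequence rule.

    Autocorrelations are accumulated in pairs (rho_{2m} + rho_{2m+1}) until a
    pair sum turns non-positive; the result is clipped to (0, n].
    """
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    if n < 10:
        raise ValueError("series too short for an ESS estimate")
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise ValueError("constant series has no defined ESS")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = -1.0
    for m in range(n // 2):
        pair = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < n else 0.0)
        if pair <= 0:
            break
        tau += 2.0 * pair
    tau = max(tau, 1.0 / n)
    return float(min(n / tau, n))


class GBLUPRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn-style Bayesian GBLUP for one microbial taxon.

    ``fit(X, y)`` takes the animals x SNP dosage matrix (0/1/2, NaN for
    missing) and the taxon's relative abundance; it imputes missing calls,
    builds the VanRaden genomic relationship matrix, adds the first
    ``n_pcs`` principal components of G and the ``groups`` factor (passed to
    ``fit``) to the fixed effects, and runs the Gibbs sampler.

    ``predict(X)`` returns genomic values for dosage matrices over the same
    SNP panel via backsolved marker effects plus the intercept; for the
    training animals it reproduces intercept + posterior-mean u.

    Parameters follow the analysis defaults (102,000 iterations, 2,000
    burn-in, thinning 10, df 5, prior R2 0.20); shorten the chain for
    exploratory fits.
    """

    def __init__(self, n_iter: int = 102_000, burn_in: int = 2_000,
                 thin: int = 10, df: float = 5.0, r2: float = 0.20,
                 n_pcs: int = 2, seed: int | None = None):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.df = df
        self.r2 = r2
        self.n_pcs = n_pcs
        self.seed = seed

    def fit(self, X, y, groups=None, covariates=None):
        y = np.asarray(y, dtype=float).ravel()
        geno = X if isinstance(X, GenotypeMatrix) else GenotypeMatrix(
            np.asarray(X, dtype=float),
            _default_map(np.asarray(X).shape[1]),
        )
        geno = impute_missing_mean(geno)
        cg = center_genotypes(geno)
        self.grm_ = vanraden_grm(cg)
        self._cg = cg
        pcs = None
        if self.n_pcs:
            scores, _ = grm_pca(self.grm_, n_components=self.n_pcs)
            pcs = scores
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            pcs_arr = pcs.to_numpy() if pcs is not None else np.empty((len(y), 0))
            pcs = np.hstack([pcs_arr, cov if cov.ndim == 2 else cov[:, None]])
        design, names = build_design(len(y), pcs=pcs, groups=groups)
        priors = default_priors(y, self.grm_, r2=self.r2, df=self.df)
        settings = ChainSettings(n_iter=self.n_iter, burn_in=self.burn_in,
                                 thin=self.thin, seed=self.seed)
        self.chain_ = fit_gblup_gibbs(y, design, self.grm_, priors=priors,
                                      settings=settings,
                                      fixed_effect_names=names)
        self.h2_mean_, self.h2_sd_ = heritability_summary(self.chain_)
        self.u_ = self.chain_.posterior_mean_u()
        self.b_ = self.chain_.posterior_mean_b()
        self.fixed_effect_names_ = names
        self.ess_h2_ = effective_sample_size(self.chain_.h2)
        return self

    @property
    def marker_effects_(self) -> np.ndarray:
        from .windows import backsolve_marker_effects

        if not hasattr(self, "chain_"):
            raise AttributeError("fit the model before requesting marker effects")
        return backsolve_marker_effects(self._cg, self.grm_, self.u_)

    def predict(self, X):
        dos = X.dosages if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
        M = dos - 2.0 * self._cg.p
        return self.b_[0] + M @ self.marker_effects_


def _default_map(m: int) -> pd.DataFrame:
    """Placeholder single-chromosome map for bare-array genotype input."""
    return pd.DataFrame({
        "chrom": 1, "id": [f"snp_{j + 1}" for j in range(m)],
        "bp": np.arange(1, m + 1),
    })
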