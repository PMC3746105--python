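"""Linear-mixed-model association with a pedigree random effect.

Per-variant model:  y = W alpha + x beta + u + e,  with
u ~ N(0, sigma_g^2 K) for relatedness matrix K and e ~ N(0, sigma_e^2 I).
The variance ratio lambda = sigma_g^2 / sigma_e^2 is estimated by REML
through a one-dimensional optimization over log(lambda), made cheap by
rotating the model into the eigenbasis of K (where the covariance is
diagonal).  The effect of the focal variant is then tested with a Wald
statistic beta_hat^2 / se^2 referred to chi-square(1).

Phenotype preprocessing mirrors common mixed-model GWAS practice:
quantitative phenotypes are quantile-normalized to a standard normal
(rank-based inverse-normal transform), ages enter as "adjusted age"
(2 * age / maximum species age, spanning [0, 2]), and a categorical
two-species phenotype is coded 2/1 and used raw.  Candidate covariates
are screened one at a time in the same mixed model and retained when
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PhenotypeVector",
    "CovariateSet",
    "AssocResult",
    "quantile_normalize",
    "adjusted_age",
    "encode_species",
    "screen_covariates",
    "lmm_wald",
    "association_scan",
    "KEigen",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PhenotypeVector:
    ids: list
    y: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if len(self.ids) != self.y.size:
            raise ValueError("ids/values length mismatch")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotype values must be finite")


@dataclass
class CovariateSet:
    """Fixed-effect design matrix with an intercept column."""

    design: np.ndarray
    names: list

    def __post_init__(self):
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.design.shape[1] != len(self.names):
            raise ValueError("design/names mismatch")
        if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @classmethod
    def intercept_only(cls, n: int) -> "CovariateSet":
        return cls(np.ones((n, 1)), ["intercept"])

    def with_column(self, col, name) -> "CovariateSet":
        return CovariateSet(np.column_stack([self.design, col]), [*self.names, name])


@dataclass
class AssocResult:
    variant_id: str
    beta: float
    se: float
    wald: float
    p_value: float
    lambda_hat: float
    n_used: int
    tested: bool = True

    @classmethod
    def untested(cls, variant_id, n, reason="monomorphic"):
        r = cls(variant_id, np.nan, np.nan, np.nan, np.nan, np.nan, n, tested=False)
        r.reason = reason
        return r


def quantile_normalize(x, ids=None, label="") -> PhenotypeVector:
    """Rank-based inverse-normal transform to a standard normal scale.

    Ties receive average ranks; rank r of n maps to the standard normal
    quantile at (r - 0.5) / n.  Order is preserved, so the transform is
    invariant to monotone transformations of tie-free input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]):
        raise ValueError("phenotype has no variation")
    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf((ranks - 0.5) / x.size)
    if ids is None:
        ids = list(range(x.size))
    return PhenotypeVector(ids=list(ids), y=z, label=label)


def adjusted_age(age, max_age) -> np.ndarray | float:
    """Age rescaled to [0, 2]: two times age divided by maximum age."""
    age = np.asarray(age, dtype=float)
    if np.any(np.asarray(max_age) <= 0):
        raise ValueError("max_age must be positive")
    if np.any(age < 0) or np.any(age > max_age):
        raise ValueError("ages must lie in [0, max_age]")
    out = 2.0 * age / max_age
    return float(out) if out.ndim == 0 else out


def encode_species(labels, ids=None, coding=None) -> PhenotypeVector:
    """Categorical two-species phenotype, coded 2 / 1 and used raw.

    Default coding: ``black`` -> 2, ``blue-eyed`` -> 1 (substring match
    on "blue").  The coded vector is deliberately not normalized.
    """
    if coding is None:
        coding = {}
        for lab in labels:
            key = str(lab).lower()
            coding[lab] = 1 if "blue" in key else 2 if "black" in key else None
        if any(v is None for v in coding.values()):
            bad = [k for k, v in coding.items() if v is None]
            raise ValueError(f"unknown species labels: {sorted(set(map(str, bad)))}")
    else:
        unknown = set(labels) - set(coding)
        if unknown:
            raise ValueError(f"unknown species labels: {sorted(map(str, unknown))}")
    y = np.array([coding[lab] for lab in labels], dtype=float)
    if np.all(y == y[0]):
        raise ValueError("phenotype has no variation")
    if ids is None:
        ids = list(range(len(labels)))
    return PhenotypeVector(ids=list(ids), y=y, label="species")


# ---------------------------------------------------------------------------
# REML machinery


class KEigen:
    """Cached eigendecomposition of a relatedness matrix.

    Rotating y and the design by U' makes the mixed-model covariance
    diagonal, so each REML objective evaluation is O(n p^2); computing
    this once per kinship matrix and reusing it across a variant scan
    is what keeps the scan linear in the number of variants.
    """

    def __init__(self, K):
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T):
            raise ValueError("K must be symmetric")
        self.s, self.U = np.linalg.eigh(K)
        if self.s.min() < -1e-8:
            raise ValueError("K is not positive semi-definite")
        self.s = np.maximum(self.s, 0.0)
        self.n = K.shape[0]

    def rotate(self, a):
        return self.U.T @ a


def _reml_neg_loglik(log_lam, yt, Xt, s):
    """Negative REML log-likelihood profile in the eigenbasis (up to
    terms constant in lambda)."""
    lam = np.exp(log_lam)
    d = lam * s + 1.0
    n, p = Xt.shape
    Xw = Xt / d[:, None]
    A = Xt.T @ Xw
    b = Xw.T @ yt
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    rss = float(yt @ (yt / d) - b @ beta)
    if rss <= 0:
        return np.inf
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return 0.5 * (np.log(d).sum() + logdetA + (n - p) * np.log(rss))


def _fit_reml(yt, Xt, s, bounds=(-10.0, 10.0)):
    """Minimize the REML objective over log(lambda) on a bounded interval."""
    obj = lambda t: _reml_neg_loglik(t, yt, Xt, s)
    res = optimize.minimize_scalar(obj, bounds=bounds, method="bounded", options={"xatol": 1e-8})
    # the bounded minimizer can miss boundary optima; compare explicitly
    cands = [(obj(bounds[0]), bounds[0]), (obj(bounds[1]), bounds[1]), (res.fun, res.x)]
    _, best = min(cands, key=lambda c: c[0])
    return float(np.exp(best))


def _gls_wald(yt, Xt, s, lam):
    """GLS estimate, SE and Wald test for the LAST column of Xt."""
    d = lam * s + 1.0
    n, p = Xt.shape
    Xw = Xt / d[:, None]
    A = Xt.T @ Xw
    b = Xw.T @ yt
    Ainv = np.linalg.inv(A)
    beta = Ainv @ b
    rss = float(yt @ (yt / d) - b @ beta)
    sigma_e2 = rss / (n - p)
    se = float(np.sqrt(sigma_e2 * Ainv[-1, -1]))
    bhat = float(beta[-1])
    wald = (bhat / se) ** 2
    p_value = float(stats.chi2.sf(wald, df=1))
    return bhat, se, wald, p_value


def lmm_wald(
    y,
    x,
    W: CovariateSet | None = None,
    K=None,
    eig: KEigen | None = None,
    variant_id: str = "",
    force_lambda: float | None = None,
    missing: str = "impute",
) -> AssocResult:
    """Mixed-model Wald test of a focal predictor.

    Parameters
    ----------
    y : PhenotypeVector or array of phenotype values.
    x : focal predictor (genotype dosages in {0,1,2} or a covariate);
        np.nan marks missing values.
    W : fixed-effect covariates (default intercept only).
    K : relatedness matrix (default identity); alternatively pass a
        precomputed ``eig=KEigen(K)`` to reuse across variants.
    force_lambda : pin the variance ratio instead of REML-estimating it
        (``force_lambda=0`` reduces the model to ordinary regression).
    missing : "impute" mean-imputes missing genotypes per variant;
        "drop" removes those individuals.

    Returns NA results (``tested=False``) for predictors that are
    constant after missing-data handling, mirroring the treatment of
    monomorphic variants in association tables.
    """
    yv = np.asarray(y.y if isinstance(y, PhenotypeVector) else y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = yv.size
    if x.size != n:
        raise ValueError("x length mismatch")
    if W is None:
        W = CovariateSet.intercept_only(n)
    if W.design.shape[0] != n:
        raise ValueError("covariate rows mismatch")

    miss = ~np.isfinite(x)
    keep = np.ones(n, dtype=bool)
    if miss.any():
        if missing == "impute":
            if miss.all():
                return AssocResult.untested(variant_id, 0, reason="all missing")
            x = x.copy()
            x[miss] = x[~miss].mean()
        elif missing == "drop":
            keep = ~miss
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    xk, yk, Wk = x[keep], yv[keep], W.design[keep]
    n_used = int(keep.sum())
    if n_used < Wk.shape[1] + 2 or np.ptp(xk) == 0:
        return AssocResult.untested(variant_id, n_used)

    X = np.column_stack([Wk, xk])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: focal predictor collinear with covariates")

    if eig is None and K is not None:
        eig = KEigen(np.asarray(K))
    if eig is None:
        # identity kinship: the eigenbasis is the original basis
        yt, Xt, s = yk, X, np.ones(n_used)
    else:
        if eig.n != n:
            raise ValueError("kinship dimension mismatch")
        if keep.all():
            yt, Xt, s = eig.rotate(yk), eig.rotate(X), eig.s
        else:
            # dropping individuals breaks the cached rotation; redo on the subset
            Ksub = (eig.U * eig.s) @ eig.U.T
            sub = KEigen(Ksub[np.ix_(keep, keep)])
            yt, Xt, s = sub.rotate(yk), sub.rotate(X), sub.s

    lam = float(force_lambda) if force_lambda is not None else _fit_reml(yt, Xt, s)
    bhat, se, wald, p_value = _gls_wald(yt, Xt, s, lam)
    return AssocResult(variant_id, bhat, se, wald, p_value, lam, n_used)


def screen_covariates(
    y,
    candidates: CovariateSet,
    K=None,
    alpha: float = 0.05,
) -> CovariateSet:
    """Retain candidate covariates individually significant in the LMM.

    Each non-intercept candidate is tested one at a time as the focal
    fixed effect (intercept-only base model, same kinship random
    effect); those with p < alpha are kept alongside the intercept.
    """
    yv = np.asarray(y.y if isinstance(y, PhenotypeVector) else y, dtype=float)
    n = yv.size
    eig = KEigen(np.eye(n) if K is None else np.asarray(K))
    base = CovariateSet.intercept_only(n)
    kept_cols, kept_names = [np.ones(n)], ["intercept"]
    for j, name in enumerate(candidates.names):
        if name == "intercept":
            continue
        res = lmm_wald(yv, candidates.design[:, j], W=base, eig=eig, variant_id=name)
        if res.tested and res.p_value < alpha:
            kept_cols.append(candidates.design[:, j])
            kept_names.append(name)
    return CovariateSet(np.column_stack(kept_cols), kept_names)


def association_scan(
    y,
    genotypes: pd.DataFrame,
    W: CovariateSet | None = None,
    K=None,
    missing: str = "impute",
) -> pd.DataFrame:
    """Per-variant mixed-model Wald scan.

    Parameters
    ----------
    genotypes : DataFrame of derived-allele dosages, individuals in rows
        (aligned with y), variants in columns; NaN marks missing.

    Returns
    -------
    DataFrame with columns ``variant beta se wald p lambda_hat n_used``;
    monomorphic or untestable variants carry NA statistics.
    """
    yv = np.asarray(y.y if isinstance(y, PhenotypeVector) else y, dtype=float)
    n = yv.size
    eig = KEigen(np.eye(n) if K is None else np.asarray(K))
    rows = []
    for var in genotypes.columns:
        res = lmm_wald(
            yv, genotypes[var].to_numpy(dtype=float), W=W, eig=eig, variant_id=str(var), missing=missing
        )
        rows.append(
            {
                "variant": res.variant_id,
                "beta": res.beta,
                "se": res.se,
                "wald": res.wald,
                "p": res.p_value,
                "lambda_hat": res.lambda_hat,
                "n_used": res.n_used,
            }
        )
    return pd.DataFrame(rows)
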