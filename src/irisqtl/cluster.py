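"""Two clusters versus one: mixture LRT with a parametric-bootstrap null.

A univariate phenotype sample is tested for bimodality by comparing the
maximized log-likelihood of a two-component Gaussian mixture against
that of a single Gaussian.  Because the usual chi-square asymptotics do
not apply on the boundary of the mixture parameter space, the test
statistic ``lambda = 2 (loglik_mix - loglik_normal)`` is calibrated by
simulating datasets from the fitted single Gaussian and recomputing the
statistic on each (a parametric bootstrap); the p-value uses the
add-one estimator ``(n_exceed + 1) / (B + 1)``, which can never be
exactly zero.

The EM fits are batched: bootstrap replicates and restarts are stacked
into a single array and iterated together, which keeps a 100,000-dataset
null affordable.  Mixture likelihoods with unequal variances are
unbounded, so component variances are floored at ``1e-6`` times the
sample variance; solutions in which a floored component carries
essentially a single observation are the classical spurious maximizers
and are discarded from the max over restarts whenever a non-spurious
solution exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormalFit",
    "Mixture2Fit",
    "MixtureLRT",
    "SubsampleResult",
    "fit_normal",
    "fit_mixture2",
    "lrt_statistic",
    "bootstrap_cluster_test",
    "min_related_subset",
    "subsample_comparison",
]

_LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR_REL = 1e-6


@dataclass
class NormalFit:
    mu: float
    sigma2: float
    loglik: float


@dataclass
class Mixture2Fit:
    weights: tuple[float, float]
    means: tuple[float, float]
    variances: tuple[float, float]
    loglik: float
    n_restarts_used: int
    converged: bool


@dataclass
class MixtureLRT:
    lambda_obs: float
    B: int
    n_exceed: int
    p_value: float
    seed: int | None
    null_statistics: np.ndarray | None = field(default=None, repr=False)


@dataclass
class SubsampleResult:
    n_subsamples: int
    subsample_size: int
    statistics: np.ndarray
    lambda_ref: float
    n_more_extreme: int
    seed: int | None


def _variance_floor(x: np.ndarray) -> float:
    s2 = float(np.var(x))
    if s2 > 0:
        return _VAR_FLOOR_REL * s2
    mu = float(np.mean(x))
    return 1e-12 * max(1.0, mu * mu)


def fit_normal(x) -> NormalFit:
    """Maximum-likelihood Gaussian fit (variance divisor n, floored)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    mu = float(np.mean(x))
    s2 = float(np.var(x))
    floor = _variance_floor(x)
    if s2 < floor:
        warnings.warn("zero/near-zero sample variance: variance floor applied")
        s2 = floor
    n = x.size
    loglik = -0.5 * n * (_LOG2PI + np.log(s2)) - float(np.sum((x - mu) ** 2)) / (2 * s2)
    return NormalFit(mu=mu, sigma2=s2, loglik=float(loglik))


# ---------------------------------------------------------------------------
# Batched EM machinery.  All fits (single dataset, bootstrap replicates,
# subsamples) funnel through _best_mixture_batch, which runs EM on an
# (n_datasets * n_restarts, n) row stack and reduces over restarts.


def _mixture_loglik_rows(X, w, mu, var):
    """Row-wise mixture log-likelihood.  Shapes: X (m, n), params (m, 2)."""
    # log components: (m, 2, n)
    d = X[:, None, :] - mu[:, :, None]
    logc = -0.5 * (_LOG2PI + np.log(var)[:, :, None]) - d * d / (2 * var[:, :, None])
    logc = logc + np.log(w)[:, :, None]
    top = logc.max(axis=1)
    lse = top + np.log(np.exp(logc - top[:, None, :]).sum(axis=1))
    return lse.sum(axis=1)


def _em_batch(X, w, mu, var, floor, max_iter=1000, tol=1e-8):
    """Run EM rows in parallel until each row's log-likelihood converges.

    Parameters are updated in place.  Returns (loglik, n_iter, converged).
    """
    m, n = X.shape
    ll = _mixture_loglik_rows(X, w, mu, var)
    converged = np.zeros(m, dtype=bool)
    active = np.arange(m)
    n_iter = np.zeros(m, dtype=int)
    for it in range(max_iter):
        Xa = X[active]
        wa, mua, vara = w[active], mu[active], var[active]
        fa = floor[active]
        d = Xa[:, None, :] - mua[:, :, None]
        logc = (
            -0.5 * (_LOG2PI + np.log(vara)[:, :, None])
            - d * d / (2 * vara[:, :, None])
            + np.log(wa)[:, :, None]
        )
        top = logc.max(axis=1, keepdims=True)
        p = np.exp(logc - top)
        denom = p.sum(axis=1, keepdims=True)
        r = p / denom  # responsibilities (ma, 2, n)
        new_ll = (top[:, 0, :] + np.log(denom[:, 0, :])).sum(axis=1)

        Nk = r.sum(axis=2)  # (ma, 2)
        # guard empty components: keep previous parameters for them
        ok = Nk > 1e-12
        wa = np.where(ok, Nk / n, wa)
        wa = np.maximum(wa, 1e-12)
        wa = wa / wa.sum(axis=1, keepdims=True)
        mua = np.where(ok, (r * Xa[:, None, :]).sum(axis=2) / np.maximum(Nk, 1e-300), mua)
        d2 = (Xa[:, None, :] - mua[:, :, None]) ** 2
        vara = np.where(ok, (r * d2).sum(axis=2) / np.maximum(Nk, 1e-300), vara)
        vara = np.maximum(vara, fa[:, None])

        w[active], mu[active], var[active] = wa, mua, vara
        done = np.abs(new_ll - ll[active]) < tol
        ll[active] = new_ll
        n_iter[active] = it + 1
        if done.any():
            converged[active[done]] = True
            active = active[~done]
        if active.size == 0:
            break
    # the loop tracks the pre-M-step likelihood; evaluate once at the
    # final parameters (EM monotonicity means this can only be higher)
    ll = _mixture_loglik_rows(X, w, mu, var)
    return ll, n_iter, converged


def _initial_params(X, restarts, rng, floor=None):
    """Initialization stack: deterministic splits first, then random.

    Restart 0: single-normal solution split symmetrically (mu +- 0.1 sd);
    restart 1: below/above-median split; restart 2: quartile split;
    restarts 3-4: boundary initializations putting one floor-variance
    component on the extreme low/high observation (these target the
    small-cluster maximizers of the unbounded mixture likelihood, which
    smooth initializations never reach).  Remaining restarts center
    components on two distinct random points.
    Returns (w, mu, var) each of shape (m, restarts, 2).
    """
    m, n = X.shape
    mean = X.mean(axis=1)
    sd = X.std(axis=1)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = np.sort(X, axis=1)
    half = n // 2
    w = np.full((m, restarts, 2), 0.5)
    mu = np.empty((m, restarts, 2))
    var = np.empty((m, restarts, 2))

    k = 0
    mu[:, k, 0] = mean - 0.1 * sd
    mu[:, k, 1] = mean + 0.1 * sd
    var[:, k, :] = (sd**2)[:, None]
    k += 1
    if restarts > 1:
        lo, hi = Xs[:, :half], Xs[:, half:]
        mu[:, k, 0], mu[:, k, 1] = lo.mean(axis=1), hi.mean(axis=1)
        var[:, k, 0] = np.maximum(lo.var(axis=1), 1e-4 * sd**2)
        var[:, k, 1] = np.maximum(hi.var(axis=1), 1e-4 * sd**2)
        w[:, k, 0] = half / n
        w[:, k, 1] = 1 - half / n
        k += 1
    if restarts > 2:
        q = max(1, n // 4)
        mu[:, k, 0], mu[:, k, 1] = Xs[:, q - 1], Xs[:, n - q]
        var[:, k, :] = (sd**2)[:, None]
        k += 1
    if floor is not None:
        for extreme in (0, n - 1):
            if restarts <= k:
                break
            rest = Xs[:, 1:] if extreme == 0 else Xs[:, :-1]
            mu[:, k, 0] = Xs[:, extreme]
            mu[:, k, 1] = rest.mean(axis=1)
            var[:, k, 0] = floor
            var[:, k, 1] = np.maximum(rest.var(axis=1), floor)
            w[:, k, 0] = 1.0 / n
            w[:, k, 1] = 1.0 - 1.0 / n
            k += 1
    for j in range(k, restarts):
        idx = rng.integers(0, n, size=(m, 2))
        picked = np.take_along_axis(X, idx, axis=1)
        mu[:, j, :] = np.sort(picked, axis=1)
        same = mu[:, j, 0] == mu[:, j, 1]
        mu[same, j, 1] = mu[same, j, 1] + sd[same]
        var[:, j, :] = (sd**2)[:, None]
        w[:, j, 0] = rng.uniform(0.2, 0.8, size=m)
        w[:, j, 1] = 1 - w[:, j, 0]
    return w, mu, var


def _exhaustive_inits(x, floor):
    """Initializations covering every plausible small-cluster maximizer.

    For small samples the mixture likelihood has local maxima in which
    one component captures a short contiguous run of sorted
    observations (a singleton, pair or triple) or one tail of a
    threshold split.  Enumerating all of these as EM starting points
    makes the restart max a reliable global maximizer for n <= ~15.
    Returns (w, mu, var) arrays of shape (r, 2).
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    spans = {
        (start, start + size)
        for size in (1, 2, 3)
        for start in range(max(0, n - size + 1))
        if size < n
    }
    # plus every threshold split (prefix windows of any size)
    spans |= {(0, k) for k in range(1, n)}
    inits = []
    for start, stop in sorted(spans):
        size = stop - start
        win = xs[start:stop]
        rest = np.concatenate([xs[:start], xs[stop:]])
        inits.append(
            (
                (size / n, 1 - size / n),
                (win.mean(), rest.mean()),
                (max(win.var(), floor), max(rest.var(), floor)),
            )
        )
    w = np.array([i[0] for i in inits])
    mu = np.array([i[1] for i in inits])
    var = np.array([i[2] for i in inits])
    return w, mu, var


def _best_mixture_batch(
    X,
    restarts=10,
    tol=1e-8,
    max_iter=1000,
    rng=None,
    discard_spurious=True,
    return_params=False,
    var_floor=None,
    extra_inits=None,
):
    """Best two-component mixture per row of X, maxing over restarts.

    Returns a dict with per-dataset arrays: loglik, loglik_normal, and
    optionally the winning parameters.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if n < 4:
        raise ValueError("too few observations for two components")
    if rng is None:
        rng = np.random.default_rng()

    mean = X.mean(axis=1)
    s2 = X.var(axis=1)
    if var_floor is None:
        floor_ds = np.array([_variance_floor(row) for row in X])
    else:
        floor_ds = np.full(m, float(var_floor))
    s2f = np.maximum(s2, floor_ds)
    ll_normal = -0.5 * n * (_LOG2PI + np.log(s2f)) - ((X - mean[:, None]) ** 2).sum(axis=1) / (2 * s2f)

    w0, mu0, var0 = _initial_params(X, restarts, rng, floor=floor_ds)
    R = restarts
    if extra_inits is not None:
        if m != 1:
            raise ValueError("extra_inits only supported for a single dataset")
        we, mue, vare = extra_inits
        w0 = np.concatenate([w0, we[None, :, :]], axis=1)
        mu0 = np.concatenate([mu0, mue[None, :, :]], axis=1)
        var0 = np.concatenate([var0, vare[None, :, :]], axis=1)
        R += we.shape[0]
    Xr = np.repeat(X, R, axis=0)
    floor_r = np.repeat(floor_ds, R)
    w = w0.reshape(m * R, 2).copy()
    mu = mu0.reshape(m * R, 2).copy()
    var = np.maximum(var0.reshape(m * R, 2), floor_r[:, None]).copy()

    ll, _, conv = _em_batch(Xr, w, mu, var, floor_r, max_iter=max_iter, tol=tol)

    llm = ll.reshape(m, R)
    if discard_spurious:
        min_w = w.reshape(m, R, 2).min(axis=2)
        min_v = var.reshape(m, R, 2).min(axis=2)
        spurious = (min_w < 1.5 / n) & (min_v <= floor_ds[:, None] * (1 + 1e-9))
        masked = np.where(spurious, -np.inf, llm)
        # fall back to the unmasked max when every restart is spurious
        all_bad = np.isinf(masked).all(axis=1)
        best_idx = np.where(all_bad, llm.argmax(axis=1), masked.argmax(axis=1))
    else:
        best_idx = llm.argmax(axis=1)
    rows = np.arange(m) * R + best_idx
    best_ll = np.maximum(ll[rows], ll_normal)  # nesting: never below the normal fit

    out = {
        "loglik": best_ll,
        "loglik_normal": ll_normal,
        "converged": conv.reshape(m, R)[np.arange(m), best_idx],
    }
    if return_params:
        out["weights"] = w[rows]
        out["means"] = mu[rows]
        out["variances"] = var[rows]
        out["mixture_beats_normal"] = ll[rows] >= ll_normal
        if m == 1:
            # ranked restart solutions, best first, for optional polishing
            order = np.argsort(llm[0])[::-1]
            out["ranked"] = (w[order], mu[order], var[order], ll[order])
    return out


def _polish_solution(x, floor, w, mu, var):
    """Direct local maximization of the mixture likelihood from an EM
    solution (Nelder-Mead on unconstrained parameters, variances clamped
    at the floor).  EM converges linearly and can stall on likelihood
    ridges; a direct polish recovers the last few digits.
    Returns (loglik, w, mu, var)."""
    from scipy import optimize

    w0 = min(max(float(w[0]), 1e-9), 1 - 1e-9)
    th0 = np.array([np.log(w0 / (1 - w0)), mu[0], mu[1], np.log(var[0]), np.log(var[1])])

    def neg(th):
        ww = 1.0 / (1.0 + np.exp(-th[0]))
        v1 = max(np.exp(th[3]), floor)
        v2 = max(np.exp(th[4]), floor)
        c1 = ww * np.exp(-0.5 * (x - th[1]) ** 2 / v1) / np.sqrt(2 * np.pi * v1)
        c2 = (1 - ww) * np.exp(-0.5 * (x - th[2]) ** 2 / v2) / np.sqrt(2 * np.pi * v2)
        return -float(np.log(c1 + c2).sum())

    r = optimize.minimize(
        neg, th0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000}
    )
    ww = 1.0 / (1.0 + np.exp(-r.x[0]))
    out_w = np.array([ww, 1 - ww])
    out_mu = np.array([r.x[1], r.x[2]])
    out_var = np.maximum(np.exp(r.x[3:5]), floor)
    return -r.fun, out_w, out_mu, out_var


def fit_mixture2(
    x,
    restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed=None,
    discard_spurious: bool = True,
    var_floor: float | None = None,
    exhaustive: bool = False,
    polish: bool = False,
) -> Mixture2Fit:
    """EM fit of a two-component Gaussian mixture, best of ``restarts``.

    One restart is initialized at the single-Gaussian solution split
    symmetrically, so the returned log-likelihood never falls below the
    single-Gaussian log-likelihood (the models are nested).
    ``var_floor`` overrides the default relative floor (1e-6 times the
    sample variance) with an absolute bound on component variances.
    ``exhaustive`` appends the small-sample initialization schedule of
    :func:`_exhaustive_inits`, making the restart max a reliable global
    maximizer for small n.  ``polish`` refines the best EM solution with a
    direct Nelder-Mead maximization of the likelihood, which recovers the
    last few digits when EM stalls on a likelihood ridge.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("too few observations for two components")
    rng = np.random.default_rng(seed)
    extra = None
    if exhaustive:
        floor = float(var_floor) if var_floor is not None else _variance_floor(x)
        extra = _exhaustive_inits(x, floor)
    res = _best_mixture_batch(
        x[None, :],
        restarts=restarts,
        tol=tol,
        max_iter=max_iter,
        rng=rng,
        discard_spurious=discard_spurious,
        return_params=True,
        var_floor=var_floor,
        extra_inits=extra,
    )
    loglik = float(res["loglik"][0])
    if res["mixture_beats_normal"][0]:
        wts = tuple(res["weights"][0])
        mus = tuple(res["means"][0])
        vrs = tuple(res["variances"][0])
        if polish:
            floor = float(var_floor) if var_floor is not None else _variance_floor(x)
            # polish the top-ranked restart solutions, not only the best:
            # near-ties can sit in different basins of the likelihood
            rw, rmu, rvar, rll = res["ranked"]
            keep = min(8, rll.size)
            for i in range(keep):
                pll, pw, pmu, pvar = _polish_solution(x, floor, rw[i], rmu[i], rvar[i])
                if pll > loglik:
                    loglik = pll
                    wts, mus, vrs = tuple(pw), tuple(pmu), tuple(pvar)
    else:
        nf = fit_normal(x)
        wts, mus, vrs = (0.5, 0.5), (nf.mu, nf.mu), (nf.sigma2, nf.sigma2)
    return Mixture2Fit(
        weights=wts,
        means=mus,
        variances=vrs,
        loglik=loglik,
        n_restarts_used=restarts,
        converged=bool(res["converged"][0]),
    )


def lrt_statistic(x, restarts: int = 10, tol: float = 1e-8, max_iter: int = 1000, seed=None) -> float:
    """``lambda = 2 (loglik_mix - loglik_normal)``, clipped at zero."""
    nf = fit_normal(x)
    mf = fit_mixture2(x, restarts=restarts, tol=tol, max_iter=max_iter, seed=seed)
    return max(0.0, 2.0 * (mf.loglik - nf.loglik))


def _lambda_batch(X, restarts, tol, max_iter, rng, chunk=50_000):
    """LRT statistics for many datasets stacked as rows of X."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[0])
    rows_per_chunk = max(1, chunk // max(1, restarts))
    for start in range(0, X.shape[0], rows_per_chunk):
        sl = slice(start, start + rows_per_chunk)
        res = _best_mixture_batch(X[sl], restarts=restarts, tol=tol, max_iter=max_iter, rng=rng)
        out[sl] = np.maximum(0.0, 2.0 * (res["loglik"] - res["loglik_normal"]))
    return out


def bootstrap_cluster_test(
    x,
    B: int = 100_000,
    seed=None,
    restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    keep_null: bool = False,
) -> MixtureLRT:
    """Parametric-bootstrap test of two Gaussian clusters versus one.

    ``B`` datasets of the same size are simulated from the fitted single
    Gaussian; the LRT statistic is recomputed on each with the same
    fitting configuration; ``p = (n_exceed + 1) / (B + 1)``.
    """
    x = np.asarray(x, dtype=float)
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    nf = fit_normal(x)
    lam_obs = _lambda_batch(x[None, :], restarts, tol, max_iter, rng)[0]
    sims = rng.normal(nf.mu, np.sqrt(nf.sigma2), size=(B, x.size))
    lam_null = _lambda_batch(sims, restarts, tol, max_iter, rng)
    n_exceed = int(np.sum(lam_null >= lam_obs))
    return MixtureLRT(
        lambda_obs=float(lam_obs),
        B=B,
        n_exceed=n_exceed,
        p_value=(n_exceed + 1) / (B + 1),
        seed=seed,
        null_statistics=lam_null if keep_null else None,
    )


def min_related_subset(individuals, kinship, max_phi: float = 0.125):
    """Maximal subset with every pairwise kinship coefficient <= max_phi.

    The default threshold 0.125 admits avuncular and more distant
    relationships but excludes parent-offspring and full siblings.
    Greedy heuristic: repeatedly drop the individual involved in the
    most remaining violations (ties broken by identifier order, last
    sorted identifier dropped first).

    Parameters
    ----------
    individuals : sequence of identifiers
    kinship : object with ``.ids`` and ``.phi`` (see KinshipMatrix), or a
        pandas DataFrame indexed by identifier.
    """
    ids = list(individuals)
    if not ids:
        return []
    if hasattr(kinship, "phi"):
        order = {v: i for i, v in enumerate(kinship.ids)}
        missing = [i for i in ids if i not in order]
        if missing:
            raise ValueError(f"kinship matrix does not cover: {missing}")
        phi = np.asarray(kinship.phi)
        sub = phi[np.ix_([order[i] for i in ids], [order[i] for i in ids])]
    else:  # DataFrame
        sub = kinship.loc[ids, ids].to_numpy()
    keep = set(range(len(ids)))
    viol = {i: {j for j in keep if j != i and sub[i, j] > max_phi} for i in keep}
    while True:
        offenders = [i for i in keep if viol[i]]
        if not offenders:
            break
        worst = max(offenders, key=lambda i: (len(viol[i]), str(ids[i])))
        keep.discard(worst)
        for j in viol[worst]:
            viol[j].discard(worst)
        viol[worst] = set()
    return [ids[i] for i in sorted(keep)]


def subsample_comparison(
    x_pool,
    lambda_ref: float,
    m: int = 1000,
    k: int = 8,
    seed=None,
    restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> SubsampleResult:
    """Distribution of the cluster LRT over random size-k subsamples.

    Emulates comparing a small, strongly clustered sample against
    size-matched random subsamples from a larger group: draws ``m``
    simple random samples of size ``k`` without replacement from the
    pool, computes the LRT statistic for each, and counts statistics at
    least as extreme as ``lambda_ref``.
    """
    x_pool = np.asarray(x_pool, dtype=float)
    if x_pool.size < k:
        raise ValueError("pool smaller than subsample size")
    rng = np.random.default_rng(seed)
    idx = np.array([rng.choice(x_pool.size, size=k, replace=False) for _ in range(m)])
    stats = _lambda_batch(x_pool[idx], restarts, tol, max_iter, rng)
    return SubsampleResult(
        n_subsamples=m,
        subsample_size=k,
        statistics=stats,
        lambda_ref=float(lambda_ref),
        n_more_extreme=int(np.sum(stats >= lambda_ref)),
        seed=seed,
    )
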