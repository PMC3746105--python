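import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from irisqtl.kinship import kinship_from_pedigree, relatedness
from irisqtl.lmm import (
    AssocResult,
    CovariateSet,
    KEigen,
    PhenotypeVector,
    adjusted_age,
    association_scan,
    encode_species,
    lmm_wald,
    quantile_normalize,
    screen_covariates,
)
from irisqtl.simulate import (
    GeneticsConfig,
    PedigreeConfig,
    PhenotypeConfig,
    gen_genotypes,
    gen_pedigree,
    gen_phenotypes,
)


def test_quantile_normalize_properties(rng):
    x = rng.exponential(size=101)  # heavily skewed input
    pv = quantile_normalize(x, label="b")
    assert pv.label == "b"
    # order preserved
    assert np.array_equal(np.argsort(pv.y), np.argsort(x))
    # matches the documented rank -> (r - 0.5)/n -> Phi^-1 map
    ranks = stats.rankdata(x)
    assert np.allclose(pv.y, stats.norm.ppf((ranks - 0.5) / x.size))
    # invariant to monotone transforms of tie-free input
    assert np.allclose(quantile_normalize(np.exp(x)).y, pv.y)


def test_quantile_normalize_ties_and_errors():
    y = quantile_normalize([1.0, 1.0, 2.0, 3.0]).y
    assert y[0] == y[1]  # average ranks for ties
    with pytest.raises(ValueError):
        quantile_normalize([2.0, 2.0, 2.0])
    with pytest.raises(ValueError):
        quantile_normalize([1.0])


def test_adjusted_age():
    assert adjusted_age(15.0, 30.0) == pytest.approx(1.0)
    assert np.allclose(adjusted_age([0.0, 30.0], 30.0), [0.0, 2.0])
    with pytest.raises(ValueError):
        adjusted_age(5.0, 0.0)
    with pytest.raises(ValueError):
        adjusted_age(31.0, 30.0)


def test_encode_species_default_and_custom_coding():
    pv = encode_species(["black lemur", "blue-eyed black lemur", "black lemur"])
    assert pv.y.tolist() == [2.0, 1.0, 2.0]
    pv2 = encode_species(["x", "y"], coding={"x": 2, "y": 1})
    assert pv2.y.tolist() == [2.0, 1.0]
    with pytest.raises(ValueError, match="unknown species"):
        encode_species(["gibbon"])
    with pytest.raises(ValueError, match="no variation"):
        encode_species(["black", "black"])


def test_covariate_set_validation():
    with pytest.raises(ValueError, match="rank deficient"):
        CovariateSet(np.ones((5, 2)), ["a", "b"])
    W = CovariateSet.intercept_only(4).with_column([1.0, 2.0, 3.0, 4.0], "age")
    assert W.names == ["intercept", "age"]
    assert W.design.shape == (4, 2)


def _ols_oracle(y, X):
    """Independent OLS fit via statsmodels; chi2(1) Wald p per our convention."""
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    b, se = fit.params[-1], fit.bse[-1]
    return b, se, float(stats.chi2.sf((b / se) ** 2, df=1))


def test_lmm_equals_ols_at_lambda_zero(rng):
    for _ in range(20):
        n = int(rng.integers(20, 60))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        x = rng.integers(0, 3, size=n).astype(float)
        y = rng.normal(size=n)
        W = CovariateSet(X, ["intercept", "cov"])
        res = lmm_wald(y, x, W=W, K=np.eye(n), force_lambda=0.0)
        b, se, p = _ols_oracle(y, np.column_stack([X, x]))
        assert res.beta == pytest.approx(b, abs=1e-8)
        assert res.se == pytest.approx(se, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-6)


def test_lmm_identity_k_reml_matches_forced_zero(rng):
    # with K = I the model is i.i.d. for any lambda; beta/se must agree
    n = 50
    x = rng.integers(0, 3, size=n).astype(float)
    y = rng.normal(size=n)
    a = lmm_wald(y, x, K=np.eye(n))
    b = lmm_wald(y, x, force_lambda=0.0)
    assert a.beta == pytest.approx(b.beta, rel=1e-6)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-4)


def test_lmm_reml_recovers_variance_ratio():
    # strong polygenic signal: lambda_hat should be large; no signal: small
    rng = np.random.default_rng(8)
    ped = gen_pedigree(PedigreeConfig(n_founders=24, n_generations=3), rng=1)
    kin = kinship_from_pedigree(ped)
    K = relatedness(kin)
    n = K.shape[0]
    s, U = np.linalg.eigh(K)
    u = U @ (np.sqrt(np.maximum(s, 0) * 4.0) * rng.standard_normal(n))
    y = u + rng.normal(0, 0.5, n)
    x = rng.integers(0, 3, n).astype(float)
    res = lmm_wald(y, x, K=K)
    assert res.lambda_hat > 1.0
    y0 = rng.normal(size=n)
    res0 = lmm_wald(y0, x, K=K)
    assert res0.lambda_hat < 1.0


def test_lmm_missing_policies(rng):
    n = 40
    x = rng.integers(0, 3, size=n).astype(float)
    y = rng.normal(size=n)
    x[3] = np.nan
    imp = lmm_wald(y, x, missing="impute")
    assert imp.n_used == n
    drp = lmm_wald(y, x, missing="drop")
    assert drp.n_used == n - 1
    # drop result equals a fresh fit on the complete subset
    keep = np.isfinite(x)
    ref = lmm_wald(y[keep], x[keep])
    assert drp.beta == pytest.approx(ref.beta)
    with pytest.raises(ValueError):
        lmm_wald(y, x, missing="what")


def test_lmm_drop_with_kinship_subsets_k(rng):
    ped = gen_pedigree(PedigreeConfig(n_founders=12, n_generations=2), rng=2)
    K = relatedness(kinship_from_pedigree(ped))
    n = K.shape[0]
    x = rng.integers(0, 3, size=n).astype(float)
    y = rng.normal(size=n)
    x[0] = np.nan
    res = lmm_wald(y, x, K=K, missing="drop")
    keep = np.isfinite(x)
    ref = lmm_wald(y[keep], x[keep], K=K[np.ix_(keep, keep)])
    assert res.beta == pytest.approx(ref.beta, rel=1e-8)
    assert res.p_value == pytest.approx(ref.p_value, rel=1e-6)


def test_lmm_untested_cases(rng):
    y = rng.normal(size=10)
    res = lmm_wald(y, np.ones(10), variant_id="mono")
    assert not res.tested and np.isnan(res.p_value) and res.variant_id == "mono"
    res2 = lmm_wald(y, np.full(10, np.nan), variant_id="gone")
    assert not res2.tested and res2.reason == "all missing"
    assert isinstance(res, AssocResult)


def test_lmm_collinear_design_raises(rng):
    y = rng.normal(size=10)
    x = rng.normal(size=10)
    W = CovariateSet(np.column_stack([np.ones(10), x]), ["intercept", "dup"])
    with pytest.raises(ValueError, match="collinear"):
        lmm_wald(y, x, W=W)


def test_keigen_validation(rng):
    with pytest.raises(ValueError, match="symmetric"):
        KEigen(rng.normal(size=(4, 4)))
    with pytest.raises(ValueError, match="positive semi-definite"):
        KEigen(np.array([[0.0, 1.0], [1.0, 0.0]]))


def test_screen_covariates_keeps_signal_drops_noise(rng):
    n = 120
    age = rng.uniform(0, 2, n)
    noise = rng.normal(size=n)
    y = 2.0 * age + rng.normal(size=n)
    cands = CovariateSet(
        np.column_stack([np.ones(n), age, noise]), ["intercept", "age", "noise"]
    )
    kept = screen_covariates(y, cands, alpha=0.01)
    assert kept.names == ["intercept", "age"]


def test_association_scan_ranks_causal_first():
    ped = gen_pedigree(PedigreeConfig(n_founders=30, n_generations=3), rng=3)
    gcfg = GeneticsConfig(n_variants=8, causal_index=2, beta=1.5)
    geno, _ = gen_genotypes(ped, gcfg, rng=4)
    y, truth = gen_phenotypes(ped, geno, PhenotypeConfig(), gcfg, rng=5)
    qn = quantile_normalize(y.to_numpy(), ids=list(y.index))
    table = association_scan(qn, geno, K=truth["K"])
    assert list(table.columns) == ["variant", "beta", "se", "wald", "p", "lambda_hat", "n_used"]
    assert table.sort_values("p").iloc[0]["variant"] == truth["causal"]


def test_association_scan_handles_monomorphic_column(rng):
    import pandas as pd

    n = 30
    y = rng.normal(size=n)
    geno = pd.DataFrame({"v0": rng.integers(0, 3, n), "mono": np.zeros(n)})
    table = association_scan(y, geno)
    assert np.isnan(table.set_index("variant").loc["mono", "p"])
    assert np.isfinite(table.set_index("variant").loc["v0", "p"])


def test_phenotype_vector_validation():
    with pytest.raises(ValueError):
        PhenotypeVector(ids=["a"], y=[1.0, 2.0])
    with pytest.raises(ValueError):
        PhenotypeVector(ids=["a", "b"], y=[1.0, np.inf])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_wald_p_in_unit_interval_property(seed):
    rng = np.random.default_rng(seed)
    n = 25
    x = rng.integers(0, 3, size=n).astype(float)
    if np.ptp(x) == 0:
        x[0] = 1.0 if x[0] != 1.0 else 2.0
    y = rng.normal(size=n)
    res = lmm_wald(y, x)
    assert 0.0 <= res.p_value <= 1.0 and res.se > 0
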