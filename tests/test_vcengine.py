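"""REML engine: oracle equivalence, fixed effects, Wald tests, invariants."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla

from famvc.errors import ConfigurationError, NumericalError
from famvc.relmat import RelationshipMatrix
from famvc.vcengine import (
    ModelSpec,
    REMLWorkspace,
    build_fixed_effects,
    h2_vs_cutoff,
    reml_fit,
    wald_test,
)


def textbook_reml_logl(y, X, V):
    """Standard restricted log-likelihood, computed directly from V and X."""
    n, p = X.shape
    c = sla.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.log(np.diag(c[0])).sum()
    vx = sla.cho_solve(c, X)
    xtvx = X.T @ vx
    _, logdet_x = np.linalg.slogdet(xtvx)
    beta = np.linalg.solve(xtvx, vx.T @ y)
    r = y - X @ beta
    ypy = float(r @ sla.cho_solve(c, r))
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + logdet_x + ypy)


def _family_kernel(n, size=4):
    v = np.zeros((n, n))
    for i in range(0, n - size + 1, size):
        v[i:i + size, i:i + size] = 0.5
    np.fill_diagonal(v, 1.0)
    return v


def _one_kernel_instance(n=60, h2=0.5, seed=3):
    rng = np.random.default_rng(seed)
    K = _family_kernel(n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    L = np.linalg.cholesky(K)
    y = L @ rng.normal(size=n) * np.sqrt(h2) + rng.normal(size=n) * np.sqrt(1 - h2)
    return y, X, K


# ---------------------------------------------------------------------------
# closed forms and oracles
# ---------------------------------------------------------------------------


def test_residual_only_closed_form():
    ws = REMLWorkspace(np.ones((3, 1)), {})
    res = ws.fit(np.array([1.0, 2.0, 3.0]), ())
    assert res.sigma2[0] == pytest.approx(1.0)  # REML divisor n - 1
    assert res.ratios[0] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [3, 11, 29])
def test_single_component_matches_grid_oracle(seed):
    """AI-REML equals a brute-force 1-D restricted-likelihood search."""
    y, X, K = _one_kernel_instance(seed=seed)
    n = len(y)
    ws = REMLWorkspace(X, {"G": K})
    fit = ws.fit(y, ("G",), constrained=True)
    assert fit.converged
    # profile the total scale on a fine grid over the variance ratio
    best = -np.inf
    for h in np.linspace(1e-6, 1 - 1e-6, 3000):
        V = h * K + (1 - h) * np.eye(n)
        c = sla.cho_factor(V, lower=True)
        vx = sla.cho_solve(c, X)
        xtvx = X.T @ vx
        beta = np.linalg.solve(xtvx, vx.T @ y)
        r = y - X @ beta
        s2 = float(r @ sla.cho_solve(c, r)) / (n - X.shape[1])
        best = max(best, textbook_reml_logl(y, X, s2 * V))
    assert fit.logL >= best - 1e-4
    assert abs(fit.logL - best) < 1e-4


def test_logl_matches_textbook_formula_multikernel(rng):
    n = 80
    K1 = _family_kernel(n)
    K2 = np.kron(np.eye(n // 2), np.ones((2, 2)))
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = rng.normal(size=n)
    ws = REMLWorkspace(X, {"G": K1, "S": K2})
    fit = ws.fit(y, ("G", "S"), constrained=False)
    V = fit.sigma2[0] * K1 + fit.sigma2[1] * K2 + fit.sigma2[2] * np.eye(n)
    assert fit.logL == pytest.approx(textbook_reml_logl(y, X, V), abs=1e-8)


def test_ratio_shares_sum_to_one(small_cohort, rng):
    ws = small_cohort.workspace
    y = rng.normal(size=ws.n)
    for model in ("G", "GK", "GKFSC"):
        fit = ws.fit(y, model)
        assert fit.ratios.sum() == pytest.approx(1.0, abs=1e-8)
        assert (fit.se_sigma2 >= 0).all() and (fit.se_ratios >= 0).all()


def test_permutation_invariance(rng):
    y, X, K = _one_kernel_instance(n=40, seed=5)
    fit = REMLWorkspace(X, {"G": K}).fit(y, ("G",))
    perm = rng.permutation(len(y))
    fit_p = REMLWorkspace(X[perm], {"G": K[np.ix_(perm, perm)]}).fit(
        y[perm], ("G",))
    assert fit_p.logL == pytest.approx(fit.logL, abs=1e-6)
    np.testing.assert_allclose(fit_p.sigma2, fit.sigma2, atol=1e-6)


def test_nested_logl_never_exceeds_full(small_cohort):
    from famvc.simgen import SimulationConfig, simulate_phenotype
    y, _ = simulate_phenotype(
        small_cohort.geno, small_cohort.ped,
        SimulationConfig(h2g=0.3, ec2=0.2), seed=9)
    ws = small_cohort.workspace
    logl = {m: ws.fit(y, m).logL for m in ("G", "GC", "GKC", "GKFSC")}
    assert logl["G"] <= logl["GC"] + 1e-6
    assert logl["GC"] <= logl["GKC"] + 1e-6
    assert logl["GKC"] <= logl["GKFSC"] + 1e-6


def test_complete_case_alignment(rng):
    y, X, K = _one_kernel_instance(n=50, seed=8)
    y_miss = y.copy()
    y_miss[[3, 17]] = np.nan
    mats = [RelationshipMatrix([f"i{j}" for j in range(50)], K, "GRM_g")]
    fit = reml_fit(y_miss, X, mats)
    keep = np.isfinite(y_miss)
    fit_ref = REMLWorkspace(X[keep], {"G": K[np.ix_(keep, keep)]}).fit(
        y[keep], ("G",))
    assert fit.n == 48
    assert fit.logL == pytest.approx(fit_ref.logL, abs=1e-9)


def test_delta_method_agrees_with_jackknife():
    """Ratio SEs from the AI matrix vs a delete-a-group jackknife."""
    from famvc.simgen import (PedigreeDesign, SimulationConfig, build_cohort,
                              simulate_phenotype)
    coh = build_cohort(PedigreeDesign(n_families=100, n_singletons=100),
                       n_snps=1000, seed=13, n_pcs=0)
    y, _ = simulate_phenotype(coh.geno, coh.ped, SimulationConfig(h2g=0.4),
                              seed=13)
    n = len(y)
    K = coh.grm_g.values
    X = np.ones((n, 1))
    full = REMLWorkspace(X, {"G": K}).fit(y, ("G",))
    # contiguous blocks delete whole families together, keeping the
    # delete-a-group jackknife's independence assumption honest
    groups = np.arange(n) // (n // 20)
    groups[groups >= 20] = 19
    thetas = []
    for g in range(20):
        keep = groups != g
        f = REMLWorkspace(X[keep], {"G": K[np.ix_(keep, keep)]}).fit(
            y[keep], ("G",))
        thetas.append(f.ratio_of("G"))
    thetas = np.array(thetas)
    jk_se = np.sqrt((len(thetas) - 1) / len(thetas)
                    * ((thetas - thetas.mean()) ** 2).sum())
    assert abs(full.ratio_se_of("G") - jk_se) / jk_se < 0.30


# ---------------------------------------------------------------------------
# model specification and fixed effects
# ---------------------------------------------------------------------------


def test_modelspec_parsing():
    assert ModelSpec.parse("CKG").components == ("G", "K", "C")
    assert ModelSpec.parse("gkfsc").code == "GKFSC"
    with pytest.raises(ConfigurationError):
        ModelSpec.parse("GG")
    with pytest.raises(ConfigurationError):
        ModelSpec.parse("GX")


def test_fixed_effects_sex_age_terms():
    tab = pd.DataFrame({"sex": [0, 1, 0, 1, 1, 0, 1, 0],
                        "age": [30.0, 40, 50, 60, 35, 45, 55, 65]},
                       index=list("abcdefgh"))
    X, names = build_fixed_effects(tab, covariates=("sex", "age"))
    assert names == ["intercept", "sex", "age", "age2", "sex_age"]
    np.testing.assert_allclose(X[:, 3], tab["age"] ** 2)
    np.testing.assert_allclose(X[:, 4], tab["sex"] * tab["age"])


def test_fixed_effects_single_clinic_drops_out(rng):
    tab = pd.DataFrame({"clinic": ["A"] * 6, "age": rng.uniform(20, 60, 6),
                        "sex": rng.integers(0, 2, 6)}, index=range(6))
    X, names = build_fixed_effects(tab)
    assert not any(n.startswith("clinic") for n in names)


def test_fixed_effects_collinear_dropped(rng):
    n = 30
    tab = pd.DataFrame({"sex": rng.integers(0, 2, n).astype(float)},
                       index=range(n))
    pcs = np.column_stack([tab["sex"].to_numpy()])  # duplicates sex
    with pytest.warns(UserWarning):
        X, names = build_fixed_effects(tab, pcs=pcs, covariates=("sex",))
    assert np.linalg.matrix_rank(X) == X.shape[1]
    assert len(names) == 2


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------


def _fit_with(s2, se, comp="G"):
    from famvc.vcengine import FitResult
    return FitResult(
        components=(comp,), sigma2=np.array([s2, 1 - s2]),
        se_sigma2=np.array([se, 0.1]), ratios=np.array([s2, 1 - s2]),
        se_ratios=np.array([se, 0.1]), logL=0.0, n=100, n_fixed=1,
        n_iter=5, converged=True, ai=np.eye(2), sigma2_cov=np.eye(2))


def test_wald_examples():
    assert wald_test(_fit_with(0.2, 0.05), "G") == pytest.approx(6.33e-5,
                                                                 rel=1e-2)
    assert wald_test(_fit_with(0.0, 0.05), "G") == 1.0
    assert wald_test(_fit_with(0.05, 0.05), "G") == pytest.approx(0.3173,
                                                                  abs=1e-4)
    with pytest.raises(NumericalError):
        wald_test(_fit_with(0.2, 0.0), "G")


# ---------------------------------------------------------------------------
# cutoff scan
# ---------------------------------------------------------------------------


def test_cutoff_below_everything_equals_unpruned(small_cohort, rng):
    from famvc.simgen import SimulationConfig, simulate_phenotype
    y, _ = simulate_phenotype(small_cohort.geno, small_cohort.ped,
                              SimulationConfig(h2g=0.4), seed=21)
    g = small_cohort.grm_g
    X = np.ones((g.n, 1))
    tab = h2_vs_cutoff(y, X, g, cutoffs=[1.5], n_pcs=5)
    assert tab.loc[0, "n_retained"] == g.n
    direct = REMLWorkspace(
        np.column_stack([X, __import__("famvc.relmat", fromlist=["x"])
                         .grm_eigenvectors(g, 5)]),
        {"G": g.values}).fit(y, ("G",))
    assert tab.loc[0, "h2g"] == pytest.approx(direct.ratio_of("G"), abs=1e-8)
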