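import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from picv import (
    GenotypeDataset,
    ModelSpec,
    classify,
    coefficient_table,
    fit_logistic,
    likelihood_ratio_test,
    predict_prob,
    simulate_balanced_dataset,
)
from picv.glm import _individual_design


def observed_cell_fractions(ds):
    cells = 3 * ds.snp1 + ds.snp2
    totals = np.bincount(cells, minlength=9).astype(float)
    cases = np.bincount(cells, weights=ds.status, minlength=9)
    with np.errstate(invalid="ignore"):
        return (cases / totals).reshape(3, 3), totals.reshape(3, 3)


def refit_with_statsmodels(ds, kind):
    X, _ = _individual_design(ds, ModelSpec(kind))
    X = X[:, X.any(axis=0)]
    return sm.Logit(ds.status, X).fit(disp=0, method="newton", tol=1e-12, maxiter=200)


def test_saturated_interaction_fit_reproduces_cell_fractions(dataset2000):
    fit = fit_logistic(dataset2000, ModelSpec("interaction"))
    frac, totals = observed_cell_fractions(dataset2000)
    occupied = totals > 0
    np.testing.assert_allclose(
        fit.cell_probs[occupied], frac[occupied], atol=1e-12
    )


def test_fast_paths_match_individual_level_irls(dataset2000):
    """The aggregated/saturated covariate-free fits must agree with a
    direct individual-level IRLS fit of the same design."""
    for kind in ("main_effects", "interaction"):
        fit = fit_logistic(dataset2000, ModelSpec(kind))
        oracle = refit_with_statsmodels(dataset2000, kind)
        assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-8)


def test_interaction_loglik_dominates_main_effects(dataset2000):
    main = fit_logistic(dataset2000, ModelSpec("main_effects"))
    inter = fit_logistic(dataset2000, ModelSpec("interaction"))
    assert inter.log_likelihood >= main.log_likelihood - 1e-10
    assert inter.n_params - main.n_params == 4


def test_constant_snp2_reduces_to_one_factor_model(rng):
    ds = GenotypeDataset(
        snp1=rng.integers(0, 3, 300),
        snp2=np.zeros(300, dtype=int),
        status=rng.integers(0, 2, 300),
    )
    fit = fit_logistic(ds, ModelSpec("main_effects"))
    # oracle: one-factor logistic on SNP1 alone
    X = np.column_stack(
        [np.ones(300), (ds.snp1 == 1).astype(float), (ds.snp1 == 2).astype(float)]
    )
    oracle = sm.Logit(ds.status, X).fit(disp=0, method="newton", tol=1e-12)
    assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-8)


def test_null_data_fit_approaches_flat_half(scenario15):
    rng = np.random.default_rng(0)
    n = 80_000
    ds = GenotypeDataset(
        snp1=rng.integers(0, 3, n),
        snp2=rng.integers(0, 3, n),
        status=np.tile([0, 1], n // 2),
    )
    fit = fit_logistic(ds, ModelSpec("main_effects"))
    assert abs(fit.coefficients["intercept"]) < 0.1
    for term, beta in fit.coefficients.items():
        if term != "intercept":
            assert abs(beta) < 0.1
    np.testing.assert_allclose(fit.cell_probs, 0.5, atol=0.05)


def test_predict_reference_cell_is_logistic_intercept(dataset2000):
    fit = fit_logistic(dataset2000, ModelSpec("main_effects"))
    row = GenotypeDataset(snp1=[0], snp2=[0], status=[0])
    expected = 1 / (1 + np.exp(-fit.coefficients["intercept"]))
    assert predict_prob(fit, row)[0] == pytest.approx(expected, abs=1e-12)


def test_single_class_outcome_rejected():
    ds = GenotypeDataset(snp1=[0, 1], snp2=[0, 1], status=[1, 1])
    with pytest.raises(ValueError):
        fit_logistic(ds, ModelSpec("main_effects"))


def test_empty_training_cell_falls_back_to_main_effects(rng):
    # no (2, 2) individuals in training data
    snp1 = np.array([0, 0, 1, 1, 2, 2, 0, 1] * 30)
    snp2 = np.array([0, 1, 0, 1, 0, 1, 2, 2] * 30)
    status = rng.integers(0, 2, snp1.size)
    ds = GenotypeDataset(snp1=snp1, snp2=snp2, status=status)
    inter = fit_logistic(ds, ModelSpec("interaction"))
    main = fit_logistic(ds, ModelSpec("main_effects"))
    assert not inter.training_cells_present[2, 2]
    assert any(f.startswith("empty_training_cells") for f in inter.flags)
    row = GenotypeDataset(snp1=[2], snp2=[2], status=[0])
    assert predict_prob(inter, row)[0] == pytest.approx(
        predict_prob(main, row)[0], abs=1e-10
    )


def test_saturated_cells_are_flagged_not_fatal():
    # cell (0, 0) all cases: separation must saturate, not raise
    ds = GenotypeDataset(
        snp1=[0, 0, 0, 1, 1, 1, 2, 2],
        snp2=[0, 0, 0, 0, 0, 0, 0, 0],
        status=[1, 1, 1, 0, 1, 0, 0, 1],
    )
    fit = fit_logistic(ds, ModelSpec("interaction"))
    assert fit.cell_probs[0, 0] == 1.0
    assert "saturated_cells" in fit.flags


def test_classify_cutoff_and_ties():
    assert np.array_equal(classify(np.array([0.49, 0.51])), [0, 1])
    assert classify(np.array([0.5]))[0] == 0
    assert classify(np.array([])).size == 0
    with pytest.raises(ValueError):
        classify(np.array([1.2]))


def test_lrt_identical_fits_give_unit_p(dataset2000):
    main = fit_logistic(dataset2000, ModelSpec("main_effects"))
    inter = fit_logistic(dataset2000, ModelSpec("interaction"))
    stat, df, p = likelihood_ratio_test(main, inter)
    assert df == 4
    # cross-check the statistic against the direct IRLS refits
    o_main = refit_with_statsmodels(dataset2000, "main_effects")
    o_inter = refit_with_statsmodels(dataset2000, "interaction")
    assert stat == pytest.approx(2 * (o_inter.llf - o_main.llf), abs=1e-6)
    with pytest.raises(ValueError):
        likelihood_ratio_test(inter, main)


def test_lrt_invariant_to_reference_level_relabeling(dataset2000):
    main = fit_logistic(dataset2000, ModelSpec("main_effects"))
    inter = fit_logistic(dataset2000, ModelSpec("interaction"))
    stat, _, _ = likelihood_ratio_test(main, inter)
    remap = np.array([2, 0, 1])
    ds2 = GenotypeDataset(
        snp1=remap[dataset2000.snp1],
        snp2=remap[dataset2000.snp2],
        status=dataset2000.status,
    )
    stat2, _, _ = likelihood_ratio_test(
        fit_logistic(ds2, ModelSpec("main_effects")),
        fit_logistic(ds2, ModelSpec("interaction")),
    )
    assert stat2 == pytest.approx(stat, abs=1e-8)


def test_covariate_adjusted_fit(scenario15):
    rng = np.random.default_rng(2)
    ds = simulate_balanced_dataset(scenario15, 800, rng)
    ds.covariates = pd.DataFrame({"age": rng.normal(50, 10, 800)})
    spec = ModelSpec("interaction", covariate_names=("age",))
    fit = fit_logistic(ds, spec)
    assert "age" in fit.coefficients
    probs = predict_prob(fit, ds)
    assert probs.shape == (800,)
    assert np.all((probs >= 0) & (probs <= 1))
    with pytest.raises(ValueError):
        fit_logistic(
            GenotypeDataset(ds.snp1, ds.snp2, ds.status),
            spec,
        )


def test_coefficient_table_export(dataset2000):
    fit = fit_logistic(dataset2000, ModelSpec("interaction"))
    table = coefficient_table(fit)
    assert set(table.columns) == {"term", "estimate"}
    assert "intercept" in set(table["term"])
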