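"""Mechanism fitting: parameter recovery, model discrimination, identifiability."""

import numpy as np
import pandas as pd
import pytest

from allokin import (
    ActivationParameters,
    GeneralModifierRegressor,
    IdentifiabilityError,
    Mechanism,
    NoiseModel,
    RateTable,
    compare_mechanisms,
    fit_mechanism,
    fixtures,
    generate_rate_grid,
    predict_rates,
    rate,
)
from allokin.fitting import _FREE_PARAMS

from conftest import perturbed_starts

NM, UM = 1e-9, 1e-6


@pytest.fixture(scope="module")
def fx():
    return fixtures()


def _rel(a, b):
    return abs(a - b) / abs(b)


OSF_PARAMS = ActivationParameters(
    "ordered_substrate_first", Km=15 * NM, Ka=12 * UM, kcat=0.009, Et=10 * NM, beta=36.0
)
OAF_PARAMS = ActivationParameters(
    "ordered_activator_first", Km=15 * NM, Ka=12 * UM, kcat=0.009, Et=10 * NM,
    alpha=1.0, beta=1.0,  # lumped effective constants; see fitting docstring
)


class TestNoiselessRecovery:
    @pytest.mark.parametrize("preset_name", ["bromoguanine", "deazaguanine"])
    def test_random_mechanism_roundtrip_from_perturbed_starts(self, fx, preset_name):
        """Noiseless generate-then-fit recovers the generating constants to
        well under 0.1% when every start parameter is off by x3 / /3."""
        p = getattr(fx, preset_name)
        doses = getattr(fx, f"{preset_name}_doses")
        table = generate_rate_grid(p, fx.substrate_series, doses, replicates=1)
        starts = perturbed_starts(p, _FREE_PARAMS[Mechanism.RANDOM])
        fr = fit_mechanism(table, "random", starts=starts)
        e = fr.estimates
        for nm in ("V", "Km", "Ka", "alpha", "beta"):
            assert _rel(getattr(e, nm), getattr(p, nm)) < 1e-3
        assert fr.converged

    @pytest.mark.parametrize(
        "params",
        [OSF_PARAMS, OAF_PARAMS],
        ids=["substrate_first", "activator_first"],
    )
    def test_ordered_mechanism_roundtrip(self, fx, params):
        table = generate_rate_grid(
            params, fx.substrate_series, fx.bromoguanine_doses, replicates=1
        )
        starts = perturbed_starts(params, _FREE_PARAMS[params.mechanism])
        fr = fit_mechanism(table, params.mechanism, starts=starts)
        for nm in _FREE_PARAMS[params.mechanism]:
            assert _rel(getattr(fr.estimates, nm), getattr(params, nm)) < 1e-3

    def test_neutral_modifier_data_give_beta_near_one(self, fx):
        p = ActivationParameters(
            "random", Km=15 * NM, Ka=12 * UM, kcat=0.009, Et=10 * NM, alpha=1.0, beta=1.0
        )
        table = generate_rate_grid(p, fx.substrate_series, fx.bromoguanine_doses)
        fr = fit_mechanism(table, "random", n_starts=8, random_state=0)
        assert 0.99 <= fr.estimates.beta <= 1.01

    def test_exactly_determined_grid_interpolates(self, fx):
        """A 2x2 noiseless grid pins the 4-parameter substrate-first law."""
        table = generate_rate_grid(
            OSF_PARAMS, [7.5 * NM, 60 * NM], [2.5 * UM, 20 * UM], replicates=1
        )
        fr = fit_mechanism(
            table, "ordered_substrate_first",
            starts=perturbed_starts(OSF_PARAMS, _FREE_PARAMS[Mechanism.ORDERED_SUBSTRATE_FIRST]),
        )
        assert fr.sse < 1e-12 * float(np.mean(table.rate)) ** 2


class TestPredictRates:
    def test_half_saturation_point(self, fx):
        p = fx.bromoguanine
        t = predict_rates(p, [(p.Km, 0.0), (1e-6, 0.0)])
        assert t.rate[0] == pytest.approx(0.5 * p.V, rel=1e-12)

    def test_monotone_in_activator_for_pure_kcat_activation(self, fx):
        p = ActivationParameters(
            "random", Km=15 * NM, Ka=12 * UM, kcat=0.009, Et=10 * NM, alpha=1.0, beta=36.0
        )
        grid = [(50 * NM, a) for a in np.linspace(0, 50 * UM, 12)]
        assert np.all(np.diff(predict_rates(p, grid).rate) > 0)

    def test_refit_of_predictions_is_self_consistent(self, fx):
        p = fx.bromoguanine
        grid = [(s, a) for s in fx.substrate_series for a in fx.bromoguanine_doses]
        table = predict_rates(p, grid)
        table.Et = p.Et
        fr = fit_mechanism(
            table, "random", starts=perturbed_starts(p, _FREE_PARAMS[Mechanism.RANDOM])
        )
        refit = fit_mechanism(
            predict_rates(fr.estimates, grid), "random",
            starts=perturbed_starts(fr.estimates, _FREE_PARAMS[Mechanism.RANDOM]),
        )
        for nm in ("V", "Km", "Ka", "alpha", "beta"):
            assert _rel(getattr(refit.estimates, nm), getattr(fr.estimates, nm)) < 1e-6


class TestInvariances:
    def test_row_order_and_duplication(self, fx):
        table = generate_rate_grid(
            fx.bromoguanine, fx.substrate_series, fx.bromoguanine_doses,
            noise=NoiseModel("proportional", 0.05, seed=11), replicates=1,
        )
        starts = perturbed_starts(fx.bromoguanine, _FREE_PARAMS[Mechanism.RANDOM], (2.0,))
        fr = fit_mechanism(table, "random", starts=starts)
        shuffled = RateTable(
            table.data.sample(frac=1.0, random_state=5).reset_index(drop=True),
            Et=table.Et,
        )
        fr_shuf = fit_mechanism(shuffled, "random", starts=starts)
        doubled = RateTable(
            pd.concat([table.data, table.data], ignore_index=True), Et=table.Et
        )
        fr_dup = fit_mechanism(doubled, "random", starts=starts)
        for nm in ("V", "Km", "Ka", "alpha", "beta"):
            assert _rel(getattr(fr_shuf.estimates, nm), getattr(fr.estimates, nm)) < 1e-6
            assert _rel(getattr(fr_dup.estimates, nm), getattr(fr.estimates, nm)) < 1e-6
        # duplicating every row tightens the variance estimate, not the fit
        assert fr_dup.standard_errors["Ka"] < fr.standard_errors["Ka"]
        assert fr_dup.sse == pytest.approx(2 * fr.sse, rel=1e-6)


class TestIdentifiability:
    def test_single_activator_concentration_raises(self, fx):
        table = generate_rate_grid(
            fx.bromoguanine, fx.substrate_series, [5 * UM], replicates=1
        )
        with pytest.raises(IdentifiabilityError) as exc:
            fit_mechanism(table, "random")
        assert "Ka" in exc.value.parameters

    def test_single_substrate_concentration_raises(self, fx):
        table = generate_rate_grid(
            fx.bromoguanine, [100 * NM], fx.bromoguanine_doses, replicates=1
        )
        with pytest.raises(IdentifiabilityError) as exc:
            fit_mechanism(table, "random")
        assert "Km" in exc.value.parameters

    def test_single_activator_comparison_is_ambiguous(self, fx):
        table = generate_rate_grid(
            fx.bromoguanine, fx.substrate_series, [5 * UM], replicates=1
        )
        cmp_ = compare_mechanisms(table)
        assert cmp_.ambiguous is True
        assert cmp_.selected is None
        assert set(cmp_.failures) == {"random", "ordered_substrate_first"}


class TestModelDiscrimination:
    def test_random_data_select_random(self, fx):
        table = generate_rate_grid(
            fx.bromoguanine, fx.substrate_series, fx.bromoguanine_doses,
            noise=NoiseModel("proportional", 0.02, seed=0),
        )
        cmp_ = compare_mechanisms(table, n_starts=8, random_state=0)
        assert cmp_.selected == "random"
        assert cmp_.f_test is not None and cmp_.f_test["p_value"] < 0.05

    def test_substrate_first_data_mostly_select_substrate_first(self, fx):
        """Seeded simulation study, 100 replicates at 2% proportional noise.

        The substrate-first scheme is nested in the random one, so AICc
        picks the (true) simpler model only when the extra parameter fails
        to pay its ~2.3-unit penalty — theoretically P(chi2_1 < 2.3) ~ 0.87
        of the time.  Assert a bound consistent with that selection rate,
        and that the F-test rarely rejects the true reduced model."""
        wins = 0
        f_rejections = 0
        for i in range(100):
            table = generate_rate_grid(
                OSF_PARAMS, fx.substrate_series, fx.bromoguanine_doses,
                noise=NoiseModel("proportional", 0.02, seed=50_000 + i),
            )
            cmp_ = compare_mechanisms(table, n_starts=4, random_state=i)
            wins += cmp_.selected == "ordered_substrate_first"
            if cmp_.f_test is not None:
                f_rejections += cmp_.f_test["p_value"] < 0.05
        assert wins >= 80
        assert f_rejections <= 12  # ~5% nominal size, binomial slack

    def test_noisy_replicates_have_small_median_bias(self, fx):
        """At 5% proportional noise the median relative bias of Ka and beta
        across seeded replicates stays below 5%."""
        p = fx.bromoguanine
        ka, beta = [], []
        for i in range(40):
            table = generate_rate_grid(
                p, fx.substrate_series, fx.bromoguanine_doses,
                noise=NoiseModel("proportional", 0.05, seed=60_000 + i),
            )
            fr = fit_mechanism(table, "random", n_starts=4, random_state=i)
            ka.append(fr.estimates.Ka / p.Ka - 1)
            beta.append(fr.estimates.beta / p.beta - 1)
        assert abs(np.median(ka)) < 0.05
        assert abs(np.median(beta)) < 0.05


def test_proportional_weighting_runs_and_recovers_noiseless(fx):
    p = fx.bromoguanine
    table = generate_rate_grid(p, fx.substrate_series, fx.bromoguanine_doses, replicates=1)
    fr = fit_mechanism(
        table, "random", weighting="proportional",
        starts=perturbed_starts(p, _FREE_PARAMS[Mechanism.RANDOM]),
    )
    assert _rel(fr.estimates.Ka, p.Ka) < 1e-3


def test_regressor_sklearn_interface(fx):
    from sklearn.base import clone

    p = fx.bromoguanine
    table = generate_rate_grid(p, fx.substrate_series, fx.bromoguanine_doses, replicates=1)
    est = GeneralModifierRegressor(mechanism="random", n_starts=4, random_state=0, Et=p.Et)
    est2 = clone(est)
    X = np.column_stack([table.S, table.A])
    est2.fit(X, table.rate)
    assert est2.score(X, table.rate) > 0.999
    assert est2.params_.kcat == pytest.approx(p.kcat, rel=1e-3)
    assert est2.get_params()["mechanism"] == "random"
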