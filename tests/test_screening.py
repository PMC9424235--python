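"""Percent-activation normalization, hit calling and Hill dose-response."""

import numpy as np
import pandas as pd
import pytest

from allokin import (
    ControlFailureError,
    HillRegressor,
    NoiseModel,
    call_hits,
    fit_hill,
    fixtures,
    generate_screen_plate,
    hill_response,
    normalize_plate,
    percent_activation,
    rate,
)

UM = 1e-6


class TestPercentActivation:
    @pytest.mark.parametrize(
        "v_sample, v_basal, v_positive, expected",
        [
            (5.0, 1.0, 5.0, 100.0),  # the positive control defines 100%
            (1.0, 1.0, 5.0, 0.0),  # basal defines 0%
            (2.0, 1.0, 5.0, 25.0),
            (9.0, 1.0, 5.0, 200.0),  # super-activators exceed 100%
        ],
    )
    def test_worked_values(self, v_sample, v_basal, v_positive, expected):
        assert percent_activation(v_sample, v_basal, v_positive) == pytest.approx(expected)

    def test_failed_positive_control_rejects_plate(self):
        with pytest.raises(ControlFailureError):
            percent_activation(2.0, 5.0, 5.0)
        with pytest.raises(ControlFailureError):
            percent_activation(2.0, 5.0, 4.0)

    def test_idempotent_on_normalized_values(self):
        vals = np.array([0.0, 20.0, 55.0, 100.0, 130.0])
        assert np.allclose(percent_activation(vals, 0.0, 100.0), vals)

    def test_invariant_to_common_gain_rescaling(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1.0, 5.0, 50)
        a = percent_activation(v, 1.0, 5.0)
        b = percent_activation(7.5 * v, 7.5 * 1.0, 7.5 * 5.0)
        assert np.allclose(a, b)


class TestHitCalling:
    def _records(self, percents):
        return pd.DataFrame(
            {
                "compound_id": [f"C{i}" for i in range(len(percents))],
                "role": "compound",
                "percent_activation": percents,
            }
        )

    def test_threshold_is_strict(self):
        df = call_hits(self._records([19.0, 20.0, 21.0]))
        assert df["is_hit"].tolist() == [False, False, True]

    def test_controls_never_flagged(self):
        df = self._records([150.0, 99.0])
        df.loc[0, "role"] = "positive"
        out = call_hits(df)
        assert out["is_hit"].tolist() == [False, True]

    def test_plate_normalization_uses_control_medians(self):
        plate = pd.DataFrame(
            {
                "role": ["basal"] * 3 + ["positive"] * 3 + ["compound"],
                "compound_id": ["DMSO"] * 3 + ["ref"] * 3 + ["C1"],
                "rate": [1.0, 1.0, 50.0, 5.0, 5.0, 5.1, 3.0],
            }
        )
        out = normalize_plate(plate)  # medians: basal 1.0, positive 5.0
        assert out.loc[6, "percent_activation"] == pytest.approx(50.0)

    def test_planted_actives_are_all_recovered(self):
        """Ten strong planted actives on a noisy plate are all called hits."""
        fx = fixtures()
        ref = fx.bromoguanine

        def strong_active(rng):
            from allokin import ActivationParameters

            return ActivationParameters(
                "random", Km=ref.Km, Ka=2 * UM, kcat=ref.kcat, Et=ref.Et,
                alpha=1.0, beta=36.0,
            )

        plate, truth = generate_screen_plate(
            n_compounds=500,
            hit_fraction=0.02,  # 10 actives
            active_params_sampler=strong_active,
            noise=NoiseModel("proportional", 0.02, seed=4),
            seed=4,
        )
        # the planted compound is a strong activator at the screening dose
        v_active = rate(strong_active(None), fx.screening_substrate, fx.screening_compound_dose)
        v_basal = rate(ref, fx.screening_substrate, 0.0)
        v_pos = rate(ref, fx.screening_substrate, fx.screening_positive_dose)
        assert percent_activation(v_active, v_basal, v_pos) > 40.0
        out = call_hits(normalize_plate(plate))
        called = set(out.loc[out["is_hit"], "compound_id"])
        planted = set(truth.loc[truth["is_active"], "compound_id"])
        assert planted <= called
        assert len(planted) == 10


HILL_TRUE = dict(Emax=100.0, EC50=1 * UM, n=1.0, B=0.0)


class TestHillFit:
    doses = np.array([0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0]) * UM

    def test_noiseless_recovery(self):
        y = hill_response(self.doses, **HILL_TRUE)
        p = fit_hill(self.doses, y)
        assert p.Emax == pytest.approx(100.0, rel=1e-3)
        assert p.EC50 == pytest.approx(1 * UM, rel=1e-3)
        assert p.n == pytest.approx(1.0, rel=1e-3)
        assert abs(p.B) < 0.1
        assert not p.low_confidence

    def test_midpoint_identity_holds_exactly(self):
        """The fitted curve satisfies v(EC50) = (Emax + B)/2 by construction."""
        rng = np.random.default_rng(1)
        y = hill_response(self.doses, 90.0, 2 * UM, 1.5, 5.0) + rng.normal(0, 2, self.doses.size)
        p = fit_hill(self.doses, y)
        v_mid = hill_response(p.EC50, p.Emax, p.EC50, p.n, p.B)
        assert v_mid == pytest.approx((p.Emax + p.B) / 2.0, abs=1e-9)

    @staticmethod
    def _grid_search(doses, y, Emax_g, EC50_g, n_g, B_g):
        best = (np.inf, None)
        for b in B_g:
            resp = hill_response(
                doses[None, None, None, :],
                Emax_g[:, None, None, None],
                EC50_g[None, :, None, None],
                n_g[None, None, :, None],
                b,
            )
            sse = ((resp - y) ** 2).sum(axis=-1)
            i = np.unravel_index(np.argmin(sse), sse.shape)
            if sse[i] < best[0]:
                best = (sse[i], (Emax_g[i[0]], EC50_g[i[1]], n_g[i[2]], b))
        return best

    def test_noisy_fit_matches_grid_search_oracle(self):
        """The optimizer lands within one refined-grid step of an exhaustive
        coarse-then-refined grid search over (Emax, EC50, n, B)."""
        rng = np.random.default_rng(8)
        y = hill_response(self.doses, **HILL_TRUE) + rng.normal(0, 5.0, self.doses.size)
        p = fit_hill(self.doses, y)
        coarse = self._grid_search(
            self.doses, y,
            np.linspace(80, 120, 41),
            np.geomspace(0.2 * UM, 5 * UM, 61),
            np.linspace(0.4, 2.5, 36),
            np.linspace(-20, 20, 41),
        )
        Em_c, EC_c, n_c, B_c = coarse[1]
        fine = self._grid_search(
            self.doses, y,
            np.linspace(Em_c - 3, Em_c + 3, 31),
            np.geomspace(EC_c / 1.3, EC_c * 1.3, 31),
            np.linspace(n_c - 0.15, n_c + 0.15, 31),
            np.linspace(B_c - 3, B_c + 3, 31),
        )
        (Emax_o, EC50_o, n_o, B_o) = fine[1]
        assert p.sse <= fine[0] + 1e-9  # the continuous fit beats the grid
        assert abs(p.Emax - Emax_o) <= 0.2
        assert abs(np.log(p.EC50 / EC50_o)) <= np.log(1.3) / 15
        assert abs(p.n - n_o) <= 0.01
        assert abs(p.B - B_o) <= 0.2

    def test_fit_invariant_to_dose_order(self):
        y = hill_response(self.doses, 80.0, 0.5 * UM, 1.2, 10.0)
        perm = np.random.default_rng(2).permutation(self.doses.size)
        p1 = fit_hill(self.doses, y)
        p2 = fit_hill(self.doses[perm], y[perm])
        assert p1.EC50 == pytest.approx(p2.EC50, rel=1e-8)
        assert p1.Emax == pytest.approx(p2.Emax, rel=1e-8)

    def test_unbracketed_ec50_flagged_low_confidence(self):
        doses = np.array([0.001, 0.002, 0.004, 0.008]) * UM  # far below EC50
        y = hill_response(doses, **HILL_TRUE)
        p = fit_hill(doses, y)
        assert p.low_confidence

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_hill(np.array([1, 1, 2, 3]) * UM, [1.0, 1.0, 2.0, 3.0])

    def test_regressor_predict_roundtrip(self):
        y = hill_response(self.doses, **HILL_TRUE)
        est = HillRegressor(random_state=0).fit(self.doses, y)
        assert np.allclose(est.predict(self.doses), y, rtol=1e-6, atol=1e-8)
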