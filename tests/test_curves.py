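import itertools

import numpy as np
import pandas as pd
import pytest

from traitflow.curves import (
    CurveFitError,
    SamplingCurveModel,
    core_curve,
    fc,
    fit_curve,
    fit_pan,
    fs,
    pan_curve,
    pan_model,
    specific_curve,
)
from traitflow.occurrence import OccurrenceMatrix
from traitflow.synthetic import simulate_curve_data

FIG_CORE = (3000.0, 3.04, 1761.0)
FIG_SPEC = (1234.0, 4.05, 258.0)
FIG_PAN_D = 3634.0


def brute_force_means(presence: pd.DataFrame, kind: str) -> dict[int, float]:
    """Independent subset-enumeration oracle using python sets."""
    genomes = {
        g: {f for f in presence.index if presence.loc[f, g] == 1}
        for g in presence.columns
    }
    out = {}
    for n in range(1, len(genomes) + 1):
        vals = []
        for combo in itertools.combinations(genomes, n):
            sets = [genomes[g] for g in combo]
            if kind == "core":
                vals.append(len(set.intersection(*sets)))
            elif kind == "pan":
                vals.append(len(set.union(*sets)))
            else:  # specific: families in exactly one member, per genome
                count = 0
                for g in combo:
                    others = set.union(*(s for h, s in zip(combo, sets) if h != g)) \
                        if n > 1 else set()
                    count += len(genomes[g] - others)
                vals.append(count / n)
        out[n] = float(np.mean(vals))
    return out


class TestSamplingCurves:
    @pytest.mark.parametrize("kind,builder", [
        ("core", core_curve), ("specific", specific_curve), ("pan", pan_curve),
    ])
    def test_exhaustive_means_match_brute_force(self, toy4, toy4_presence,
                                                kind, builder):
        curve = builder(toy4, max_subsets=1000, seed=0)
        oracle = brute_force_means(toy4_presence, kind)
        for n, mean in curve.means.items():
            assert mean == pytest.approx(oracle[n])

    def test_identical_genomes_share_everything(self):
        presence = pd.DataFrame({"G1": [1, 1, 1], "G2": [1, 1, 1]},
                                index=["a", "b", "c"])
        curve = core_curve(OccurrenceMatrix(presence))
        assert curve.means[2] == 3.0

    def test_disjoint_genomes(self):
        presence = pd.DataFrame({"G1": [1, 1, 0], "G2": [0, 0, 1]},
                                index=["a", "b", "c"])
        m = OccurrenceMatrix(presence)
        spec = specific_curve(m)
        assert spec.means[1] == pytest.approx((2 + 1) / 2)  # a genome alone
        assert spec.means[2] == pytest.approx((2 + 1) / 2)
        assert pan_curve(m).means[2] == 3.0

    def test_monotonicity_and_pan_total(self, random_matrix):
        core = core_curve(random_matrix, max_subsets=50, seed=1)
        pan = pan_curve(random_matrix, max_subsets=50, seed=1)
        cm = [core.means[n] for n in sorted(core.means)]
        pm = [pan.means[n] for n in sorted(pan.means)]
        assert all(a >= b - 1e-9 for a, b in zip(cm, cm[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(pm, pm[1:]))
        assert pan.means[random_matrix.n_genomes] == random_matrix.n_families

    def test_subsampling_converges_to_exhaustive(self, toy4, toy4_presence):
        sub = pan_curve(toy4, max_subsets=6, seed=0)   # C(4,2)=6 exact
        oracle = brute_force_means(toy4_presence, "pan")
        assert sub.means[2] == pytest.approx(oracle[2])
        assert sub.subsets_used[2] == 6

    def test_bad_max_subsets_rejected(self, toy4):
        with pytest.raises(ValueError):
            core_curve(toy4, max_subsets=0)


class TestFitCurve:
    def test_noiseless_core_model_recovered_exactly(self):
        ns = np.arange(1, 14)
        fit = fit_curve((ns, fc(ns, *FIG_CORE)), "Fc")
        for name, true in zip(("Kc", "tau_c", "Omega"), FIG_CORE):
            assert fit.params[name] == pytest.approx(true, rel=1e-6)
        assert float(fit.residuals @ fit.residuals) < 1e-10
        assert fit.r2 == pytest.approx(1.0)

    def test_noiseless_specific_model_recovered_exactly(self):
        ns = np.arange(1, 14)
        fit = fit_curve((ns, fs(ns, *FIG_SPEC)), "Fs")
        for name, true in zip(("Ks", "tau_s", "tg_theta"), FIG_SPEC):
            assert fit.params[name] == pytest.approx(true, rel=1e-6)

    def test_noisy_monte_carlo_recovery_of_asymptote(self):
        omegas = []
        for seed in range(1, 51):
            ns, ys = simulate_curve_data(fc, FIG_CORE, 10.0, range(1, 14), seed)
            omegas.append(fit_curve((ns, ys), "Fc").params["Omega"])
        assert np.mean(omegas) == pytest.approx(FIG_CORE[2], rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_curve(([1, 2, 3], [5.0, 4.0, 3.0]), "Fc")

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            fit_curve(([1, 2, 3, 4], [4.0, 3.0, 2.0, 1.5]), "Pn")


class TestFitPan:
    def test_p1_equals_d(self):
        assert pan_model(1, FIG_PAN_D, *FIG_SPEC) == pytest.approx(FIG_PAN_D)

    def test_increment_identity_matches_fs(self):
        ns = np.arange(2, 14)
        inc = pan_model(ns, FIG_PAN_D, *FIG_SPEC) - pan_model(
            ns - 1, FIG_PAN_D, *FIG_SPEC
        )
        np.testing.assert_allclose(inc, fs(ns, *FIG_SPEC), rtol=1e-12)

    def test_noiseless_d_recovery(self):
        ns = np.arange(1, 14)
        fs_fit = fit_curve((ns, fs(ns, *FIG_SPEC)), "Fs")
        pan_fit = fit_pan((ns, pan_model(ns, FIG_PAN_D, *FIG_SPEC)), fs_fit)
        assert pan_fit.params["D"] == pytest.approx(FIG_PAN_D, rel=1e-6)
        assert pan_fit.r2 == pytest.approx(1.0)

    def test_missing_inherited_params_rejected(self):
        ns = np.arange(1, 14)
        core_fit = fit_curve((ns, fc(ns, *FIG_CORE)), "Fc")
        with pytest.raises(ValueError):
            fit_pan((ns, pan_model(ns, FIG_PAN_D, *FIG_SPEC)), core_fit)


class TestSamplingCurveModel:
    def test_model_results_round_trip(self, random_matrix):
        core = SamplingCurveModel.from_matrix(
            random_matrix, "core", max_subsets=50, seed=2
        )
        res = core.fit()
        assert set(res.params) == {"Kc", "tau_c", "Omega"}
        assert res.rsquared <= 1.0
        assert "Sampling-curve fit" in res.summary()

    def test_pan_model_requires_fs_results(self, random_matrix):
        with pytest.raises(ValueError):
            SamplingCurveModel.from_matrix(random_matrix, "pan")

    def test_pan_chain(self, random_matrix):
        fs_res = SamplingCurveModel.from_matrix(
            random_matrix, "specific", max_subsets=50, seed=2
        ).fit()
        pan_res = SamplingCurveModel.from_matrix(
            random_matrix, "pan", max_subsets=50, seed=2, fs_fit=fs_res.fit
        ).fit()
        assert pan_res.params["Ks"] == fs_res.params["Ks"]
        # fitted pan curve passes near the full-union point
        assert pan_res.predict(13) == pytest.approx(
            random_matrix.n_families, rel=0.15
        )
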