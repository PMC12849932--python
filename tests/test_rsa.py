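import numpy as np
import pytest
from scipy import stats

from reciprsa import rsa, simulate
from reciprsa.design import EfficiencyCondition
from reciprsa.rsa import (
    CONDITION_GRID,
    COGNITIVE_MODELS,
    DegenerateParcelError,
    bh_adjust,
    cognitive_rdm,
    fdr_correct,
    mixed_rsa,
    parcel_rdm,
    rdm_from_vector,
    roi_rsa,
    rsa_parcels,
    vectorize_lower,
    ParcelResult,
)


def cell_index(cond: str, cost: int) -> int:
    return CONDITION_GRID.index((EfficiencyCondition(cond), cost))


class TestConditionGrid:
    def test_27_cells(self):
        assert len(CONDITION_GRID) == 27

    def test_canonical_order(self):
        assert CONDITION_GRID[0] == (EfficiencyCondition.A1S3, 4)
        assert CONDITION_GRID[9] == (EfficiencyCondition.A1S1, 4)
        assert CONDITION_GRID[-1] == (EfficiencyCondition.A3S1, 20)


class TestCognitiveRDM:
    def test_codings_pinned(self):
        assert COGNITIVE_MODELS == {
            "general": (3, 1, 3),
            "altruistic": (1, 1, 3),
            "strategic": (3, 1, 1),
            "linear": (1, 2, 3),
        }

    def test_linear_model_entries(self):
        rdm = cognitive_rdm("linear")
        assert rdm[cell_index("A1S3", 4), cell_index("A3S1", 20)] == 2
        assert rdm[cell_index("A1S3", 4), cell_index("A1S1", 8)] == 1

    def test_general_model_high_conditions_similar(self):
        rdm = cognitive_rdm("general")
        assert rdm[cell_index("A1S3", 4), cell_index("A3S1", 12)] == 0
        assert rdm[cell_index("A1S3", 4), cell_index("A1S1", 12)] == 2

    def test_same_condition_zero_for_every_model(self):
        for model in COGNITIVE_MODELS:
            rdm = cognitive_rdm(model)
            assert rdm[cell_index("A1S1", 4), cell_index("A1S1", 20)] == 0

    def test_symmetric_zero_diagonal(self):
        for model in COGNITIVE_MODELS:
            rdm = cognitive_rdm(model)
            np.testing.assert_array_equal(rdm, rdm.T)
            assert (np.diag(rdm) == 0).all()

    def test_models_mutually_distinct(self):
        vecs = {m: vectorize_lower(cognitive_rdm(m)) for m in COGNITIVE_MODELS}
        names = list(vecs)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                r = np.corrcoef(vecs[a], vecs[b])[0, 1]
                assert r < 1.0 - 1e-9, f"{a} and {b} are collinear"

    def test_binary_mode_proportional_except_linear(self):
        for model in ("general", "altruistic", "strategic"):
            graded = cognitive_rdm(model)
            binary = cognitive_rdm(model, binary=True)
            np.testing.assert_allclose(graded, 2 * binary)
        lin_graded = cognitive_rdm("linear")
        lin_binary = cognitive_rdm("linear", binary=True)
        assert not np.allclose(
            lin_graded / lin_graded.max(), lin_binary
        )

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            cognitive_rdm("quadratic")


class TestParcelRDM:
    def test_identical_patterns_zero(self, rng):
        X = rng.normal(size=(27, 10))
        X[5] = X[3]
        rdm = parcel_rdm(X)
        assert rdm[5, 3] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_patterns_two(self, rng):
        X = rng.normal(size=(27, 10))
        X[7] = -(X[2] - X[2].mean()) + X[2].mean()
        rdm = parcel_rdm(X)
        assert rdm[7, 2] == pytest.approx(2.0)

    def test_bounded_and_symmetric(self, rng):
        rdm = parcel_rdm(rng.normal(size=(27, 8)))
        assert (rdm >= -1e-12).all() and (rdm <= 2 + 1e-12).all()
        np.testing.assert_allclose(rdm, rdm.T)
        assert np.allclose(np.diag(rdm), 0)

    def test_invariant_to_uniform_shift_and_positive_scale(self, rng):
        X = rng.normal(size=(27, 12))
        base = parcel_rdm(X)
        np.testing.assert_allclose(parcel_rdm(X + 7.5), base, atol=1e-10)
        np.testing.assert_allclose(parcel_rdm(X * 3.2), base, atol=1e-10)

    def test_zero_variance_condition_rejected(self, rng):
        X = rng.normal(size=(27, 10))
        X[4] = 2.0
        with pytest.raises(DegenerateParcelError):
            parcel_rdm(X)

    def test_too_few_voxels_rejected(self, rng):
        with pytest.raises(DegenerateParcelError):
            parcel_rdm(rng.normal(size=(27, 2)))

    def test_wrong_cell_count_rejected(self, rng):
        with pytest.raises(ValueError):
            parcel_rdm(rng.normal(size=(26, 10)))


class TestVectorizeLower:
    def test_length_351(self, rng):
        rdm = parcel_rdm(rng.normal(size=(27, 10)))
        assert vectorize_lower(rdm).shape == (351,)

    def test_constant_off_diagonal(self):
        M = np.full((27, 27), 0.7)
        np.fill_diagonal(M, 0.0)
        np.testing.assert_allclose(vectorize_lower(M), 0.7)

    def test_canonical_ordering(self):
        M = np.zeros((27, 27))
        M[2, 1] = M[1, 2] = 5.0
        M[3, 1] = M[1, 3] = 9.0
        v = vectorize_lower(M)
        assert np.flatnonzero(v == 5.0)[0] < np.flatnonzero(v == 9.0)[0]

    def test_roundtrip(self, rng):
        rdm = parcel_rdm(rng.normal(size=(27, 10)))
        np.testing.assert_allclose(
            rdm_from_vector(vectorize_lower(rdm)), rdm
        )

    def test_asymmetric_rejected(self, rng):
        M = rng.normal(size=(27, 27))
        with pytest.raises(ValueError, match="symmetric"):
            vectorize_lower(M)


class TestMixedRSA:
    def test_perfect_fit_slope_one(self):
        x = vectorize_lower(cognitive_rdm("linear"))
        Y = np.tile(x, (4, 1))
        res = mixed_rsa(Y, x)
        assert res.coefficient == pytest.approx(1.0)
        assert res.se == 0.0
        assert res.p_raw == 0.0

    def test_affine_case_absorbed_by_random_intercepts(self):
        x = vectorize_lower(cognitive_rdm("general"))
        offsets = np.array([1.0, -2.0, 5.0, 0.25])
        Y = 2.0 * x[None, :] + offsets[:, None]
        res = mixed_rsa(Y, x)
        assert res.coefficient == pytest.approx(2.0)

    def test_closed_form_matches_reml(self, rng):
        x = vectorize_lower(cognitive_rdm("altruistic"))
        Y = (0.05 * x[None, :] + rng.normal(0, 0.3, size=(6, 1))
             + rng.normal(0, 0.2, size=(6, len(x))))
        cf = mixed_rsa(Y, x, engine="closed_form")
        ml = mixed_rsa(Y, x, engine="reml")
        assert cf.coefficient == pytest.approx(ml.coefficient, abs=1e-8)
        assert cf.se == pytest.approx(ml.se, rel=1e-4)

    def test_constant_model_vector_rejected(self, rng):
        Y = rng.normal(size=(4, 10))
        with pytest.raises(ValueError, match="constant"):
            mixed_rsa(Y, np.ones(10))

    def test_too_few_participants(self, rng):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            mixed_rsa(rng.normal(size=(2, 10)), x)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            mixed_rsa(rng.normal(size=(4, 9)), np.arange(10.0))

    def test_z_and_ci_consistent(self, rng):
        x = vectorize_lower(cognitive_rdm("strategic"))
        Y = 0.1 * x[None, :] + rng.normal(0, 1, size=(8, len(x)))
        res = mixed_rsa(Y, x)
        assert res.z == pytest.approx(res.coefficient / res.se)
        assert res.ci_low < res.coefficient < res.ci_high
        assert res.p_raw == pytest.approx(
            2 * stats.norm.sf(abs(res.z))
        )


class TestFDR:
    def test_all_small_p_all_significant(self):
        results = [
            ParcelResult(i, "general", 0, 1, 0, 0, 0, p_raw=0.001)
            for i in range(200)
        ]
        fdr_correct(results, alpha=0.05)
        assert all(r.significant for r in results)

    def test_single_test_identity(self):
        r = [ParcelResult(0, "m", 0, 1, 0, 0, 0, p_raw=0.03)]
        fdr_correct(r)
        assert r[0].p_fdr == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_adjusted_not_below_raw(self, rng):
        p = rng.uniform(size=30)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


@pytest.fixture(scope="module")
def planted_neural():
    spec = simulate.NeuralGenSpec.for_rsa(
        n_parcels=24, voxels_per_parcel=30, n_signal_per_model=2
    )
    data = simulate.simulate_condition_maps(spec, 25, seed=77)
    return spec, data


class TestRsaParcels:
    def test_planted_parcels_recovered(self, planted_neural):
        spec, data = planted_neural
        res = rsa_parcels(data.maps, data.parcellation)
        for model, planted in spec.signal_parcels.items():
            found = set(
                res.query("model == @model and significant")["parcel_id"]
            )
            own = {p + 1 for p in planted}  # labels are 1-based
            assert own <= found

    def test_noise_parcel_rate_controlled(self, planted_neural):
        spec, data = planted_neural
        res = rsa_parcels(data.maps, data.parcellation)
        planted_all = {
            p + 1 for ps in spec.signal_parcels.values() for p in ps
        }
        noise_hits = res.query("significant")["parcel_id"]
        noise_hits = [p for p in noise_hits if p not in planted_all]
        # 16 noise parcels x 4 models; a handful of hits would indicate
        # broken calibration
        assert len(noise_hits) <= 4

    def test_fdr_applied_per_model(self, planted_neural):
        _, data = planted_neural
        res = rsa_parcels(data.maps, data.parcellation, models=["linear"])
        assert (res["p_fdr"] >= res["p_raw"] - 1e-12).all()
        assert set(res["model"]) == {"linear"}

    def test_degenerate_parcel_skipped(self, planted_neural, caplog):
        _, data = planted_neural
        maps = data.maps.copy()
        maps[:, :, data.parcellation == 5] = 1.0  # constant parcel
        import logging

        with caplog.at_level(logging.WARNING, logger="reciprsa.rsa"):
            res = rsa_parcels(maps, data.parcellation, models=["general"])
        assert 5 not in set(res["parcel_id"])
        assert "skipped" in caplog.text

    def test_shape_validation(self, planted_neural):
        _, data = planted_neural
        with pytest.raises(ValueError):
            rsa_parcels(data.maps[:, :5], data.parcellation)
        with pytest.raises(ValueError):
            rsa_parcels(data.maps, data.parcellation[:-1])


class TestRoiRSA:
    def test_roi_identical_to_parcel(self, planted_neural):
        spec, data = planted_neural
        parcel_label = 1
        mask = data.parcellation == parcel_label
        roi = roi_rsa(data.maps, {"roi": mask}, model="general")
        whole = rsa_parcels(data.maps, data.parcellation, models=["general"])
        row = whole[whole["parcel_id"] == parcel_label].iloc[0]
        assert roi["coefficient"].iloc[0] == pytest.approx(row["coefficient"])
        assert roi["se"].iloc[0] == pytest.approx(row["se"])

    def test_planted_strategic_roi_only(self):
        spec = simulate.NeuralGenSpec.for_rsa(
            n_parcels=24, voxels_per_parcel=30, n_signal_per_model=2
        )
        data = simulate.simulate_condition_maps(spec, 25, seed=5)
        strategic_parcel = spec.signal_parcels["strategic"][0]
        masks = {
            "ventral_striatum": data.parcellation == strategic_parcel + 1,
            # noise parcels as the other striatal fixtures
            "putamen": data.parcellation == 20,
            "caudate": data.parcellation == 21,
            "pallidum": data.parcellation == 22,
        }
        res = roi_rsa(data.maps, masks, model="strategic").set_index(
            "parcel_id"
        )
        assert res.loc["ventral_striatum", "significant"]
        assert not res.loc[["putamen", "caudate", "pallidum"],
                           "significant"].any()

    def test_empty_mask_rejected(self, planted_neural):
        _, data = planted_neural
        with pytest.raises(ValueError, match="empty"):
            roi_rsa(
                data.maps,
                {"vs": np.zeros_like(data.parcellation, bool)},
                model="general",
            )

    def test_tiny_mask_rejected(self, planted_neural):
        _, data = planted_neural
        mask = np.zeros_like(data.parcellation, bool)
        mask[:2] = True
        with pytest.raises(ValueError, match="3 voxels"):
            roi_rsa(data.maps, {"vs": mask}, model="general")
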