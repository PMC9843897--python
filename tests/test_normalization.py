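import numpy as np
import pandas as pd
import pytest

from convexpr.errors import ConfigurationError, ValidationError
from convexpr.normalization import (
    NormalizedMatrix,
    TMMParams,
    coefficient_of_variation,
    filter_low_expressed,
    getmm_normalize,
    rpk,
    tmm_factors,
)


def brute_force_untrimmed_factors(x, ref):
    """Oracle: 2**mean(M) over genes positive in both sample and reference,
    no trimming, no weights, geometric-mean rescaled."""
    lib = x.sum(axis=0)
    factors = []
    for j in range(x.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        ok = (x[:, j] > 0) & (x[:, ref] > 0)
        m = np.log2((x[ok, j] / lib[j]) / (x[ok, ref] / lib[ref]))
        factors.append(2.0 ** np.mean(m))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestFilter:
    def test_single_zero_drops_row(self):
        m = pd.DataFrame(
            {"a1": [5, 0, 3], "a2": [2, 1, 4], "b1": [9, 8, 7], "b2": [1, 1, 1]},
            index=["g1", "g2", "g3"],
        )
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        out = filter_low_expressed(m, species)
        assert list(out.index) == ["g1", "g3"]

    def test_all_positive_retained(self):
        m = pd.DataFrame({"a1": [1, 2], "b1": [3, 4]}, index=["g1", "g2"])
        out = filter_low_expressed(m, {"a1": "A", "b1": "B"})
        assert list(out.index) == ["g1", "g2"]

    def test_empty_matrix(self):
        m = pd.DataFrame(columns=["a1", "b1"])
        assert filter_low_expressed(m, {"a1": "A", "b1": "B"}).empty

    def test_unknown_sample_is_configuration_error(self):
        m = pd.DataFrame({"a1": [1], "zz": [2]})
        with pytest.raises(ConfigurationError):
            filter_low_expressed(m, {"a1": "A"})


class TestRPK:
    def test_arithmetic(self):
        counts = pd.DataFrame({"s1": [500, 0, 7]}, index=["g1", "g2", "g3"])
        out = rpk(counts, [2000, 1500, 1000])
        assert out.loc["g1", "s1"] == 250.0
        assert out.loc["g2", "s1"] == 0.0
        assert out.loc["g3", "s1"] == 7.0  # length 1000 -> identity

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"s1": [1]})
        with pytest.raises(ValidationError):
            rpk(counts, [0])

    def test_matrix_lengths(self):
        counts = pd.DataFrame({"s1": [100], "s2": [100]})
        out = rpk(counts, np.array([[1000, 2000]]))
        assert out.iloc[0, 0] == 100.0
        assert out.iloc[0, 1] == 50.0


class TestTMM:
    def test_identical_samples_unit_factors(self):
        x = np.tile(np.array([[10], [40], [100]]), (1, 2)).astype(float)
        np.testing.assert_allclose(tmm_factors(x), [1.0, 1.0], atol=1e-9)

    def test_doubled_sample_unit_factors(self, rng):
        col = rng.integers(1, 500, size=100).astype(float)
        x = np.column_stack([col, 2 * col])
        np.testing.assert_allclose(tmm_factors(x), [1.0, 1.0], atol=1e-9)

    def test_untrimmed_unweighted_matches_oracle(self, random_counts):
        x = random_counts.to_numpy(dtype=float)
        params = TMMParams(logratio_trim=0.0, abs_trim=0.0,
                           reference_sample="s0", weighted=False)
        got = tmm_factors(random_counts, params)
        np.testing.assert_allclose(got, brute_force_untrimmed_factors(x, 0), atol=1e-12)

    def test_geometric_mean_is_one(self, random_counts):
        f = tmm_factors(random_counts)
        assert abs(np.exp(np.mean(np.log(f))) - 1) < 1e-12

    def test_invariant_to_sample_order(self, random_counts):
        f = tmm_factors(random_counts, TMMParams(reference_sample="s0"))
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        fp = tmm_factors(random_counts[perm], TMMParams(reference_sample="s0"))
        got = pd.Series(fp, index=perm).loc[random_counts.columns].to_numpy()
        np.testing.assert_allclose(got, f, rtol=1e-12)

    def test_all_zero_sample_rejected(self):
        x = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            tmm_factors(x)

    def test_bad_trim_rejected(self):
        with pytest.raises(ValidationError):
            TMMParams(logratio_trim=0.5)


class TestGeTMM:
    def test_identical_samples_identical_columns(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        norm = getmm_normalize(counts, [1000, 2000, 500])
        np.testing.assert_allclose(norm.values["s1"], norm.values["s2"])

    def test_scale_invariance(self, random_counts):
        lengths = np.full(len(random_counts), 1500)
        base = getmm_normalize(random_counts, lengths)
        scaled = random_counts.copy()
        scaled["s2"] = scaled["s2"] * 7
        rescaled = getmm_normalize(scaled, lengths)
        np.testing.assert_allclose(
            rescaled.values["s2"], base.values["s2"], rtol=1e-9
        )

    def test_column_rescaling_leaves_output_unchanged(self, random_counts, rng):
        lengths = rng.integers(500, 3000, size=len(random_counts))
        base = getmm_normalize(random_counts, lengths)
        diag = rng.uniform(0.2, 5.0, size=random_counts.shape[1])
        scaled = random_counts * diag
        out = getmm_normalize(scaled, lengths)
        np.testing.assert_allclose(
            out.values.to_numpy(), base.values.to_numpy(), rtol=1e-9
        )

    def test_normalized_matrix_invariants(self, random_counts):
        norm = getmm_normalize(random_counts, np.full(len(random_counts), 1000))
        assert isinstance(norm, NormalizedMatrix)
        assert (norm.scaling_factors > 0).all()
        assert np.isfinite(norm.values.to_numpy()).all()

    def test_no_de_between_species_log_ratio_centred(self):
        from convexpr.synthetic_data import SimConfig, simulate_counts

        cfg = SimConfig(
            n_species=4, n_genes=800, n_convergent_up=0, n_convergent_down=0,
            effect_log2fc=0.0, species_effect_sd=0.0, seed=21,
        )
        mats, genes, _ = simulate_counts(cfg)
        counts = pd.DataFrame(
            np.hstack([m.counts for m in mats]),
            columns=[s for m in mats for s in m.sample_ids],
        )
        lengths = np.hstack(
            [
                np.tile(
                    np.array([r.length for r in genes[m.species]])[:, None],
                    (1, len(m.sample_ids)),
                )
                for m in mats
            ]
        )
        keep = (counts.to_numpy() > 0).all(axis=1)
        norm = getmm_normalize(counts.loc[keep], lengths[keep])
        sp_means = {
            m.species: norm.values[m.sample_ids].mean(axis=1) for m in mats
        }
        log_ratio = np.log2(sp_means["sp1"] / sp_means["sp3"])
        assert abs(np.median(log_ratio)) < 0.05


class TestCV:
    def test_constant_row_zero(self):
        m = pd.DataFrame([[5, 5, 5, 5]], index=["g"], columns=list("abcd"))
        assert coefficient_of_variation(m).loc["g"] == 0

    def test_two_point_row(self):
        m = pd.DataFrame([[1, 3]], index=["g"], columns=["a", "b"])
        assert coefficient_of_variation(m).loc["g"] == pytest.approx(
            np.sqrt(2) / 2, abs=1e-12
        )

    def test_zero_mean_rows_excluded(self):
        m = pd.DataFrame([[0, 0], [1, 2]], index=["g0", "g1"], columns=["a", "b"])
        cv = coefficient_of_variation(m)
        assert list(cv.index) == ["g1"]
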