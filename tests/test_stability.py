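"""geNorm, comparative dCt, BestKeeper and NormFinder unit behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refstab import (
    DomainError,
    GroupingError,
    InsufficientDataError,
    bestkeeper,
    delta_ct_stability,
    genorm,
    genorm_m_values,
    genorm_pairwise_variation,
    normfinder,
    to_log_quantities,
)
from conftest import matrix_from_rows, random_matrix

M_AC = math.sqrt(11 / 12)  # SD of {0, 1, -1, 1}: hand-computed, = 0.9574...


class TestToLogQuantities:
    def test_doubling_definition(self):
        m = matrix_from_rows({"A": [20, 21, 23], "B": [20, 20, 20], "C": [21, 22, 24]})
        lq = to_log_quantities(m)
        assert lq.logq.loc["A"].tolist() == [0.0, -1.0, -3.0]
        assert lq.logq.loc["B"].tolist() == [0.0, 0.0, 0.0]

    def test_non_doubling_efficiency(self):
        m = matrix_from_rows({"A": [20, 21], "B": [20, 20]})
        lq = to_log_quantities(m, efficiencies={"A": 1.9313})
        assert lq.logq.loc["A", "s2"] == pytest.approx(-math.log2(1.9313))
        assert lq.logq.loc["A", "s2"] == pytest.approx(-0.9496, abs=1e-4)

    def test_anchor_is_per_gene_minimum(self):
        m = random_matrix(np.random.default_rng(0))
        lq = to_log_quantities(m)
        assert np.allclose(lq.logq.max(axis=1), 0.0)
        assert (lq.logq <= 1e-12).all().all()

    def test_bad_efficiency_factor(self):
        m = matrix_from_rows({"A": [20, 21], "B": [20, 20]})
        with pytest.raises(DomainError):
            to_log_quantities(m, efficiencies={"A": 0.9})


class TestGenorm:
    def test_hand_computed_first_pass_m(self, three_gene_lq_matrix):
        # A and B track exactly (V_AB = 0); C wobbles against both with
        # pairwise-difference SD sqrt(11/12) = 0.9574.
        m = genorm_m_values(to_log_quantities(three_gene_lq_matrix))
        assert m["A"] == pytest.approx(M_AC / 2)
        assert m["B"] == pytest.approx(M_AC / 2)
        assert m["C"] == pytest.approx(M_AC)

    def test_removal_order_and_final_pair_tie(self, three_gene_lq_matrix):
        res = genorm(to_log_quantities(three_gene_lq_matrix))
        assert res.details["gene"].tolist() == ["C"]
        assert res.values["C"] == pytest.approx(M_AC)
        assert res.ranks == {"A": 1.5, "B": 1.5, "C": 3.0}

    def test_all_identical_genes_tie_completely(self):
        m = matrix_from_rows({g: [20, 21, 22, 23] for g in "ABCD"})
        res = genorm(to_log_quantities(m))
        assert all(v == 0.0 for v in res.values.values())
        assert set(res.ranks.values()) == {2.5}

    def test_needs_three_genes(self):
        m = matrix_from_rows({"A": [20, 21, 22], "B": [21, 22, 23]})
        with pytest.raises(InsufficientDataError):
            genorm(to_log_quantities(m))

    def test_first_pass_matches_delta_ct_at_common_efficiency(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_matrix(rng, n_genes=6, n_samples=10)
            first_pass = genorm_m_values(to_log_quantities(m))
            dct = delta_ct_stability(m).values
            for g in first_pass:
                assert first_pass[g] == pytest.approx(dct[g], abs=1e-12)


class TestPairwiseVariation:
    def test_sequence_length(self):
        m = random_matrix(np.random.default_rng(3), n_genes=6, n_samples=9)
        pv = genorm_pairwise_variation(to_log_quantities(m))
        assert len(pv.v_values) == 6 - 2

    def test_duplicate_of_constant_shifted_stable_set_gives_zero_v(self):
        # Three noiseless genes differing only by constant shifts, one
        # duplicate of the first, and one noisy outlier: every pair in the
        # stable set has identical logq, so adding the 4th (duplicate)
        # normalization gene changes no factor -> V(3/4) = 0.
        m = matrix_from_rows({
            "A": [20, 21, 22, 23, 24],
            "B": [22, 23, 24, 25, 26],
            "C": [19, 20, 21, 22, 23],
            "D": [20, 21, 22, 23, 24],  # duplicate of A
            "E": [20, 23, 20, 26, 21],  # unstable
        })
        pv = genorm_pairwise_variation(to_log_quantities(m))
        assert set(pv.gene_order[:4]) == {"A", "B", "C", "D"}
        assert pv.v_values[1] == pytest.approx(0.0, abs=1e-12)  # V(3/4)
        assert pv.optimal_n == 2

    def test_matches_geometric_mean_oracle(self):
        # Independent route: back-transform to the linear quantity scale,
        # take true geometric means, and the SD of log2 of their ratio.
        rng = np.random.default_rng(21)
        m = random_matrix(rng, n_genes=5, n_samples=8)
        lq = to_log_quantities(m)
        pv = genorm_pairwise_variation(lq)
        q = np.power(2.0, lq.logq.loc[pv.gene_order])
        for i, n in enumerate(range(2, 5)):
            nf_n = stats.gmean(q.iloc[:n], axis=0)
            nf_n1 = stats.gmean(q.iloc[: n + 1], axis=0)
            expected = np.std(np.log2(nf_n / nf_n1), ddof=1)
            assert pv.v_values[i] == pytest.approx(float(expected), abs=1e-12)


class TestDeltaCt:
    def test_hand_computed(self, three_gene_lq_matrix):
        res = delta_ct_stability(three_gene_lq_matrix)
        assert res.values["A"] == pytest.approx(M_AC / 2)
        assert res.ranks["C"] == 3.0

    def test_constant_shift_pair_has_zero_pair_sd(self):
        m = matrix_from_rows({
            "A": [20, 21, 22], "B": [23, 24, 25], "C": [20, 25, 21],
        })
        res = delta_ct_stability(m)
        # A's only variable partner is C, B's likewise; pair SD(A,B) = 0
        sd_ac = np.std(np.diff([[20, 21, 22], [20, 25, 21]], axis=0), ddof=1)
        assert res.values["A"] == pytest.approx(sd_ac / 2)
        assert res.values["B"] == pytest.approx(sd_ac / 2)

    def test_global_sample_shift_cancels(self):
        m = matrix_from_rows({"A": [20, 21, 22, 24], "B": [22, 21, 25, 23],
                              "C": [19, 23, 21, 22]})
        shifted = matrix_from_rows({
            g: (m.mean_cq.loc[g] + pd.Series([1.0, -2.0, 0.5, 3.0],
                                             index=m.mean_cq.columns)).tolist()
            for g in m.genes
        })
        a = delta_ct_stability(m).values
        b = delta_ct_stability(shifted).values
        for g in a:
            assert a[g] == pytest.approx(b[g], abs=1e-12)


class TestBestKeeper:
    def test_constant_gene_most_stable(self):
        m = matrix_from_rows({"A": [20, 20, 20], "B": [22, 24, 23]})
        res = bestkeeper(m)
        assert res.values["A"] == 0.0
        assert res.ranks["A"] == 1.0
        assert res.details.loc["A", "cv_percent"] == 0.0
        assert not res.details.loc["A", "inconsistent"]

    def test_proportional_genes_correlate_perfectly_with_index(self):
        a = np.array([20.0, 22.0, 24.0, 21.0])
        m = matrix_from_rows({"A": a.tolist(), "B": (1.1 * a).tolist()})
        res = bestkeeper(m)
        index = stats.gmean(np.vstack([a, 1.1 * a]), axis=0)
        assert np.allclose(res.details.attrs["index_values"], index)
        assert res.details.loc["A", "r_vs_index"] == pytest.approx(1.0)
        assert res.details.loc["B", "r_vs_index"] == pytest.approx(1.0)

    def test_matches_direct_evaluation_oracle(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, n_genes=4, n_samples=7)
        res = bestkeeper(m)
        cq = m.mean_cq.to_numpy()
        index = stats.gmean(cq, axis=0)
        for gi, g in enumerate(m.genes):
            sd_plus = np.mean(np.abs(cq[gi] - cq[gi].mean()))
            assert res.values[g] == pytest.approx(float(sd_plus), abs=1e-12)
            r, p = stats.pearsonr(cq[gi], index)
            assert res.details.loc[g, "r_vs_index"] == pytest.approx(float(r))
            assert res.details.loc[g, "p_value"] == pytest.approx(float(p))

    def test_high_dispersion_flagged_inconsistent(self):
        m = matrix_from_rows({"A": [20, 20, 20], "B": [20, 26, 23]})
        res = bestkeeper(m)
        assert bool(res.details.loc["B", "inconsistent"])

    def test_nonpositive_cq_rejected(self):
        m = matrix_from_rows({"A": [0.0, 20, 20], "B": [20, 20, 20]})
        with pytest.raises(DomainError):
            bestkeeper(m)


class TestNormFinder:
    def test_pure_additive_data_scores_zero(self):
        shift = np.array([0.0, 1.5, -0.5, 2.0, 1.0])
        rows = {f"g{i}": (20 + 2 * i + shift).tolist() for i in range(4)}
        res = normfinder(matrix_from_rows(rows))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in res.values.values())

    def test_group_confounded_gene_penalised(self):
        rng = np.random.default_rng(9)
        n = 12
        groups = {f"s{i+1}": ("g1" if i < 6 else "g2") for i in range(n)}
        offset = np.where(np.arange(n) < 6, 1.0, -1.0)
        shift = rng.normal(0, 0.3, n)
        rows = {}
        for i in range(5):
            rows[f"gene{i}"] = (20 + i + shift + rng.normal(0, 0.05, n)).tolist()
        rows["confounded"] = (25 + shift - offset + rng.normal(0, 0.05, n)).tolist()
        res = normfinder(matrix_from_rows(rows, groups=groups), use_groups=True)
        others = [v for g, v in res.values.items() if g != "confounded"]
        assert res.values["confounded"] > max(others)
        assert res.ranks["confounded"] == 6.0

    def test_needs_four_genes(self):
        m = matrix_from_rows({"A": [20, 21, 22], "B": [21, 22, 23],
                              "C": [20, 20, 21]})
        with pytest.raises(InsufficientDataError):
            normfinder(m)

    def test_small_group_rejected_by_name(self):
        groups = {"s1": "big", "s2": "big", "s3": "big", "s4": "tiny"}
        rows = {f"g{i}": [20 + i, 21 + i, 22 + i, 23 + i] for i in range(4)}
        with pytest.raises(GroupingError, match="tiny"):
            normfinder(matrix_from_rows(rows, groups=groups), use_groups=True)

    def test_incomplete_matrix_rejected(self):
        rows = {
            "g0": [20.0, 21.0, 22.0, None],
            "g1": [21.0, 22.0, 23.0, 24.0],
            "g2": [20.0, 20.5, 21.0, 21.5],
            "g3": [23.0, 24.0, 22.0, 25.0],
        }
        m = matrix_from_rows(rows)
        with pytest.raises(InsufficientDataError, match="complete"):
            normfinder(m)
        # after dropping incomplete samples it runs
        res = normfinder(m.complete_subset())
        assert len(res.values) == 4

    def test_variance_reconstruction_and_unbiasedness(self):
        # The estimator inverts E[u_g] = (1 - 2/k) sigma_g^2 + sum sigma^2
        # / k^2.  Where the zero-truncation is inactive (noise SDs well
        # above the estimator's own sampling noise) the inversion is an
        # exact algebraic identity, and the variance estimates are
        # unbiased for sigma_g^2 (Monte Carlo at 3 SE per gene).
        rng = np.random.default_rng(17)
        k, n, reps = 6, 100, 500
        true_sd = np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        var_hats = np.empty((reps, k))
        for rep in range(reps):
            y = rng.normal(0, 1, n)[None, :] + rng.normal(0, 1, (k, n)) * true_sd[:, None]
            resid = (y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True)
                     + y.mean())
            u = (resid**2).sum(1) / (n - 1)
            rows = {f"g{i}": (20 + y[i]).tolist() for i in range(k)}
            res = normfinder(matrix_from_rows(rows))
            var_hat = np.array([res.values[f"g{i}"] ** 2 for i in range(k)])
            # exact reconstruction of the raw mean squares, per replicate
            u_implied = (1 - 2 / k) * var_hat + var_hat.sum() / k**2
            assert np.allclose(u_implied.sum(), u.sum(), atol=1e-9)
            var_hats[rep] = var_hat
        mean = var_hats.mean(axis=0)
        se = var_hats.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean - true_sd**2) < 3 * se)
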