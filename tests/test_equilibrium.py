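"""Mutational profile, stationary solve, and its inference machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atskew import (
    MutationCounts,
    SnpRecord,
    age_class_randomization,
    bootstrap_ci,
    equilibrium,
    equilibrium_at_skew,
    expected_false_positive_snps,
    filter_singletons,
    infer_composition,
    leave_k_out,
    rates_from_counts,
)


def power_iteration_stationary(rates, tol=1e-14, max_iter=2_000_000):
    """Independent oracle: stationary distribution as the long-run limit of
    the discrete chain I + eps*Q, by repeated left-multiplication."""
    R = np.asarray(rates, dtype=float)
    Q = R.copy()
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    eps = 0.5 / max(abs(np.diag(Q)).max(), 1e-300)
    P = np.eye(4) + eps * Q
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        nxt = f @ P
        nxt /= nxt.sum()
        if np.abs(nxt - f).max() < tol:
            return nxt
        f = nxt
    return f


class TestCountsAndRates:
    def test_counts_from_pairs_total(self, tw20_counts):
        assert tw20_counts.total == 140
        pairs = tw20_counts.to_pairs()
        assert pairs["AG"] == 31 and pairs["TC"] == 21 and pairs["CG"] == 0

    def test_singleton_filter_drops_multiplicity(self):
        snps = [
            SnpRecord(10, "A", "G", 1, "intergenic_ex", "leading"),
            SnpRecord(20, "A", "G", 2, "intergenic_ex", "leading"),
            SnpRecord(30, "C", "T", 1, "codon3", "leading"),
        ]
        counts = filter_singletons(snps, context="intergenic_ex")
        assert counts.total == 1 and counts.to_pairs()["AG"] == 1

    def test_lagging_snps_complemented_onto_leading_strand(self):
        snps = [SnpRecord(10, "A", "G", 1, "intergenic_ex", "lagging")]
        counts = filter_singletons(snps)
        assert counts.to_pairs()["TC"] == 1

    def test_empty_input_gives_zero_counts(self):
        assert filter_singletons([]).total == 0

    @pytest.mark.parametrize(
        "pair,printed",
        [("AG", 6.59462e-4), ("TA", 1.79965e-4), ("CT", 1.67602e-3), ("TG", 4.49913e-5)],
    )
    def test_rates_reproduce_printed_values(self, tw20_counts, tw20_composition, pair, printed):
        from atskew.genome import BASE_INDEX

        r = rates_from_counts(tw20_counts, tw20_composition)
        assert r[BASE_INDEX[pair[0]], BASE_INDEX[pair[1]]] == pytest.approx(printed, rel=1e-4)

    def test_zero_composition_with_counts_rejected(self):
        counts = MutationCounts.from_pairs({"AG": 5})
        with pytest.raises(ValueError):
            rates_from_counts(counts, [0.0, 100.0, 100.0, 100.0])


class TestInferComposition:
    def test_recovers_published_site_counts(self, tw20_counts, tw20_rates):
        N = infer_composition(tw20_counts, tw20_rates)
        assert N.tolist() == [47008, 13723, 18778, 44453]  # A, C, G, T

    def test_total_magnitude(self, tw20_counts, tw20_rates):
        assert infer_composition(tw20_counts, tw20_rates).sum() == pytest.approx(1.24e5, rel=0.01)

    def test_exact_inversion_of_synthetic_counts(self):
        N = np.array([5000.0, 2000.0, 3000.0, 4000.0])
        counts = MutationCounts.from_pairs({"AG": 50, "AT": 25, "CA": 20, "GA": 30, "GT": 15, "TA": 40, "TC": 8})
        r = rates_from_counts(counts, N)
        assert (infer_composition(counts, r) == N).all()

    def test_inconsistent_table_rejected(self):
        counts = MutationCounts.from_pairs({"AG": 50, "AT": 25})
        rates = np.zeros((4, 4))
        rates[0, 2] = 50 / 5000.0
        rates[0, 3] = 25 / 9000.0  # implies a different N_A
        with pytest.raises(ValueError, match="inconsistent"):
            infer_composition(counts, rates)


class TestEquilibrium:
    def test_published_rate_matrix(self, tw20_rates):
        f = equilibrium(tw20_rates)
        assert np.round(f, 4).tolist() == [0.2257, 0.1319, 0.0931, 0.5493]  # A, C, G, T
        assert equilibrium_at_skew(f) == pytest.approx(-0.4176, abs=5e-5)

    def test_equal_rates_give_uniform(self):
        r = np.full((4, 4), 0.001)
        np.fill_diagonal(r, 0.0)
        assert equilibrium(r) == pytest.approx(np.full(4, 0.25))

    def test_scale_invariance(self, tw20_rates):
        assert equilibrium(17.3 * tw20_rates) == pytest.approx(equilibrium(tw20_rates))

    def test_stationarity_residual(self, tw20_rates):
        f = equilibrium(tw20_rates)
        loss = f * tw20_rates.sum(axis=1)
        gain = f @ tw20_rates
        assert np.abs(loss - gain).max() < 1e-10

    def test_strand_complementarity(self, tw20_counts, tw20_composition):
        """Complementing counts and composition mirrors the skew exactly."""
        comp_counts = tw20_counts.complement()
        comp_N = np.asarray(tw20_composition)[[3, 2, 1, 0]]
        sk_lead = equilibrium_at_skew(equilibrium(rates_from_counts(tw20_counts, tw20_composition)))
        sk_lag = equilibrium_at_skew(equilibrium(rates_from_counts(comp_counts, comp_N)))
        assert sk_lag == pytest.approx(-sk_lead)
        assert sk_lag == pytest.approx(0.4176, abs=5e-5)

    def test_absorbing_base_warns_not_crashes(self, caplog):
        r = np.zeros((4, 4))
        r[0, 1] = 1e-3  # A -> C, C has no outflow: C absorbs
        with caplog.at_level("WARNING"):
            f = equilibrium(r)
        assert f[1] == pytest.approx(1.0)
        assert "absorbing" in caplog.text

    def test_reducible_matrix_rejected(self):
        r = np.zeros((4, 4))
        r[0, 3] = r[3, 0] = 1e-3  # A<->T and C<->G: two closed classes
        r[1, 2] = r[2, 1] = 1e-3
        with pytest.raises(ValueError, match="reducible"):
            equilibrium(r)

    def test_untouched_bases_carry_no_mass(self):
        r = np.zeros((4, 4))
        r[0, 3] = r[3, 0] = 1e-3  # only A<->T ever observed
        f = equilibrium(r)
        assert f[1] == f[2] == 0.0
        assert f[0] == pytest.approx(0.5) and f[3] == pytest.approx(0.5)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000_000))
    def test_matches_power_iteration_oracle(self, seed):
        """On random strictly positive rate matrices the null-space solve and
        a long-run power-iteration oracle agree."""
        rng = np.random.default_rng(seed)
        r = rng.uniform(0.05, 1.0, size=(4, 4)) * 1e-3
        np.fill_diagonal(r, 0.0)
        f = equilibrium(r)
        oracle = power_iteration_stationary(r)
        assert np.abs(f - oracle).max() < 1e-8


class TestBootstrap:
    def test_ci_matches_published_interval(self, tw20_counts, tw20_composition):
        for seed in (1, 2, 3):
            res = bootstrap_ci(tw20_counts, tw20_composition, B=1000, seed=seed)
            assert res.ci_low == pytest.approx(-0.6792, abs=0.05)
            assert res.ci_high == pytest.approx(-0.1522, abs=0.05)
            assert res.at_skew == pytest.approx(-0.4176, abs=5e-5)

    def test_single_replicate_degenerate(self, tw20_counts, tw20_composition):
        res = bootstrap_ci(tw20_counts, tw20_composition, B=1, seed=0)
        assert res.ci_low == res.ci_high == res.bootstrap_skews[0]

    def test_concentrated_counts_have_zero_width(self):
        counts = MutationCounts.from_pairs({"AT": 30})
        res = bootstrap_ci(counts, [100.0, 100.0, 100.0, 100.0], B=50, seed=0)
        assert res.ci_low == res.ci_high == pytest.approx(-1.0)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(MutationCounts(np.zeros((4, 4))), [1.0] * 4, B=10)


class TestLeaveKOut:
    def test_zero_removals_reproduce_point_estimate(self, tw20_counts, tw20_composition):
        skews = leave_k_out(tw20_counts, tw20_composition, k=0, sims=20, seed=0)
        point = equilibrium_at_skew(equilibrium(rates_from_counts(tw20_counts, tw20_composition)))
        assert skews == pytest.approx(np.full(20, point))

    def test_k_at_least_total_rejected(self, tw20_composition):
        counts = MutationCounts.from_pairs({"AG": 2})
        with pytest.raises(ValueError):
            leave_k_out(counts, tw20_composition, k=2, sims=10)

    def test_sampled_extremes_within_exhaustive_envelope(self, tw20_counts, tw20_composition):
        """Brute-force oracle: enumerate every distinct 3-SNP removal multiset
        and check the sampled extremes lie inside the exhaustive extremes."""
        import itertools

        flat = tw20_counts.matrix.flatten()
        N = np.asarray(tw20_composition, dtype=float)
        vals = []
        offdiag = [i for i in range(16) if i % 5 != 0]
        for combo in itertools.combinations_with_replacement(offdiag, 3):
            removal = np.bincount(np.array(combo), minlength=16)
            if (flat < removal).any():
                continue
            rates = (flat - removal).reshape(4, 4) / N[:, None]
            vals.append(equilibrium_at_skew(equilibrium(rates, warn_absorbing=False)))
        vals = np.array(vals)
        sampled = leave_k_out(tw20_counts, tw20_composition, k=3, sims=1000, seed=5)
        assert vals.min() - 1e-12 <= sampled.min()
        assert sampled.max() <= vals.max() + 1e-12
        assert (vals < 0).all() and (sampled < 0).all()


class TestAgeClassRandomization:
    def test_p_value_formula(self):
        from atskew import randomization_pvalue

        assert randomization_pvalue(12, 2000) == pytest.approx(13 / 2001)
        assert round(randomization_pvalue(12, 2000), 4) == 0.0065

    def test_identical_groups_never_significant(self, tw20_counts, tw20_composition):
        res = age_class_randomization(tw20_counts, tw20_counts, tw20_composition, n_sims=500, seed=3)
        assert res.observed_difference == pytest.approx(0.0)
        assert res.P > 0.5  # observed 0 can never beat the null draws

    def test_type_one_error_calibrated_under_null(self, tw20_composition):
        """Two groups drawn from one mutation process should rarely test
        significant: the P distribution is roughly uniform."""
        rng = np.random.default_rng(8)
        base = MutationCounts.from_pairs(
            {"AG": 30, "GA": 12, "GT": 20, "TA": 9, "TC": 20, "TG": 3, "AC": 4, "CA": 7, "AT": 12, "CT": 23}
        )
        p = base.matrix.flatten() / base.total
        pvals = []
        for rep in range(20):
            young = MutationCounts(rng.multinomial(140, p).reshape(4, 4))
            old = MutationCounts(rng.multinomial(54, p).reshape(4, 4))
            res = age_class_randomization(young, old, tw20_composition, n_sims=200, seed=rep)
            pvals.append(res.P)
        assert np.mean(np.array(pvals) < 0.05) <= 0.25
        assert np.median(pvals) > 0.15

    def test_empty_group_rejected(self, tw20_counts, tw20_composition):
        with pytest.raises(ValueError):
            age_class_randomization(tw20_counts, MutationCounts(np.zeros((4, 4))), tw20_composition)


def test_false_positive_expectation():
    from atskew.datasets import (
        TW20_CHROMOSOME_LENGTH,
        TW20_EX_OPERONIC_BASES,
        TW20_N_GENOMES,
    )

    expected = expected_false_positive_snps(
        TW20_EX_OPERONIC_BASES, TW20_CHROMOSOME_LENGTH, TW20_N_GENOMES
    )
    assert round(expected, 2) == 2.55
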