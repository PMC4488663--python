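"""The sum(-log10 p) statistic, permutation null, empirical p and m_eff."""

import numpy as np
import pytest

from permgsa import selfcontained as sc
from permgsa import simulate
from permgsa.datatypes import PanelSpec, PermutationNull, SetSNPList, TraitSpec

from conftest import make_dataset


def eq1_oracle(real_stat, null_stats):
    """Literal loop count of the tie-inclusive empirical p-value."""
    count = 0
    for s in null_stats:
        if s >= real_stat:
            count += 1
    return count / len(null_stats)


class TestSumNeglog10:
    def test_known_values(self):
        assert sc.sum_neglog10([1.0, 1.0]) == 0.0
        assert sc.sum_neglog10([0.1]) == pytest.approx(1.0)
        assert sc.sum_neglog10([0.05, 0.5]) == pytest.approx(1.60206, abs=1e-5)

    def test_empty_gives_zero(self):
        assert sc.sum_neglog10([]) == 0.0

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.1]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            sc.sum_neglog10(bad)

    def test_p_of_one_is_neutral(self, rng):
        pvals = rng.uniform(0.01, 1, size=10)
        assert sc.sum_neglog10(pvals) == pytest.approx(
            sc.sum_neglog10(list(pvals) + [1.0]))


class TestPermutePhenotype:
    def test_multiset_preserved(self, rng):
        y = rng.standard_normal(100)
        perm = sc.permute_phenotype(y, rng)
        assert np.array_equal(np.sort(perm), np.sort(y))

    def test_seeded_reproducibility(self):
        y = np.arange(1000.0)
        a = sc.permute_phenotype(y, 42)
        b = sc.permute_phenotype(y, 42)
        c = sc.permute_phenotype(y, 43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sc.permute_phenotype([1.0], 0)


class TestEmpiricalP:
    def test_tie_counts_toward_numerator(self):
        null = PermutationNull("s", [2.0, 1.0, 3.0], m_obs=1)
        assert sc.empirical_p_selfcontained(2.0, null) == pytest.approx(2 / 3)

    def test_edges(self):
        null = PermutationNull("s", [1.0, 2.0, 3.0], m_obs=1)
        assert sc.empirical_p_selfcontained(10.0, null) == 0.0
        assert sc.empirical_p_selfcontained(0.5, null) == 1.0

    def test_matches_loop_oracle_exactly(self, rng):
        """Exact agreement with a literal loop on 1000 random small nulls,
        tie cases planted."""
        for _ in range(1000):
            k = int(rng.integers(1, 11))
            null_stats = np.round(rng.uniform(0, 5, size=k), 1)
            real = float(rng.choice(np.r_[null_stats, rng.uniform(0, 5, size=3)]))
            null = PermutationNull("s", null_stats, m_obs=1)
            assert sc.empirical_p_selfcontained(real, null) == eq1_oracle(real, null_stats)

    def test_values_quantized_to_k_over_n(self, rng):
        nperms = 37
        null = PermutationNull("s", rng.uniform(0, 5, nperms), m_obs=3)
        for real in rng.uniform(0, 5, size=20):
            p = sc.empirical_p_selfcontained(real, null)
            assert (p * nperms) == pytest.approx(round(p * nperms))

    def test_smoothed_estimator_never_zero(self):
        null = PermutationNull("s", [1.0, 2.0], m_obs=1)
        assert sc.empirical_p_selfcontained(10.0, null, smoothed=True) == pytest.approx(1 / 3)

    def test_empty_null_rejected(self):
        null = PermutationNull("s", [], m_obs=1)
        with pytest.raises(ValueError):
            sc.empirical_p_selfcontained(1.0, null)


def _null_with_variance(target_var, nperms, rng):
    """A vector whose sample variance (ddof=1) is exactly target_var."""
    x = rng.standard_normal(nperms)
    x = (x - x.mean()) / x.std(ddof=1) * np.sqrt(target_var)
    return x - x.min()  # keep entries non-negative


class TestEffectiveSnps:
    def test_independence_identity(self, rng):
        m_obs = 40
        null = PermutationNull("s", _null_with_variance(sc.VAR_COEF * m_obs, 500, rng), m_obs)
        assert sc.effective_snps(null) == pytest.approx(m_obs, rel=1e-9)

    def test_double_variance_halves_m_eff(self, rng):
        m_obs = 40
        null = PermutationNull("s", _null_with_variance(2 * sc.VAR_COEF * m_obs, 500, rng), m_obs)
        assert sc.effective_snps(null) == pytest.approx(20.0, rel=1e-9)

    def test_duplicated_snps_monte_carlo(self, rng):
        """20 independent uniform p-values duplicated (m_obs = 40, perfect
        pairwise LD): duplication doubles each -log10 p, quadrupling the
        variance, so m_eff recovers about 20."""
        draws = 5000
        p = rng.uniform(size=(draws, 20))
        sums = (-np.log10(p)).sum(axis=1) * 2.0
        null = PermutationNull("dup", sums, m_obs=40)
        assert sc.effective_snps(null) == pytest.approx(20.0, rel=0.10)

    def test_zero_variance_is_error(self):
        null = PermutationNull("s", np.ones(100), m_obs=5)
        with pytest.raises(ValueError, match="degenerate"):
            sc.effective_snps(null)

    def test_few_permutations_warns(self, rng, caplog):
        null = PermutationNull("s", rng.uniform(1, 2, size=10), m_obs=2)
        with caplog.at_level("WARNING", logger="permgsa.selfcontained"):
            sc.effective_snps(null)
        assert any("unstable" in r.message for r in caplog.records)

    @pytest.mark.parametrize("m", [10, 50, 200])
    def test_variance_law_for_independent_pvalues(self, m):
        """Sample variance of sum(-log10 U_i) over M independent uniforms is
        0.189 M (within Monte-Carlo tolerance)."""
        rng = np.random.default_rng(m)
        sums = (-np.log10(rng.uniform(size=(8000, m)))).sum(axis=1)
        assert np.var(sums, ddof=1) == pytest.approx(sc.VAR_COEF * m, rel=0.05)

    def test_m_eff_decreases_with_engineered_ld(self, rng):
        """Duplicating SNP columns progressively shrinks m_eff/m_obs."""
        draws, base = 4000, 24
        p = rng.uniform(size=(draws, base))
        ratios = []
        for reps in (1, 2, 4):
            sums = (-np.log10(p)).sum(axis=1) * reps
            null = PermutationNull("x", sums, m_obs=base * reps)
            ratios.append(sc.effective_snps(null) / (base * reps))
        assert ratios[0] > ratios[1] > ratios[2]


class TestQQPoints:
    def test_single_point_uses_half(self):
        ((exp, obs),) = sc.qq_points([0.5])
        assert exp == pytest.approx(-np.log10(0.5))
        assert obs == pytest.approx(-np.log10(0.5))

    def test_monotone_in_both_coordinates(self, rng):
        pts = sc.qq_points(rng.uniform(size=200))
        exps, obss = zip(*pts)
        assert all(a >= b for a, b in zip(exps, exps[1:]))
        assert all(a >= b for a, b in zip(obss, obss[1:]))

    def test_uniform_sample_tracks_diagonal(self, rng):
        pts = np.array(sc.qq_points(rng.uniform(size=1000)))
        # drop the extreme tail where -log10 quantiles are noisy
        body = pts[20:]
        assert np.abs(body[:, 0] - body[:, 1]).max() < 0.35

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.qq_points([])


def _sets_from_blocks(data, snps_per_set):
    ids = list(data.snps["snp_id"])
    out = []
    for k in range(0, len(ids) - snps_per_set + 1, snps_per_set):
        out.append(SetSNPList(set_name=f"S{k}", snp_ids=ids[k:k + snps_per_set],
                              n_genes_mapped=1))
    return out


class TestRunSelfcontained:
    def test_nperms_zero_rejected(self, small_quantitative):
        sets = _sets_from_blocks(small_quantitative, 3)
        with pytest.raises(ValueError):
            sc.run_selfcontained(small_quantitative, sets, nperms=0)

    def test_reproducible_from_seed(self, small_quantitative):
        sets = _sets_from_blocks(small_quantitative, 3)
        a = sc.run_selfcontained(small_quantitative, sets, 50, rng_seed=9)
        b = sc.run_selfcontained(small_quantitative, sets, 50, rng_seed=9)
        for (ra, na), (rb, nb) in zip(a, b):
            assert ra.p_self == rb.p_self and ra.statistic == rb.statistic
            assert np.array_equal(na.null_stats, nb.null_stats)

    def test_null_calibration_band(self):
        """Null data, 200 sets, 1000 permutations: the fraction of
        p_self < 0.05 falls in the 95% binomial band [0.02, 0.09]."""
        rng = np.random.default_rng(7)
        G = rng.integers(0, 3, size=(300, 400)).astype(np.int8)
        y = rng.standard_normal(300)
        data = make_dataset(G, y)
        sets = _sets_from_blocks(data, 2)  # 200 disjoint sets
        res = sc.run_selfcontained(data, sets, nperms=1000, rng_seed=11)
        frac = np.mean([r.p_self < 0.05 for r, _ in res])
        assert 0.02 <= frac <= 0.09

    def test_planted_signal_detected(self):
        """5 causal SNPs at 1% variance each, n=1000: median p_self over
        20 seeds is below 0.05."""
        pvals = []
        for seed in range(20):
            panel = PanelSpec(n_samples=1000, n_blocks=10, snps_per_block=2,
                              rng_seed=seed)
            data = simulate.simulate_genotypes(panel)
            causal = tuple(f"snp{i:05d}" for i in range(5))
            y = simulate.simulate_phenotype(
                data, TraitSpec(kind="quantitative", causal_snps=causal,
                                variance_explained_per_snp=0.01), rng_seed=100 + seed)
            data = simulate.with_phenotype(data, y, binary=False)
            sets = [SetSNPList(set_name="causal", snp_ids=list(causal), n_genes_mapped=5)]
            ((r, _),) = sc.run_selfcontained(data, sets, nperms=200, rng_seed=seed)
            pvals.append(r.p_self)
        assert np.median(pvals) < 0.05

    def test_empty_set_flagged(self, small_quantitative):
        data = small_quantitative
        data.genotypes[:, 0] = 2  # constant -> undefined everywhere
        sets = [SetSNPList(set_name="empty", snp_ids=["rs0"], n_genes_mapped=1)]
        ((r, _),) = sc.run_selfcontained(data, sets, nperms=20)
        assert r.p_self is None and r.m_obs == 0


class TestReferenceNull:
    def test_independent_reference_recovers_m_obs(self):
        rng = np.random.default_rng(5)
        G = rng.integers(0, 3, size=(400, 30)).astype(np.int8)
        ref = make_dataset(G)
        sets = [SetSNPList(set_name="all", snp_ids=[f"rs{i}" for i in range(30)],
                           n_genes_mapped=30)]
        nulls = sc.null_from_reference(ref, sets, nperms=1500, rng_seed=3)
        null, covered = nulls["all"]
        m_eff = sc.effective_snps(null)
        assert len(covered) == 30
        assert abs(m_eff / null.m_obs - 1.0) < 0.15

    def test_uncovered_snps_dropped_and_sets_excluded(self, rng, caplog):
        G = rng.integers(0, 3, size=(50, 4)).astype(np.int8)
        ref = make_dataset(G)
        sets = [
            SetSNPList(set_name="ok", snp_ids=["rs0", "rs1", "rsX"], n_genes_mapped=1),
            SetSNPList(set_name="gone", snp_ids=["rsX", "rsY", "rsZ"], n_genes_mapped=1),
        ]
        with caplog.at_level("WARNING", logger="permgsa.selfcontained"):
            nulls = sc.null_from_reference(ref, sets, nperms=30, rng_seed=0)
        assert set(nulls) == {"ok"}
        assert nulls["ok"][1] == ["rs0", "rs1"]

    def test_summary_pvalues_all_one_gives_p_one(self, rng):
        G = rng.integers(0, 3, size=(80, 6)).astype(np.int8)
        ref = make_dataset(G)
        sets = [SetSNPList(set_name="s", snp_ids=[f"rs{i}" for i in range(6)],
                           n_genes_mapped=2)]
        summary = {f"rs{i}": 1.0 for i in range(6)}
        ((r, _),) = sc.run_selfcontained_summary(summary, ref, sets, nperms=100, rng_seed=1)
        assert r.statistic == 0.0
        assert r.p_self == 1.0

    def test_summary_mode_consistent_with_raw(self):
        """Raw-genotype and summary-statistics modes agree on the same
        panel within Monte-Carlo error of the empirical p-value."""
        diffs = []
        for seed in range(10):
            r = np.random.default_rng(200 + seed)
            G = r.integers(0, 3, size=(250, 20)).astype(np.int8)
            y = r.standard_normal(250)
            data = make_dataset(G, y)
            sets = [SetSNPList(set_name="s", snp_ids=[f"rs{i}" for i in range(20)],
                               n_genes_mapped=4)]
            nperms = 400
            ((raw, _),) = sc.run_selfcontained(data, sets, nperms, rng_seed=seed)
            from permgsa.association import test_all_snps
            summary = dict(test_all_snps(data, model="linear").pvalues)
            ((summ, _),) = sc.run_selfcontained_summary(summary, data, sets, nperms,
                                                        rng_seed=900 + seed)
            diffs.append(raw.p_self - summ.p_self)
        se = np.sqrt(0.5 * 0.5 * 2 / 400)  # conservative MC error of one difference
        assert abs(np.mean(diffs)) < 2 * se
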