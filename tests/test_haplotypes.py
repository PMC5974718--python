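"""EM haplotype frequencies against a brute-force likelihood oracle, dosage
conservation, and the haplotype regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import softmax

from deltafst import (
    MISSING,
    em_frequencies,
    haplotype_dosages,
    haplotype_glm,
)
from deltafst.haplotypes import _compatible_pairs

from conftest import make_panel


# -- independent oracle: direct maximisation of the multinomial likelihood ----


def brute_force_frequencies(genotypes):
    """Maximise the phase-marginal likelihood over the frequency simplex.

    Independent of the EM path: enumerates compatible pairs per individual
    and optimises a softmax-parametrised simplex from many random starts.
    """
    pair_lists = [_compatible_pairs(np.asarray(g)) for g in genotypes]
    universe = {}
    for pairs in pair_lists:
        for h1, h2 in pairs:
            for h in (h1, h2):
                universe.setdefault(h, len(universe))
    idx_pairs = [[(universe[a], universe[b]) for a, b in pairs]
                 for pairs in pair_lists]
    n_hap = len(universe)

    def nll(theta):
        f = softmax(theta)
        total = 0.0
        for pairs in idx_pairs:
            s = sum((2.0 if a != b else 1.0) * f[a] * f[b] for a, b in pairs)
            total -= np.log(max(s, 1e-300))
        return total

    rng = np.random.default_rng(99)
    best = None
    for start in [np.zeros(n_hap)] + [rng.normal(0, 2, n_hap)
                                      for _ in range(15)]:
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10,
                                "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    freqs = softmax(best.x)
    return {h: freqs[i] for h, i in universe.items()}


def em_as_dict(hs):
    """EM frequencies keyed by 0/1 haplotype tuples for comparison."""
    out = {}
    for hap, f in zip(hs.haplotypes, hs.frequencies):
        key = tuple(1 if c in "BG" else 0 for c in hap)
        out[key] = f
    return out


class TestEmFrequencies:
    def test_all_homozygous_is_direct_counting(self):
        calls = np.array([[0, 0, 0]] * 6 + [[2, 2, 2]] * 4)
        hs = em_frequencies(make_panel(calls), ["m0", "m1", "m2"])
        freqs = dict(zip(hs.haplotypes, hs.frequencies))
        assert freqs["AAA"] == pytest.approx(0.6, abs=1e-9)
        assert freqs["GGG"] == pytest.approx(0.4, abs=1e-9)
        assert hs.n_iter <= 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_likelihood_oracle(self, seed):
        rng = np.random.default_rng(seed)
        true_haps = np.array([[0, 0, 0], [1, 0, 1], [1, 1, 1], [0, 1, 0]])
        p = rng.dirichlet([2, 2, 2, 2])
        draws = rng.choice(4, size=(20, 2), p=p)
        genotypes = true_haps[draws[:, 0]] + true_haps[draws[:, 1]]
        hs = em_frequencies(make_panel(genotypes), ["m0", "m1", "m2"],
                            tol=1e-10)
        oracle = brute_force_frequencies(genotypes)
        mine = em_as_dict(hs)
        for h, f in oracle.items():
            assert mine.get(h, 0.0) == pytest.approx(f, abs=1e-3)

    def test_log_likelihood_non_decreasing(self, rng):
        calls = rng.binomial(2, rng.uniform(0.2, 0.8, 5), (40, 5))
        hs = em_frequencies(make_panel(calls), [f"m{j}" for j in range(5)])
        ll = np.array(hs.log_likelihood)
        assert (np.diff(ll) >= -1e-9).all()

    def test_invariant_to_individual_ordering(self, rng):
        calls = rng.binomial(2, 0.5, (30, 4))
        panel = make_panel(calls)
        perm = rng.permutation(30)
        shuffled = panel.subset_samples(perm)
        a = em_as_dict(em_frequencies(panel, panel.marker_ids))
        b = em_as_dict(em_frequencies(shuffled, panel.marker_ids))
        for h in set(a) | set(b):
            assert a.get(h, 0) == pytest.approx(b.get(h, 0), abs=1e-6)

    def test_missing_individuals_excluded(self, rng):
        calls = rng.binomial(2, 0.5, (10, 3)).astype(np.int8)
        calls[3, 1] = MISSING
        hs = em_frequencies(make_panel(calls), ["m0", "m1", "m2"])
        assert hs.excluded_sample_ids == ["s3"]
        assert len(hs.sample_ids) == 9

    def test_window_size_bound(self, rng):
        calls = rng.binomial(2, 0.5, (5, 13))
        with pytest.raises(ValueError, match="enumeration bound"):
            em_frequencies(make_panel(calls), [f"m{j}" for j in range(13)])

    def test_published_pool_recovered_at_study_scale(self, rng):
        """7-SNP truth pool (0.34/0.33/0.19/0.12) recovered within +-0.04
        from 400 unphased genotypes."""
        from deltafst import LdBlockSpec
        blk = LdBlockSpec()
        site_alleles = blk.site_alleles()
        hap_mat = np.array(
            [[1 if h[s] == site_alleles[s][1] else 0 for s in range(7)]
             for h in blk.haplotypes]
        )
        p = np.array(blk.frequencies) / np.sum(blk.frequencies)
        draws = rng.choice(4, size=(400, 2), p=p)
        calls = hap_mat[draws[:, 0]] + hap_mat[draws[:, 1]]
        hs = em_frequencies(make_panel(calls), [f"m{j}" for j in range(7)])
        est = em_as_dict(hs)
        for row, truth in zip(hap_mat, p):
            assert est.get(tuple(row), 0.0) == pytest.approx(truth, abs=0.04)


class TestHaplotypeDosages:
    def test_double_homozygote_unambiguous(self):
        calls = np.array([[0, 0], [2, 2], [0, 0]])
        hs = em_frequencies(make_panel(calls), ["m0", "m1"])
        dos = haplotype_dosages(hs)
        assert dos.loc["s0", "AA"] == pytest.approx(2.0)
        assert dos.loc["s0", "GG"] == pytest.approx(0.0)

    def test_symmetric_double_het_splits_evenly(self):
        # balanced pool: the lone double het resolves 50/50 over both phases
        calls = np.array([[1, 1]] + [[0, 0]] * 5 + [[2, 2]] * 5
                         + [[0, 2]] * 5 + [[2, 0]] * 5)
        hs = em_frequencies(make_panel(calls), ["m0", "m1"])
        dos = haplotype_dosages(hs)
        row = dos.loc["s0"]
        assert np.allclose(sorted(row), [0.5, 0.5, 0.5, 0.5], atol=1e-6)

    def test_dosages_sum_to_two(self, rng):
        calls = rng.binomial(2, rng.uniform(0.2, 0.8, 6), (50, 6))
        hs = em_frequencies(make_panel(calls), [f"m{j}" for j in range(6)])
        dos = haplotype_dosages(hs)
        assert np.allclose(dos.sum(axis=1), 2.0, atol=1e-8)


def simulate_hap_trait(rng, n=400, effect=-0.4):
    """Two-SNP four-haplotype panel and a trait hit by one haplotype."""
    haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    p = np.array([0.4, 0.3, 0.2, 0.1])
    draws = rng.choice(4, size=(n, 2), p=p)
    calls = haps[draws[:, 0]] + haps[draws[:, 1]]
    target_count = (draws == 2).sum(axis=1)  # copies of haplotype GA
    covs = pd.DataFrame(
        {
            "sex": rng.choice(["mare", "gelding"], n),
            "age": rng.integers(6, 15, n),
            "country": rng.choice(["SE", "NO"], n, p=[0.8, 0.2]),
            "dmrt3": rng.choice(["AA", "CA", "CC"], n, p=[0.36, 0.48, 0.16]),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    y = (
        0.25 * (covs["sex"] == "mare").to_numpy()
        + 0.04 * (covs["age"].to_numpy() - 10)
        + effect * target_count
        + rng.normal(size=n)
    )
    trait = pd.Series(y, index=covs.index, name="trait")
    return make_panel(calls), trait, covs


class TestHaplotypeGlm:
    def test_base_is_most_frequent(self, rng):
        panel, trait, covs = simulate_hap_trait(rng)
        hs = em_frequencies(panel, ["m0", "m1"])
        out = haplotype_glm(trait, hs, covs)
        base = out[out.is_base]
        assert len(base) == 1
        assert base["frequency"].iloc[0] == out["frequency"].max()

    def test_deleterious_haplotype_sign_recovered(self, rng):
        negative = 0
        n_rep = 30
        for _ in range(n_rep):
            panel, trait, covs = simulate_hap_trait(rng, effect=-0.4)
            hs = em_frequencies(panel, ["m0", "m1"])
            out = haplotype_glm(trait, hs, covs)
            coef = out.loc[out.haplotype == "GA", "coefficient"]
            negative += (len(coef) == 1) and (coef.iloc[0] < 0)
        assert negative >= 0.95 * n_rep

    def test_null_haplotype_type_i_error(self, rng):
        hits = total = 0
        for _ in range(40):
            panel, trait, covs = simulate_hap_trait(rng, effect=0.0)
            hs = em_frequencies(panel, ["m0", "m1"])
            out = haplotype_glm(trait, hs, covs)
            pv = out.loc[~out.is_base, "p_value"]
            hits += (pv < 0.05).sum()
            total += len(pv)
        assert hits / total <= 0.10

    def test_rare_haplotypes_not_modeled(self, rng):
        panel, trait, covs = simulate_hap_trait(rng, n=500)
        hs = em_frequencies(panel, ["m0", "m1"], rare_threshold=0.25)
        out = haplotype_glm(trait, hs, covs)
        assert (out["frequency"] >= 0.25).all()
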