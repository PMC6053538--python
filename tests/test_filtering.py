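"""Calling rules, filtering cascade, HWE exact test, FDR, LD pruning."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import standkin as sk
from standkin.filtering import FilterConfig, hwe_exact_sites, subset_sites


def _sites(m, scaffold="sc1", spacing=100):
    return pd.DataFrame(
        {
            "scaffold": [scaffold] * m,
            "pos": np.arange(m) * spacing,
            "ref": ["A"] * m,
            "alt": ["C"] * m,
        }
    )


def _gm(codes, scaffolds=None, positions=None):
    codes = np.asarray(codes, dtype=float)
    n, m = codes.shape
    sites = _sites(m)
    if scaffolds is not None:
        sites["scaffold"] = scaffolds
    if positions is not None:
        sites["pos"] = positions
    return sk.GenotypeMatrix(codes, [f"s{i}" for i in range(n)], sites)


class TestCalling:
    @pytest.mark.parametrize(
        "depth,alt,expected",
        [
            (9, 4, np.nan),  # below depth threshold -> missing
            (20, 10, 0.0),  # 50% -> het
            (20, 5, -1.0),  # 25% < 30% -> reference homozygote
            (20, 6, 0.0),  # exactly 30% -> het (inclusive boundary)
            (20, 14, 0.0),  # exactly 70% -> het
            (20, 15, 1.0),  # 75% -> alternate homozygote
            (10, 0, -1.0),
        ],
    )
    def test_threshold_rules(self, depth, alt, expected):
        tab = sk.SiteCallTable(
            depth=np.array([[depth]]), alt_reads=np.array([[alt]]), samples=["s0"], sites=_sites(1)
        )
        got = sk.call_genotypes(tab).codes[0, 0]
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_het_fraction_at_depth_ten(self):
        """At depth exactly 10 with no error, the fraction of heterozygous
        calls among true hets equals the binomial two-tail mass
        P(3 <= Bin(10, 0.5) <= 7) = 0.890625 (enumeration oracle)."""
        exact = sum(comb(10, k) for k in range(3, 8)) / 2**10
        assert exact == 0.890625
        rng = np.random.default_rng(0)
        m = 40000
        alt = rng.binomial(10, 0.5, size=(1, m))
        tab = sk.SiteCallTable(
            depth=np.full((1, m), 10), alt_reads=alt, samples=["s0"], sites=_sites(m)
        )
        called = sk.call_genotypes(tab).codes
        assert abs((called == 0.0).mean() - exact) < 0.005

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            sk.SiteCallTable(
                depth=np.array([[5]]), alt_reads=np.array([[6]]), samples=["s0"], sites=_sites(1)
            )


class TestPolymorphism:
    def test_all_hom_ref(self):
        assert not sk.polymorphic_sites(_gm([[-1], [-1], [-1]]))[0]

    def test_single_het(self):
        codes = np.full((300, 1), -1.0)
        codes[17, 0] = 0.0
        assert sk.polymorphic_sites(_gm(codes))[0]

    def test_hom_only_difference_is_not_snp(self):
        # literal rule: both homozygote classes present but no het
        assert not sk.polymorphic_sites(_gm([[-1], [1], [-1], [1]]))[0]


class TestSampleSiteFilters:
    def test_sample_missingness_boundary(self):
        rng = np.random.default_rng(1)
        m = 100
        fractions = [0.0, 0.10, 0.19, 0.20, 0.21, 0.50]
        codes = np.zeros((len(fractions), m))
        for i, f in enumerate(fractions):
            codes[i, : int(f * m)] = np.nan
        g = sk.filter_samples(_gm(codes))
        assert g.samples == ["s0", "s1", "s2", "s3"]  # > 0.20 removed, 0.20 kept

    def test_site_callrate_and_anchoring(self):
        codes = np.zeros((100, 3))
        codes[:6, 0] = np.nan  # call rate 0.94 -> removed
        g = _gm(codes, scaffolds=["sc1", "sc1", "scX"])
        out = sk.filter_sites(g, {"sc1": True, "scX": False})
        # column 0 fails call rate, column 2 unanchored despite full calls
        assert out.m == 1 and out.sites.iloc[0]["scaffold"] == "sc1"

    def test_survivors_match_recount(self):
        rng = np.random.default_rng(2)
        codes = rng.choice([-1.0, 0.0, 1.0], size=(40, 200))
        mask = rng.random((40, 200)) < rng.uniform(0, 0.4, size=(40, 1))
        codes[mask] = np.nan
        g = _gm(codes)
        out = sk.filter_samples(g)
        expected = [i for i in range(40) if np.isnan(codes[i]).mean() <= 0.20]
        assert out.samples == [f"s{i}" for i in expected]
        out2 = sk.filter_sites(out)
        surv = ~np.isnan(out.codes)
        expected_sites = np.flatnonzero(surv.mean(axis=0) >= 0.95)
        np.testing.assert_array_equal(out2.sites.index.to_numpy(), np.arange(len(expected_sites)))
        assert out2.m == len(expected_sites)


def hwe_oracle(naa, nab, nbb):
    """Independent exact-rational full enumeration of the conditional
    heterozygote-count distribution."""
    n = naa + nab + nbb
    na = 2 * naa + nab
    rare = min(na, 2 * n - na)
    probs, tot = {}, Fraction(0)
    for h in range(rare % 2, rare + 1, 2):
        nr = (rare - h) // 2
        w = Fraction(2) ** h * comb(n, h) * comb(n - h, nr)
        probs[h] = w
        tot += w
    p_obs = probs[nab] / tot
    return float(sum(v / tot for v in probs.values() if v / tot <= p_obs))


class TestHWE:
    def test_no_data_errors(self):
        with pytest.raises(ValueError):
            sk.hwe_exact(0, 0, 0)

    def test_most_probable_configuration(self):
        assert sk.hwe_exact(25, 50, 25) > 0.99

    @pytest.mark.parametrize(
        "counts",
        [(3, 5, 2), (10, 1, 10), (50, 21, 29), (0, 3, 97), (1469, 138, 5), (7, 0, 7), (40, 100, 60)],
    )
    def test_matches_full_enumeration(self, counts):
        assert sk.hwe_exact(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-9)

    def test_uniform_conservative_under_null(self):
        """Under a simulated Hardy-Weinberg null, P(p <= alpha) <= alpha
        (plus Monte-Carlo slack) across alpha levels."""
        rng = np.random.default_rng(5)
        n, m = 100, 10000
        p = rng.uniform(0.1, 0.9, m)
        probs = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
        pvals = np.empty(m)
        for j in range(m):
            counts = rng.multinomial(n, probs[j])
            pvals[j] = sk.hwe_exact(*counts)
        for alpha in (0.01, 0.05, 0.10, 0.25):
            assert (pvals <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / m)


class TestFDR:
    def test_stepup_hand_example(self):
        np.testing.assert_allclose(
            sk.fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(sk.fdr_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_unchanged(self):
        assert sk.fdr_adjust([0.3])[0] == pytest.approx(0.3)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=50),
        st.randoms(use_true_random=False),
    )
    def test_order_invariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        adjusted = sk.fdr_adjust(p)
        adjusted_perm = sk.fdr_adjust(p[perm])
        np.testing.assert_allclose(adjusted[perm], adjusted_perm, rtol=1e-12)


class TestLDPrune:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(3)
        col = rng.choice([-1.0, 0.0, 1.0], size=(30, 1))
        g = _gm(np.hstack([col, col]))
        keep = sk.ld_prune(g, mode="r2-window")
        np.testing.assert_array_equal(keep, [True, False])

    def test_independent_columns_mostly_kept(self):
        rng = np.random.default_rng(4)
        codes = rng.choice([-1.0, 0.0, 1.0], size=(500, 200), p=[0.25, 0.5, 0.25])
        keep = sk.ld_prune(_gm(codes), mode="r2-window")
        assert keep.mean() >= 0.95

    def test_spacing_greedy(self):
        codes = np.zeros((4, 4))
        codes[0] = [-1, 1, -1, 1]
        g = _gm(codes, positions=[0, 500, 1000, 2600])
        keep = sk.ld_prune(g, mode="spacing")
        np.testing.assert_array_equal(keep, [True, False, True, True])

    def test_unsorted_positions_rejected(self):
        g = _gm(np.zeros((3, 3)), positions=[10, 5, 20])
        with pytest.raises(ValueError):
            sk.ld_prune(g, mode="spacing")

    def test_window_limit(self):
        """Correlated pair farther apart than the marker window survives."""
        rng = np.random.default_rng(6)
        col = rng.choice([-1.0, 0.0, 1.0], size=(40, 1))
        filler = rng.choice([-1.0, 0.0, 1.0], size=(40, 60))
        codes = np.hstack([col, filler, col])
        cfg = FilterConfig(ld_window=50)
        keep = sk.ld_prune(_gm(codes), cfg, mode="r2-window")
        assert keep[0] and keep[-1]


class TestMafTier:
    def test_boundary_strictly_greater(self):
        codes = np.full((100, 1), -1.0)
        codes[:2, 0] = 0.0  # 2 het of 100 -> maf 0.01 exactly
        assert not sk.maf_tier(_gm(codes), 0.01)[0]
        assert sk.maf_tier(_gm(codes), 0.009)[0]

    def test_monomorphic_fails_all_tiers(self):
        g = _gm(np.full((10, 1), 1.0))
        for t in FilterConfig().maf_tiers:
            assert not sk.maf_tier(g, t)[0]

    def test_recount_oracle(self):
        rng = np.random.default_rng(7)
        codes = rng.choice([-1.0, 0.0, 1.0], size=(60, 300))
        codes[rng.random(codes.shape) < 0.1] = np.nan
        g = _gm(codes)
        mask = sk.maf_tier(g, 0.1)
        for j in rng.choice(300, 40, replace=False):
            col = codes[:, j]
            col = col[~np.isnan(col)]
            p = (col + 1).sum() / (2 * len(col))
            assert mask[j] == (min(p, 1 - p) > 0.1)


class TestCascade:
    def test_stages_only_remove(self):
        rng = np.random.default_rng(8)
        ped = sk.build_pedigree(20, 20, {}, seed=1)
        f = sk.simulate_species_freqs(300, 0.05, seed=2)
        g = sk.drop_genotypes(ped, f, seed=3)
        rc = sk.simulate_read_counts(g, mean_depth=40, dropout=0.05, seed=4)
        out, stages = sk.filtering.apply_filter_cascade(rc, None)
        counts = stages["sites"].to_numpy()
        assert (np.diff(counts) <= 0).all()
        assert stages["samples"].is_monotonic_decreasing
        # surviving calls are identical to the originally called values
        called = sk.call_genotypes(rc)
        kept_sites = out.sites["pos"].to_numpy()
        orig_idx = {p: j for j, p in enumerate(called.sites["pos"])}
        sample_idx = [called.samples.index(s) for s in out.samples]
        for jj, p in enumerate(kept_sites[::7]):
            col_new = out.codes[:, list(kept_sites).index(p)]
            col_old = called.codes[sample_idx, orig_idx[p]]
            np.testing.assert_array_equal(np.isnan(col_new), np.isnan(col_old))
            np.testing.assert_array_equal(col_new[~np.isnan(col_new)], col_old[~np.isnan(col_old)])
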