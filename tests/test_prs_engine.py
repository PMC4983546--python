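from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from polycomorb import prs_engine
from polycomorb.prs_engine import (
    ClumpParams,
    QcThresholds,
    clump,
    compute_variant_stats,
    harmonize,
    hwe_exact_p,
    qc_filter,
    score,
)
from polycomorb.synthetic_cohort import MISSING


# ---------------------------------------------------------------------------
# oracles


def hwe_oracle(n_hom_a, n_het, n_hom_b):
    """Exact-rational full enumeration of the conditional HWE distribution."""
    n = n_hom_a + n_het + n_hom_b
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het

    def weight(h):
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        return Fraction(
            2**h * factorial(n), factorial(a) * factorial(h) * factorial(b)
        )

    hs = [h for h in range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2)]
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def clump_oracle(df, r2, params):
    """Literal greedy procedure on an explicit r^2 matrix."""
    remaining = df.sort_values(
        ["pvalue", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    pos = {r.id: (r.chrom, r.pos) for r in remaining.itertuples()}
    alive = list(remaining["id"])
    index = []
    while alive:
        lead = alive.pop(0)
        index.append(lead)
        lc, lp = pos[lead]
        survivors = []
        for v in alive:
            c, p = pos[v]
            if (
                c == lc
                and abs(p - lp) <= params.window_kb * 1000
                and r2.loc[lead, v] >= params.r2_threshold
            ):
                continue
            survivors.append(v)
        alive = survivors
    return index


# ---------------------------------------------------------------------------
# HWE exact test


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(25, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 7) == 1.0

    def test_single_het_is_one(self):
        assert hwe_exact_p(0, 1, 0) == 1.0

    def test_enumeration_example(self):
        assert hwe_exact_p(3, 5, 2) == pytest.approx(
            hwe_oracle(3, 5, 2), abs=1e-12
        )

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)

    def test_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, h, b = rng.integers(0, 40, 3)
            if a + h + b == 0:
                continue
            p = hwe_exact_p(int(a), int(h), int(b))
            assert 0 < p <= 1

    def test_matches_oracle_moderate_grid(self):
        # exhaustive totals <= 50 run in the acceptance suite; spot-check a
        # coarser grid here
        for a in range(0, 16, 3):
            for h in range(0, 16, 3):
                for b in range(0, 16, 3):
                    if a + h + b == 0:
                        continue
                    assert hwe_exact_p(a, h, b) == pytest.approx(
                        hwe_oracle(a, h, b), abs=1e-12
                    )

    def test_large_counts_no_overflow(self):
        p = hwe_exact_p(500, 1000, 600)
        assert 0 < p <= 1


# ---------------------------------------------------------------------------
# QC


def stats_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "pos", "a1", "a2", "call_rate", "maf", "hwe_p"],
    )


class TestQcFilter:
    def test_maf_boundary_is_strict(self):
        stats = stats_frame(
            [("v1", 1, 100, "A", "G", 1.0, 0.02, 1.0),
             ("v2", 1, 200, "A", "G", 1.0, 0.021, 1.0)]
        )
        assert qc_filter(stats) == ["v2"]

    def test_mhc_exclusion(self):
        stats = stats_frame(
            [("v1", 6, 30_000_000, "A", "G", 1.0, 0.3, 1.0),
             ("v2", 6, 24_999_999, "A", "G", 1.0, 0.3, 1.0),
             ("v3", 6, 35_000_001, "A", "G", 1.0, 0.3, 1.0),
             ("v4", 5, 30_000_000, "A", "G", 1.0, 0.3, 1.0)]
        )
        assert qc_filter(stats) == ["v2", "v3", "v4"]

    def test_hand_audited_fixture(self):
        # ten variants; one deliberate failure per rule, four failures total
        rows = [
            ("ok1", 1, 100, "A", "G", 1.00, 0.30, 0.9),
            ("low_maf", 1, 200, "A", "G", 1.00, 0.01, 0.9),
            ("ok2", 2, 300, "C", "T", 0.99, 0.25, 0.5),
            ("low_call", 2, 400, "C", "T", 0.97, 0.25, 0.5),
            ("ok3", 3, 500, "A", "G", 1.00, 0.45, 1.0),
            ("bad_hwe", 3, 600, "A", "G", 1.00, 0.45, 1e-7),
            ("ok4", 6, 10_000, "A", "G", 1.00, 0.10, 0.8),
            ("in_mhc", 6, 26_000_000, "A", "G", 1.00, 0.10, 0.8),
            ("ok5", 7, 700, "C", "T", 0.99, 0.05, 0.3),
            ("ok6", 8, 800, "C", "T", 1.00, 0.50, 0.2),
        ]
        stats = stats_frame(rows)
        survivors = qc_filter(stats)
        # independent row-by-row audit
        expected = []
        for r in rows:
            _, chrom, pos, _, _, cr, maf, hwe = r
            if maf > 0.02 and cr > 0.98 and hwe > 1e-6 and not (
                chrom == 6 and 25_000_000 <= pos <= 35_000_000
            ):
                expected.append(r[0])
        assert survivors == expected
        assert len(survivors) == 6

    def test_empty_output_allowed(self):
        stats = stats_frame([("v1", 1, 100, "A", "G", 0.5, 0.3, 1.0)])
        assert qc_filter(stats) == []

    def test_custom_thresholds(self):
        stats = stats_frame([("v1", 1, 100, "A", "G", 1.0, 0.04, 1.0)])
        assert qc_filter(stats, QcThresholds(maf_min=0.05)) == []


class TestComputeVariantStats:
    def test_known_counts(self):
        variants = pd.DataFrame(
            {"id": ["v1"], "chrom": [1], "pos": [100], "a1": ["A"], "a2": ["G"]}
        )
        dosages = np.array([[0], [1], [1], [2], [MISSING]], dtype=np.int8)
        stats = compute_variant_stats(variants, dosages)
        assert stats.loc[0, "call_rate"] == pytest.approx(0.8)
        # 4 called: hom_b=1, het=2, hom_a=1 -> freq a1 = 4/8 = 0.5
        assert stats.loc[0, "freq_a1"] == pytest.approx(0.5)
        assert stats.loc[0, "maf"] == pytest.approx(0.5)
        assert stats.loc[0, "hwe_p"] == pytest.approx(
            hwe_oracle(1, 2, 1), abs=1e-12
        )


# ---------------------------------------------------------------------------
# harmonization


def target_variants(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "a1", "a2"])


def sumstats_row(vid, ea, oa, beta=0.5, p=0.01):
    return {
        "id": vid, "chrom": 1, "pos": 100, "effect_allele": ea,
        "other_allele": oa, "beta": beta, "pvalue": p,
    }


class TestHarmonize:
    def test_direct_match_keeps_beta(self):
        ss = pd.DataFrame([sumstats_row("v1", "A", "G")])
        tv = target_variants([("v1", 1, 100, "A", "G")])
        out = harmonize(ss, tv)
        assert out.loc[0, "beta"] == 0.5

    def test_swap_negates_beta(self):
        ss = pd.DataFrame([sumstats_row("v1", "A", "G")])
        tv = target_variants([("v1", 1, 100, "G", "A")])
        out = harmonize(ss, tv)
        assert out.loc[0, "beta"] == -0.5

    def test_complement_match_keeps_beta(self):
        ss = pd.DataFrame([sumstats_row("v1", "A", "G")])
        tv = target_variants([("v1", 1, 100, "T", "C")])
        out = harmonize(ss, tv)
        assert out.loc[0, "beta"] == 0.5

    def test_complement_swap_negates_beta(self):
        ss = pd.DataFrame([sumstats_row("v1", "A", "G")])
        tv = target_variants([("v1", 1, 100, "C", "T")])
        out = harmonize(ss, tv)
        assert out.loc[0, "beta"] == -0.5

    def test_ambiguous_pairs_dropped(self):
        ss = pd.DataFrame(
            [sumstats_row("v1", "A", "T"), sumstats_row("v2", "C", "G")]
        )
        tv = target_variants(
            [("v1", 1, 100, "A", "T"), ("v2", 1, 200, "C", "G")]
        )
        assert len(harmonize(ss, tv)) == 0

    def test_unresolvable_pairs_dropped(self):
        ss = pd.DataFrame([sumstats_row("v1", "A", "G")])
        tv = target_variants([("v1", 1, 100, "A", "C")])
        assert len(harmonize(ss, tv)) == 0

    def test_duplicate_ids_error(self):
        ss = pd.DataFrame(
            [sumstats_row("v1", "A", "G"), sumstats_row("v1", "A", "G")]
        )
        tv = target_variants([("v1", 1, 100, "A", "G")])
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(ss, tv)

    def test_restricted_to_shared_variants(self):
        ss = pd.DataFrame([sumstats_row("v1", "A", "G"),
                           sumstats_row("v9", "A", "G")])
        tv = target_variants([("v1", 1, 100, "A", "G")])
        out = harmonize(ss, tv)
        assert list(out["id"]) == ["v1"]


# ---------------------------------------------------------------------------
# clumping


def ld_block(n, m, r, rng, maf=0.3):
    """Equicorrelated-copula dosage block for clump tests."""
    q = np.full(m, maf)
    from scipy.stats import norm

    thr = norm.ppf(q)
    dos = np.zeros((n, m), dtype=np.int8)
    for _ in range(2):
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.standard_normal((n, m))
        dos += (z < thr).astype(np.int8)
    return dos


class TestClump:
    def make_frame(self, ids, chroms, pos, pvals):
        return pd.DataFrame(
            {"id": ids, "chrom": chroms, "pos": pos,
             "beta": np.zeros(len(ids)), "pvalue": pvals}
        ), pd.DataFrame(
            {"id": ids, "chrom": chroms, "pos": pos,
             "a1": "A", "a2": "G"}
        )

    def test_independent_snps_all_index(self, rng):
        m = 8
        ss, tv = self.make_frame(
            [f"v{i}" for i in range(m)], [1] * m,
            np.arange(m) * 10_000 + 1, rng.uniform(0, 1, m),
        )
        dosages = rng.integers(0, 3, size=(4000, m)).astype(np.int8)
        out = clump(ss, tv, dosages)
        assert sorted(out) == sorted(ss["id"])

    def test_single_block_vs_oracle(self, rng):
        m = 5
        dosages = ld_block(800, m, 0.9, rng)
        ss, tv = self.make_frame(
            [f"v{i}" for i in range(m)], [1] * m,
            np.arange(m) * 1_000 + 1, [0.5, 0.01, 0.2, 0.9, 0.05],
        )
        r2 = pd.DataFrame(
            np.corrcoef(dosages.T.astype(float)) ** 2,
            index=ss["id"], columns=ss["id"],
        )
        params = ClumpParams()
        assert clump(ss, tv, dosages, params) == clump_oracle(ss, r2, params)

    def test_window_excludes_distant_pair(self, rng):
        # identical genotypes (r^2 = 1) but 600 kb apart: both retained
        x = rng.integers(0, 3, size=(500, 1)).astype(np.int8)
        dosages = np.hstack([x, x])
        ss, tv = self.make_frame(
            ["v0", "v1"], [1, 1], [1, 600_001], [0.01, 0.5]
        )
        out = clump(ss, tv, dosages)
        assert sorted(out) == ["v0", "v1"]

    def test_window_absorbs_near_pair(self, rng):
        x = rng.integers(0, 3, size=(500, 1)).astype(np.int8)
        dosages = np.hstack([x, x])
        ss, tv = self.make_frame(
            ["v0", "v1"], [1, 1], [1, 400_001], [0.01, 0.5]
        )
        assert clump(ss, tv, dosages) == ["v0"]

    def test_row_order_invariance(self, rng):
        m = 10
        dosages = ld_block(600, m, 0.8, rng)
        pv = rng.uniform(0, 1, m)
        ss, tv = self.make_frame(
            [f"v{i}" for i in range(m)], [1] * m,
            np.arange(m) * 2_000 + 1, pv,
        )
        out1 = clump(ss, tv, dosages)
        shuffled = ss.sample(frac=1, random_state=3).reset_index(drop=True)
        out2 = clump(shuffled, tv, dosages)
        assert out1 == out2

    def test_monomorphic_never_clumped(self, rng):
        x = rng.integers(0, 3, size=(300, 1)).astype(np.int8)
        mono = np.ones((300, 1), dtype=np.int8)
        dosages = np.hstack([x, mono])
        ss, tv = self.make_frame(["v0", "v1"], [1, 1], [1, 101], [0.01, 0.5])
        assert sorted(clump(ss, tv, dosages)) == ["v0", "v1"]

    def test_missing_variant_errors(self, rng):
        ss, tv = self.make_frame(["v0"], [1], [1], [0.5])
        tv2 = tv.copy()
        tv2["id"] = ["other"]
        with pytest.raises(KeyError):
            clump(ss, tv2, np.zeros((10, 1), dtype=np.int8))

    def test_index_has_min_p_in_clump(self, rng):
        # every absorbed variant's p >= its index's p
        m = 12
        dosages = ld_block(600, m, 0.85, rng)
        pv = rng.uniform(0, 1, m)
        ss, tv = self.make_frame(
            [f"v{i}" for i in range(m)], [1] * m,
            np.arange(m) * 2_000 + 1, pv,
        )
        index = clump(ss, tv, dosages)
        pmap = dict(zip(ss["id"], ss["pvalue"]))
        r2 = np.corrcoef(dosages.T.astype(float)) ** 2
        idx_of = {v: i for i, v in enumerate(ss["id"])}
        for v in ss["id"]:
            if v in index:
                continue
            # must be linked to some index variant with smaller-or-equal p
            linked = [
                u for u in index
                if r2[idx_of[u], idx_of[v]] >= 0.10 and pmap[u] <= pmap[v]
            ]
            assert linked


# ---------------------------------------------------------------------------
# scoring


def aligned_frame(ids, betas, pvals):
    return pd.DataFrame({"id": ids, "beta": betas, "pvalue": pvals})


class TestScore:
    def test_single_variant_formula(self):
        aligned = aligned_frame(["v1"], [np.log(2)], [0.001])
        tv = pd.DataFrame({"id": ["v1"]})
        dosages = np.array([[2]], dtype=np.int8)
        s, m = score(aligned, tv, dosages, 0.05)
        assert m == 1
        assert s[0] == pytest.approx(2 * np.log(2))

    def test_hand_computed_fixture(self):
        # 3 variants x 2 samples, spreadsheet-style expected values
        betas = [0.5, -0.3, 0.2]
        pvals = [0.001, 0.01, 0.2]
        aligned = aligned_frame(["v1", "v2", "v3"], betas, pvals)
        tv = pd.DataFrame({"id": ["v1", "v2", "v3"]})
        dosages = np.array([[0, 1, 2], [2, 2, 0]], dtype=np.int8)
        s, m = score(aligned, tv, dosages, 0.5)
        assert m == 3
        expected0 = (0.5 * 0 + -0.3 * 1 + 0.2 * 2) / 3
        expected1 = (0.5 * 2 + -0.3 * 2 + 0.2 * 0) / 3
        assert s[0] == pytest.approx(expected0, abs=1e-12)
        assert s[1] == pytest.approx(expected1, abs=1e-12)

    def test_zero_betas_zero_scores(self):
        aligned = aligned_frame(["v1", "v2"], [0.0, 0.0], [0.001, 0.001])
        tv = pd.DataFrame({"id": ["v1", "v2"]})
        dosages = np.array([[1, 2], [0, 1]], dtype=np.int8)
        s, _ = score(aligned, tv, dosages, 0.05)
        assert np.all(s == 0)

    def test_empty_threshold_errors_with_name(self):
        aligned = aligned_frame(["v1"], [0.5], [0.5])
        tv = pd.DataFrame({"id": ["v1"]})
        with pytest.raises(ValueError, match="0.0001"):
            score(aligned, tv, np.array([[1]], dtype=np.int8), 0.0001)

    def test_strict_inequality_on_threshold(self):
        aligned = aligned_frame(["v1"], [0.5], [0.05])
        tv = pd.DataFrame({"id": ["v1"]})
        with pytest.raises(ValueError):
            score(aligned, tv, np.array([[1]], dtype=np.int8), 0.05)

    def test_missing_imputed_as_mean(self):
        aligned = aligned_frame(["v1"], [1.0], [0.001])
        tv = pd.DataFrame({"id": ["v1"]})
        dosages = np.array([[0], [2], [MISSING]], dtype=np.int8)
        s, _ = score(aligned, tv, dosages, 0.05)
        # allele freq among called = 2/4 = 0.5 -> imputed dosage 1.0
        assert s[2] == pytest.approx(1.0)


class TestBuildProfiles:
    @pytest.fixture
    def profile_inputs(self, small_cohort):
        stats = compute_variant_stats(
            small_cohort.variants, small_cohort.dosages
        )
        keep = set(qc_filter(stats))
        aligned = harmonize(
            small_cohort.sumstats,
            small_cohort.variants[small_cohort.variants["id"].isin(keep)],
        )
        return aligned, small_cohort

    def test_threshold_one_uses_all(self, profile_inputs):
        aligned, cohort = profile_inputs
        profiles = prs_engine.build_profiles(
            aligned, cohort.variants, cohort.dosages, cohort.sample_ids
        )
        n_used = profiles.attrs["n_snps_used"]
        assert n_used[1.0] == len(aligned)

    def test_n_snps_used_non_decreasing(self, profile_inputs):
        aligned, cohort = profile_inputs
        profiles = prs_engine.build_profiles(
            aligned, cohort.variants, cohort.dosages, cohort.sample_ids
        )
        counts = [profiles.attrs["n_snps_used"][t]
                  for t in prs_engine.P_THRESHOLDS]
        assert all(np.diff(counts) >= 0)

    def test_variant_order_invariance(self, profile_inputs):
        aligned, cohort = profile_inputs
        p1 = prs_engine.build_profiles(
            aligned, cohort.variants, cohort.dosages, cohort.sample_ids
        )
        shuffled = aligned.sample(frac=1, random_state=0).reset_index(drop=True)
        p2 = prs_engine.build_profiles(
            shuffled, cohort.variants, cohort.dosages, cohort.sample_ids
        )
        for t in prs_engine.P_THRESHOLDS:
            np.testing.assert_allclose(
                p1[f"prs_{t}"], p2[f"prs_{t}"], atol=1e-12
            )

    def test_allele_swap_shifts_by_constant(self, profile_inputs):
        aligned, cohort = profile_inputs
        s1, m = score(aligned, cohort.variants, cohort.dosages, 1.0)
        flipped = cohort.dosages.copy()
        obs = flipped != MISSING
        flipped[obs] = 2 - flipped[obs]
        aligned2 = aligned.copy()
        aligned2["beta"] = -aligned2["beta"]
        s2, m2 = score(aligned2, cohort.variants, flipped, 1.0)
        assert m == m2
        diffs = s2 - s1
        assert np.ptp(diffs) < 1e-10  # constant shift across samples

    def test_nested_variant_sets(self, profile_inputs):
        aligned, _ = profile_inputs
        sets = [
            set(aligned.loc[aligned["pvalue"] < t, "id"])
            for t in prs_engine.P_THRESHOLDS
        ]
        for a, b in zip(sets, sets[1:]):
            assert a <= b
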