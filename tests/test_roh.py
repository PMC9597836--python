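"""ROH detection against a brute-force definition-based oracle, and F_ROH."""

import numpy as np
import pandas as pd
import pytest

from rohbridge.roh import (
    GENERATION_MAP,
    LENGTH_CLASSES_MB,
    RohParams,
    call_roh,
    froh,
    froh_by_class,
    l_auto,
    roh_summary,
    froh_table,
    snp_eligibility,
)
from rohbridge.plinkio import SnpMap

from conftest import make_dataset, roh_oracle_one


def segs(iid, chrom, *triples):
    return pd.DataFrame(
        [(iid, chrom, a, b, n, (b - a + 1) / 1000.0) for a, b, n in triples],
        columns=["IID", "CHR", "POS1", "POS2", "NSNP", "KB"],
    )


class TestEligibility:
    def test_all_homozygous_chromosome_fully_eligible(self):
        g = np.zeros(40, dtype=np.int8)
        assert snp_eligibility(g).all()

    def test_heterozygote_never_eligible_when_no_het_allowed(self):
        g = np.zeros(60, dtype=np.int8)
        g[30] = 1
        mask = snp_eligibility(g)
        assert not mask[30]

    def test_short_chromosome_all_ineligible(self):
        assert not snp_eligibility(np.zeros(19, dtype=np.int8)).any()

    def test_missing_calls_tolerated_up_to_window_limit(self):
        # exactly one window: two missing calls keep it homozygous,
        # a third breaks it for every SNP it covers
        g = np.zeros(20, dtype=np.int8)
        g[[5, 6]] = -1
        assert snp_eligibility(g).all()
        g[7] = -1
        assert not snp_eligibility(g).any()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_window_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 120))
        g = rng.choice([0, 1, 2, -1], size=n,
                       p=[0.45, 0.06, 0.45, 0.04]).astype(np.int8)
        pos = np.sort(rng.choice(5 * 10**6, size=n, replace=False)) + 1
        params = RohParams()
        expect = np.zeros(n, dtype=bool)
        w = params.window_snps
        if n >= w:
            hom = [
                (g[s:s + w] == 1).sum() <= params.window_het_max
                and (g[s:s + w] == -1).sum() <= params.window_missing_max
                for s in range(n - w + 1)
            ]
            for i in range(n):
                cov = hom[max(0, i - w + 1): min(i, n - w) + 1]
                expect[i] = sum(cov) / len(cov) >= params.window_hit_threshold
        np.testing.assert_array_equal(snp_eligibility(g, params), expect)


class TestCallRoh:
    def test_single_clean_segment(self):
        g = np.zeros((1, 60), dtype=np.int8)
        pos = np.linspace(1, 3_000_000, 60).astype(np.int64)
        ds = make_dataset(g, {"1": pos})
        out = call_roh(ds)
        assert len(out) == 1
        assert out.iloc[0]["NSNP"] == 60
        assert out.iloc[0]["POS1"] == 1 and out.iloc[0]["POS2"] == 3_000_000

    def test_short_span_fails_length_filter(self):
        g = np.zeros((1, 25), dtype=np.int8)
        pos = np.linspace(1, 800_000, 25).astype(np.int64)
        assert len(call_roh(make_dataset(g, {"1": pos}))) == 0

    def test_big_gap_splits_run(self):
        g = np.zeros((1, 80), dtype=np.int8)
        left = np.linspace(1, 2_000_000, 40).astype(np.int64)
        right = np.linspace(2_700_000, 4_700_000, 40).astype(np.int64)
        out = call_roh(make_dataset(g, {"1": np.concatenate([left, right])}))
        assert len(out) == 2
        assert out["POS2"].iloc[0] == 2_000_000 and out["POS1"].iloc[1] == 2_700_000

    def test_unsorted_map_fatal(self):
        g = np.zeros((1, 30), dtype=np.int8)
        ds = make_dataset(g, {"1": np.arange(30) * 100_000 + 1})
        ds.snps.table.loc[5, "pos"] = 600_001
        ds.snps.table.loc[6, "pos"] = 500_001
        with pytest.raises(ValueError, match="sorted"):
            call_roh(ds)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(314)
        params = RohParams()
        for _ in range(150):
            n_chrom = int(rng.integers(1, 4))
            pos_by_chrom, genos = {}, []
            for c in range(n_chrom):
                n = int(rng.integers(10, 201))
                pos_by_chrom[str(c + 1)] = np.sort(
                    rng.choice(8 * 10**6, size=n, replace=False)) + 1
                genos.append(rng.choice(
                    [0, 1, 2, -1], size=n,
                    p=[0.47, 0.04, 0.45, 0.04]).astype(np.int8))
            geno = np.concatenate(genos)[None, :]
            ds = make_dataset(geno, pos_by_chrom)
            got = call_roh(ds, params)
            for c, pos in pos_by_chrom.items():
                cols = ds.snps.table["chrom"] == c
                expect = roh_oracle_one(geno[0, cols.to_numpy()], pos, params)
                sub = got.loc[got["CHR"] == c]
                assert (
                    list(zip(sub["POS1"], sub["POS2"], sub["NSNP"])) == expect
                )

    def test_raising_min_length_never_increases_froh(self):
        rng = np.random.default_rng(99)
        g = rng.choice([0, 1, 2], size=(5, 300), p=[0.48, 0.04, 0.48]).astype(np.int8)
        pos = {"1": np.sort(rng.choice(2 * 10**7, 300, replace=False)) + 1}
        ds = make_dataset(g, pos)
        la = l_auto(ds.snps)
        prev = None
        for min_kb in (1000.0, 2000.0, 4000.0):
            t = froh_table(ds, call_roh(ds, RohParams(min_length_kb=min_kb)))
            cur = t["f_roh"].to_numpy()
            if prev is not None:
                assert (cur <= prev + 1e-15).all()
            prev = cur

    def test_fully_homozygous_dense_chromosome_always_covered(self):
        g = np.zeros((1, 100), dtype=np.int8)
        pos = np.linspace(1, 2_500_000, 100).astype(np.int64)
        out = call_roh(make_dataset(g, {"1": pos}))
        assert len(out) == 1 and out.iloc[0]["NSNP"] == 100


class TestFroh:
    def test_l_auto_arithmetic(self):
        rows = [("1", "a", 0.0, 1_000_000, "A", "B"),
                ("1", "b", 0.0, 101_000_000, "A", "B"),
                ("2", "c", 0.0, 50_000_000, "A", "B"),
                ("2", "d", 0.0, 150_000_000, "A", "B")]
        sm = SnpMap(pd.DataFrame(rows, columns=["chrom", "snp_id", "cm",
                                                "pos", "a1", "a2"]))
        assert l_auto(sm) == 200_000_002

    def test_l_auto_single_snp_chromosome(self):
        sm = SnpMap(pd.DataFrame([("1", "a", 0.0, 5000, "A", "B")],
                                 columns=["chrom", "snp_id", "cm", "pos",
                                          "a1", "a2"]))
        assert l_auto(sm) == 1

    def test_l_auto_sort_invariant(self):
        rng = np.random.default_rng(3)
        rows = [(str(c), f"s{c}_{i}", 0.0, int(p), "A", "B")
                for c in (1, 2)
                for i, p in enumerate(rng.choice(10**7, 30, replace=False) + 1)]
        df = pd.DataFrame(rows, columns=["chrom", "snp_id", "cm", "pos", "a1", "a2"])
        shuffled = df.sample(frac=1.0, random_state=1)
        assert l_auto(SnpMap(df)) == l_auto(SnpMap(shuffled))

    def test_froh_examples(self):
        assert froh(segs("i", "1"), 1000) == 0.0
        s = segs("i", "1", (1, 240_000_000, 100))
        assert froh(s, 2_400_000_000) == pytest.approx(0.1)
        assert froh(s, 240_000_000) == pytest.approx(1.0)

    def test_class_decomposition_sums_to_total(self):
        s = segs("i", "1", (1, 1_500_000, 30), (2_000_000, 11_000_000, 60),
                 (12_000_000, 29_500_000, 100))
        la = 1e8
        by = froh_by_class(s, la)
        assert sum(by.values()) == pytest.approx(froh(s, la), abs=1e-12)

    def test_exact_16mb_goes_to_open_class(self):
        s = segs("i", "1", (1, 16_000_000, 50))  # exactly 16 Mb
        by = froh_by_class(s, 1e8)
        assert by[(16.0, float("inf"))] > 0
        assert by[(8.0, 16.0)] == 0.0

    def test_mass_split_across_classes(self):
        s = segs("i", "1", (1, 1_500_000, 30), (10_000_000, 19_000_000, 60))
        by = froh_by_class(s, 1e8)
        assert by[(1.0, 2.0)] == pytest.approx(1_500_000 / 1e8)
        assert by[(8.0, 16.0)] == pytest.approx(9_000_001 / 1e8)

    def test_generation_map_covers_all_classes(self):
        assert set(GENERATION_MAP) == set(LENGTH_CLASSES_MB)
        assert GENERATION_MAP[(1.0, 2.0)] == 50.0
        assert GENERATION_MAP[(16.0, float("inf"))] == 3.0


class TestSummary:
    def test_breed_without_roh(self):
        per_ind = pd.DataFrame({
            "iid": ["a", "b"], "n_segments": [0, 0],
            "total_length_bp": [0.0, 0.0], "mean_length_bp": [np.nan, np.nan],
            "f_roh": [0.0, 0.0]})
        out = roh_summary(per_ind, pd.Series(["X", "X"]))
        assert out.iloc[0]["n_without_roh"] == 2
        assert out.iloc[0]["mean_total_length_mb"] == 0.0
        assert np.isnan(out.iloc[0]["mean_segment_length_mb"])

    def test_mean_segment_count(self):
        per_ind = pd.DataFrame({
            "iid": ["a", "b"], "n_segments": [2, 4],
            "total_length_bp": [2e6, 4e6], "mean_length_bp": [1e6, 1e6],
            "f_roh": [0.01, 0.02]})
        out = roh_summary(per_ind)
        assert out.iloc[0]["mean_n_segments"] == pytest.approx(3.0)

    def test_summary_matches_direct_tally_on_random_fixture(self):
        rng = np.random.default_rng(21)
        g = rng.choice([0, 1, 2], size=(8, 200), p=[0.49, 0.02, 0.49]).astype(np.int8)
        ds = make_dataset(g, {"1": np.sort(rng.choice(10**7, 200, replace=False)) + 1})
        seg = call_roh(ds)
        per_ind = froh_table(ds, seg)
        out = roh_summary(per_ind)
        assert out.iloc[0]["n_individuals"] == 8
        assert out.iloc[0]["mean_n_segments"] == pytest.approx(len(seg) / 8)
        la = l_auto(ds.snps)
        total = (seg["POS2"] - seg["POS1"] + 1).sum()
        assert out.iloc[0]["mean_f_roh"] == pytest.approx(total / la / 8)
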