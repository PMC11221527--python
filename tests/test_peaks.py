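import numpy as np
import pandas as pd
import pytest

from hoodspot.peaks import (
    PeakFormatError,
    PeakSet,
    annotate_distribution,
    compare_enrichment,
    read_bed,
    read_narrowpeak,
    signal_kmeans,
    subtract_intervals,
    top_fraction,
    write_bed,
)

from .oracles import brute_ks_d, brute_overlap_mask


def make_peaks(rng, n, chroms=("chr1", "chr2"), span=10_000):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, 100, size=n)
    return PeakSet(
        pd.DataFrame(
            {
                "chrom": rng.choice(chroms, size=n),
                "start": starts,
                "end": starts + lengths,
                "name": [f"p{i}" for i in range(n)],
                "enrichment": rng.normal(4, 1, size=n),
                "strand": ".",
            }
        )
    )


class TestPeakSet:
    def test_sorted_on_construction(self, rng):
        ps = make_peaks(rng, 50)
        df = ps.records
        assert df.equals(df.sort_values(["chrom", "start", "end"],
                                        kind="stable").reset_index(drop=True))

    def test_invalid_interval_rejected(self):
        with pytest.raises(PeakFormatError, match="start >= end"):
            PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [10],
                                  "name": ["x"], "enrichment": [1.0]}))

    def test_non_finite_enrichment_rejected(self):
        with pytest.raises(PeakFormatError, match="finite"):
            PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5],
                                  "name": ["x"], "enrichment": [np.nan]}))


class TestBedIO:
    def test_roundtrip_bed(self, rng, tmp_path):
        ps = make_peaks(rng, 20)
        path = tmp_path / "a.bed"
        write_bed(ps, path)
        back = read_bed(path)
        assert np.array_equal(back.records["start"], ps.records["start"])
        assert np.allclose(back.enrichment, ps.enrichment, atol=1e-4)

    def test_malformed_line_names_location(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t5\t10\tok\t1\t.\nchr1\t20\t20\tbad\t1\t.\n")
        with pytest.raises(PeakFormatError, match="bad.bed:2"):
            read_bed(path)

    def test_narrowpeak_columns(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text(
            "chr1\t100\t200\tpeak1\t0\t.\t7.5\t3.1\t2.2\t40\n"
            "chr1\t300\t400\tpeak2\t0\t.\t2.5\t1.0\t0.5\t-1\n"
        )
        ps = read_narrowpeak(path)
        assert list(ps.enrichment) == [7.5, 2.5]
        assert list(ps.records["summit"]) == [40, -1]


class TestSubtractIntervals:
    def test_disjoint_sets_unchanged(self, rng):
        a = make_peaks(rng, 20, chroms=("chr1",))
        b = make_peaks(rng, 20, chroms=("chr9",))
        assert len(subtract_intervals(a, b)) == len(a)

    def test_self_subtraction_empty(self, rng):
        a = make_peaks(rng, 20)
        assert len(subtract_intervals(a, a)) == 0

    def test_matches_all_pairs_oracle(self, rng):
        """500 random intervals per side vs the O(n^2) overlap oracle."""
        for _ in range(5):
            a = make_peaks(rng, 500)
            b = make_peaks(rng, 500)
            result = subtract_intervals(a, b)
            expect = a.records[~brute_overlap_mask(a.records, b.records)]
            assert len(result) == len(expect)
            assert np.array_equal(result.records["start"].to_numpy(),
                                  expect["start"].to_numpy())

    def test_conservation_and_idempotence(self, rng):
        a = make_peaks(rng, 200)
        b = make_peaks(rng, 200)
        specific = subtract_intervals(a, b)
        overlapping = brute_overlap_mask(a.records, b.records).sum()
        assert len(specific) + overlapping == len(a)
        again = subtract_intervals(specific, b)
        assert again.records.equals(specific.records)

    def test_min_overlap_fraction_relaxes_removal(self):
        a = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                                  "name": ["a"], "enrichment": [1.0]}))
        b = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [90], "end": [200],
                                  "name": ["b"], "enrichment": [1.0]}))
        assert len(subtract_intervals(a, b)) == 0  # any overlap removes
        assert len(subtract_intervals(a, b, min_overlap_frac=0.5)) == 1  # 10% < 50%
        assert len(subtract_intervals(a, b, min_overlap_frac=0.05)) == 0


class TestTopFraction:
    def test_twenty_peaks_keep_two(self, rng):
        assert len(top_fraction(make_peaks(rng, 20), 0.10)) == 2

    def test_frac_one_is_identity(self, rng):
        ps = make_peaks(rng, 17)
        assert len(top_fraction(ps, 1.0)) == 17

    @pytest.mark.parametrize("n,frac,expect", [(15, 0.1, 2), (10, 0.25, 3), (7, 0.5, 4)])
    def test_size_is_ceiling(self, rng, n, frac, expect):
        assert len(top_fraction(make_peaks(rng, n), frac)) == expect

    def test_boundary_ties_deterministic(self, rng):
        df = make_peaks(rng, 15).records
        df["enrichment"] = 5.0  # all tied
        ps = PeakSet(df)
        first = top_fraction(ps, 0.1)
        assert len(first) == 2
        for _ in range(3):
            again = top_fraction(PeakSet(df.sample(frac=1, random_state=1)), 0.1)
            assert again.records[["chrom", "start"]].equals(
                first.records[["chrom", "start"]])

    def test_empty_set_warns(self, rng):
        ps = make_peaks(rng, 5)
        empty = PeakSet(ps.records.iloc[:0])
        with pytest.warns(UserWarning, match="empty"):
            assert len(top_fraction(empty)) == 0

    def test_invalid_fraction(self, rng):
        with pytest.raises(ValueError, match="frac"):
            top_fraction(make_peaks(rng, 5), 0.0)


class TestCompareEnrichment:
    def _with_scores(self, rng, scores):
        ps = make_peaks(rng, len(scores))
        df = ps.records
        df["enrichment"] = np.asarray(scores, dtype=float)
        return PeakSet(df)

    def test_identical_scores_d_zero_p_one(self, rng):
        a = self._with_scores(rng, [1, 2, 3, 4])
        b = self._with_scores(rng, [4, 3, 2, 1])
        comp = compare_enrichment(a, b)
        assert comp.ks_d == 0.0
        assert comp.p == 1.0

    def test_fully_separated_d_one(self, rng):
        a = self._with_scores(rng, [1, 2, 3])
        b = self._with_scores(rng, [4, 5, 6])
        comp = compare_enrichment(a, b)
        assert comp.ks_d == 1.0
        assert comp.direction == -1

    def test_d_matches_ecdf_oracle(self, rng):
        for _ in range(10):
            a = self._with_scores(rng, rng.normal(size=rng.integers(5, 60)))
            b = self._with_scores(rng, rng.normal(1, 2, size=rng.integers(5, 60)))
            comp = compare_enrichment(a, b)
            assert comp.ks_d == pytest.approx(
                brute_ks_d(a.enrichment, b.enrichment), abs=1e-12)

    def test_d_invariant_under_monotone_transform(self, rng):
        a = self._with_scores(rng, rng.normal(size=30))
        b = self._with_scores(rng, rng.normal(1, 1, size=40))
        d0 = compare_enrichment(a, b).ks_d
        a2 = self._with_scores(rng, np.exp(a.enrichment))
        b2 = self._with_scores(rng, np.exp(b.enrichment))
        assert compare_enrichment(a2, b2).ks_d == pytest.approx(d0)

    def test_empty_side_rejected(self, rng):
        a = make_peaks(rng, 5)
        empty = PeakSet(a.records.iloc[:0])
        with pytest.raises(ValueError, match="non-empty"):
            compare_enrichment(a, empty)


class TestAnnotateDistribution:
    @staticmethod
    def _tss():
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "tss_position": [10_000, 100_000],
                "strand": ["+", "-"],
                "gene_id": ["gplus", "gminus"],
            }
        )

    @staticmethod
    def _peak(chrom, start, end):
        return PeakSet(pd.DataFrame({"chrom": [chrom], "start": [start],
                                     "end": [end], "name": ["p"],
                                     "enrichment": [1.0]}))

    def test_500bp_upstream_plus_strand_is_promoter(self):
        # midpoint 9,500 -> 500 bp 5' of the + strand TSS at 10,000
        fracs, cats = annotate_distribution(self._peak("chr1", 9400, 9600), self._tss())
        assert cats[0] == "promoter_le1kb"
        assert fracs["promoter_le1kb"] == 1.0

    def test_strand_flip_same_category(self):
        # midpoint 100,500: 500 bp beyond a - strand TSS = 500 bp upstream
        _, cats = annotate_distribution(self._peak("chr1", 100_400, 100_600),
                                        self._tss())
        assert cats[0] == "promoter_le1kb"

    @pytest.mark.parametrize(
        "mid,expect",
        [
            (8_000, "upstream_1to3kb"),       # 2 kb 5' of + TSS
            (4_000, "upstream_3to10kb"),      # 6 kb 5'
            (15_000, "genebody_downstream_1to10kb"),  # 5 kb 3'
            (40_000, "distal_gt10kb"),
        ],
    )
    def test_binning(self, mid, expect):
        _, cats = annotate_distribution(self._peak("chr1", mid - 50, mid + 50),
                                        self._tss())
        assert cats[0] == expect

    def test_fractions_always_sum_to_one(self, rng):
        ps = make_peaks(rng, 200, chroms=("chr1",), span=200_000)
        fracs, _ = annotate_distribution(ps, self._tss())
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_chromosome_rejected(self, rng):
        ps = make_peaks(rng, 5, chroms=("chrX",))
        with pytest.raises(ValueError, match="chrX"):
            annotate_distribution(ps, self._tss())

    def test_empty_tss_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            annotate_distribution(make_peaks(rng, 5), self._tss().iloc[:0])

    def test_summit_used_when_present(self):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [25_000],
                           "name": ["p"], "enrichment": [1.0], "summit": [4800]})
        # midpoint 15,000 would be gene body; summit 5000+4800=9800 is promoter
        _, cats = annotate_distribution(PeakSet(df), self._tss())
        assert cats[0] == "promoter_le1kb"


class TestSignalKmeans:
    def test_two_separated_blobs_perfectly_split(self, rng):
        a = rng.normal(0, 0.1, size=(30, 2))
        b = rng.normal(8, 0.1, size=(25, 2))
        res = signal_kmeans(np.vstack([a, b]), k=2, seed=0)
        la, lb = set(res.assignment[:30]), set(res.assignment[30:])
        assert len(la) == 1 and len(lb) == 1 and la != lb

    def test_k_one_inertia_is_total_scatter(self, rng):
        x = rng.normal(size=(40, 3))
        res = signal_kmeans(x, k=1, seed=0)
        assert res.inertia == pytest.approx(((x - x.mean(0)) ** 2).sum())

    def test_identical_rows_one_effective_cluster(self):
        x = np.ones((10, 2))
        res = signal_kmeans(x, k=2, seed=0)
        assert res.inertia == pytest.approx(0.0)

    def test_k_exceeds_sites_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            signal_kmeans(rng.normal(size=(3, 2)), k=5, seed=0)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(50, 2))
        r1 = signal_kmeans(x, k=4, seed=9)
        r2 = signal_kmeans(x, k=4, seed=9)
        assert np.array_equal(r1.assignment, r2.assignment)
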