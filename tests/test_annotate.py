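"""Flank extension, interval merging and gene assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epipattern.annotate import (
    GenomicRegion,
    assign_regions_to_genes,
    extend_and_merge,
    filter_tfs,
    regions_to_bed,
    rna_gene_hits,
)


def union_oracle(loci, flank):
    """Quadratic base-by-base union of the extended loci, per chromosome."""
    covered = {}
    for chrom, pos, *_ in loci:
        s = covered.setdefault(chrom, set())
        s.update(range(max(0, pos - flank), pos + flank + 1))
    return {c: sorted(s) for c, s in covered.items()}


def regions_as_bases(regions):
    covered = {}
    for r in regions:
        covered.setdefault(r.chrom, set()).update(range(r.start, r.end))
    return {c: sorted(s) for c, s in covered.items()}


annotation = pd.DataFrame(
    {
        "gene_id": ["g1", "g2", "g3"],
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [10_000, 30_000, 10_000],
        "end": [12_000, 32_000, 12_000],
        "strand": ["+", "-", "+"],
        "is_tf": [True, False, True],
    }
)


class TestExtendAndMerge:
    def test_single_locus_arithmetic(self):
        (r,) = extend_and_merge([("chr1", 10_000)], flank=2000)
        assert (r.chrom, r.start, r.end) == ("chr1", 8000, 12_001)

    def test_nearby_loci_merge(self):
        (r,) = extend_and_merge([("chr1", 10_000), ("chr1", 13_000)], flank=2000)
        assert (r.start, r.end) == (8000, 15_001)
        assert len(r.source_loci) == 2

    def test_distant_loci_stay_separate(self):
        regions = extend_and_merge([("chr1", 10_000), ("chr1", 20_000)], flank=2000)
        assert [(r.start, r.end) for r in regions] == [(8000, 12_001), (18_000, 22_001)]

    def test_book_ended_regions_merge(self):
        # [pos-f, pos+f+1) spans touch exactly when positions differ by 2f+1
        (r,) = extend_and_merge([("chr1", 1000), ("chr1", 1000 + 2001)], flank=1000)
        assert (r.start, r.end) == (0, 4002)

    def test_zero_flank_gives_point_regions(self):
        regions = extend_and_merge([("chr1", 5), ("chr1", 9)], flank=0)
        assert [(r.start, r.end) for r in regions] == [(5, 6), (9, 10)]

    def test_start_clipped_at_zero(self):
        (r,) = extend_and_merge([("chr1", 100)], flank=2000)
        assert r.start == 0

    def test_end_clipped_at_chromosome_length_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            (r,) = extend_and_merge(
                [("chr1", 950)], flank=100, chrom_lengths={"chr1": 1000}
            )
        assert (r.start, r.end) == (850, 1000)

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            extend_and_merge([("chr1", 5)], flank=-1)

    def test_output_is_sorted_and_disjoint(self, rng):
        loci = [("chr1", int(p)) for p in rng.integers(0, 100_000, size=200)]
        regions = extend_and_merge(loci, flank=500)
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.start  # disjoint, non-book-ended, sorted

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.sampled_from(["chr1", "chr2"]),
                      st.integers(min_value=0, max_value=3000)),
            min_size=1, max_size=25,
        ),
        st.integers(min_value=0, max_value=200),
    )
    def test_matches_base_level_union_oracle(self, loci, flank):
        regions = extend_and_merge(loci, flank=flank)
        assert regions_as_bases(regions) == union_oracle(loci, flank)

    def test_merge_is_idempotent_and_order_invariant(self, rng):
        loci = [("chr1", int(p)) for p in rng.integers(0, 50_000, size=60)]
        regions = extend_and_merge(loci, flank=800)
        spans = [(r.chrom, r.start, r.end) for r in regions]
        shuffled = [loci[i] for i in rng.permutation(len(loci))]
        assert [(r.chrom, r.start, r.end)
                for r in extend_and_merge(shuffled, flank=800)] == spans
        # re-merging each region's own start points with flank 0 keeps bases
        inner = [(c, s) for c, s, e in spans]
        again = extend_and_merge(inner, flank=0)
        assert [r.start for r in again] == [s for _, s in inner]

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            GenomicRegion("chr1", 10, 10)


class TestAssignment:
    def test_overlap_requires_at_least_one_base(self):
        inside = [GenomicRegion("chr1", 11_999, 12_500, [("chr1", 11_999)])]
        outside = [GenomicRegion("chr1", 12_000, 12_500, [("chr1", 12_000)])]
        hit = assign_regions_to_genes(inside, annotation, "5mC", "c")
        miss = assign_regions_to_genes(outside, annotation, "5mC", "c")
        assert list(hit["gene_id"]) == ["g1"]
        assert len(miss) == 0

    def test_region_spanning_two_genes_hits_both(self):
        r = [GenomicRegion("chr1", 11_000, 31_000, [("chr1", 21_000)])]
        hits = assign_regions_to_genes(r, annotation, "5mC", "c")
        assert sorted(hits["gene_id"]) == ["g1", "g2"]

    def test_unknown_chromosome_raises(self):
        r = [GenomicRegion("chrX", 0, 10, [("chrX", 5)])]
        with pytest.raises(ValueError, match="unknown chromosome"):
            assign_regions_to_genes(r, annotation, "5mC", "c")

    def test_majority_direction(self):
        srcs = [("chr1", 10_500), ("chr1", 10_800), ("chr1", 11_200)]
        r = [GenomicRegion("chr1", 10_000, 12_000, list(srcs))]
        directions = {srcs[0]: +0.3, srcs[1]: +0.2, srcs[2]: -0.4}
        hits = assign_regions_to_genes(r, annotation, "5mC", "c", directions)
        assert list(hits["direction"]) == ["gain"]

    def test_exact_tie_records_both_directions(self):
        srcs = [("chr1", 10_500), ("chr1", 11_200)]
        r = [GenomicRegion("chr1", 10_000, 12_000, list(srcs))]
        directions = {srcs[0]: +0.3, srcs[1]: -0.3}
        hits = assign_regions_to_genes(r, annotation, "5mC", "c", directions)
        assert sorted(hits["direction"]) == ["gain", "loss"]

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n_genes = int(rng.integers(1, 6))
            starts = rng.integers(0, 5000, size=n_genes)
            genes = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n_genes)],
                    "chrom": rng.choice(["chr1", "chr2"], size=n_genes),
                    "start": starts,
                    "end": starts + rng.integers(1, 2000, size=n_genes),
                    "strand": "+",
                    "is_tf": False,
                }
            )
            chroms = sorted(set(genes["chrom"]))
            loci = [
                (str(c), int(p))
                for c, p in zip(rng.choice(chroms, size=8),
                                rng.integers(0, 6000, size=8))
            ]
            regions = extend_and_merge(loci, flank=int(rng.integers(0, 500)))
            hits = assign_regions_to_genes(regions, genes, "5mC", "c")
            expected = set()
            for g in genes.itertuples():
                for r in regions:
                    if (r.chrom == g.chrom
                            and max(r.start, g.start) < min(r.end, g.end)):
                        expected.add(g.gene_id)
            assert set(hits["gene_id"]) == expected

    def test_rna_hits_are_direct(self):
        frame = pd.DataFrame(
            {
                "feature_id": ["g1", "g2", "g3"],
                "log2fc": [2.0, -3.0, 0.1],
                "significant": [True, True, False],
            }
        )
        hits = rna_gene_hits(frame, "c")
        assert list(hits["gene_id"]) == ["g1", "g2"]
        assert list(hits["direction"]) == ["gain", "loss"]

    def test_regions_to_bed_counts_sources(self):
        regions = extend_and_merge([("chr1", 100), ("chr1", 150)], flank=100)
        bed = regions_to_bed(regions)
        assert bed.loc[0, "n_loci"] == 2


class TestFilterTFs:
    def test_keeps_only_tf_genes(self):
        hits = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "modality": "5mC",
             "comparison": "c", "direction": "gain", "n_loci": 1}
        )
        out = filter_tfs(hits, annotation)
        assert sorted(out["gene_id"]) == ["g1", "g3"]

    def test_no_tfs_yields_empty(self):
        ann = annotation.assign(is_tf=False)
        hits = pd.DataFrame({"gene_id": ["g1"], "modality": ["5mC"],
                             "comparison": ["c"], "direction": ["gain"],
                             "n_loci": [1]})
        assert len(filter_tfs(hits, ann)) == 0
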