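"""Region calling, interval arithmetic, gene lookup, recombinant narrowing."""

import numpy as np
import pandas as pd
import pytest

from bsaqtl import regions


def _windows(starts, deltas, step=1000, size=3000, chrom="chr1", n_sites=5):
    starts = np.asarray(starts)
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "window_start": starts,
            "window_end": starts + size,
            "midpoint": starts + size // 2,
            "mean_delta": deltas,
            "n_sites": n_sites,
        }
    )


class TestCallRegions:
    def test_nothing_above_threshold(self):
        win = _windows([1, 1001, 2001], [0.1, 0.2, 0.1])
        assert regions.call_regions(win, "mean_delta", 0.5) == []

    def test_single_contiguous_block(self):
        win = _windows(np.arange(1, 8001, 1000), [0.1, 0.6, 0.7, 0.8, 0.7, 0.6, 0.1, 0.1])
        regs = regions.call_regions(win, "mean_delta", 0.5, step=1000)
        assert len(regs) == 1
        r = regs[0]
        assert (r.start, r.end) == (1001, 8001)  # min start .. max end of the run
        assert r.peak_value == pytest.approx(0.8)
        assert r.start <= r.peak_position <= r.end

    def test_gap_splits_regions(self):
        """Two above-threshold blocks separated by a below-threshold window."""
        win = _windows(np.arange(1, 7001, 1000), [0.6, 0.7, 0.1, 0.1, 0.8, 0.9, 0.1])
        regs = regions.call_regions(win, "mean_delta", 0.5, step=1000)
        assert len(regs) == 2
        # overlapping windows may let the extents touch, but the runs are
        # distinct: second block starts after the first and peaks separately
        assert regs[0].start < regs[1].start
        assert (regs[0].peak_value, regs[1].peak_value) == (0.7, 0.9)

    def test_empty_windows_never_called(self):
        win = _windows([1, 1001], [0.9, 0.9], n_sites=0)
        assert regions.call_regions(win, "mean_delta", 0.5) == []

    def test_per_window_threshold_column(self):
        win = _windows([1, 1001, 2001], [0.4, 0.6, 0.4])
        win["ci95_high"] = [0.5, 0.5, 0.3]
        regs = regions.call_regions(win, "mean_delta", "ci95_high", step=1000)
        # windows 2 and 3 each clear their own bound and are adjacent: one run
        assert [(r.start, r.end) for r in regs] == [(1001, 5001)]
        assert regs[0].peak_value == pytest.approx(0.6)


class TestIntersectRegions:
    def _r(self, chrom, start, end, method="delta_index"):
        return regions.QTLRegion(chrom, start, end, (start + end) // 2, 1.0, method)

    def test_published_overlap(self):
        """The Delta-index and G' regions on chromosome 14 intersect to the
        reported target region 718001-1711000."""
        a = [self._r("Cmo_Chr14", 718001, 1711000)]
        b = [self._r("Cmo_Chr14", 159993, 1750879, "g_prime")]
        out = regions.intersect_regions(a, b)
        assert len(out) == 1
        assert (out[0].chromosome, out[0].start, out[0].end) == ("Cmo_Chr14", 718001, 1711000)
        assert out[0].method == "intersection"

    def test_disjoint_and_cross_chromosome(self):
        assert regions.intersect_regions(
            [self._r("chr1", 1, 100)], [self._r("chr1", 200, 300)]
        ) == []
        assert regions.intersect_regions(
            [self._r("chr1", 1, 100)], [self._r("chr2", 1, 100)]
        ) == []

    def test_commutative_and_idempotent(self):
        rng = np.random.default_rng(3)
        pairs = rng.integers(1, 10_000, size=(10, 2))
        regs = [self._r("chr1", min(a, b), max(a, b)) for a, b in pairs]
        singles = [[r] for r in regs]
        for x in singles:
            for y in singles:
                ab = regions.intersect_regions(x, y)
                ba = regions.intersect_regions(y, x)
                assert [(r.start, r.end) for r in ab] == [(r.start, r.end) for r in ba]
            same = regions.intersect_regions(x, x)
            assert [(r.start, r.end) for r in same] == [(x[0].start, x[0].end)]


class TestIntervalLength:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(791_681, 842_449, 50.77), (0, 1000, 1.00), (100, 100, 0.00), (0, 1005, 1.01)],
    )
    def test_lengths(self, start, end, expected):
        assert regions.interval_length_kb(start, end) == expected

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            regions.interval_length_kb(100, 50)


class TestGenesInInterval:
    def _region(self):
        return regions.QTLRegion("chr14", 791_681, 842_449, 800_000, 1.0, "intersection")

    def test_eight_genes_found(self, gff_eight_genes):
        genes = regions.genes_in_interval(gff_eight_genes, self._region())
        assert len(genes) == 8
        assert [g[0] for g in genes] == [f"GENE{i:02d}" for i in range(1, 9)]
        assert genes == sorted(genes, key=lambda g: g[1])

    def test_boundary_straddler_included(self, gff_eight_genes):
        """The last gene extends past the interval end; any-overlap keeps it."""
        genes = regions.genes_in_interval(gff_eight_genes, self._region())
        assert any(g[2] > 842_449 for g in genes)

    def test_empty_annotation(self, tmp_path):
        gff = tmp_path / "empty.gff3"
        gff.write_text("##gff-version 3\n")
        assert regions.genes_in_interval(gff, self._region()) == []

    def test_missing_file_errors(self):
        with pytest.raises(FileNotFoundError):
            regions.genes_in_interval("/nonexistent.gff3", self._region())


class TestNarrowByRecombinants:
    MARKERS = ["CmoM15", "CmoM16", "CmoM17", "CmoM18", "CmoM19", "CmoM20"]

    def _table(self, rows):
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.MARKERS)

    def test_three_critical_recombinants(self):
        """Breakpoints on both sides of the causal locus leave (CmoM17, CmoM18)
        as the only adjacent pair consistent with every phenotype."""
        geno = self._table(
            {
                "F2-89": ["P1hom"] * 3 + ["P2hom"] * 3,   # breakpoint in M17..M18
                "F2-21": ["P2hom"] * 3 + ["P1hom"] * 3,   # reciprocal breakpoint
                "F2-273": ["het"] * 3 + ["P1hom"] * 3,    # right-side recombinant
                "F2-01": ["P1hom"] * 6,
                "F2-02": ["P2hom"] * 6,
                "F2-03": ["het"] * 6,
            }
        )
        pheno = {"F2-89": "P2hom", "F2-21": "P1hom", "F2-273": "P2hom",
                 "F2-01": "P1hom", "F2-02": "P2hom", "F2-03": "het"}
        result = regions.narrow_by_recombinants(geno, pheno)
        assert tuple(result) == ("CmoM17", "CmoM18")
        assert result.conflicts == []

    def test_zero_recombinants_returns_full_interval(self):
        geno = self._table({"F2-01": ["P1hom"] * 6, "F2-02": ["het"] * 6})
        pheno = {"F2-01": "P1hom", "F2-02": "het"}
        assert tuple(regions.narrow_by_recombinants(geno, pheno)) == ("CmoM15", "CmoM20")

    def test_single_recombinant_trims_left_only(self):
        geno = self._table(
            {
                "F2-10": ["P1hom"] + ["het"] * 5,  # breakpoint after CmoM15
                "F2-11": ["het"] * 6,
            }
        )
        pheno = {"F2-10": "het", "F2-11": "het"}
        left, right = regions.narrow_by_recombinants(geno, pheno)
        assert left == "CmoM15"     # excluded marker becomes the left flank
        assert right == "CmoM20"    # right flank unchanged

    def test_contradictory_individuals_reported(self):
        geno = self._table({"F2-20": ["P1hom"] * 6, "F2-21": ["P1hom"] * 6})
        pheno = {"F2-20": "P1hom", "F2-21": "P2hom"}
        result = regions.narrow_by_recombinants(geno, pheno)
        assert result.conflicts  # same genotype, different phenotype class

    def test_validation(self):
        geno = self._table({"F2-01": ["P1hom"] * 6})
        with pytest.raises(ValueError, match="phenotype class"):
            regions.narrow_by_recombinants(geno, {})
        bad = geno.copy()
        bad.iloc[0, 0] = "weird"
        with pytest.raises(ValueError, match="P1hom"):
            regions.narrow_by_recombinants(bad, {"F2-01": "P1hom"})


def test_region_export_roundtrip(tmp_path):
    regs = [regions.QTLRegion("chr5", 1001, 5000, 3000, 0.42, "delta_index")]
    tsv, bed = tmp_path / "r.tsv", tmp_path / "r.bed"
    regions.write_regions_tsv(regs, tsv)
    regions.write_regions_bed(regs, bed)
    df = pd.read_csv(tsv, sep="\t")
    assert df.loc[0, "length_kb"] == pytest.approx(4.0, abs=0.01)
    assert bed.read_text().startswith("chr5\t1000\t5000\tdelta_index")
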