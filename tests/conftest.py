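"""Shared fixtures: small genomes, toy VCF/GFF builders, simulated datasets."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from bsaqtl import simdata

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr14,length=2000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tKG1\tMBF\tL-pool\tS-pool
"""

ROLES = {
    "parent1": "KG1",
    "parent2": "MBF",
    "bulk_long": "L-pool",
    "bulk_short": "S-pool",
}


@pytest.fixture
def make_vcf(tmp_path):
    """Write a VCF from raw record lines (header supplied)."""

    def _make(records: list[str], name: str = "toy.vcf") -> Path:
        path = tmp_path / name
        path.write_text(VCF_HEADER + "".join(line + "\n" for line in records))
        return path

    return _make


@pytest.fixture(scope="session")
def small_genome() -> simdata.GenomeMap:
    """Four chromosomes, ~100 kb marker spacing — fast but multi-chromosome."""
    return simdata.default_genome(n_chromosomes=4, marker_spacing=100_000)


@pytest.fixture(scope="session")
def scan_genome() -> simdata.GenomeMap:
    """The 20-chromosome desk-scale genome (~10,000 marker sites)."""
    return simdata.default_genome()


def make_individuals(doses_by_chrom: dict[str, list[int]], phenotypes: list[float]):
    """Hand-built F2 individuals with constant per-individual marker dose."""
    out = []
    for i, ph in enumerate(phenotypes):
        geno = {
            chrom: np.full(n, doses_by_chrom_value, dtype=np.int64)
            for chrom, (n, doses_by_chrom_value) in doses_by_chrom.items()
        }
        out.append(
            simdata.F2Individual(
                id=f"F2-{i + 1:03d}", genotype_at_markers=geno,
                phenotype=ph, qtl_dose=0,
            )
        )
    return out


@pytest.fixture
def gff_eight_genes(tmp_path) -> Path:
    """GFF3 with 8 genes inside chr14:791681-842449 and 2 outside.

    Synthetic stand-in mirroring an eight-gene fine-mapping interval; gene
    coordinates are invented.
    """
    interval = (791_681, 842_449)
    inside = []
    start = interval[0] + 500
    for i in range(8):
        # the eighth gene straddles the right boundary (any-overlap rule)
        end = interval[1] + 2_000 if i == 7 else start + 3_000
        inside.append((f"GENE{i + 1:02d}", start, end))
        start = start + 5_500
    outside = [("OUT01", 700_000, 705_000), ("OUT02", 900_000, 905_000)]
    lines = ["##gff-version 3"]
    for gid, s, e in inside + outside:
        lines.append(
            f"chr14\ttest\tgene\t{s}\t{e}\t.\t+\t.\tID={gid};product=protein {gid}"
        )
    path = tmp_path / "genes.gff3"
    path.write_text("\n".join(lines) + "\n")
    return path
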