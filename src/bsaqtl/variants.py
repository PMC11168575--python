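"""Variant-site ingestion and parental-homozygosity / depth filtering.

A bulked-segregant scan works on biallelic sites where the two parents are
homozygous for different alleles, so every read in a bulk can be assigned to
one parental haplotype.  This module reads a four-sample VCF (two parents,
two bulks), orients each site to the long-fruit parent's (KG1) allele, and
applies the coverage and parental-consistency filters that precede index
calculation.

Coordinates are 1-based inclusive throughout (VCF/GFF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: genotype categories for a parent sample
HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"

#: canonical sample roles expected in the VCF
ROLES = ("parent1", "parent2", "bulk_long", "bulk_short")


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site with parental genotypes and per-bulk allele depths.

    ``long_bulk_depths`` / ``short_bulk_depths`` are ``(kg1_reads, other_reads)``
    pairs oriented to the KG1 (parent1, long-fruit) allele whenever the parents
    are opposite homozygotes; otherwise the pair is stored in (ref, alt) order
    and ``kg1_allele`` is ``None`` (such sites are removed by filtering).
    """

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    parent1_gt: str
    parent2_gt: str
    long_bulk_depths: tuple[int, int]
    short_bulk_depths: tuple[int, int]
    kg1_allele: str | None = None  # "ref" | "alt" | None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for pair in (self.long_bulk_depths, self.short_bulk_depths):
            if min(pair) < 0:
                raise ValueError(f"allele depths must be >= 0, got {pair}")

    @property
    def opposite_homozygous(self) -> bool:
        return {self.parent1_gt, self.parent2_gt} == {HOM_REF, HOM_ALT}


def _gt_category(alleles: Sequence[int]) -> str:
    """Classify a diploid genotype (allele indices; -1 = missing)."""
    calls = [a for a in alleles if a >= 0]
    if len(calls) < 2:
        return MISSING
    if calls[0] == calls[1]:
        return HOM_REF if calls[0] == 0 else HOM_ALT
    return HET


def read_sites(vcf_path: str | Path, sample_roles: Mapping[str, str]) -> list[VariantSite]:
    """Read biallelic sites with GT and AD for the four named samples.

    Parameters
    ----------
    vcf_path
        VCF 4.x file (plain or bgzipped).
    sample_roles
        Maps each role in ``("parent1", "parent2", "bulk_long", "bulk_short")``
        to a sample name present in the VCF.  ``parent1`` is the long-fruit
        parent (KG1) whose allele orients the SNP-index.

    Multiallelic and symbolic records, and records with malformed AD fields,
    are skipped with a logged count.
    """
    from cyvcf2 import VCF

    missing_roles = [r for r in ROLES if r not in sample_roles]
    if missing_roles:
        raise ValueError(f"sample_roles missing roles: {missing_roles}")

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    try:
        idx = {role: samples.index(sample_roles[role]) for role in ROLES}
    except ValueError as exc:
        raise ValueError(
            f"sample not found in VCF {vcf_path}: {exc}; VCF samples: {samples}"
        ) from exc

    sites: list[VariantSite] = []
    n_multi = 0
    n_bad_ad = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or any(a.startswith("<") for a in rec.ALT):
            n_multi += 1
            continue
        ad = rec.format("AD")
        if ad is None or ad.shape[1] < 2:
            n_bad_ad += 1
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        p1 = _gt_category(gts[idx["parent1"]][:2])
        p2 = _gt_category(gts[idx["parent2"]][:2])

        def _depths(i: int) -> tuple[int, int]:
            r, a = int(ad[i, 0]), int(ad[i, 1])
            # cyvcf2 encodes missing AD as negative sentinels
            if r < 0 or a < 0:
                raise ValueError("missing AD")
            return r, a

        try:
            dl = _depths(idx["bulk_long"])
            ds = _depths(idx["bulk_short"])
        except ValueError:
            n_bad_ad += 1
            continue

        if {p1, p2} == {HOM_REF, HOM_ALT}:
            kg1 = "ref" if p1 == HOM_REF else "alt"
        else:
            kg1 = None
        if kg1 == "alt":
            dl = (dl[1], dl[0])
            ds = (ds[1], ds[0])
        sites.append(
            VariantSite(
                chromosome=rec.CHROM,
                position=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                parent1_gt=p1,
                parent2_gt=p2,
                long_bulk_depths=dl,
                short_bulk_depths=ds,
                kg1_allele=kg1,
            )
        )
    if n_multi or n_bad_ad:
        logger.info(
            "read_sites(%s): skipped %d multiallelic/symbolic and %d malformed-AD records",
            vcf_path, n_multi, n_bad_ad,
        )
    return sites


#: default per-bulk depth cutoff; the study reports depth filtering without a
#: number, and its minimum reported average depth is ~10x.
DEFAULT_MIN_DEPTH = 10


def filter_sites(
    sites: Iterable[VariantSite],
    min_depth_per_bulk: int = DEFAULT_MIN_DEPTH,
    require_opposite_homozygous: bool = True,
) -> list[VariantSite]:
    """Keep scan-ready sites: opposite-homozygous parents, adequate bulk depth.

    Order is preserved and the operation is idempotent.
    """
    if min_depth_per_bulk < 1:
        raise ValueError("min_depth_per_bulk must be >= 1")
    kept = []
    for s in sites:
        if require_opposite_homozygous and not s.opposite_homozygous:
            continue
        if sum(s.long_bulk_depths) < min_depth_per_bulk:
            continue
        if sum(s.short_bulk_depths) < min_depth_per_bulk:
            continue
        kept.append(s)
    return kept


def swap_parents(site: VariantSite) -> VariantSite:
    """Relabel parent1 <-> parent2 (flips the KG1 orientation of the depths)."""
    if site.kg1_allele is None:
        kg1 = None
        dl, ds = site.long_bulk_depths, site.short_bulk_depths
    else:
        kg1 = "alt" if site.kg1_allele == "ref" else "ref"
        dl = (site.long_bulk_depths[1], site.long_bulk_depths[0])
        ds = (site.short_bulk_depths[1], site.short_bulk_depths[0])
    return replace(
        site,
        parent1_gt=site.parent2_gt,
        parent2_gt=site.parent1_gt,
        long_bulk_depths=dl,
        short_bulk_depths=ds,
        kg1_allele=kg1,
    )


def sites_to_frame(sites: Iterable[VariantSite]) -> pd.DataFrame:
    """Tabulate sites as the filtered-site TSV schema."""
    rows = [
        {
            "chrom": s.chromosome,
            "pos": s.position,
            "ref": s.ref_allele,
            "alt": s.alt_allele,
            "kg1_reads_L": s.long_bulk_depths[0],
            "other_reads_L": s.long_bulk_depths[1],
            "kg1_reads_S": s.short_bulk_depths[0],
            "other_reads_S": s.short_bulk_depths[1],
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt",
            "kg1_reads_L", "other_reads_L", "kg1_reads_S", "other_reads_S",
        ],
    )


def write_sites_tsv(sites: Iterable[VariantSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[VariantSite]:
    """Read back a filtered-site TSV (sites are KG1-oriented by construction)."""
    df = pd.read_csv(path, sep="\t")
    return [
        VariantSite(
            chromosome=str(r.chrom),
            position=int(r.pos),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            parent1_gt=HOM_REF,
            parent2_gt=HOM_ALT,
            long_bulk_depths=(int(r.kg1_reads_L), int(r.other_reads_L)),
            short_bulk_depths=(int(r.kg1_reads_S), int(r.other_reads_S)),
            kg1_allele="ref",
        )
        for r in df.itertuples()
    ]
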