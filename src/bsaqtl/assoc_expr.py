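"""Marker-genotype association, expression formulas, and promoter motif scans.

The downstream validation layer of the mapping pipeline: one-way ANOVA of
fruit length across KASP genotype classes at the candidate SNP, trait
correlations, the relative-expression (2^-ddCt) and FPKM formulas, and exact
scanning for the GT1CONSENSUS cis-element (GGAAAA) with before/after analysis
of a promoter variant.
"""

from __future__ import annotations

import decimal
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPE_CLASSES = ("hom_p1", "het", "hom_p2")

GT1_CONSENSUS = "GGAAAA"

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifHit:
    """An exact motif occurrence; position is 1-based on the given strand."""

    motif: str
    position: int
    strand: str  # "+" | "-"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not self.motif:
            raise ValueError("motif must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class AssociationResult:
    """Group summaries plus ANOVA and pairwise Welch t-test results."""

    group_stats: dict[str, tuple[int, float, float]]  # class -> (n, mean, sd)
    anova_f: float
    anova_p: float
    pairwise_p: dict[tuple[str, str], float]
    pairwise_errors: dict[tuple[str, str], str]
    bonferroni: bool = False


def genotype_association(
    table: pd.DataFrame, bonferroni: bool = False
) -> AssociationResult:
    """One-way ANOVA and Welch pairwise t-tests of phenotype by genotype class.

    ``table`` needs columns ``genotype`` (in hom_p1/het/hom_p2) and
    ``phenotype``.  Pairwise tests are Welch (unequal variances); a
    Bonferroni correction over the tested pairs is applied when requested.
    Pairs that cannot be tested (singleton groups) are reported, not dropped.
    """
    if not {"genotype", "phenotype"}.issubset(table.columns):
        raise ValueError("table needs 'genotype' and 'phenotype' columns")
    unknown = set(table["genotype"]) - set(GENOTYPE_CLASSES)
    if unknown:
        raise ValueError(f"unknown genotype classes: {sorted(unknown)}")
    groups = {
        g: grp["phenotype"].to_numpy(float)
        for g, grp in table.groupby("genotype", sort=False)
        if len(grp) > 0
    }
    if len(groups) < 2:
        raise ValueError("need at least two non-empty genotype groups")

    stats_by_group = {
        g: (len(v), float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else float("nan"))
        for g, v in groups.items()
    }
    f, p = stats.f_oneway(*groups.values())
    pairwise_p: dict[tuple[str, str], float] = {}
    pairwise_err: dict[tuple[str, str], str] = {}
    pairs = list(itertools.combinations(sorted(groups, key=GENOTYPE_CLASSES.index), 2))
    for ga, gb in pairs:
        va, vb = groups[ga], groups[gb]
        if len(va) < 2 or len(vb) < 2:
            pairwise_err[(ga, gb)] = "fewer than two observations in a group"
            continue
        pairwise_p[(ga, gb)] = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
    if bonferroni and pairwise_p:
        m = len(pairwise_p)
        pairwise_p = {k: min(1.0, v * m) for k, v in pairwise_p.items()}
    return AssociationResult(stats_by_group, float(f), float(p),
                             pairwise_p, pairwise_err, bonferroni)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _round_half_up(value: float, decimals: int = 2) -> float:
    q = decimal.Decimal("1." + "0" * decimals)
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def carpopodium_fraction(carpopodium_cm: float, total_fl_cm: float) -> float:
    """Carpopodium share of total fruit length, percent to 2 decimals."""
    if total_fl_cm <= 0:
        raise ValueError("total fruit length must be positive")
    if not 0 <= carpopodium_cm <= total_fl_cm:
        raise ValueError("carpopodium length must lie in [0, total]")
    return _round_half_up(100.0 * carpopodium_cm / total_fl_cm)


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt comparative method.

    ddCt = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_calibrator,
    with the reference an internal-control gene (e.g. ACTIN).
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if any(ct <= 0 for ct in cts):
        raise ValueError("Ct values must be positive")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))


def fpkm(fragments: int, gene_length_bp: int, total_mapped_fragments: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped_fragments <= 0:
        raise ValueError("total mapped fragments must be positive")
    if fragments < 0:
        raise ValueError("fragment count must be >= 0")
    return float(fragments * 1e9 / (gene_length_bp * total_mapped_fragments))


def _validate_dna(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    return _validate_dna(sequence)[::-1].translate(_COMPLEMENT)


def motif_scan(
    sequence: str, motif: str = GT1_CONSENSUS, search_both_strands: bool = False
) -> list[MotifHit]:
    """All (possibly overlapping) exact occurrences of ``motif``.

    Positions are 1-based on the strand searched; N never matches.  Reverse-
    strand hits (off by default) are positions in the reverse complement.
    """
    seq = _validate_dna(sequence)
    mot = _validate_dna(motif)
    if "N" in mot:
        raise ValueError("motif must be unambiguous (no N)")

    def _scan(s: str, strand: str) -> list[MotifHit]:
        hits, start = [], s.find(mot)
        while start != -1:
            window = s[start:start + len(mot)]
            if "N" not in window:
                hits.append(MotifHit(mot, start + 1, strand))
            start = s.find(mot, start + 1)
        return hits

    hits = _scan(seq, "+")
    if search_both_strands:
        hits += _scan(reverse_complement(seq), "-")
    return hits


def variant_motif_effect(
    sequence: str,
    pos: int,
    ref_base: str,
    alt_base: str,
    motif: str = GT1_CONSENSUS,
    search_both_strands: bool = False,
) -> tuple[list[MotifHit], list[MotifHit], list[MotifHit], list[MotifHit]]:
    """Motif occurrences before vs after a substitution at 1-based ``pos``.

    Returns (hits_before, hits_after, lost, gained), where lost/gained are
    the set differences of hit positions.  A promoter SNP that destroys a
    cis-element (e.g. the GT1CONSENSUS G->T change) shows up in ``lost``.
    """
    seq = _validate_dna(sequence)
    if not 1 <= pos <= len(seq):
        raise ValueError(f"pos {pos} outside sequence of length {len(seq)}")
    ref = _validate_dna(ref_base)
    alt = _validate_dna(alt_base)
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only single-base substitutions are supported")
    if seq[pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at {pos}: sequence has {seq[pos - 1]!r}, expected {ref!r}"
        )
    mutated = seq[:pos - 1] + alt + seq[pos:]
    before = motif_scan(seq, motif, search_both_strands)
    after = motif_scan(mutated, motif, search_both_strands)
    keys_before = {(h.position, h.strand): h for h in before}
    keys_after = {(h.position, h.strand): h for h in after}
    lost = [h for k, h in sorted(keys_before.items()) if k not in keys_after]
    gained = [h for k, h in sorted(keys_after.items()) if k not in keys_before]
    return before, after, lost, gained


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns id, genotype (hom_p1/het/hom_p2), phenotype."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "genotype", "phenotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"genotype table needs columns {required}")
    return df


def read_promoter_fasta(path: str | Path, name: str | None = None) -> str:
    """First (or named) record of a FASTA file as an uppercase DNA string."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if name is None or rec.id == name:
            return _validate_dna(str(rec.seq))
    raise ValueError(f"no record {name!r} in {path}" if name else f"empty FASTA: {path}")


def association_report(result: AssociationResult) -> dict:
    """JSON-serializable report of an association analysis."""
    return {
        "groups": {
            g: {"n": n, "mean": mean, "sd": sd}
            for g, (n, mean, sd) in result.group_stats.items()
        },
        "anova": {"F": result.anova_f, "p": result.anova_p},
        "pairwise_p": {f"{a}_vs_{b}": p for (a, b), p in result.pairwise_p.items()},
        "pairwise_errors": {f"{a}_vs_{b}": e for (a, b), e in result.pairwise_errors.items()},
        "bonferroni": result.bonferroni,
    }
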