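"""Candidate-region calling, interval arithmetic, and fine-mapping logic.

A QTL region is a maximal run of consecutive above-threshold windows; the
Delta-index and G' detectors each produce regions, and their intersection is
the target region.  Fine mapping then narrows the interval with recombinant
marker genotypes and lists annotated genes in the final window.

Coordinates are 1-based inclusive; BED export converts to 0-based half-open.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QTLRegion:
    """Contiguous above-threshold genomic interval with its peak statistic."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int
    peak_position: int
    peak_value: float
    method: str  # "delta_index" | "g_prime" | "intersection"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if not self.start <= self.peak_position <= self.end:
            raise ValueError("peak_position outside [start, end]")


def call_regions(
    windows: pd.DataFrame,
    stat_column: str = "mean_delta",
    threshold: float | str = "ci95_high",
    step: int | None = None,
    method: str = "delta_index",
    two_sided: bool = False,
) -> list[QTLRegion]:
    """Merge maximal runs of consecutive above-threshold windows into regions.

    ``threshold`` is a scalar or the name of a per-window column (e.g. the
    simulated 95% bound).  Only windows with sites participate; runs whose
    window starts are separated by more than one step are distinct regions.
    With ``two_sided`` the magnitude |stat| is compared against the threshold
    (used for Delta when a short-parent-oriented QTL is also of interest).
    """
    if windows.empty:
        return []
    if step is None:
        starts = np.sort(windows["window_start"].unique())
        step = int(np.diff(starts).min()) if len(starts) > 1 else 1
    thr = windows[threshold] if isinstance(threshold, str) else float(threshold)
    values = windows[stat_column]
    above = (values.abs() if two_sided else values) > thr
    above &= windows["n_sites"] > 0
    above &= values.notna()

    regions: list[QTLRegion] = []
    hits = windows.loc[above].sort_values(["chromosome", "window_start"], kind="stable")
    for chrom, grp in hits.groupby("chromosome", sort=False):
        ws = grp["window_start"].to_numpy()
        breaks = np.where(np.diff(ws) > step)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(ws)]])
        for i in range(len(bounds) - 1):
            run = grp.iloc[bounds[i]:bounds[i + 1]]
            vals = run[stat_column].to_numpy(float)
            peak = run.iloc[int(np.argmax(np.abs(vals) if two_sided else vals))]
            regions.append(
                QTLRegion(
                    chromosome=str(chrom),
                    start=int(run["window_start"].min()),
                    end=int(run["window_end"].max()),
                    peak_position=int(peak["midpoint"]),
                    peak_value=float(peak[stat_column]),
                    method=method,
                )
            )
    return regions


def intersect_regions(a: Sequence[QTLRegion], b: Sequence[QTLRegion]) -> list[QTLRegion]:
    """Pairwise same-chromosome intersections (start = max, end = min).

    Commutative and idempotent; the peak of the first operand is kept when it
    falls inside the overlap, otherwise the overlap midpoint stands in.
    """
    out: list[QTLRegion] = []
    for ra in a:
        for rb in b:
            if ra.chromosome != rb.chromosome:
                continue
            start, end = max(ra.start, rb.start), min(ra.end, rb.end)
            if start > end:
                continue
            peak = ra.peak_position if start <= ra.peak_position <= end else (start + end) // 2
            out.append(
                QTLRegion(
                    chromosome=ra.chromosome,
                    start=start,
                    end=end,
                    peak_position=peak,
                    peak_value=ra.peak_value,
                    method="intersection",
                )
            )
    return out


def interval_length_kb(start_bp: int, end_bp: int) -> float:
    """Interval span in kb, (end - start)/1000, rounded half-up to 2 decimals.

    The end - start convention (no +1) reproduces published marker-interval
    lengths computed directly from marker coordinates.
    """
    if end_bp < start_bp:
        raise ValueError(f"end {end_bp} < start {start_bp}")
    kb = decimal.Decimal(end_bp - start_bp) / decimal.Decimal(1000)
    return float(kb.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def genes_in_interval(
    gff_path: str | Path, region: QTLRegion
) -> list[tuple[str, int, int, str]]:
    """Genes whose span overlaps the region (any overlap), sorted by start.

    Returns (gene_id, start, end, product_text) tuples; the product text is
    taken from common GFF3 attribute keys (product / description / Note).
    """
    import gffutils

    path = Path(gff_path)
    if not path.exists():
        raise FileNotFoundError(f"GFF not found: {path}")
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    hits = []
    for gene in db.features_of_type("gene"):
        if gene.seqid != region.chromosome:
            continue
        if gene.end < region.start or gene.start > region.end:
            continue
        product = ""
        for key in ("product", "description", "Note"):
            if key in gene.attributes:
                product = gene.attributes[key][0]
                break
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        hits.append((gene_id, gene.start, gene.end, product))
    return sorted(hits, key=lambda t: t[1])


# ---------------------------------------------------------------------------
# Recombinant-driven interval narrowing
# ---------------------------------------------------------------------------

#: marker/phenotype classes for fine-mapping tables
P1HOM = "P1hom"
P2HOM = "P2hom"
HET = "het"
_CLASSES = (P1HOM, P2HOM, HET)


@dataclass
class NarrowResult:
    left_marker: str
    right_marker: str
    conflicts: list[str] = field(default_factory=list)

    def __iter__(self):
        # allow tuple unpacking: left, right = narrow_by_recombinants(...)
        return iter((self.left_marker, self.right_marker))


def narrow_by_recombinants(
    marker_genotypes: pd.DataFrame,
    phenotype_classes: Mapping[str, str],
    marker_order: Sequence[str] | None = None,
) -> NarrowResult:
    """Tightest flanking marker pair consistent with recombinant phenotypes.

    ``marker_genotypes``: individuals (rows, index = id) x ordered markers
    (columns), entries in {P1hom, P2hom, het}.  ``phenotype_classes`` assigns
    each individual the genotype class its phenotype indicates at the causal
    locus (for an additive major gene: long ~ P1hom, short ~ P2hom,
    intermediate ~ het).

    Logic: an individual whose genotype at a marker differs from its
    phenotype class is a recombinant between that marker and the causal locus,
    which *excludes* that marker from containing the locus.  The locus lies in
    the maximal run of non-excluded markers; the flanking pair is the nearest
    excluded marker on each side (or the outermost marker when no recombinant
    trims that side).  When every marker is excluded, the locus falls between
    two adjacent markers: the adjacent pair is chosen whose non-recombinant
    individuals (same genotype at both flanks) all match their phenotype
    class.  Individuals with identical enclosed genotypes but different
    phenotype classes are reported as conflicts, never silently dropped.
    """
    markers = list(marker_order) if marker_order is not None else list(marker_genotypes.columns)
    if len(markers) < 2:
        raise ValueError("need at least two ordered markers")
    geno = marker_genotypes[markers]
    bad = ~geno.isin(_CLASSES)
    if bad.to_numpy().any():
        raise ValueError("genotype entries must be in {P1hom, P2hom, het}")
    missing = [i for i in geno.index if i not in phenotype_classes]
    if missing:
        raise ValueError(f"individuals without phenotype class: {missing}")

    # marker m excluded iff some individual's genotype at m mismatches its
    # phenotype class (a recombination between m and the causal locus)
    excluded = []
    for m in markers:
        mism = geno[m] != pd.Series({i: phenotype_classes[i] for i in geno.index})
        excluded.append(bool(mism.any()))

    conflicts = _find_conflicts(geno, phenotype_classes, markers, excluded)

    if not any(excluded):
        return NarrowResult(markers[0], markers[-1], conflicts)

    runs = _runs_of_false(excluded)
    if runs:
        # locus inside the (first, normally unique) run of concordant markers
        a, b = runs[0]
        if len(runs) > 1:
            conflicts.append(
                f"ambiguous: {len(runs)} disjoint concordant marker runs; using the first"
            )
        left = markers[a - 1] if a > 0 else markers[0]
        right = markers[b + 1] if b + 1 < len(markers) else markers[-1]
        return NarrowResult(left, right, conflicts)

    # every marker excluded: locus sits between two adjacent markers
    for i in range(len(markers) - 1):
        mi, mj = markers[i], markers[i + 1]
        ok = True
        for ind in geno.index:
            gi, gj = geno.at[ind, mi], geno.at[ind, mj]
            if gi == gj and gi != phenotype_classes[ind]:
                ok = False
                break
        if ok:
            return NarrowResult(mi, mj, conflicts)
    conflicts.append("no adjacent marker pair is consistent with the phenotypes")
    return NarrowResult(markers[0], markers[-1], conflicts)


def _runs_of_false(flags: Sequence[bool]) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, f in enumerate(flags):
        if not f and start is None:
            start = i
        elif f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def _find_conflicts(
    geno: pd.DataFrame,
    phenotype_classes: Mapping[str, str],
    markers: Sequence[str],
    excluded: Sequence[bool],
) -> list[str]:
    """Individuals with identical genotypes across concordant markers but
    different phenotype classes."""
    enclosed = [m for m, ex in zip(markers, excluded) if not ex] or list(markers)
    seen: dict[tuple, tuple[str, str]] = {}
    conflicts = []
    for ind in geno.index:
        key = tuple(geno.loc[ind, enclosed])
        ph = phenotype_classes[ind]
        if key in seen and seen[key][1] != ph:
            conflicts.append(
                f"individuals {seen[key][0]} and {ind} share genotype "
                f"{key} but differ in phenotype class ({seen[key][1]} vs {ph})"
            )
        else:
            seen.setdefault(key, (str(ind), ph))
    return conflicts


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def regions_to_frame(regions: Sequence[QTLRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": r.chromosome, "start": r.start, "end": r.end,
                "peak_position": r.peak_position, "peak_value": r.peak_value,
                "length_kb": interval_length_kb(r.start, r.end), "method": r.method,
            }
            for r in regions
        ],
        columns=["chromosome", "start", "end", "peak_position", "peak_value",
                 "length_kb", "method"],
    )


def write_regions_tsv(regions: Sequence[QTLRegion], path: str | Path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Sequence[QTLRegion], path: str | Path) -> None:
    """BED export: 0-based half-open, name = method, score = peak value."""
    lines = [
        f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.method}\t{r.peak_value:.4g}"
        for r in regions
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
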