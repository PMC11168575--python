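"""Synthetic F2 populations, extreme bulks, and bulk-sequencing allele depths.

The generator emulates the experimental design the scan assumes: a biparental
cross between a long-fruit parent (KG1) and a short-fruit parent (MBF), an F2
of selfed F1 plants segregating for one additive major QTL plus polygenic and
environmental noise, phenotypic extreme bulks, and short-read allele-depth
sampling at biallelic marker sites across 20 chromosomes.

Model summary
-------------
* Gametes are produced by a Markov walk along ordered marker positions with
  Haldane recombination fractions r = (1 - exp(-2d/100))/2 for the genetic
  distance d (cM) between adjacent markers; genetic position is uniform
  cM/Mb within each chromosome.
* Phenotype = m + QTL effect (+a / +d / -a for doses 2/1/0 of the KG1 allele)
  + N(0, polygenic_sd^2) + N(0, env_sd^2).
* Bulk sequencing: per site and bulk, the true KG1-allele frequency is
  p = (sum of doses) / (2 * bulk size); depth ~ Poisson(depth_mean) truncated
  at >= 1; KG1-allele reads ~ Binomial(depth, p*(1-e) + (1-p)*e) with
  symmetric sequencing error e.

All randomness flows from one root seed through named substreams
(genotypes, phenotypes, depths, reads), so each stage replays independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import HOM_ALT, HOM_REF, VariantSite

_SUBSTREAMS = ("genotypes", "phenotypes", "depths", "reads")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG derived deterministically from the root seed."""
    if name not in _SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}; expected one of {_SUBSTREAMS}")
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return np.random.default_rng(children[_SUBSTREAMS.index(name)])


@dataclass(frozen=True)
class Chromosome:
    name: str
    physical_length: int  # bp
    genetic_length: float  # cM

    def __post_init__(self) -> None:
        if self.physical_length < 1 or self.genetic_length <= 0:
            raise ValueError(f"invalid chromosome dimensions: {self}")

    def cm_at(self, position_bp: np.ndarray | float) -> np.ndarray | float:
        """Genetic position under the uniform cM/Mb assumption."""
        return np.asarray(position_bp) * self.genetic_length / self.physical_length


@dataclass
class GenomeMap:
    """Chromosome dimensions plus sorted marker positions per chromosome."""

    chromosomes: list[Chromosome]
    marker_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        names = {c.name for c in self.chromosomes}
        for name, pos in self.marker_positions.items():
            if name not in names:
                raise ValueError(f"markers on undeclared chromosome {name!r}")
            pos = np.asarray(pos, dtype=np.int64)
            chrom = self.chromosome(name)
            if len(pos) and (pos.min() < 1 or pos.max() > chrom.physical_length):
                raise ValueError(f"marker positions off chromosome {name}")
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions not strictly increasing on {name}")
            self.marker_positions[name] = pos

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.marker_positions.values())


def default_genome(
    n_chromosomes: int = 20,
    min_length: int = 2_000_000,
    max_length: int = 10_000_000,
    marker_spacing: int = 12_000,
    cm_per_mb: float = 10.0,
) -> GenomeMap:
    """Deterministic desk-scale genome: 20 chromosomes of 2-10 Mb.

    Marker positions are evenly spaced.  ``cm_per_mb`` defaults to 10, the
    order of magnitude of published Cucurbita consensus maps (~3000 cM over
    ~270 Mb).  This is a test-scale stand-in, not the 269 Mb assembly.
    """
    lengths = np.linspace(min_length, max_length, n_chromosomes).astype(np.int64)
    chroms = [
        Chromosome(f"chr{i + 1:02d}", int(L), float(L) / 1e6 * cm_per_mb)
        for i, L in enumerate(lengths)
    ]
    markers = {
        c.name: np.arange(marker_spacing, c.physical_length + 1, marker_spacing, dtype=np.int64)
        for c in chroms
    }
    return GenomeMap(chroms, markers)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic F2 + bulk-sequencing experiment.

    Defaults mirror the study conditions: 231 F2 individuals, extreme bulks of
    20 + 20 selected by fruit-length thresholds (< 20 cm / > 45 cm), one
    additive major QTL, and ~30x bulk depth.  Phenotype units are cm.
    """

    n_f2: int = 231
    qtl_chromosome: str = "chr14"
    qtl_position: int = 1_200_000
    additive_effect: float = 12.5  # a: half the homozygote difference
    dominance_effect: float = 0.0  # d
    baseline: float = 32.5  # m: mixture midpoint, centred between bulk cutoffs
    polygenic_sd: float = 5.0
    env_sd: float = 3.0
    depth_mean: float = 30.0
    seq_error: float = 0.001
    bulk_rule: tuple[float, float] = (20.0, 45.0)  # thresholds (short <, long >)
    bulk_mode: str = "threshold"  # "threshold" | "top_n"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 <= 0:
            raise ValueError("n_f2 must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if self.additive_effect < 0:
            raise ValueError("additive_effect must be >= 0")
        if self.bulk_mode not in ("threshold", "top_n"):
            raise ValueError(f"unknown bulk_mode {self.bulk_mode!r}")


@dataclass
class F2Individual:
    """One selfed-F1 offspring: per-marker KG1-allele doses and a phenotype."""

    id: str
    genotype_at_markers: dict[str, np.ndarray]  # chromosome -> doses in {0,1,2}
    phenotype: float
    qtl_dose: int

    def dose_at(self, chromosome: str, marker_index: int) -> int:
        return int(self.genotype_at_markers[chromosome][marker_index])


def _simulate_gametes(
    rng: np.random.Generator, genetic_pos_cm: np.ndarray, n_gametes: int
) -> np.ndarray:
    """Markov walk along ordered markers; returns (n_gametes, n_markers) in {0,1}.

    Allele 1 = KG1.  The F1 is heterozygous everywhere, so the first marker
    allele is Bernoulli(1/2) and each interval switches with its Haldane
    recombination fraction.
    """
    k = len(genetic_pos_cm)
    first = rng.integers(0, 2, size=(n_gametes, 1))
    if k == 1:
        return first
    d = np.diff(genetic_pos_cm)  # cM
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    switches = rng.random((n_gametes, k - 1)) < r
    # parity of accumulated switches flips the starting allele
    parity = np.cumsum(switches, axis=1, dtype=np.int64) % 2
    return np.hstack([first, (first + parity) % 2])


def simulate_f2(genome: GenomeMap, config: SimConfig) -> list[F2Individual]:
    """Simulate an F2 population by selfing a fully heterozygous F1.

    Deterministic given ``config.seed``.  The QTL is simulated as a pseudo-
    marker inserted into the walk on its chromosome, so its dose is linked to
    the surrounding markers exactly as the map dictates.
    """
    for c in genome.chromosomes:
        if len(genome.marker_positions.get(c.name, ())) == 0:
            raise ValueError(f"no markers defined on chromosome {c.name}")
    try:
        qtl_chrom = genome.chromosome(config.qtl_chromosome)
    except KeyError as exc:
        raise ValueError(f"QTL chromosome not on map: {config.qtl_chromosome!r}") from exc
    if not 1 <= config.qtl_position <= qtl_chrom.physical_length:
        raise ValueError(
            f"QTL position {config.qtl_position} off chromosome "
            f"{qtl_chrom.name} (length {qtl_chrom.physical_length})"
        )

    rng_g = substream(config.seed, "genotypes")
    rng_p = substream(config.seed, "phenotypes")
    n = config.n_f2

    doses: dict[str, np.ndarray] = {}
    qtl_dose = np.zeros(n, dtype=np.int64)
    for chrom in genome.chromosomes:
        pos = genome.marker_positions[chrom.name]
        insert_at = None
        walk_pos = pos
        if chrom.name == config.qtl_chromosome:
            insert_at = int(np.searchsorted(pos, config.qtl_position))
            on_marker = insert_at < len(pos) and pos[insert_at] == config.qtl_position
            if not on_marker:
                walk_pos = np.insert(pos, insert_at, config.qtl_position)
        cm = np.asarray(chrom.cm_at(walk_pos), dtype=float)
        maternal = _simulate_gametes(rng_g, cm, n)
        paternal = _simulate_gametes(rng_g, cm, n)
        d = maternal + paternal
        if insert_at is not None:
            qtl_dose = d[:, insert_at].copy()
            if len(walk_pos) != len(pos):  # pseudo-marker was inserted; drop it
                d = np.delete(d, insert_at, axis=1)
        doses[chrom.name] = d

    effect = np.select(
        [qtl_dose == 2, qtl_dose == 1],
        [config.additive_effect, config.dominance_effect],
        default=-config.additive_effect,
    )
    noise = rng_p.normal(0.0, config.polygenic_sd, n) + rng_p.normal(0.0, config.env_sd, n)
    phenotype = config.baseline + effect + noise

    width = len(str(n))
    return [
        F2Individual(
            id=f"F2-{i + 1:0{width}d}",
            genotype_at_markers={c: doses[c][i] for c in doses},
            phenotype=float(phenotype[i]),
            qtl_dose=int(qtl_dose[i]),
        )
        for i in range(n)
    ]


def select_bulks(
    individuals: Sequence[F2Individual],
    rule: tuple[float, float] | tuple[int, int],
    mode: str = "threshold",
) -> tuple[list[str], list[str]]:
    """Select the (long_ids, short_ids) extreme bulks.

    ``mode="threshold"``: rule = (low, high); short bulk = phenotype < low,
    long bulk = phenotype > high (the study used FL < 20 cm and FL > 45 cm).
    ``mode="top_n"``: rule = (n_low, n_high) most extreme individuals per
    tail, ties broken by id order (stable sort).
    """
    if mode == "threshold":
        low, high = rule
        if low >= high:
            raise ValueError(f"thresholds overlap: low {low} >= high {high}")
        short_ids = [ind.id for ind in individuals if ind.phenotype < low]
        long_ids = [ind.id for ind in individuals if ind.phenotype > high]
    elif mode == "top_n":
        n_low, n_high = int(rule[0]), int(rule[1])
        if n_low + n_high > len(individuals):
            raise ValueError(
                f"requested {n_low}+{n_high} individuals from population of {len(individuals)}"
            )
        # stable sorts: ties resolve to input (id) order, and the two tails are
        # drawn from disjoint pools so the bulks never share an individual
        ascending = sorted(individuals, key=lambda ind: ind.phenotype)
        short_ids = [ind.id for ind in ascending[:n_low]]
        remaining = ascending[n_low:]
        descending = sorted(remaining, key=lambda ind: -ind.phenotype)
        long_ids = [ind.id for ind in descending[:n_high]]
    else:
        raise ValueError(f"unknown bulk mode {mode!r}")
    return long_ids, short_ids


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1 (bulk depth; a sequenced site has reads)."""
    out = rng.poisson(mean, size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(mean, int(zero.sum()))
        zero = out == 0
    return out


def simulate_bulk_reads(
    individuals: Sequence[F2Individual],
    long_ids: Sequence[str],
    short_ids: Sequence[str],
    genome: GenomeMap,
    config: SimConfig,
) -> list[VariantSite]:
    """Draw per-site allele depths for the two bulks; parents emitted as fixed
    homozygotes.

    To exercise downstream orientation handling, KG1 carries the REF allele at
    even marker ranks and the ALT allele at odd ranks.
    """
    if not long_ids or not short_ids:
        raise ValueError("both bulks must be non-empty")
    if genome.n_markers == 0:
        raise ValueError("empty marker set")
    by_id = {ind.id: ind for ind in individuals}
    long_bulk = [by_id[i] for i in long_ids]
    short_bulk = [by_id[i] for i in short_ids]

    rng_d = substream(config.seed, "depths")
    rng_r = substream(config.seed, "reads")
    e = config.seq_error

    sites: list[VariantSite] = []
    rank = 0
    for chrom in genome.chromosomes:
        pos = genome.marker_positions[chrom.name]
        if len(pos) == 0:
            continue
        dose_long = np.vstack([ind.genotype_at_markers[chrom.name] for ind in long_bulk])
        dose_short = np.vstack([ind.genotype_at_markers[chrom.name] for ind in short_bulk])
        p_long = dose_long.sum(axis=0) / (2.0 * len(long_bulk))
        p_short = dose_short.sum(axis=0) / (2.0 * len(short_bulk))

        k = len(pos)
        depth_long = _truncated_poisson(rng_d, config.depth_mean, k)
        depth_short = _truncated_poisson(rng_d, config.depth_mean, k)
        kg1_long = rng_r.binomial(depth_long, p_long * (1 - e) + (1 - p_long) * e)
        kg1_short = rng_r.binomial(depth_short, p_short * (1 - e) + (1 - p_short) * e)

        for j in range(k):
            kg1_is_ref = (rank % 2 == 0)
            rank += 1
            sites.append(
                VariantSite(
                    chromosome=chrom.name,
                    position=int(pos[j]),
                    ref_allele="A" if kg1_is_ref else "T",
                    alt_allele="T" if kg1_is_ref else "A",
                    parent1_gt=HOM_REF if kg1_is_ref else HOM_ALT,
                    parent2_gt=HOM_ALT if kg1_is_ref else HOM_REF,
                    long_bulk_depths=(int(kg1_long[j]), int(depth_long[j] - kg1_long[j])),
                    short_bulk_depths=(int(kg1_short[j]), int(depth_short[j] - kg1_short[j])),
                    kg1_allele="ref" if kg1_is_ref else "alt",
                )
            )
    return sites


# ---------------------------------------------------------------------------
# External interfaces: 4-sample VCF, phenotype TSV, declarative config file
# ---------------------------------------------------------------------------

SAMPLE_NAMES = ("KG1", "MBF", "L-pool", "S-pool")


def write_vcf(
    sites: Sequence[VariantSite],
    genome: GenomeMap,
    path: str | Path,
    config: SimConfig | None = None,
) -> None:
    """Write a minimal 4-sample VCF (KG1, MBF, L-pool, S-pool) with GT and AD.

    Parent AD fields are emitted as clean homozygous depths (depth_mean on the
    parental allele) — the parents are inbred lines, and the scan only uses
    parental genotypes, not parental depths.
    """
    depth = int(round(config.depth_mean)) if config is not None else 30
    lines = ["##fileformat=VCFv4.2", "##source=bsaqtl-simdata"]
    lines += [
        f"##contig=<ID={c.name},length={c.physical_length}>" for c in genome.chromosomes
    ]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(SAMPLE_NAMES),
    ]
    for s in sites:
        kg1_ref = s.kg1_allele == "ref"
        p1_gt, p2_gt = ("0/0", "1/1") if kg1_ref else ("1/1", "0/0")
        p1_ad = f"{depth},0" if kg1_ref else f"0,{depth}"
        p2_ad = f"0,{depth}" if kg1_ref else f"{depth},0"

        def _ad(pair: tuple[int, int]) -> str:
            kg1, other = pair
            ref, alt = (kg1, other) if kg1_ref else (other, kg1)
            return f"{ref},{alt}"

        lines.append(
            "\t".join(
                [
                    s.chromosome, str(s.position), ".", s.ref_allele, s.alt_allele,
                    ".", "PASS", ".", "GT:AD",
                    f"{p1_gt}:{p1_ad}", f"{p2_gt}:{p2_ad}",
                    f"0/1:{_ad(s.long_bulk_depths)}", f"0/1:{_ad(s.short_bulk_depths)}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_phenotypes(
    individuals: Sequence[F2Individual],
    long_ids: Sequence[str],
    short_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Phenotype TSV: id, phenotype, bulk in {L, S, -}."""
    long_set, short_set = set(long_ids), set(short_ids)
    rows = [
        {
            "id": ind.id,
            "phenotype": ind.phenotype,
            "bulk": "L" if ind.id in long_set else ("S" if ind.id in short_set else "-"),
        }
        for ind in individuals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_config_file(path: str | Path) -> SimConfig:
    """Parse a declarative key = value config mirroring SimConfig."""
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, val = (p.strip() for p in line.split("=", 1))
        raw[key] = val
    kwargs: dict = {}
    fields = SimConfig.__dataclass_fields__
    for key, val in raw.items():
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        ftype = fields[key].type
        if key == "bulk_rule":
            parts = [float(x) for x in val.replace(",", " ").split()]
            kwargs[key] = (parts[0], parts[1])
        elif ftype == "int":
            kwargs[key] = int(val)
        elif ftype == "float":
            kwargs[key] = float(val)
        else:
            kwargs[key] = val
    return SimConfig(**kwargs)


def simulate_experiment(
    genome: GenomeMap, config: SimConfig
) -> tuple[list[F2Individual], list[str], list[str], list[VariantSite]]:
    """Convenience wrapper: F2 -> bulks -> allele depths in one call."""
    individuals = simulate_f2(genome, config)
    long_ids, short_ids = select_bulks(individuals, config.bulk_rule, config.bulk_mode)
    sites = simulate_bulk_reads(individuals, long_ids, short_ids, genome, config)
    return individuals, long_ids, short_ids, sites
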