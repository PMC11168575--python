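"""SNP-index / Delta-index and G/G' bulked-segregant QTL scan statistics.

Two detectors run over the same filtered sites:

* **Delta SNP-index** — per bulk, the SNP-index is the fraction of reads
  carrying the long-parent (KG1) allele; their difference Delta = index_L -
  index_S is ~0 under no linkage and approaches +1 at a locus where the long
  bulk is fixed for the KG1 allele.  Window means of Delta are compared
  against Monte-Carlo simulated null quantiles (95% / 99%) that condition on
  bulk size and read depth.
* **G / G'** — the likelihood-ratio statistic of the 2x2 allele-by-bulk read
  count table, tricube-smoothed over physical distance.

Window convention: per chromosome, windows of ``window_size`` start at
position 1 and advance by ``step``; a site at position p belongs to windows
with window_start <= p < window_start + window_size.  Windows without sites
are excluded from threshold crossing.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import VariantSite

#: the study's genome-scale scan settings
DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 1_000

RECORD_COLUMNS = [
    "chromosome", "position", "index_long", "index_short", "delta",
    "depth_long", "depth_short", "g_stat",
]
WINDOW_COLUMNS = [
    "chromosome", "window_start", "window_end", "midpoint", "mean_delta",
    "mean_index_long", "mean_index_short", "g_prime", "n_sites",
    "ci95_low", "ci95_high", "ci99_low", "ci99_high",
]


def snp_index(kg1_reads: int, other_reads: int) -> float:
    """Fraction of reads in a bulk carrying the KG1 (long-parent) allele."""
    total = kg1_reads + other_reads
    if total < 1:
        raise ValueError("zero total depth: site must be filtered before indexing")
    return kg1_reads / total


def delta_index(index_long: float, index_short: float) -> float:
    """Delta(All-index): long-bulk index minus short-bulk index, in [-1, 1]."""
    return index_long - index_short


def g_statistic(kg1_long: int, other_long: int, kg1_short: int, other_short: int) -> float:
    """Likelihood-ratio G of the 2x2 allele-by-bulk table.

    G = 2 * sum n_i * ln(n_i / e_i) with expected counts under independence;
    empty cells contribute 0 (x ln x -> 0 limit).
    """
    obs = np.array([[kg1_long, other_long], [kg1_short, other_short]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    if (row < 1).any():
        raise ValueError("each bulk needs at least one read")
    col = obs.sum(axis=0)
    total = obs.sum()
    exp = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2.0 * terms.sum())


def compute_index_records(sites: Iterable[VariantSite]) -> pd.DataFrame:
    """Per-site SNP-index, Delta-index, and G for KG1-oriented filtered sites."""
    rows = []
    for s in sites:
        kl, ol = s.long_bulk_depths
        ks, os_ = s.short_bulk_depths
        il = snp_index(kl, ol)
        is_ = snp_index(ks, os_)
        rows.append(
            (s.chromosome, s.position, il, is_, il - is_,
             kl + ol, ks + os_, g_statistic(kl, ol, ks, os_))
        )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)


def _check_sorted(records: pd.DataFrame) -> None:
    for _, grp in records.groupby("chromosome", sort=False):
        if not grp["position"].is_monotonic_increasing:
            raise ValueError("records must be sorted by (chromosome, position)")


def sliding_windows(
    records: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    chromosome_ends: Mapping[str, int] | None = None,
    extra_mean_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Window means of Delta (and indices) on a fixed genome-anchored grid.

    ``chromosome_ends`` defaults to the last site position per chromosome.
    ``extra_mean_columns`` are additional per-site columns (e.g. site-level
    null thresholds) to average over each window.  Empty windows are kept
    with n_sites = 0 and NaN means so the grid stays regular; callers exclude
    them from threshold crossing.
    """
    _check_sorted(records)
    mean_cols = ["delta", "index_long", "index_short", "g_stat", *extra_mean_columns]
    out = []
    for chrom, grp in records.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        end = int(chromosome_ends[chrom]) if chromosome_ends else int(pos.max())
        starts = np.arange(1, end + 1, step, dtype=np.int64)
        # prefix sums -> O(1) window means via searchsorted
        prefixes = {c: np.concatenate([[0.0], np.cumsum(grp[c].to_numpy(float))]) for c in mean_cols}
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size, side="left")
        n = (hi - lo).astype(np.int64)
        frame = {
            "chromosome": chrom,
            "window_start": starts,
            "window_end": starts + window_size,
            "midpoint": starts + window_size // 2,
            "n_sites": n,
        }
        with np.errstate(invalid="ignore", divide="ignore"):
            for c in mean_cols:
                sums = prefixes[c][hi] - prefixes[c][lo]
                frame["mean_" + c] = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
        out.append(pd.DataFrame(frame))
    if not out:
        return pd.DataFrame(columns=["chromosome", "window_start", "window_end",
                                     "midpoint", "n_sites"])
    df = pd.concat(out, ignore_index=True)
    return df.rename(columns={"mean_index_long": "mean_index_long",
                              "mean_index_short": "mean_index_short"})


def tricube_smooth(
    positions: np.ndarray, values: np.ndarray, eval_points: np.ndarray, half_window: float
) -> np.ndarray:
    """Nadaraya-Watson smoothing with a tricube kernel over physical distance.

    k_i = (1 - (d_i/h)^3)^3 for d_i <= h, else 0.  At an evaluation point with
    no site within h the nearest site's value is used (only relevant for
    evaluation grids wider than the data).
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    eval_points = np.asarray(eval_points, dtype=float)
    out = np.empty(len(eval_points))
    lo = np.searchsorted(positions, eval_points - half_window, side="left")
    hi = np.searchsorted(positions, eval_points + half_window, side="right")
    for j, x in enumerate(eval_points):
        sl = slice(lo[j], hi[j])
        d = np.abs(positions[sl] - x)
        w = (1.0 - (d / half_window) ** 3) ** 3
        w[d > half_window] = 0.0
        total = w.sum()
        if total <= 0:
            nearest = np.argmin(np.abs(positions - x))
            out[j] = values[nearest]
        else:
            out[j] = float(w @ values[sl]) / total
    return out


def g_prime(records: pd.DataFrame, window_size: int = DEFAULT_WINDOW) -> pd.Series:
    """Per-site G': tricube-smoothed G over physical distance (h = window/2)."""
    _check_sorted(records)
    h = window_size / 2.0
    out = np.empty(len(records))
    for _, grp in records.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy(float)
        out[grp.index.to_numpy()] = tricube_smooth(pos, grp["g_stat"].to_numpy(float), pos, h)
    return pd.Series(out, index=records.index, name="g_prime")


@lru_cache(maxsize=1024)
def null_thresholds(
    bulk_size: int = 20,
    depth: int = 30,
    quantiles: tuple[float, ...] = (0.95, 0.99),
    replicates: int = 10_000,
    seed: int = 0,
) -> dict[float, tuple[float, float]]:
    """Monte-Carlo null quantiles of |Delta| for given bulk size and depth.

    Each replicate draws two independent bulks of ``bulk_size`` F2 individuals
    with genotype probabilities (1/4, 1/2, 1/4), computes each bulk's true
    allele frequency, samples Binomial(depth, freq) reads per bulk, and forms
    Delta.  Returns symmetric (low, high) = (-q, +q) per quantile, with q the
    empirical quantile of |Delta|.
    """
    if replicates < 1000:
        raise ValueError("need >= 1000 replicates for stable tail quantiles")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, bulk_size, depth)))
    deltas = np.empty(replicates)
    doses = rng.binomial(2, 0.5, size=(replicates, 2, bulk_size))  # Binomial(2,1/2) = 1:2:1
    freqs = doses.sum(axis=2) / (2.0 * bulk_size)
    reads = rng.binomial(depth, freqs)
    idx = reads / depth
    deltas = idx[:, 0] - idx[:, 1]
    abs_q = np.quantile(np.abs(deltas), quantiles)
    return {q: (-float(v), float(v)) for q, v in zip(quantiles, abs_q)}


def attach_site_thresholds(
    records: pd.DataFrame,
    bulk_size: int = 20,
    replicates: int = 10_000,
    seed: int = 0,
    depth_bin: int = 5,
) -> pd.DataFrame:
    """Add per-site null-threshold columns (thr95, thr99) conditioned on depth.

    Site depth = mean of the two bulk depths, binned to multiples of
    ``depth_bin`` so the Monte-Carlo table stays small; each bin's thresholds
    are simulated once and cached.
    """
    depth = (records["depth_long"] + records["depth_short"]) / 2.0
    bins = np.maximum(depth_bin, (np.round(depth / depth_bin) * depth_bin)).astype(int)
    out = records.copy()
    thr95 = np.empty(len(records))
    thr99 = np.empty(len(records))
    for b in np.unique(bins):
        table = null_thresholds(bulk_size=bulk_size, depth=int(b),
                                replicates=replicates, seed=seed)
        mask = bins == b
        thr95[mask] = table[0.95][1]
        thr99[mask] = table[0.99][1]
    out["thr95"] = thr95
    out["thr99"] = thr99
    return out


def scan(
    sites: Iterable[VariantSite],
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    bulk_size: int = 20,
    replicates: int = 10_000,
    seed: int = 0,
    chromosome_ends: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scan: per-site records (with G') and window statistics with
    95%/99% Delta confidence bounds.

    The window threshold is the mean of the member sites' depth-conditioned
    thresholds, mirroring how the window Delta is a mean of site Deltas.
    """
    records = compute_index_records(sites)
    records["g_prime"] = g_prime(records, window_size)
    records = attach_site_thresholds(
        records, bulk_size=bulk_size, replicates=replicates, seed=seed
    )
    windows = sliding_windows(
        records, window_size, step, chromosome_ends, extra_mean_columns=("thr95", "thr99")
    )
    windows["ci95_high"] = windows.pop("mean_thr95")
    windows["ci99_high"] = windows.pop("mean_thr99")
    windows["ci95_low"] = -windows["ci95_high"]
    windows["ci99_low"] = -windows["ci99_high"]
    # windowed G' evaluated at window midpoints from per-site G
    gp = np.empty(len(windows))
    for chrom, grp in windows.groupby("chromosome", sort=False):
        sub = records[records["chromosome"] == chrom]
        gp[grp.index.to_numpy()] = tricube_smooth(
            sub["position"].to_numpy(float), sub["g_stat"].to_numpy(float),
            grp["midpoint"].to_numpy(float), window_size / 2.0,
        )
    windows["g_prime"] = gp
    windows.loc[windows["n_sites"] == 0, "g_prime"] = np.nan
    return records, windows
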