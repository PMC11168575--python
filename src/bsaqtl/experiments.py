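"""Replicated synthetic experiments at the study's design conditions.

These drive the package's self-validation: seeded replicate sweeps that
measure QTL localization accuracy, null-threshold calibration, and
segregation-model recovery under the experimental design the scan targets
(an F2 of a few hundred plants, extreme bulks of 20 + 20, ~30x bulk depth,
one additive major QTL over a polygenic background).

Problem sizes are desk-scale: the 20-chromosome default genome carries
~10,000 marker sites (2-10 Mb chromosomes), and windows advance in 10 kb
steps (1 Mb width) — detection geometry is unchanged at coarser steps while
keeping a 50-replicate sweep in the minutes range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bsa_scan, inheritance, regions, simdata
from .variants import filter_sites

#: residual (polygenic + environmental) phenotype SD of the default design
_POLYGENIC_SD = 5.0
_ENV_SD = 3.0
RESIDUAL_SD = float(np.hypot(_POLYGENIC_SD, _ENV_SD))

SCAN_WINDOW = 1_000_000
SCAN_STEP = 10_000


def _design(seed: int, additive_effect: float, n_f2: int = 200) -> simdata.SimConfig:
    return simdata.SimConfig(
        n_f2=n_f2,
        qtl_chromosome="chr14",
        qtl_position=3_500_000,
        additive_effect=additive_effect,
        dominance_effect=0.0,
        baseline=35.0,
        polygenic_sd=_POLYGENIC_SD,
        env_sd=_ENV_SD,
        depth_mean=30.0,
        seq_error=0.001,
        bulk_rule=(20, 20),
        bulk_mode="top_n",
        seed=seed,
    )


@dataclass
class LocalizationSummary:
    n_replicates: int
    delta_peak_within_2mb: int
    gprime_same_chromosome: int
    region_contains_qtl: int

    @property
    def delta_rate(self) -> float:
        return self.delta_peak_within_2mb / self.n_replicates

    @property
    def gprime_rate(self) -> float:
        return self.gprime_same_chromosome / self.n_replicates

    @property
    def region_rate(self) -> float:
        return self.region_contains_qtl / self.n_replicates


def qtl_localization(
    n_replicates: int = 50,
    seed: int = 0,
    effect_in_residual_sds: float = 1.5,
    threshold_replicates: int = 10_000,
) -> LocalizationSummary:
    """Replicated single-QTL detection: 200 F2, bulks 20+20, depth 30, one
    additive QTL with a = ``effect_in_residual_sds`` x residual phenotype SD.

    Counts the replicates where (i) the maximal-Delta window midpoint falls
    within 2 Mb of the true QTL, (ii) the G' peak lands on the QTL
    chromosome, and (iii) a called 95% Delta region contains the QTL.
    """
    genome = simdata.default_genome()
    ends = {c.name: c.physical_length for c in genome.chromosomes}
    a = effect_in_residual_sds * RESIDUAL_SD
    hit_delta = hit_gp = hit_region = 0
    for rep in range(n_replicates):
        cfg = _design(seed=seed * 1000 + rep, additive_effect=a)
        _, _, _, sites = simdata.simulate_experiment(genome, cfg)
        kept = filter_sites(sites, min_depth_per_bulk=10)
        _, windows = bsa_scan.scan(
            kept, window_size=SCAN_WINDOW, step=SCAN_STEP,
            bulk_size=20, replicates=threshold_replicates, seed=seed,
            chromosome_ends=ends,
        )
        populated = windows[windows["n_sites"] > 0]
        top = populated.loc[populated["mean_delta"].idxmax()]
        if (
            top["chromosome"] == cfg.qtl_chromosome
            and abs(int(top["midpoint"]) - cfg.qtl_position) <= 2_000_000
        ):
            hit_delta += 1
        gp_top = populated.loc[populated["g_prime"].idxmax()]
        if gp_top["chromosome"] == cfg.qtl_chromosome:
            hit_gp += 1
        called = regions.call_regions(windows, "mean_delta", "ci95_high",
                                      step=SCAN_STEP)
        if any(
            r.chromosome == cfg.qtl_chromosome and r.start <= cfg.qtl_position <= r.end
            for r in called
        ):
            hit_region += 1
    return LocalizationSummary(n_replicates, hit_delta, hit_gp, hit_region)


def null_calibration(
    seed: int = 0, threshold_replicates: int = 10_000
) -> tuple[float, int]:
    """No-QTL genome (~10,000 sites, depth 30): fraction of populated windows
    whose |mean Delta| exceeds the simulated 95% bound.

    Returns (fraction, number of populated windows).  Overlapping windows are
    correlated, and window-mean averaging is conservative relative to the
    per-site bound, so the fraction should sit at or below the nominal 5%.
    """
    genome = simdata.default_genome()
    ends = {c.name: c.physical_length for c in genome.chromosomes}
    cfg = _design(seed=seed, additive_effect=0.0)
    _, _, _, sites = simdata.simulate_experiment(genome, cfg)
    kept = filter_sites(sites, min_depth_per_bulk=10)
    _, windows = bsa_scan.scan(
        kept, window_size=SCAN_WINDOW, step=SCAN_STEP,
        bulk_size=20, replicates=threshold_replicates, seed=seed,
        chromosome_ends=ends,
    )
    populated = windows[windows["n_sites"] > 0]
    frac = float((populated["mean_delta"].abs() > populated["ci95_high"]).mean())
    return frac, len(populated)


@dataclass
class SegregationSummary:
    n_seeds: int
    a_within_2: int
    m_within_1p5: int
    mean_a: float
    mean_m: float
    aic_rank_n: int
    aic_rank_wins: int
    null_selects_0mg: bool

    @property
    def aic_rank_rate(self) -> float:
        return self.aic_rank_wins / self.aic_rank_n


def segregation_recovery(
    n_seeds: int = 20, n_rank_replicates: int = 50, seed: int = 0
) -> SegregationSummary:
    """Parameter recovery and AIC model ranking at the inheritance-model
    design point (m = 30, a = 20, sigma_f = 5, n_F2 = 500).

    Also runs the strong-effect (a = 3 sigma_f) AIC ranking sweep and the
    pure-normal null selection check.
    """
    a_ok = m_ok = 0
    a_hats, m_hats = [], []
    for s in range(n_seeds):
        data = inheritance.simulate_generations(
            m=30.0, a=20.0, sigma_env=3.0, sigma_f2=5.0, n_f2=500,
            seed=seed * 1000 + s,
        )
        fit = inheritance.fit_model(data, "1MG-A")
        a_hats.append(fit.params["a"])
        m_hats.append(fit.params["m"])
        a_ok += abs(fit.params["a"] - 20.0) <= 2.0
        m_ok += abs(fit.params["m"] - 30.0) <= 1.5

    wins = 0
    for s in range(n_rank_replicates):
        data = inheritance.simulate_generations(
            m=30.0, a=15.0, sigma_env=3.0, sigma_f2=5.0, n_f2=300,
            seed=seed * 1000 + 500 + s,
        )
        _, ranked = inheritance.select_model(data, ("0MG", "1MG-A"))
        wins += ranked[0].model_id == "1MG-A"

    null_data = inheritance.simulate_generations(
        m=30.0, a=0.0, sigma_env=3.0, sigma_f2=6.0, n_f2=500,
        model_id="0MG", seed=seed * 1000 + 999,
    )
    null_best, _ = inheritance.select_model(null_data)

    return SegregationSummary(
        n_seeds=n_seeds,
        a_within_2=a_ok,
        m_within_1p5=m_ok,
        mean_a=float(np.mean(a_hats)),
        mean_m=float(np.mean(m_hats)),
        aic_rank_n=n_rank_replicates,
        aic_rank_wins=wins,
        null_selects_0mg=null_best.model_id == "0MG",
    )


def g_statistic_oracle_gap(n_tables: int = 1000, seed: int = 0) -> float:
    """Max |G - scipy log-likelihood-ratio G| over random 2x2 tables."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    tables = rng.integers(0, 60, size=(n_tables, 4))
    tables[:, 0] += 1
    tables[:, 3] += 1
    gap = 0.0
    for a, b, c, d in tables:
        obs = np.array([[a, b], [c, d]])
        if 0 in obs.sum(axis=0):
            continue
        g_ref, _, _, _ = stats.chi2_contingency(
            obs, correction=False, lambda_="log-likelihood"
        )
        gap = max(gap, abs(bsa_scan.g_statistic(a, b, c, d) - g_ref))
    return float(gap)
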