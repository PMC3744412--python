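"""Null-simulation calibration studies of the simultaneous inference.

These routines measure, by seeded replication of the full simulator +
smoothing + Monte-Carlo inference chain, the operating characteristics the
method promises: simultaneous band coverage under the null, familywise
type-I error of the threshold-adjusted p-values, and the 1:1 segregation of
an unselected pool.
"""

from __future__ import annotations

import numpy as np

from .cross import CrossConfig, sequence_pool, simulate_segregants
from .genome import Chromosome, GenomeLayout, evenly_spaced_markers
from .inference import InferenceConfig, build_profiles
from .smoothing import SmoothBasis, fit_pool_chromosome

MORGANS_PER_BP = 4e-6  # ~0.4 cM/kb, typical S. cerevisiae recombination rate


def _null_layout(n_chromosomes: int, chrom_length: int, markers_per_chrom: int) -> GenomeLayout:
    chroms = [
        Chromosome(f"chr{i + 1}", chrom_length, chrom_length * MORGANS_PER_BP)
        for i in range(n_chromosomes)
    ]
    return evenly_spaced_markers(
        GenomeLayout(chroms), markers_per_chrom * n_chromosomes
    )


def _fit_null_pools(
    layout: GenomeLayout,
    pool_size: int,
    coverage: float,
    rng: np.random.Generator,
    basis: SmoothBasis,
    seed: int,
):
    """Two independent unselected pools, fitted per chromosome."""
    cfg = CrossConfig(
        n_segregants=pool_size,
        pool_size=pool_size,
        mean_coverage=coverage,
        sequencing_error=0.002,
        seed=seed,
    )
    fits_q, fits_0 = {}, {}
    for fits in (fits_q, fits_0):
        genomes = simulate_segregants(layout, pool_size, rng)
        counts = sequence_pool(genomes, layout, cfg, rng)
        for chrom in layout.chromosome_names:
            sub = counts[counts["chrom"] == chrom]
            fits[chrom] = fit_pool_chromosome(
                sub["pos"].to_numpy(),
                sub["variant_count"].to_numpy(),
                sub["total_count"].to_numpy(),
                basis,
                pool_id="q" if fits is fits_q else "0",
                chrom=chrom,
                chrom_length=layout.chromosome(chrom).length_bp,
            )
    return fits_q, fits_0


def null_replicate(
    seed: int,
    *,
    n_chromosomes: int = 1,
    chrom_length: int = 1_000_000,
    markers_per_chrom: int = 300,
    pool_size: int = 58,
    coverage: float = 100.0,
    n_sims: int = 10_000,
    knots: int = 20,
    grid_bp: int = 5_000,
    alpha: float = 0.05,
    delta: float | None = None,
) -> tuple[bool, bool]:
    """One null genome: no QTLs, two unselected pools.

    Returns (band contains zero everywhere, any adjusted p < alpha).
    """
    layout = _null_layout(n_chromosomes, chrom_length, markers_per_chrom)
    rng = np.random.Generator(np.random.PCG64(seed))
    basis = SmoothBasis(knots=knots, grid_bp=grid_bp)
    fits_q, fits_0 = _fit_null_pools(layout, pool_size, coverage, rng, basis, seed)
    config = InferenceConfig(
        n_sims=n_sims,
        seed=seed,
        alpha=alpha,
        pool_size=pool_size,
        morgans_per_bp=MORGANS_PER_BP,
        **({} if delta is None else {"delta": delta}),
    )
    profiles = build_profiles(fits_q, fits_0, config)
    covered = all(bool(np.all((p.lo <= 0) & (0 <= p.hi))) for p in profiles)
    any_sig = any(bool(np.any(p.p_adj < alpha)) for p in profiles)
    return covered, any_sig


def band_coverage(n_replicates: int, seed: int, **kwargs) -> float:
    """Percent of null replicates whose band contains zero everywhere."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_replicates) % (2**31)
    hits = sum(null_replicate(int(s), **kwargs)[0] for s in seeds)
    return 100.0 * hits / n_replicates


def familywise_error(n_replicates: int, seed: int, **kwargs) -> float:
    """Fraction of null genomes with any adjusted p below the cut-off."""
    ss = np.random.SeedSequence(seed + 1)
    seeds = ss.generate_state(n_replicates) % (2**31)
    hits = sum(null_replicate(int(s), **kwargs)[1] for s in seeds)
    return hits / n_replicates


def unselected_pool_mean_frequency(
    seed: int,
    *,
    n_segregants: int = 58,
    n_markers: int = 2_000,
    n_chromosomes: int = 4,
    chrom_length: int = 1_000_000,
    coverage: float = 100.0,
    sequencing_error: float = 0.002,
) -> float:
    """Mean SNP variant frequency (percent) of a pooled unselected cross."""
    layout = _null_layout(n_chromosomes, chrom_length, n_markers // n_chromosomes)
    rng = np.random.Generator(np.random.PCG64(seed))
    cfg = CrossConfig(
        n_segregants=n_segregants,
        pool_size=n_segregants,
        mean_coverage=coverage,
        sequencing_error=sequencing_error,
        seed=seed,
    )
    genomes = simulate_segregants(layout, n_segregants, rng)
    counts = sequence_pool(genomes, layout, cfg, rng)
    freq = counts["variant_count"] / counts["total_count"].clip(lower=1)
    return 100.0 * float(freq.mean())
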