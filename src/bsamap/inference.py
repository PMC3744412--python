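"""Pool-vs-pool contrasts with simultaneous Monte-Carlo inference.

The contrast between a selected pool q and the unselected pool 0 is the log
odds ratio c(x) = eta_q(x) - eta_0(x).  Deviations of c from 0 locate QTLs:
positive peaks indicate linkage to the superior parent, negative peaks to
the inferior parent.

Two noise sources separate a measured contrast from the cross-level truth:

* read sampling — binomial noise of sequencing the pooled DNA, captured by
  the spline fits' coefficient covariance;
* segregant sampling — a pool of M segregants has a realised allele-
  frequency profile that wanders around the cross expectation with
  logit-scale variance ~ 4/M and Haldane map correlation exp(-2 d) over
  genetic distance d; at typical coverages this term dominates.

Simultaneity is obtained by the sup-t construction: curve deviations are
drawn from the joint Gaussian of both noise sources, the supremum over the
grid of the standardised deviation |dev|/SE is recorded per draw, and the
(1 - alpha) quantile z* of that sup distribution widens the band to joint
coverage.  On a single-point grid z* reduces to the pointwise normal
critical value.

Significance is tested against a biological-relevance threshold delta on the
log-odds scale: the statistic is t(x) = max(0, |c(x)| - delta)/SE(x) and the
adjusted two-sided p-value is the null probability that the genome-wide sup
exceeds t(x); p = 1 wherever the contrast lies inside the threshold band.
The default delta corresponds to an odds ratio outside [2/3, 3/2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ConfigurationError
from .smoothing import FrequencyFit

DEFAULT_DELTA = 0.4088  # log odds-ratio threshold; ~log(3/2)
DEFAULT_MORGANS_PER_BP = 4e-6  # ~0.4 cM/kb, typical for S. cerevisiae


@dataclass
class InferenceConfig:
    """Tuning of the Monte-Carlo simultaneous inference.

    ``pool_size`` enables the segregant-sampling variance term (None turns
    it off, leaving the read-noise-only construction).  ``morgans_per_bp``
    sets the genetic map scale of its along-chromosome correlation; a dict
    keyed by chromosome name overrides the scalar per chromosome.
    """

    delta: float = DEFAULT_DELTA
    alpha: float = 0.05
    n_sims: int = 10_000  # production analyses use 1_000_000
    seed: int = 0
    mask: list[tuple[str, int, int]] = field(default_factory=list)
    pool_size: int | None = 58
    pool_size_unselected: int | None = None  # defaults to pool_size
    morgans_per_bp: float | dict[str, float] = DEFAULT_MORGANS_PER_BP

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_sims < 100:
            raise ConfigurationError("n_sims must be >= 100")
        if self.pool_size is not None and self.pool_size < 1:
            raise ConfigurationError("pool_size must be >= 1")

    def rate_for(self, chrom: str) -> float:
        if isinstance(self.morgans_per_bp, dict):
            return self.morgans_per_bp[chrom]
        return float(self.morgans_per_bp)


@dataclass
class ContrastProfile:
    """Contrast curve with simultaneous band and adjusted p-values.

    ``se`` is the total standard error used for inference (read sampling
    plus, when enabled, segregant sampling).
    """

    chrom: str
    grid: np.ndarray
    contrast: np.ndarray
    se: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    p_adj: np.ndarray
    z_star: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.grid.astype(np.int64),
                "contrast": self.contrast,
                "se": self.se,
                "lo": self.lo,
                "hi": self.hi,
                "p_adj": self.p_adj,
            }
        )


@dataclass
class QTLCall:
    """A called QTL region (1-based closed interval, grid-snapped)."""

    chrom: str
    start: int
    end: int
    peak: int
    direction: str  # "superior" | "inferior"
    min_p: float
    max_abs_contrast: float


def _check_pair(fit_q: FrequencyFit, fit_0: FrequencyFit) -> None:
    if fit_q.chrom != fit_0.chrom:
        raise ConfigurationError("contrast requires fits on the same chromosome")
    if fit_q.grid.shape != fit_0.grid.shape or not np.allclose(fit_q.grid, fit_0.grid):
        raise ConfigurationError("contrast requires identical evaluation grids")


def compute_contrast(
    fit_q: FrequencyFit, fit_0: FrequencyFit
) -> tuple[np.ndarray, np.ndarray]:
    """Log odds ratio and its read-sampling SE on the shared grid."""
    _check_pair(fit_q, fit_0)
    contrast = fit_q.eta - fit_0.eta
    se = np.sqrt(fit_q.se**2 + fit_0.se**2)
    return contrast, se


def composition_covariance(
    grid: np.ndarray, pool_sizes: tuple[int, ...], morgans_per_bp: float
) -> np.ndarray:
    """Logit-scale covariance of the pools' realised frequency profiles.

    For an unselected pool of M segregants the frequency at a marker is
    Binomial(M, 1/2)/M; on the logit scale near 1/2 its variance is 4/M and
    the correlation between positions follows the probability of identical
    parental origin under Haldane's map function, exp(-2 d) with d in
    Morgans.  Independent pools add.
    """
    d = np.abs(grid[:, None] - grid[None, :]) * morgans_per_bp
    scale = 4.0 * sum(1.0 / m for m in pool_sizes)
    return scale * np.exp(-2.0 * d)


def _chol_sampler(cov: np.ndarray, what: str) -> np.ndarray:
    """Matrix G with G @ N(0, I) ~ N(0, cov); PSD-tolerant, rank-truncated."""
    cov = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(cov)
    top = np.max(np.abs(w)) if w.size else 0.0
    if w.size and np.min(w) < -1e-8 * top:
        raise ConfigurationError(f"covariance of {what} is not positive semi-definite")
    keep = w > 1e-10 * max(top, 1e-300)
    return V[:, keep] * np.sqrt(w[keep])


def _curve_sampler(fit: FrequencyFit) -> np.ndarray:
    """Read-sampling deviations of one fitted curve on its grid."""
    G = _chol_sampler(fit.cov, f"fit ({fit.pool_id}, {fit.chrom})")
    return fit.grid_design @ G


def _samplers_and_se(
    fit_q: FrequencyFit, fit_0: FrequencyFit, config: InferenceConfig
) -> tuple[list[np.ndarray], np.ndarray]:
    """Deviation samplers (one per noise source) and the total pointwise SE.

    The composition covariance is used unshrunk (not passed through the
    smoother's influence operator), which is mildly conservative: the fitted
    curve absorbs slightly less composition noise than the full profile
    carries.
    """
    _, se_read = compute_contrast(fit_q, fit_0)
    samplers = [_curve_sampler(fit_q), _curve_sampler(fit_0)]
    var = se_read**2
    if config.pool_size is not None:
        m0 = config.pool_size_unselected or config.pool_size
        cov_c = composition_covariance(
            fit_q.grid, (config.pool_size, m0), config.rate_for(fit_q.chrom)
        )
        samplers.append(_chol_sampler(cov_c, "segregant sampling"))
        var = var + np.diag(cov_c)
    return samplers, np.sqrt(var)


def _sup_draws(
    samplers: list[np.ndarray],
    se: np.ndarray,
    n_sims: int,
    rng: np.random.Generator,
    chunk: int = 20_000,
) -> np.ndarray:
    inv_se = 1.0 / np.maximum(se, 1e-300)
    sup = np.empty(n_sims)
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        dev = np.zeros((m, se.size))
        for G in samplers:
            dev += rng.standard_normal((m, G.shape[1])) @ G.T
        np.abs(dev, out=dev)
        dev *= inv_se
        sup[done : done + m] = dev.max(axis=1)
        done += m
    return sup


def null_sup_draws(
    fit_q: FrequencyFit,
    fit_0: FrequencyFit,
    config: InferenceConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-draw supremum over the grid of |simulated contrast error| / SE.

    One Monte-Carlo pass serves both the simultaneous band (its quantile is
    the band multiplier z*) and the adjusted p-values (its empirical tail is
    the null distribution of the sup statistic).
    """
    samplers, se = _samplers_and_se(fit_q, fit_0, config)
    return _sup_draws(samplers, se, config.n_sims, rng)


def total_se(
    fit_q: FrequencyFit, fit_0: FrequencyFit, config: InferenceConfig
) -> np.ndarray:
    """Pointwise SE of the contrast including all enabled noise sources."""
    _, se = _samplers_and_se(fit_q, fit_0, config)
    return se


def simultaneous_band(
    fit_q: FrequencyFit,
    fit_0: FrequencyFit,
    config: InferenceConfig,
    sup: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Simultaneous (1 - alpha) confidence band for the contrast.

    Returns (lo, hi, z*).  A precomputed sup-draw vector may be passed to
    share one Monte-Carlo pass between the band and the p-values.
    """
    contrast, _ = compute_contrast(fit_q, fit_0)
    samplers, se = _samplers_and_se(fit_q, fit_0, config)
    if sup is None:
        rng = np.random.Generator(np.random.PCG64(config.seed))
        sup = _sup_draws(samplers, se, config.n_sims, rng)
    z_star = float(np.quantile(sup, 1.0 - config.alpha))
    return contrast - z_star * se, contrast + z_star * se, z_star


def threshold_statistic(
    contrast: np.ndarray, se: np.ndarray, delta: float
) -> np.ndarray:
    """Distance beyond the relevance threshold in SE units."""
    return np.maximum(0.0, np.abs(contrast) - delta) / np.maximum(se, 1e-300)


def pvalues_from_sup(
    contrast: np.ndarray, se: np.ndarray, sup: np.ndarray, delta: float
) -> np.ndarray:
    t = threshold_statistic(contrast, se, delta)
    sup_sorted = np.sort(sup)
    # P(sup >= t) with >= so that t == 0 yields exactly 1
    exceed = sup.size - np.searchsorted(sup_sorted, t, side="left")
    p = exceed / sup.size
    p[np.abs(contrast) <= delta] = 1.0
    return p


def adjusted_pvalues(
    fit_q: FrequencyFit,
    fit_0: FrequencyFit,
    config: InferenceConfig,
    sup: np.ndarray | None = None,
) -> np.ndarray:
    """Multiplicity-adjusted two-sided p-value profile for one chromosome."""
    contrast, _ = compute_contrast(fit_q, fit_0)
    samplers, se = _samplers_and_se(fit_q, fit_0, config)
    if sup is None:
        rng = np.random.Generator(np.random.PCG64(config.seed))
        sup = _sup_draws(samplers, se, config.n_sims, rng)
    return pvalues_from_sup(contrast, se, sup, config.delta)


def build_profiles(
    fits_q: dict[str, FrequencyFit],
    fits_0: dict[str, FrequencyFit],
    config: InferenceConfig,
) -> list[ContrastProfile]:
    """Contrast + band + adjusted p per chromosome, simultaneous genome-wide.

    Per-chromosome sup draws (one seeded stream per chromosome) are combined
    by the per-draw maximum across chromosomes, giving the null distribution
    of the genome-wide sup; both the band multiplier and every p-value are
    computed against it.  With a single chromosome this coincides with the
    per-chromosome construction.
    """
    chroms = [c for c in fits_q if c in fits_0]
    if not chroms:
        raise ConfigurationError("no shared chromosomes between pools")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(chroms))
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    genome_sup = np.zeros(config.n_sims)
    for chrom, child in zip(chroms, children):
        rng = np.random.Generator(np.random.PCG64(child))
        samplers, se = _samplers_and_se(fits_q[chrom], fits_0[chrom], config)
        sup = _sup_draws(samplers, se, config.n_sims, rng)
        contrast, _ = compute_contrast(fits_q[chrom], fits_0[chrom])
        per_chrom[chrom] = (contrast, se)
        np.maximum(genome_sup, sup, out=genome_sup)
    z_star = float(np.quantile(genome_sup, 1.0 - config.alpha))
    profiles = []
    for chrom in chroms:
        contrast, se = per_chrom[chrom]
        p = pvalues_from_sup(contrast, se, genome_sup, config.delta)
        profiles.append(
            ContrastProfile(
                chrom=chrom,
                grid=fits_q[chrom].grid,
                contrast=contrast,
                se=se,
                lo=contrast - z_star * se,
                hi=contrast + z_star * se,
                p_adj=p,
                z_star=z_star,
            )
        )
    return profiles


def _apply_mask(profile: ContrastProfile, mask: list[tuple[str, int, int]]) -> np.ndarray:
    keep = np.ones(profile.grid.size, dtype=bool)
    for chrom, start, end in mask:
        if chrom == profile.chrom:
            keep &= ~((profile.grid >= start) & (profile.grid <= end))
    return keep


def call_qtls(
    profiles: list[ContrastProfile], config: InferenceConfig
) -> list[QTLCall]:
    """Turn p-value profiles into QTL region calls.

    Maximal runs of consecutive grid points with p < alpha and constant
    contrast sign become calls; runs separated by a single grid point are
    merged; masked intervals are excluded before calling.  Calls are sorted
    by minimum adjusted p.
    """
    calls: list[QTLCall] = []
    for prof in profiles:
        keep = _apply_mask(prof, config.mask)
        sig = (prof.p_adj < config.alpha) & keep
        sign = np.sign(prof.contrast)
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            continue
        runs: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            prev = runs[-1][-1]
            if i - prev <= 2 and sign[i] == sign[prev]:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            run = np.asarray(run)
            p_run = prof.p_adj[run]
            peak_i = run[np.argmax(np.abs(prof.contrast[run]))]
            calls.append(
                QTLCall(
                    chrom=prof.chrom,
                    start=int(prof.grid[run[0]]),
                    end=int(prof.grid[run[-1]]),
                    peak=int(prof.grid[peak_i]),
                    direction="superior" if sign[peak_i] > 0 else "inferior",
                    min_p=float(p_run.min()),
                    max_abs_contrast=float(np.abs(prof.contrast[run]).max()),
                )
            )
    calls.sort(key=lambda c: (c.min_p, -c.max_abs_contrast))
    return calls


def calls_frame(calls: list[QTLCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "peak": c.peak,
                "direction": c.direction,
                "min_p_adj": c.min_p,
                "max_abs_contrast": c.max_abs_contrast,
            }
            for c in calls
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "peak",
            "direction",
            "min_p_adj",
            "max_abs_contrast",
        ],
    )


def write_calls_bed(calls: list[QTLCall], path) -> None:
    """QTL calls as BED (0-based half-open, converted from 1-based closed)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.direction}\t{c.min_p:.3g}\n"
            )


def read_mask_bed(path) -> list[tuple[str, int, int]]:
    """Read masked intervals from BED (converted to 1-based closed)."""
    mask = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            mask.append((chrom, int(start) + 1, int(end)))
    return mask
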