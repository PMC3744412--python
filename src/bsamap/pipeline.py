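"""End-to-end pipeline: simulate a study, map QTLs, score segregants.

The mapping round follows the published workflow: filter parent SNPs into a
marker catalogue, fit the smoothed logit-frequency curve per pool per
chromosome, contrast each selected pool against the unselected pool 0,
build simultaneous bands and threshold-adjusted p-values by Monte Carlo,
and call QTL regions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cross import CrossResult, parent_counts, simulate_cross
from .genome import ConfigurationError, GenomeLayout
from .inference import (
    ContrastProfile,
    InferenceConfig,
    QTLCall,
    build_profiles,
    call_qtls,
    calls_frame,
    write_calls_bed,
)
from .scenario import Scenario
from .scoring import score_region, write_score_table
from .smoothing import FrequencyFit, SmoothBasis, fit_pool_chromosome, fit_profile_frame
from .variant_io import (
    FilterConfig,
    MarkerSet,
    filter_markers,
    write_counts_tsv,
    write_genotype_matrix,
    write_marker_set,
)

log = logging.getLogger(__name__)


def rates_from_layout(layout: GenomeLayout) -> dict[str, float]:
    """Per-chromosome recombination rate (Morgans/bp) from a layout."""
    return {
        c.name: c.genetic_length_morgans / c.length_bp for c in layout.chromosomes
    }


@dataclass
class StudyData:
    """Simulated study: original cross (pool 1) and optionally the
    downgraded-parent cross (pools 0 and 2)."""

    scenario: Scenario
    parent: pd.DataFrame
    pools: dict[str, pd.DataFrame]
    crosses: dict[str, CrossResult]


def simulate_study(scenario: Scenario) -> StudyData:
    """Run the configured cross(es) and assemble the pool count tables.

    Pool 1 is the selected pool of the original cross.  When a downgraded
    cross is configured, pool 0 (unselected baseline) and pool 2 (selected)
    come from it, mirroring the two-round mapping design; otherwise pool 0
    is the original cross's unselected pool.
    """
    original = simulate_cross(scenario.layout, scenario.model, scenario.original)
    rng_parent = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(scenario.original.seed).spawn(6)[5])
    )
    parent = parent_counts(scenario.layout, scenario.original, rng_parent)
    pools = {"pool1": original.selected_counts}
    crosses = {"original": original}
    if scenario.downgraded is not None:
        downgraded = simulate_cross(scenario.layout, scenario.model, scenario.downgraded)
        pools["pool0"] = downgraded.unselected_counts
        pools["pool2"] = downgraded.selected_counts
        crosses["downgraded"] = downgraded
    else:
        pools["pool0"] = original.unselected_counts
    return StudyData(scenario=scenario, parent=parent, pools=pools, crosses=crosses)


def write_study(data: StudyData, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = data.scenario.original.seed
    paths = {"parent": out / "parent_counts.tsv"}
    write_counts_tsv(data.parent, paths["parent"], seed=seed)
    for pid, counts in data.pools.items():
        paths[pid] = out / f"{pid}_counts.tsv"
        write_counts_tsv(counts, paths[pid], seed=seed)
    for tag, cross in data.crosses.items():
        p = out / f"genotypes_{tag}.tsv"
        write_genotype_matrix(cross.genotypes, p, seed=cross.config.seed)
        paths[f"genotypes_{tag}"] = p
    return paths


@dataclass
class MappingReport:
    """Everything one mapping round produces, plus provenance."""

    marker_set: MarkerSet
    fits: dict[str, dict[str, FrequencyFit]]  # pool -> chrom -> fit
    profiles: dict[str, list[ContrastProfile]]  # selected pool -> profiles
    calls: dict[str, list[QTLCall]]
    provenance: dict = field(default_factory=dict)


def _config_hash(*objs) -> str:
    blob = json.dumps([repr(o) for o in objs], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def fit_all_pools(
    marker_set: MarkerSet,
    pool_ids: list[str],
    basis: SmoothBasis,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, dict[str, FrequencyFit]]:
    fits: dict[str, dict[str, FrequencyFit]] = {}
    chroms = marker_set.markers["chrom"].unique()
    for pid in pool_ids:
        fits[pid] = {}
        for chrom in chroms:
            sub = marker_set.pool_counts(pid, chrom)
            fits[pid][chrom] = fit_pool_chromosome(
                sub["pos"].to_numpy(),
                sub["variant_count"].to_numpy(),
                sub["total_count"].to_numpy(),
                basis,
                pool_id=pid,
                chrom=chrom,
                chrom_length=(chrom_lengths or {}).get(chrom),
            )
    return fits


def map_pools(
    parent: pd.DataFrame,
    pools: dict[str, pd.DataFrame],
    *,
    unselected: str = "pool0",
    filter_config: FilterConfig = FilterConfig(),
    basis: SmoothBasis = SmoothBasis(),
    inference: InferenceConfig = InferenceConfig(),
    chrom_lengths: dict[str, int] | None = None,
) -> MappingReport:
    """One full mapping round over all selected pools against pool 0."""
    if unselected not in pools:
        raise ConfigurationError(
            f"unselected pool {unselected!r} is required: every contrast is "
            "taken against it to absorb systematic frequency artefacts"
        )
    marker_set = filter_markers(parent, filter_config)
    if marker_set.markers.empty:
        raise ConfigurationError("no markers survive the parent quality filter")
    for pid, counts in pools.items():
        marker_set.attach_pool(pid, counts)
    selected = [p for p in pools if p != unselected]
    fits = fit_all_pools(marker_set, [unselected, *selected], basis, chrom_lengths)
    profiles: dict[str, list[ContrastProfile]] = {}
    calls: dict[str, list[QTLCall]] = {}
    for pid in selected:
        profiles[pid] = build_profiles(fits[pid], fits[unselected], inference)
        calls[pid] = call_qtls(profiles[pid], inference)
    provenance = {
        "config_hash": _config_hash(filter_config, basis, inference),
        "seed": inference.seed,
        "n_markers": int(len(marker_set.markers)),
        "pools": sorted(pools),
    }
    return MappingReport(
        marker_set=marker_set, fits=fits, profiles=profiles, calls=calls,
        provenance=provenance,
    )


def write_report(report: MappingReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_marker_set(report.marker_set, out / "markers.tsv")
    for pid, by_chrom in report.fits.items():
        frames = [fit_profile_frame(f) for f in by_chrom.values()]
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"frequency_{pid}.tsv", sep="\t", index=False
        )
    for pid, profs in report.profiles.items():
        pd.concat([p.frame() for p in profs], ignore_index=True).to_csv(
            out / f"contrast_{pid}.tsv", sep="\t", index=False
        )
        calls_frame(report.calls[pid]).to_csv(
            out / f"qtl_calls_{pid}.tsv", sep="\t", index=False
        )
        write_calls_bed(report.calls[pid], out / f"qtl_calls_{pid}.bed")
    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=2) + "\n")


def score_study(data: StudyData, cross: str = "original", snps: list[str] | None = None) -> pd.DataFrame:
    """Fine-map by scoring SNPs in the individually genotyped selected
    segregants of one cross."""
    matrix = data.crosses[cross].genotypes
    if matrix.empty:
        raise ConfigurationError("empty genotype matrix")
    return score_region(matrix, snps)
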