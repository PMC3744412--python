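"""Study-shaped simulation scenarios and their flat key=value config files.

The default scenario mirrors the design of a two-cross pooled-segregant
QTL-mapping study in yeast: 16 chromosomes, ~2,000 genome-wide markers, two
major superior-linked QTLs, one minor inferior-linked QTL that also masks a
second minor QTL through allele-specific epistasis, 950 segregants in the
original cross and 2,464 in the downgraded-parent cross, pools of 58, and
~100x pooled coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cross import CrossConfig, PhenotypeModel, QtlEffect
from .genome import Chromosome, ConfigurationError, GenomeLayout, evenly_spaced_markers

# approximate S. cerevisiae chromosome sizes (bp), ~0.4 cM/kb
_YEAST_CHROMS = [
    ("chrI", 230_000), ("chrII", 813_000), ("chrIII", 317_000), ("chrIV", 1_532_000),
    ("chrV", 577_000), ("chrVI", 270_000), ("chrVII", 1_091_000), ("chrVIII", 563_000),
    ("chrIX", 440_000), ("chrX", 746_000), ("chrXI", 667_000), ("chrXII", 1_078_000),
    ("chrXIII", 924_000), ("chrXIV", 784_000), ("chrXV", 1_091_000), ("chrXVI", 948_000),
]
_CM_PER_KB = 0.40


@dataclass
class Scenario:
    """A full two-cross study specification."""

    layout: GenomeLayout
    model: PhenotypeModel
    original: CrossConfig
    downgraded: CrossConfig | None = None


def yeast_layout(n_markers: int = 2000, n_chromosomes: int = 16, seed: int = 7) -> GenomeLayout:
    chroms = [
        Chromosome(name, bp, bp / 1000 * _CM_PER_KB / 100)
        for name, bp in _YEAST_CHROMS[:n_chromosomes]
    ]
    layout = GenomeLayout(chromosomes=chroms)
    rng = np.random.Generator(np.random.PCG64(seed))
    return evenly_spaced_markers(layout, n_markers, rng)


def default_model() -> PhenotypeModel:
    return PhenotypeModel(
        qtls=[
            QtlEffect("qtl1", "chrXIV", 455_000, 2.0),
            QtlEffect("qtl2", "chrXV", 170_000, 1.5),
            QtlEffect("qtl3", "chrIV", 975_000, -0.8),
            QtlEffect("qtl5", "chrXII", 700_000, 0.8, epistatic_mask="qtl3"),
        ],
        baseline=0.0,
        noise_sd=1.0,
    )


def default_scenario(n_markers: int = 2000, seed: int = 0) -> Scenario:
    """The study-shaped default: original cross (950 segregants) plus a
    downgraded-parent cross (2,464 segregants, qtl1 and qtl3 neutralised)."""
    layout = yeast_layout(n_markers=n_markers)
    model = default_model()
    original = CrossConfig(n_segregants=950, pool_size=58, seed=seed)
    downgraded = CrossConfig(
        n_segregants=2464, pool_size=58, downgrade=("qtl1", "qtl3"), seed=seed + 1
    )
    return Scenario(layout=layout, model=model, original=original, downgraded=downgraded)


def small_scenario(n_markers: int = 600, n_chromosomes: int = 4, seed: int = 0,
                   n_segregants: int = 400) -> Scenario:
    """A reduced scenario for fast tests: fewer chromosomes and markers,
    QTLs relocated onto the retained chromosomes."""
    layout = yeast_layout(n_markers=n_markers, n_chromosomes=n_chromosomes)
    model = PhenotypeModel(
        qtls=[
            QtlEffect("qtl1", "chrII", 400_000, 2.0),
            QtlEffect("qtl3", "chrIV", 975_000, -0.8),
            QtlEffect("qtl5", "chrIII", 160_000, 0.8, epistatic_mask="qtl3"),
        ],
        noise_sd=1.0,
    )
    original = CrossConfig(n_segregants=n_segregants, pool_size=58, seed=seed)
    downgraded = CrossConfig(
        n_segregants=n_segregants, pool_size=58, downgrade=("qtl1", "qtl3"), seed=seed + 1
    )
    return Scenario(layout=layout, model=model, original=original, downgraded=downgraded)


def recovery_scenario(n_markers: int = 600, seed: int = 0) -> Scenario:
    """Planted-QTL recovery conditions: effects well above the noise so the
    selected pools approach fixation at the causative loci.

    One superior-linked major QTL, one inferior-linked major QTL that also
    masks a minor QTL through allele-specific epistasis.  The downgraded
    cross neutralises both majors, abolishing their linkage and releasing
    the masked QTL.
    """
    layout = yeast_layout(n_markers=n_markers, n_chromosomes=4)
    model = PhenotypeModel(
        qtls=[
            QtlEffect("qtl1", "chrII", 400_000, 3.0),
            QtlEffect("qtl3", "chrIV", 975_000, -3.0),
            QtlEffect("qtl5", "chrIII", 160_000, 1.5, epistatic_mask="qtl3"),
        ],
        noise_sd=1.0,
    )
    original = CrossConfig(n_segregants=950, pool_size=58, seed=seed)
    downgraded = CrossConfig(
        n_segregants=2464, pool_size=58, downgrade=("qtl1", "qtl3"), seed=seed + 1
    )
    return Scenario(layout=layout, model=model, original=original, downgraded=downgraded)


def null_scenario(
    n_markers: int, n_chromosomes: int, n_segregants: int = 58, seed: int = 0,
    mean_coverage: float = 100.0,
) -> Scenario:
    """No QTLs: every marker segregates 1:1; used for calibration checks."""
    layout = yeast_layout(n_markers=n_markers, n_chromosomes=n_chromosomes)
    model = PhenotypeModel(qtls=[], noise_sd=1.0)
    cfg = CrossConfig(
        n_segregants=n_segregants, pool_size=n_segregants,
        mean_coverage=mean_coverage, seed=seed,
    )
    return Scenario(layout=layout, model=model, original=cfg)


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    """Serialise a scenario to a flat key=value file (repeated keys for
    chromosomes, markers and QTLs)."""
    lines = []
    for c in scenario.layout.chromosomes:
        lines.append(f"chromosome={c.name},{c.length_bp},{c.genetic_length_morgans}")
    for name, pos in scenario.layout.markers.items():
        lines.append(f"markers={name}," + ",".join(str(int(p)) for p in pos))
    for q in scenario.model.qtls:
        mask = q.epistatic_mask or "-"
        lines.append(f"qtl={q.qtl_id},{q.chrom},{q.pos},{q.effect},{mask}")
    lines.append(f"baseline={scenario.model.baseline}")
    lines.append(f"noise_sd={scenario.model.noise_sd}")
    for tag, cfg in (("original", scenario.original), ("downgraded", scenario.downgraded)):
        if cfg is None:
            continue
        lines.append(
            f"{tag}={cfg.n_segregants},{cfg.pool_size},{cfg.mean_coverage},"
            f"{cfg.sequencing_error},{cfg.seed}," + (";".join(cfg.downgrade) or "-")
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_scenario(path: str | Path) -> Scenario:
    chroms, markers, qtls = [], {}, []
    baseline, noise_sd = 0.0, 1.0
    crosses: dict[str, CrossConfig] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        if "=" not in raw:
            raise ConfigurationError(f"{path}:{lineno}: expected key=value")
        key, value = raw.split("=", 1)
        if key == "chromosome":
            name, bp, gm = value.split(",")
            chroms.append(Chromosome(name, int(bp), float(gm)))
        elif key == "markers":
            parts = value.split(",")
            markers[parts[0]] = np.array([int(p) for p in parts[1:]], dtype=np.int64)
        elif key == "qtl":
            qid, chrom, pos, effect, mask = value.split(",")
            qtls.append(
                QtlEffect(qid, chrom, int(pos), float(effect),
                          None if mask == "-" else mask)
            )
        elif key == "baseline":
            baseline = float(value)
        elif key == "noise_sd":
            noise_sd = float(value)
        elif key in ("original", "downgraded"):
            n, pool, cov, err, seed, dg = value.split(",")
            crosses[key] = CrossConfig(
                n_segregants=int(n), pool_size=int(pool), mean_coverage=float(cov),
                sequencing_error=float(err), seed=int(seed),
                downgrade=tuple(d for d in dg.split(";") if d and d != "-"),
            )
        else:
            raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
    if "original" not in crosses:
        raise ConfigurationError(f"{path}: missing 'original' cross line")
    layout = GenomeLayout(chromosomes=chroms, markers=markers)
    model = PhenotypeModel(qtls=qtls, baseline=baseline, noise_sd=noise_sd)
    return Scenario(layout=layout, model=model, original=crosses["original"],
                    downgraded=crosses.get("downgraded"))
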