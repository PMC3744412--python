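"""Synthetic yeast cross: meiosis, phenotypes, pool selection and sequencing.

Emulates the design of a pooled-segregant QTL-mapping experiment: a diploid
hybrid of a phenotypically superior and an inferior haploid parent is
sporulated; haploid F1 segregants are phenotyped; an extreme pool (and an
unselected control pool) of equal size is sequenced; per-marker read counts
carry the selection signal.

Conventions
-----------
* allele labels: ``S`` = superior-parent allele, ``I`` = inferior-parent
  allele.  "Variant" read counts always refer to the superior-parent allele
  (the reference genome matches the inferior parent).
* a positive QTL effect means the superior-parent allele raises the
  phenotype; a negative effect means the *inferior*-parent allele raises it
  (the "linked to the inferior parent" case).
* epistatic masking is complete: a masked QTL contributes nothing whenever
  its masking locus carries the masking locus's phenotypically beneficial
  allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import ConfigurationError, GenomeLayout

SUPERIOR = 1  # encodes parental origin "S"
INFERIOR = 0


@dataclass(frozen=True)
class QtlEffect:
    """A quantitative trait locus planted in the cross.

    ``effect`` is in phenotype units.  ``epistatic_mask`` names another QTL
    whose beneficial allele nullifies this one (allele-specific epistasis).
    """

    qtl_id: str
    chrom: str
    pos: int
    effect: float
    epistatic_mask: str | None = None

    @property
    def beneficial_origin(self) -> int:
        """Parental origin whose allele raises the phenotype at this locus."""
        return SUPERIOR if self.effect >= 0 else INFERIOR


@dataclass
class PhenotypeModel:
    qtls: list[QtlEffect]
    baseline: float = 0.0
    noise_sd: float = 1.0
    # QTLs whose phenotypic allele is fixed to the inferior variant
    # (downgraded parents); marker segregation is untouched.
    downgraded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        ids = [q.qtl_id for q in self.qtls]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate QTL ids")
        by_id = {q.qtl_id: q for q in self.qtls}
        for q in self.qtls:
            seen = {q.qtl_id}
            cur = q
            while cur.epistatic_mask is not None:
                if cur.epistatic_mask not in by_id:
                    raise ConfigurationError(
                        f"QTL {cur.qtl_id}: unknown mask {cur.epistatic_mask!r}"
                    )
                cur = by_id[cur.epistatic_mask]
                if cur.qtl_id in seen:
                    raise ConfigurationError("cyclic epistatic_mask chain")
                seen.add(cur.qtl_id)

    def qtl(self, qtl_id: str) -> QtlEffect:
        for q in self.qtls:
            if q.qtl_id == qtl_id:
                return q
        raise ConfigurationError(f"unknown QTL id {qtl_id!r}")


@dataclass
class SegregantGenome:
    """Haploid recombinant mosaic: per chromosome, sorted crossover
    breakpoints and the parental origin of the leftmost interval.

    Origin at position x is ``first_origin`` flipped once per breakpoint <= x.
    """

    blocks: dict[str, tuple[np.ndarray, int]]

    def origin_at(self, chrom: str, pos) -> np.ndarray:
        breakpoints, first = self.blocks[chrom]
        n_flips = np.searchsorted(breakpoints, np.atleast_1d(pos), side="right")
        return (first + n_flips) % 2


@dataclass
class CrossConfig:
    """Parameters of one simulated cross/pooling/sequencing round."""

    n_segregants: int = 950
    pool_size: int = 58
    selection: str = "top-k"  # or "phenotype-threshold"
    phenotype_threshold: float | None = None
    mean_coverage: float = 100.0
    sequencing_error: float = 0.002
    downgrade: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segregants < 1:
            raise ConfigurationError("n_segregants must be >= 1")
        if self.pool_size > self.n_segregants:
            raise ConfigurationError("pool_size must be <= n_segregants")
        if self.mean_coverage <= 0:
            raise ConfigurationError("mean_coverage must be > 0")
        if not (0 <= self.sequencing_error < 0.5):
            raise ConfigurationError("sequencing_error must be in [0, 0.5)")
        if self.selection not in ("top-k", "phenotype-threshold"):
            raise ConfigurationError(f"unknown selection mode {self.selection!r}")


def simulate_meiosis(layout: GenomeLayout, rng: np.random.Generator) -> SegregantGenome:
    """Draw one haploid segregant.

    Crossovers per chromosome are Poisson with mean equal to the genetic
    length in Morgans (no interference); breakpoints are uniform in bp.  The
    leftmost interval's parental origin is a fair coin, so every marker
    segregates 1:1 marginally.
    """
    blocks: dict[str, tuple[np.ndarray, int]] = {}
    for chrom in layout.chromosomes:
        n_co = rng.poisson(chrom.genetic_length_morgans)
        breakpoints = np.sort(rng.uniform(1.0, float(chrom.length_bp), size=n_co))
        first = int(rng.integers(0, 2))
        blocks[chrom.name] = (breakpoints, first)
    return SegregantGenome(blocks=blocks)


def simulate_segregants(
    layout: GenomeLayout, n: int, rng: np.random.Generator
) -> list[SegregantGenome]:
    return [simulate_meiosis(layout, rng) for _ in range(n)]


def _allele_at(genome: SegregantGenome, q: QtlEffect, downgraded: frozenset[str]) -> int:
    """Phenotypic allele at a QTL, honouring downgraded parents.

    Downgrading fixes the locus to the phenotypically *inferior* variant:
    the opposite of the QTL's beneficial origin.
    """
    if q.qtl_id in downgraded:
        return 1 - q.beneficial_origin
    return int(genome.origin_at(q.chrom, q.pos)[0])


def genetic_value(genome: SegregantGenome, model: PhenotypeModel) -> float:
    """Deterministic part of the phenotype: baseline + active QTL effects."""
    by_id = {q.qtl_id: q for q in model.qtls}
    total = model.baseline
    for q in model.qtls:
        if q.epistatic_mask is not None:
            masker = by_id[q.epistatic_mask]
            if _allele_at(genome, masker, model.downgraded) == masker.beneficial_origin:
                continue  # effect completely masked
        if _allele_at(genome, q, model.downgraded) == q.beneficial_origin:
            total += abs(q.effect)
    return total


def assign_phenotype(
    genome: SegregantGenome, model: PhenotypeModel, rng: np.random.Generator
) -> float:
    """Phenotype = genetic value + Gaussian environmental noise."""
    for q in model.qtls:
        chrom = genome.blocks.get(q.chrom)
        if chrom is None:
            raise ConfigurationError(f"QTL {q.qtl_id} lies off the simulated genome")
    noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
    return genetic_value(genome, model) + noise


def select_and_pool(
    phenotypes: np.ndarray, config: CrossConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the selected pool and an unselected control pool of equal size.

    Selected: the ``pool_size`` highest phenotypes (ties broken by a seeded
    draw) or everything above ``phenotype_threshold``.  Unselected: a simple
    random sample of ``pool_size`` segregants — it models a sequenced control
    pool, not the full segregant set.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    n = phenotypes.size
    if config.pool_size > n:
        raise ConfigurationError("pool_size exceeds number of segregants")
    if config.selection == "top-k":
        jitter = rng.permutation(n)  # seeded tie-break
        order = np.lexsort((jitter, -phenotypes))
        selected = np.sort(order[: config.pool_size])
    else:
        if config.phenotype_threshold is None:
            raise ConfigurationError("phenotype-threshold selection needs a threshold")
        selected = np.flatnonzero(phenotypes >= config.phenotype_threshold)
        if selected.size < config.pool_size:
            raise ConfigurationError(
                f"threshold leaves only {selected.size} segregants, "
                f"need at least {config.pool_size}"
            )
    unselected = np.sort(rng.choice(n, size=config.pool_size, replace=False))
    return selected, unselected


def pool_allele_frequencies(
    genomes: list[SegregantGenome], layout: GenomeLayout
) -> pd.DataFrame:
    """True superior-allele frequency per marker over the pool members."""
    if not genomes:
        raise ConfigurationError("empty pool")
    rows = []
    for chrom in layout.chromosomes:
        pos = layout.markers.get(chrom.name)
        if pos is None or pos.size == 0:
            continue
        freq = np.zeros(pos.size)
        for g in genomes:
            freq += g.origin_at(chrom.name, pos)
        freq /= len(genomes)
        rows.append(pd.DataFrame({"chrom": chrom.name, "pos": pos, "true_freq": freq}))
    return pd.concat(rows, ignore_index=True)


def sequence_pool(
    genomes: list[SegregantGenome],
    layout: GenomeLayout,
    config: CrossConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate pooled sequencing read counts at every marker.

    Coverage is Poisson(mean_coverage) per marker; each read's parental
    identity is drawn from the pool's true allele frequency and flipped with
    probability ``sequencing_error``.  Returns columns
    chrom, pos, variant_count, total_count (variant = superior allele).
    """
    freqs = pool_allele_frequencies(genomes, layout)
    f = freqs["true_freq"].to_numpy()
    e = config.sequencing_error
    p_read = f * (1 - e) + (1 - f) * e
    total = rng.poisson(config.mean_coverage, size=f.size)
    variant = rng.binomial(total, p_read)
    return pd.DataFrame(
        {
            "chrom": freqs["chrom"],
            "pos": freqs["pos"],
            "variant_count": variant,
            "total_count": total,
        }
    )


def apply_downgrade(model: PhenotypeModel, qtl_ids: tuple[str, ...] | list[str]) -> PhenotypeModel:
    """Return the phenotype model of the downgraded-parent cross.

    Each named QTL's beneficial allele is replaced by the inferior variant in
    every segregant, neutralising its effect (and releasing any QTL it
    masks).  The marker catalogue is unchanged.
    """
    for qid in qtl_ids:
        model.qtl(qid)  # raises on unknown id
    return replace(model, downgraded=model.downgraded | frozenset(qtl_ids))


@dataclass
class CrossResult:
    """Everything one simulated cross produces."""

    layout: GenomeLayout
    model: PhenotypeModel
    config: CrossConfig
    phenotypes: np.ndarray
    selected_ids: np.ndarray
    unselected_ids: np.ndarray
    selected_counts: pd.DataFrame
    unselected_counts: pd.DataFrame
    genotypes: pd.DataFrame  # segregants x markers, values "S"/"I"
    genomes: list[SegregantGenome] = field(repr=False, default_factory=list)


def genotype_matrix(
    genomes: list[SegregantGenome],
    layout: GenomeLayout,
    ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-segregant genotype calls at every marker, coded S/I."""
    frame = layout.marker_frame()
    cols = [f"{c}:{p}" for c, p in zip(frame["chrom"], frame["pos"])]
    sel = range(len(genomes)) if ids is None else ids
    data = []
    index = []
    for i in sel:
        g = genomes[i]
        row = np.concatenate(
            [
                g.origin_at(c.name, layout.markers[c.name])
                for c in layout.chromosomes
                if layout.markers.get(c.name) is not None and layout.markers[c.name].size
            ]
        )
        data.append(np.where(row == SUPERIOR, "S", "I"))
        index.append(f"seg{int(i):05d}")
    return pd.DataFrame(data, index=index, columns=cols)


def simulate_cross(
    layout: GenomeLayout,
    model: PhenotypeModel,
    config: CrossConfig,
) -> CrossResult:
    """Run a full cross: meiosis, phenotyping, pooling and pooled sequencing.

    All randomness flows from ``config.seed`` through independent child
    streams, so results are reproducible bit-for-bit.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_meiosis, rng_pheno, rng_pool, rng_seq_sel, rng_seq_uns = (
        np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(5)
    )
    if config.downgrade:
        model = apply_downgrade(model, config.downgrade)
    genomes = simulate_segregants(layout, config.n_segregants, rng_meiosis)
    phenotypes = np.array([assign_phenotype(g, model, rng_pheno) for g in genomes])
    selected, unselected = select_and_pool(phenotypes, config, rng_pool)
    sel_counts = sequence_pool([genomes[i] for i in selected], layout, config, rng_seq_sel)
    uns_counts = sequence_pool([genomes[i] for i in unselected], layout, config, rng_seq_uns)
    genotypes = genotype_matrix(genomes, layout, selected)
    return CrossResult(
        layout=layout,
        model=model,
        config=config,
        phenotypes=phenotypes,
        selected_ids=selected,
        unselected_ids=unselected,
        selected_counts=sel_counts,
        unselected_counts=uns_counts,
        genotypes=genotypes,
        genomes=genomes,
    )


def parent_counts(
    layout: GenomeLayout,
    config: CrossConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sequencing counts for the superior parent itself (all-S haplotype).

    Used to exercise the marker quality filter: the superior parent is
    homozygous for the variant allele at every true marker, so its variant
    ratio is 1 - sequencing_error in expectation.
    """
    frame = layout.marker_frame()
    e = config.sequencing_error
    total = rng.poisson(config.mean_coverage, size=len(frame))
    variant = rng.binomial(total, 1.0 - e)
    return pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "pos": frame["pos"],
            "variant_count": variant,
            "total_count": total,
        }
    )
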