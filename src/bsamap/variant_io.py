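"""Reading and writing variant count tables; the SNP marker quality filter.

The marker catalogue is built from the superior parent's sequencing against
the reference genome (which matches the inferior parent): a site is kept as
a marker iff the parent shows sufficient coverage (>= 20 reads by default)
and a sufficient variant ratio (>= 80% by default), both bounds inclusive.
Pool frequencies are never filtered — they are the quantity under study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ConfigurationError

log = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "variant_count", "total_count"]


@dataclass(frozen=True)
class FilterConfig:
    """Marker quality filter thresholds (both comparisons inclusive)."""

    min_coverage: int = 20
    min_ratio: float = 0.80

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ConfigurationError("min_coverage must be >= 1")
        if not (0 < self.min_ratio <= 1):
            raise ConfigurationError("min_ratio must be in (0, 1]")


@dataclass
class MarkerSet:
    """Quality-filtered markers with per-pool counts on a shared frame.

    ``markers`` has columns chrom, pos plus the parent counts; ``pools`` maps
    pool-id -> DataFrame aligned to the same (chrom, pos) rows.  Sites absent
    from a pool carry (0, 0) counts and get zero weight downstream.
    """

    markers: pd.DataFrame
    pools: dict[str, pd.DataFrame] = field(default_factory=dict)

    def attach_pool(self, pool_id: str, counts: pd.DataFrame) -> None:
        frame = self.markers[["chrom", "pos"]]
        merged = frame.merge(counts, on=["chrom", "pos"], how="left")
        merged[["variant_count", "total_count"]] = (
            merged[["variant_count", "total_count"]].fillna(0).astype(np.int64)
        )
        self.pools[pool_id] = merged

    def pool_counts(self, pool_id: str, chrom: str | None = None) -> pd.DataFrame:
        df = self.pools[pool_id]
        return df if chrom is None else df[df["chrom"] == chrom].reset_index(drop=True)


def read_counts(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a per-site count table from TSV or VCF.

    TSV dialect: header line (may start with ``#``) then columns
    chrom, pos, variant_count, total_count.  VCF: one sample, per-sample AD;
    variant_count is the ALT depth, total the sum of depths.  Multiallelic
    and indel records are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "tsv":
        return _read_counts_tsv(path)
    if format == "vcf":
        return _read_counts_vcf(path)
    raise ConfigurationError(f"unknown format {format!r}")


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "chrom":  # bare header
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), int(parts[3]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if rows[-1][2] > rows[-1][3] or rows[-1][1] < 1:
                raise ValueError(
                    f"{path}:{lineno}: need 0 <= variant_count <= total_count, pos >= 1"
                )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def _read_counts_vcf(path: Path) -> pd.DataFrame:
    import pysam

    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"{path}: expected exactly one sample, found {len(samples)}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                skipped += 1  # indel
                continue
            ad = rec.samples[samples[0]].get("AD")
            if ad is None or any(x is None for x in ad):
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks AD")
            rows.append((rec.chrom, rec.pos, int(ad[1]), int(sum(ad))))
    if skipped:
        log.info("%s: skipped %d multiallelic/indel records", path, skipped)
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("#" + "\t".join(COUNT_COLUMNS) + "\n")
        counts.to_csv(fh, sep="\t", header=False, index=False)


def write_counts_vcf(counts: pd.DataFrame, path: str | Path, sample: str = "pool") -> None:
    """Minimal single-sample VCF with AD; REF/ALT are placeholders (A/T)."""
    import pysam

    header = pysam.VariantHeader()
    for chrom, grp in counts.groupby("chrom", sort=False):
        header.contigs.add(str(chrom), length=int(grp["pos"].max()) + 1)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in counts.itertuples(index=False):
            rec = out.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1, alleles=("A", "T")
            )
            rec.samples[sample]["AD"] = (
                int(row.total_count - row.variant_count),
                int(row.variant_count),
            )
            out.write(rec)


def filter_markers(parent: pd.DataFrame, config: FilterConfig = FilterConfig()) -> MarkerSet:
    """Apply the parent coverage/ratio filter and return the marker frame.

    Retained iff total >= min_coverage AND variant/total >= min_ratio.
    Duplicated (chrom, pos) keeps the first record (logged); output sorted.
    """
    df = parent.copy()
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        log.info("dropping %d duplicated marker records (first wins)", int(dup.sum()))
        df = df[~dup]
    total = df["total_count"].to_numpy()
    variant = df["variant_count"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, variant / np.maximum(total, 1), 0.0)
    keep = (total >= config.min_coverage) & (ratio >= config.min_ratio)
    out = df[keep].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if out.empty:
        log.warning("marker filter retained no sites")
    out = out.rename(
        columns={"variant_count": "parent_variant_count", "total_count": "parent_total"}
    )
    return MarkerSet(markers=out)


def write_marker_set(ms: MarkerSet, path: str | Path) -> None:
    frame = ms.markers.copy()
    for pid, counts in ms.pools.items():
        frame[f"{pid}_variant"] = counts["variant_count"].to_numpy()
        frame[f"{pid}_total"] = counts["total_count"].to_numpy()
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(frame.columns) + "\n")
        frame.to_csv(fh, sep="\t", header=False, index=False)


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None, skiprows=_seed_rows(path))
    return df


def _seed_rows(path: str | Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.startswith("# seed=") else 0


def write_genotype_matrix(matrix: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        matrix.to_csv(fh, sep="\t")
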