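"""Genome coordinate frame and marker catalogue.

Coordinates are 1-based base pairs; intervals are closed on both ends,
matching how QTL regions are reported in yeast genetics (e.g.
"435069-475213 on chromosome XIV").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a layout, scenario or run configuration is invalid."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: physical length in bp and genetic length in Morgans."""

    name: str
    length_bp: int
    genetic_length_morgans: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ConfigurationError(f"chromosome {self.name}: length_bp must be >= 1")
        if not np.isfinite(self.genetic_length_morgans) or self.genetic_length_morgans < 0:
            raise ConfigurationError(
                f"chromosome {self.name}: genetic length must be finite and >= 0"
            )


@dataclass
class GenomeLayout:
    """Ordered chromosomes plus the parent-distinguishing SNP marker positions.

    Parameters
    ----------
    chromosomes
        Ordered list of :class:`Chromosome`.
    markers
        Mapping chromosome name -> strictly increasing 1-based bp positions.
    """

    chromosomes: list[Chromosome]
    markers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigurationError("layout needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        self.markers = {k: np.asarray(v, dtype=np.int64) for k, v in self.markers.items()}
        by_name = {c.name: c for c in self.chromosomes}
        for name, pos in self.markers.items():
            if name not in by_name:
                raise ConfigurationError(f"markers given for unknown chromosome {name!r}")
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise ConfigurationError(f"marker positions on {name} not strictly increasing")
            if pos.size and (pos[0] < 1 or pos[-1] > by_name[name].length_bp):
                raise ConfigurationError(f"marker positions on {name} outside [1, length]")

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise ConfigurationError(f"unknown chromosome {name!r}")

    def n_markers(self) -> int:
        return int(sum(len(v) for v in self.markers.values()))

    def marker_frame(self):
        """All markers as a (chrom, pos) pandas DataFrame in layout order."""
        import pandas as pd

        rows = [
            (c.name, int(p))
            for c in self.chromosomes
            for p in self.markers.get(c.name, ())
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos"])


def evenly_spaced_markers(layout: GenomeLayout, n_total: int, rng: np.random.Generator | None = None) -> GenomeLayout:
    """Return a copy of *layout* carrying ~n_total markers spread over the
    genome proportionally to physical length (jittered if *rng* given)."""
    total_bp = sum(c.length_bp for c in layout.chromosomes)
    markers: dict[str, np.ndarray] = {}
    for c in layout.chromosomes:
        n = max(2, int(round(n_total * c.length_bp / total_bp)))
        pos = np.linspace(1, c.length_bp, n)
        if rng is not None:
            step = (c.length_bp - 1) / max(n - 1, 1)
            pos = pos + rng.uniform(-0.3 * step, 0.3 * step, size=n)
            pos = np.clip(pos, 1, c.length_bp)
        pos = np.unique(np.round(pos).astype(np.int64))
        markers[c.name] = pos
    return GenomeLayout(chromosomes=list(layout.chromosomes), markers=markers)
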