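#!/usr/bin/env python
"""Fine-map the called QTLs by scoring SNPs in individual segregants.

Uses the genotype matrix of the selected segregants from the original
cross (written by 01_simulate_crosses.py), picks the scored SNPs closest
to each planted QTL plus flanking markers, computes per-SNP association
percentages, two-sided binomial exact p-values against 1:1 segregation and
Benjamini-Yekutieli FDR-adjusted p-values, and writes the report table
under results/scoring/.
"""

from pathlib import Path

import numpy as np

from bsamap.scenario import read_scenario
from bsamap.scoring import score_region, write_score_table
from bsamap.variant_io import read_genotype_matrix

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
OUT = ROOT / "results" / "scoring"


def nearest_snps(columns, chrom, pos, k=3):
    cands = [(abs(int(c.split(":")[1]) - pos), c) for c in columns
             if c.split(":")[0] == chrom]
    return [c for _, c in sorted(cands)[:k]]


def main() -> None:
    scenario = read_scenario(DATA / "scenario.cfg")
    OUT.mkdir(parents=True, exist_ok=True)
    for cross in ("original", "downgraded"):
        matrix = read_genotype_matrix(DATA / f"genotypes_{cross}.tsv")
        snps: list[str] = []
        for q in scenario.model.qtls:
            snps.extend(nearest_snps(matrix.columns, q.chrom, q.pos))
        table = score_region(matrix, sorted(set(snps)))
        write_score_table(table, OUT / f"associations_{cross}.tsv")
        print(f"\n{cross} cross, {len(matrix)} selected segregants:")
        print(table.to_string(index=False,
                              float_format=lambda x: f"{x:.3g}"))


if __name__ == "__main__":
    main()
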