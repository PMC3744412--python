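"""Fine-mapping statistics on individually genotyped segregants.

For each scored SNP, the association to the superior parent is the percent
of non-missing segregant calls carrying the superior allele; departure from
1:1 segregation is tested with a two-sided binomial exact test and adjusted
for multiple testing with the Benjamini-Yekutieli FDR method, which is valid
under arbitrary dependency between linked SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests


def binomial_exact_two_sided(k: int, n: int) -> float:
    """Two-sided exact binomial p-value against Binomial(n, 1/2).

    Convention: p = min(1, 2 * min(P(X <= k), P(X >= k))), tails exact.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def by_fdr(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    Raw p-values are inflated by m * c(m) / rank with c(m) = sum_{i<=m} 1/i,
    then made monotone from the largest rank down and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def score_region(matrix: pd.DataFrame, snps: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP association and exact-test statistics over a genotype matrix.

    ``matrix``: segregants x SNPs with values "S" (superior allele), "I"
    (inferior allele) or missing (NaN/empty).  Missing calls are excluded
    from n per SNP.  Returns a table sorted by position with columns
    snp, n, k, association_pct, p_raw, p_fdr; the BY adjustment runs across
    the scored SNP set.
    """
    if snps is None:
        snps = list(matrix.columns)
    missing_cols = [s for s in snps if s not in matrix.columns]
    if missing_cols:
        raise KeyError(f"SNPs absent from the genotype matrix: {missing_cols}")
    rows = []
    for snp in snps:
        col = matrix[snp]
        calls = col[col.isin(["S", "I"])]
        n = int(len(calls))
        if n == 0:
            raise ValueError(f"SNP {snp} has no non-missing genotype calls")
        k = int((calls == "S").sum())
        rows.append(
            {
                "snp": snp,
                "n": n,
                "k": k,
                "association_pct": round(100.0 * k / n, 2),
                "p_raw": binomial_exact_two_sided(k, n),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = by_fdr(out["p_raw"].to_numpy())
    out = out.assign(_chrom=[s.split(":")[0] for s in out["snp"]],
                     _pos=[int(s.split(":")[1]) if ":" in s else 0 for s in out["snp"]])
    out = out.sort_values(["_chrom", "_pos"], kind="mergesort").drop(columns=["_chrom", "_pos"])
    return out.reset_index(drop=True)


def write_score_table(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(table.columns) + "\n")
        table.to_csv(fh, sep="\t", header=False, index=False)
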