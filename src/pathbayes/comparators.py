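"""Frequentist baseline: single-SNP regression p-values and Fisher's method.

Fisher's method (FM) scores pathway q by T = -2 sum_i ln p_i over the
member SNPs' single-SNP p-values; under the null of independent uniform
p-values T ~ chi-square with 2 L_q degrees of freedom, L_q the member-SNP
count.  For a singleton pathway the df=2 identity gives p = exp(-T/2),
i.e. FM reduces to the SNP p-value itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, PathwayMatrix

# p-values are floored here before taking logs: the FM statistic is
# undefined at p = 0
_P_FLOOR = np.finfo(float).tiny


@dataclass
class SnpPvalues:
    snp_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if ((self.p <= 0) | (self.p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")


def single_snp_pvalues(y: np.ndarray, g: GenotypeMatrix | np.ndarray) -> SnpPvalues:
    """Two-sided t-test p-value of the slope in simple linear regression of
    y on each SNP's allele count (with intercept), vectorized over SNPs.

    SNPs with zero genotype variance get p = 1 with a logged warning.
    """
    if isinstance(g, GenotypeMatrix):
        G, snp_ids = g.values, list(g.snp_ids)
    else:
        G = np.asarray(g, dtype=float)
        snp_ids = [f"snp{j + 1}" for j in range(G.shape[1])]
    if np.isnan(G).any():
        raise ValueError("genotypes contain missing values; impute first")
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != G.shape[0]:
        raise ValueError("y and genotypes have inconsistent sample counts")
    if n < 3:
        raise ValueError("need at least 3 individuals for a slope t-test")
    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    if sy == 0:
        raise ValueError("phenotype has zero variance")
    Gc = G - G.mean(axis=0)
    sg = np.sqrt((Gc ** 2).sum(axis=0))
    zero_var = sg == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} SNP(s) have zero genotype variance; p set to 1",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Gc.T @ yc) / (sg * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isinf(t)] = 0.0  # perfect fit: underflow toward 0, floored below
    p[zero_var] = 1.0
    p = np.clip(p, _P_FLOOR, 1.0)
    return SnpPvalues(snp_ids, p)


def fisher_pathway(p: SnpPvalues, pw: PathwayMatrix, q: int) -> tuple[float, int, float]:
    """Fisher's-method statistic, degrees of freedom and p-value for
    pathway q: T = -2 sum ln p_i over member SNPs, df = 2 L_q, upper-tail
    chi-square p-value."""
    if not 0 <= q < pw.n_pathways:
        raise IndexError(f"pathway index {q} out of range")
    member = pw.membership[:, q].astype(bool)
    if not member.any():
        raise ValueError(f"pathway {pw.pathway_ids[q]} has no member SNPs")
    pvals = np.clip(p.p[member], _P_FLOOR, 1.0)
    T = float(-2.0 * np.log(pvals).sum())
    df = int(2 * member.sum())
    return T, df, float(stats.chi2.sf(T, df))


def fisher_all_pathways(p: SnpPvalues, pw: PathwayMatrix) -> pd.DataFrame:
    """Fisher's method for every pathway; vectorized over pathways."""
    logs = np.log(np.clip(p.p, _P_FLOOR, 1.0))
    member = pw.membership.astype(float)
    sizes = member.sum(axis=0)
    if (sizes == 0).any():
        raise ValueError("pathway matrix contains pathways with no member SNPs")
    T = -2.0 * (member.T @ logs)
    df = (2 * sizes).astype(int)
    pval = stats.chi2.sf(T, df)
    return pd.DataFrame(
        {
            "pathway_id": pw.pathway_ids,
            "n_snps": sizes.astype(int),
            "fm_stat": T,
            "df": df,
            "p_value": pval,
        }
    )
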