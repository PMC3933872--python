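"""Input formats, quality control and SNP-pathway membership construction.

Genotypes are minor-allele counts (0/1/2) for N individuals by L SNPs, read
either from a plain TSV or from a PLINK ``--recode A`` additive text export
(``.raw``).  Gene sets come in GMT format, gene coordinates in BED, SNP
coordinates in a BIM-like or two-column TSV.  SNPs inherit pathway membership
through genes: a SNP belongs to every pathway containing a gene whose coding
sequence overlaps a symmetric window around the SNP position.

All genomic coordinates are handled 1-based inclusive internally; BED input
is converted from 0-based half-open on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

# number of leading metadata columns (FID IID PAT MAT SEX PHENOTYPE) in a
# PLINK .raw additive export
_PLINK_RAW_META_COLS = 6


@dataclass
class GenotypeMatrix:
    """N x L matrix of minor-allele counts with per-SNP coordinates.

    ``values`` is float so that missing entries can be carried as NaN and so
    that mean imputation can produce fractional counts.  Non-missing raw
    entries are in {0, 1, 2}.
    """

    values: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray | None = None   # per-SNP chromosome label (str array)
    pos_bp: np.ndarray | None = None  # per-SNP 1-based position

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, l = self.values.shape
        if n < 1 or l < 1:
            raise ValueError("genotype matrix must have at least one sample and one SNP")
        if len(self.sample_ids) != n or len(self.snp_ids) != l:
            raise ValueError("sample/SNP id lengths do not match matrix shape")
        if len(set(self.snp_ids)) != l:
            raise ValueError("snp_ids must be unique")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            # after imputation fractional values are legal; only raw matrices
            # constructed from file input are checked strictly by the readers
            pass

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return np.isnan(self.values).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency from non-missing calls.

        The stored coding is already minor-allele counts, but the folded
        frequency min(p, 1-p) is returned so the result is a true MAF even if
        the file's coding was not checked upstream.
        """
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            p = np.nanmean(self.values, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in np.atleast_1d(idx)],
            chrom=None if self.chrom is None else self.chrom[idx],
            pos_bp=None if self.pos_bp is None else self.pos_bp[idx],
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene's coding-sequence interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start_bp > end_bp")


@dataclass
class PathwayMatrix:
    """L x M binary SNP-pathway membership matrix P.

    A SNP mapped into one pathway through several genes still has entry
    exactly 1: membership is binary, never weighted by multiplicity.
    """

    membership: np.ndarray
    pathway_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.int8)
        if self.membership.ndim != 2:
            raise ValueError("membership must be 2-D")
        if not np.isin(self.membership, (0, 1)).all():
            raise ValueError("membership entries must be 0/1")
        l, m = self.membership.shape
        if len(self.snp_ids) != l or len(self.pathway_ids) != m:
            raise ValueError("id lengths do not match membership shape")

    @property
    def n_snps(self) -> int:
        return self.membership.shape[0]

    @property
    def n_pathways(self) -> int:
        return self.membership.shape[1]

    def sizes(self) -> np.ndarray:
        """Member-SNP count per pathway."""
        return self.membership.sum(axis=0)


@dataclass(frozen=True)
class QCParams:
    """SNP quality-control thresholds (strict inequalities).

    maf_min : retain SNPs with MAF > maf_min
    hwe_p_min : retain SNPs with Hardy-Weinberg chi-square p-value > hwe_p_min
    miss_max : retain SNPs with missing-call fraction < miss_max
    """

    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    miss_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "miss_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_genotype_token(tok: str, path: str, lineno: int) -> float:
    if tok == MISSING_TOKEN:
        return np.nan
    if tok in ("0", "1", "2"):
        return float(tok)
    raise ValueError(
        f"{path}:{lineno}: genotype token {tok!r} is not one of 0/1/2/{MISSING_TOKEN}"
    )


def read_genotypes(path: str, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from text.

    dialect="tsv": whitespace/tab separated 0/1/2/NA values, one individual
    per row; an optional header row carries SNP ids and an optional leading
    column carries sample ids (detected by non-genotype tokens).

    dialect="plink-raw": PLINK additive export with six metadata columns
    (FID IID PAT MAT SEX PHENOTYPE) followed by one column per SNP.
    """
    if dialect not in ("tsv", "plink-raw"):
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty genotype file")
    rows = [ln.split() for ln in lines]
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(
                f"{path}:{i + 1}: row has {len(r)} fields, expected {width}"
            )

    if dialect == "plink-raw":
        header = rows[0]
        if len(header) <= _PLINK_RAW_META_COLS:
            raise ValueError(f"{path}: no SNP columns after PLINK metadata columns")
        snp_ids = header[_PLINK_RAW_META_COLS:]
        sample_ids, data = [], []
        for i, r in enumerate(rows[1:], start=2):
            sample_ids.append(r[1])  # IID
            data.append([_parse_genotype_token(t, path, i) for t in r[_PLINK_RAW_META_COLS:]])
        if not data:
            raise ValueError(f"{path}: PLINK .raw file has a header but no samples")
        return GenotypeMatrix(np.array(data), sample_ids, snp_ids)

    # plain TSV: detect header / sample-id column
    def is_geno(tok: str) -> bool:
        return tok in ("0", "1", "2", MISSING_TOKEN)

    has_header = not all(is_geno(t) for t in rows[0])
    body = rows[1:] if has_header else rows
    if not body:
        raise ValueError(f"{path}: genotype file has a header but no data rows")
    has_id_col = not all(is_geno(r[0]) for r in body)
    start_col = 1 if has_id_col else 0
    if has_header:
        snp_ids = rows[0][start_col:] if len(rows[0]) == width else rows[0]
    else:
        snp_ids = [f"snp{j + 1}" for j in range(width - start_col)]
    sample_ids, data = [], []
    for i, r in enumerate(body, start=2 if has_header else 1):
        sample_ids.append(r[0] if has_id_col else f"sample{len(sample_ids) + 1}")
        data.append([_parse_genotype_token(t, path, i) for t in r[start_col:]])
    return GenotypeMatrix(np.array(data), sample_ids, snp_ids)


def read_phenotype(path: str) -> np.ndarray:
    """Read a quantitative phenotype: one value per line, or id<TAB>value."""
    vals = []
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            toks = ln.split()
            if not toks:
                continue
            try:
                vals.append(float(toks[-1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: cannot parse phenotype value") from exc
    if not vals:
        raise ValueError(f"{path}: empty phenotype file")
    return np.array(vals)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read GMT gene sets: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            toks = ln.rstrip("\n").split("\t")
            if len(toks) < 3:
                raise ValueError(f"{path}:{i}: GMT line needs name, description, >=1 gene")
            sets[toks[0]] = [g for g in toks[2:] if g]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def read_gene_bed(path: str) -> list[GeneModel]:
    """Read gene coding intervals from BED (0-based half-open on disk)."""
    genes = []
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            toks = ln.split()
            if len(toks) < 4:
                raise ValueError(f"{path}:{i}: BED line needs chrom, start, end, name")
            chrom, start, end, name = toks[0], int(toks[1]), int(toks[2]), toks[3]
            genes.append(GeneModel(gene_id=name, chrom=chrom, start_bp=start + 1, end_bp=end))
    if not genes:
        raise ValueError(f"{path}: no gene records found")
    return genes


def read_snp_coords(path: str) -> dict[str, tuple[str, int]]:
    """Read SNP coordinates from a PLINK .bim or a snp_id/chrom/pos TSV.

    Returns a mapping snp_id -> (chrom, 1-based position).
    """
    coords: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            toks = ln.split()
            if not toks or toks[0].startswith("#"):
                continue
            if len(toks) >= 6:  # .bim: chrom id cm pos a1 a2
                coords[toks[1]] = (toks[0], int(toks[3]))
            elif len(toks) >= 3:  # TSV: snp_id chrom pos
                coords[toks[0]] = (toks[1], int(toks[2]))
            else:
                raise ValueError(f"{path}:{i}: unrecognized SNP coordinate line")
    if not coords:
        raise ValueError(f"{path}: no SNP coordinates found")
    return coords


def attach_coords(g: GenotypeMatrix, coords: dict[str, tuple[str, int]]) -> GenotypeMatrix:
    """Return a copy of ``g`` with chrom/pos filled from a coordinate map."""
    chrom = np.array([coords[s][0] for s in g.snp_ids], dtype=object)
    pos = np.array([coords[s][1] for s in g.snp_ids], dtype=np.int64)
    return replace(g, chrom=chrom, pos_bp=pos)


# ---------------------------------------------------------------------------
# QC and imputation
# ---------------------------------------------------------------------------

def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP Hardy-Weinberg chi-square goodness-of-fit p-value (1 df).

    Observed genotype counts are compared against expected counts
    n*( (1-p)^2, 2p(1-p), p^2 ) at the estimated allele frequency p.
    Monomorphic SNPs (p in {0, 1}) have a degenerate expectation and are
    assigned p-value 1 (they fit their own expectation exactly).
    """
    out = np.empty(g.n_snps)
    for j in range(g.n_snps):
        calls = g.values[:, j]
        calls = calls[~np.isnan(calls)]
        n = calls.size
        if n == 0:
            out[j] = np.nan
            continue
        obs = np.array([(calls == k).sum() for k in (0, 1, 2)], dtype=float)
        p = (obs[1] + 2 * obs[2]) / (2 * n)
        if p in (0.0, 1.0):
            out[j] = 1.0
            continue
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        out[j] = stats.chi2.sf(chi2, df=1)
    return out


def qc_filter(g: GenotypeMatrix, q: QCParams) -> GenotypeMatrix:
    """Retain SNPs with MAF > maf_min, HWE p > hwe_p_min, missingness < miss_max.

    All three inequalities are strict.  Idempotent: the retained submatrix
    passes the same filters again.
    """
    keep = (
        (g.maf() > q.maf_min)
        & (hwe_pvalues(g) > q.hwe_p_min)
        & (g.missing_rate() < q.miss_max)
    )
    if not keep.any():
        warnings.warn("QC filtering removed every SNP", stacklevel=2)
        # an explicitly empty result cannot be represented by GenotypeMatrix
        # (L >= 1); callers get the boolean mask via qc_mask if needed
        raise ValueError("QC filtering removed all SNPs; relax the thresholds")
    return g.subset_snps(np.flatnonzero(keep))


def impute_missing(g: GenotypeMatrix, mode: str = "mean", seed: int | None = None) -> GenotypeMatrix:
    """Replace missing genotype calls.

    mode="mean": per-SNP mean of the non-missing calls (real-valued).
    mode="frequency-sample": draw 0/1/2 from the per-SNP empirical genotype
    distribution; requires a seed for reproducibility.
    """
    if mode not in ("mean", "frequency-sample"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    if mode == "frequency-sample" and seed is None:
        raise ValueError("frequency-sample imputation requires an explicit seed")
    values = g.values.copy()
    all_missing = np.isnan(values).all(axis=0)
    if all_missing.any():
        bad = [g.snp_ids[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"SNP(s) with no observed calls cannot be imputed: {bad}")
    rng = np.random.default_rng(seed)
    for j in np.flatnonzero(np.isnan(values).any(axis=0)):
        col = values[:, j]
        miss = np.isnan(col)
        obs = col[~miss]
        if mode == "mean":
            col[miss] = obs.mean()
        else:
            freqs = np.array([(obs == k).mean() for k in (0, 1, 2)])
            col[miss] = rng.choice(3, size=miss.sum(), p=freqs)
    return replace(g, values=values)


# ---------------------------------------------------------------------------
# SNP -> gene -> pathway mapping
# ---------------------------------------------------------------------------

def map_snps_to_genes(
    g: GenotypeMatrix,
    genes: list[GeneModel],
    window_bp: int = 10_000,
) -> list[tuple[str, str]]:
    """Map each SNP to every gene whose coding sequence overlaps a symmetric
    ``window_bp`` window around the SNP position.

    Intervals are 1-based inclusive: SNP s maps to gene g iff chromosomes
    match and [pos-window, pos+window] intersects [start, end].  With
    window_bp=0 this reduces to strict containment of the SNP position.
    """
    if g.chrom is None or g.pos_bp is None:
        raise ValueError("genotype matrix has no SNP coordinates; attach_coords first")
    pairs: list[tuple[str, str]] = []
    by_chrom: dict[str, list[int]] = {}
    for j in range(g.n_snps):
        by_chrom.setdefault(str(g.chrom[j]), []).append(j)
    for chrom, snp_idx in by_chrom.items():
        pos = np.array([g.pos_bp[j] for j in snp_idx])
        order = np.argsort(pos)
        pos_sorted = pos[order]
        idx_sorted = [snp_idx[k] for k in order]
        for gene in genes:
            if gene.chrom != chrom:
                continue
            # SNP window [pos-w, pos+w] hits [start, end]  <=>
            # start - w <= pos <= end + w
            lo = np.searchsorted(pos_sorted, gene.start_bp - window_bp, side="left")
            hi = np.searchsorted(pos_sorted, gene.end_bp + window_bp, side="right")
            for k in range(lo, hi):
                pairs.append((g.snp_ids[idx_sorted[k]], gene.gene_id))
    return pairs


def build_pathway_matrix(
    pairs: list[tuple[str, str]],
    gene_sets: dict[str, list[str]],
    snp_ids: list[str],
) -> PathwayMatrix:
    """Build the binary L x M SNP-pathway membership matrix P.

    Entry (s, m) is 1 iff some gene of pathway m is paired with SNP s;
    multiple gene routes into the same pathway still give entry 1.  Pathways
    without any member SNP are dropped (with a logged notice).  SNPs pairing
    with no pathway keep an all-zero row.
    """
    if not gene_sets:
        raise ValueError("gene_sets is empty")
    snp_index = {s: i for i, s in enumerate(snp_ids)}
    gene_to_snps: dict[str, set[int]] = {}
    for snp, gene in pairs:
        if snp in snp_index:
            gene_to_snps.setdefault(gene, set()).add(snp_index[snp])
    cols, kept_ids = [], []
    for name, genes in gene_sets.items():
        members: set[int] = set()
        for gid in genes:
            members |= gene_to_snps.get(gid, set())
        if not members:
            logger.info("pathway %s has no member SNPs after mapping; dropped", name)
            continue
        col = np.zeros(len(snp_ids), dtype=np.int8)
        col[sorted(members)] = 1
        cols.append(col)
        kept_ids.append(name)
    if not cols:
        raise ValueError("no pathway has any member SNP after mapping")
    return PathwayMatrix(np.column_stack(cols), kept_ids, list(snp_ids))
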