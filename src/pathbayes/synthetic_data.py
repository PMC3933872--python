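"""Synthetic genotypes, pathway structures and phenotypes for power studies.

The generator emulates a GWAS pathway-analysis study end to end:

* genotypes: per-SNP minor-allele frequencies drawn uniformly from a
  range, genotypes sampled at Hardy-Weinberg proportions through a latent
  Gaussian copula; optional block-exchangeable LD;
* pathways: member-SNP counts from a truncated log-normal, with a
  configurable fraction of each pathway's SNPs re-drawn from SNPs already
  used by earlier pathways so that pathways overlap (smaller pathways can
  be near-subsets of larger ones, as in curated databases);
* phenotypes: y = X_J beta + Z_K u + eps, with effects restricted to J
  "true" pathways and K causal SNPs, effect vectors drawn from zero-mean
  normals rescaled so the pathway and SNP terms each explain a target
  fraction of phenotypic variance, and fresh Gaussian noise per replicate.

Scenario presets mirror a simulation design in which the true pathways are
chosen either by one of the scoring methods applied to a pilot phenotype
(so that truth reflects what that method considers associated), uniformly
at random, or uniformly among unusually small / large pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hier_model import HyperParams, MarginalModel
from .io_formats import GenotypeMatrix, PathwayMatrix

SCENARIO_IDS = (
    "nbf-selected",
    "snal-selected",
    "fm-selected",
    "random",
    "size-small",
    "size-large",
    "null",
)


class ScenarioSelectionError(ValueError):
    """Raised when a method-selected scenario yields no usable truth set."""


@dataclass(frozen=True)
class GenotypeSimParams:
    """Genotype simulator settings.

    ld_block_size=1 gives independent SNPs; larger blocks share a latent
    factor with correlation ld_rho (exchangeable within the block).
    """

    n_individuals: int = 500
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass(frozen=True)
class PathwaySimParams:
    """Pathway membership simulator settings.

    Sizes (member-SNP counts) are log-normal, truncated to size_bounds.
    overlap_fraction of each pathway's members is drawn from SNPs already
    used by earlier pathways (when available), the rest from unused SNPs.
    """

    n_pathways: int = 100
    size_log_mean: float = math.log(400.0)
    size_log_sd: float = 0.9
    size_bounds: tuple[int, int] = (30, 1500)
    overlap_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        lo, hi = self.size_bounds
        if not (1 <= lo <= hi):
            raise ValueError("size_bounds must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class ScenarioParams:
    """Settings shared by all scenario presets.

    ve_pathway / ve_snp are the fractions of phenotypic variance explained
    by the pathway and causal-SNP terms (total variance is scaled to 1);
    the residual takes the remainder.
    """

    n_true_pathways: int = 10        # J, for random/size presets
    n_causal_snps: int = 100         # K
    ve_pathway: float = 0.10
    ve_snp: float = 0.10
    n_replicates: int = 50
    seed: int = 0
    small_cut: int = 300
    large_cut: int = 700
    # pilot-phenotype selection settings for method-selected presets
    selection: str = "count"  # "count": top-J by the method's score; "threshold"
    target_count: int | None = None  # J for count mode; None = preset fraction
    # fraction of causal SNPs drawn from member SNPs of the true pathways;
    # None = preset default (0.8 for method-selected/random truth, where the
    # causal hits and the associated pathways reflect one genetic
    # architecture; 0 for the size presets, whose truth is random pathways
    # unrelated to the hits)
    snp_in_truth_frac: float | None = None
    # how effect sizes are set: "target-ve" rescales random effects to the
    # ve_pathway/ve_snp fractions; "pilot-fit" regresses a pilot phenotype
    # on [X_J | Z_K] and adopts the fitted coefficients and residual SD, so
    # truth sets unrelated to the pilot architecture receive only
    # overfit-level pathway effects.  None = preset default ("pilot-fit"
    # for the size presets, "target-ve" otherwise).
    effect_source: str | None = None
    selection_hp: HyperParams = field(default_factory=HyperParams)
    nbf_cutoff: float = 1.0
    snal_lam: float = 0.5
    fm_alpha: float = 0.05
    pilot_ve_snp: float = 0.20

    def __post_init__(self) -> None:
        if self.ve_pathway < 0 or self.ve_snp < 0 or self.ve_pathway + self.ve_snp >= 1:
            raise ValueError("variance fractions must be >= 0 and sum to < 1")


@dataclass
class SimulationScenario:
    """Ground truth of one simulation scenario.

    pathway_idx / beta: the J associated pathways and their effects;
    snp_idx / u: the K causal SNPs and their effects; sigma_eps: residual
    standard deviation.  Effects of length 0 are allowed for the null
    preset (truth labels exist but carry no signal).
    """

    scenario_id: str
    pathway_idx: np.ndarray
    beta: np.ndarray
    snp_idx: np.ndarray
    u: np.ndarray
    sigma_eps: float
    n_replicates: int = 50
    seed: int = 0
    resample_effects: bool = False

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario_id {self.scenario_id!r}")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")
        if len(self.pathway_idx) < 1 or len(self.snp_idx) < 1:
            raise ValueError("scenario needs at least one true pathway and one causal SNP")

    def truth_labels(self, n_pathways: int) -> np.ndarray:
        truth = np.zeros(n_pathways, dtype=bool)
        truth[self.pathway_idx] = True
        return truth


@dataclass
class SimulatedStudy:
    """A complete simulated dataset: design, phenotype replicates, truth."""

    genotype: GenotypeMatrix
    pathways: PathwayMatrix
    phenotypes: np.ndarray  # n_replicates x N
    truth: np.ndarray       # boolean per pathway
    scenario: SimulationScenario


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(p: GenotypeSimParams) -> GenotypeMatrix:
    """Simulate an N x L genotype matrix at Hardy-Weinberg proportions.

    Each SNP's latent Gaussian is thresholded at the HWE genotype
    cumulative probabilities ((1-f)^2, 1-f^2); within an LD block the
    latents share a common factor with weight sqrt(ld_rho).
    """
    rng = np.random.default_rng(p.seed)
    n, l = p.n_individuals, p.n_snps
    mafs = rng.uniform(p.maf_range[0], p.maf_range[1], size=l)
    z = rng.standard_normal((n, l))
    if p.ld_block_size > 1 and p.ld_rho > 0:
        n_blocks = -(-l // p.ld_block_size)
        common = rng.standard_normal((n, n_blocks))
        block_of = np.arange(l) // p.ld_block_size
        z = math.sqrt(p.ld_rho) * common[:, block_of] + math.sqrt(1 - p.ld_rho) * z
    t0 = stats.norm.ppf((1 - mafs) ** 2)
    t1 = stats.norm.ppf(1 - mafs ** 2)
    geno = (z > t0).astype(float) + (z > t1)
    chrom = np.array([str(1 + (j * 22) // l) for j in range(l)], dtype=object)
    pos = np.empty(l, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 1 + 5000 * np.arange(idx.size)
    return GenotypeMatrix(
        values=geno,
        sample_ids=[f"sample{i + 1}" for i in range(n)],
        snp_ids=[f"snp{j + 1}" for j in range(l)],
        chrom=chrom,
        pos_bp=pos,
    )


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def _truncated_lognormal_sizes(p: PathwaySimParams, rng: np.random.Generator) -> np.ndarray:
    lo, hi = p.size_bounds
    sizes = np.empty(p.n_pathways, dtype=np.int64)
    filled = 0
    for _ in range(10_000):
        draw = rng.lognormal(p.size_log_mean, p.size_log_sd, size=p.n_pathways)
        draw = np.rint(draw).astype(np.int64)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, p.n_pathways - filled)
        sizes[filled:filled + take] = ok[:take]
        filled += take
        if filled == p.n_pathways:
            return sizes
    raise RuntimeError("truncated log-normal rejection sampling failed to fill sizes")


def simulate_pathways(p: PathwaySimParams, snp_ids: list[str]) -> PathwayMatrix:
    """Simulate a binary SNP-pathway membership matrix with overlap.

    Each pathway draws overlap_fraction of its members from the pool of
    SNPs already used by earlier pathways (capped by the pool size) and
    the remainder from so-far-unused SNPs.  Raises if the unused pool
    cannot supply the fresh members (infeasible sizes for the SNP panel).
    """
    rng = np.random.default_rng(p.seed)
    l = len(snp_ids)
    sizes = _truncated_lognormal_sizes(p, rng)
    if (sizes > l).any():
        raise ValueError("requested pathway sizes exceed the number of SNPs")
    used: np.ndarray = np.array([], dtype=np.int64)
    unused = rng.permutation(l)
    membership = np.zeros((l, p.n_pathways), dtype=np.int8)
    for m in range(p.n_pathways):
        size = int(sizes[m])
        n_overlap = min(int(round(p.overlap_fraction * size)), used.size)
        n_new = size - n_overlap
        if n_new > unused.size:
            raise ValueError(
                f"pathway {m + 1} needs {n_new} unused SNPs but only "
                f"{unused.size} remain; reduce sizes or raise overlap_fraction"
            )
        ov = rng.choice(used, size=n_overlap, replace=False) if n_overlap else np.array([], dtype=np.int64)
        new = unused[:n_new]
        unused = unused[n_new:]
        members = np.concatenate([ov, new])
        membership[members, m] = 1
        used = np.union1d(used, members)
    return PathwayMatrix(
        membership=membership,
        pathway_ids=[f"pathway{m + 1}" for m in range(p.n_pathways)],
        snp_ids=list(snp_ids),
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _scaled_effects(
    design: np.ndarray, idx: np.ndarray, target_var: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean normal effects over design[:, idx], rescaled so the term's
    empirical variance across individuals equals target_var."""
    raw = rng.standard_normal(idx.size)
    if target_var == 0.0:
        return np.zeros(idx.size)
    contrib = design[:, idx] @ raw
    v = contrib.var()
    if v == 0:
        raise ValueError("effect term has zero variance; degenerate design columns")
    return raw * math.sqrt(target_var / v)


# default truth-set sizes for method-selected presets, as fractions of the
# pathway count (the published analogues selected 24, 24 and 39 of 211
# pathways for the NBF-, SNAL- and FM-selected designs)
TRUTH_FRACTIONS = {
    "nbf-selected": 24 / 211,
    "snal-selected": 24 / 211,
    "fm-selected": 39 / 211,
}


def _pilot_truth(
    g: GenotypeMatrix,
    pw: PathwayMatrix,
    scenario_id: str,
    snp_idx: np.ndarray,
    params: ScenarioParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Select the true pathways by running the named method on a pilot
    phenotype carrying causal-SNP signal only.

    In "count" mode (default) the truth set is the method's top-J
    pathways, J from ``target_count`` or the preset fraction -- the
    selection thresholds behind the published counts are not recoverable,
    so the presets target the counts instead.  In "threshold" mode the
    method's own cut-off decides, and an empty or full selection raises
    ScenarioSelectionError.
    """
    from . import comparators, nbf, snal  # deferred: avoid import cycles

    u = _scaled_effects(g.values, snp_idx, params.pilot_ve_snp, rng)
    eps = math.sqrt(1.0 - params.pilot_ve_snp) * rng.standard_normal(g.n_samples)
    y_pilot = g.values[:, snp_idx] @ u + eps

    # score = smaller-is-stronger ranking for every method
    if scenario_id == "fm-selected":
        pvals = comparators.single_snp_pvalues(y_pilot, g)
        fm = comparators.fisher_all_pathways(pvals, pw)
        score = fm["p_value"].to_numpy()
        thresh_sel = np.flatnonzero(score < params.fm_alpha)
    elif scenario_id == "nbf-selected":
        model = MarginalModel(y_pilot, g.values, pw, params.selection_hp)
        table = nbf.score_all_pathways(model, cutoff=params.nbf_cutoff, pathway_ids=pw.pathway_ids)
        score = table.bf
        thresh_sel = np.flatnonzero(table.associated)
    else:  # snal-selected
        model = MarginalModel(y_pilot, g.values, pw, params.selection_hp)
        prob = snal.whiten(model, params.snal_lam)
        if params.selection == "count":
            # rank pathways by the largest lam at which SNAL keeps them,
            # breaking ties by the coefficient magnitude at the smallest lam
            lam_grid = np.logspace(-3, 1, 20)
            fits = snal.snal_path(prob, lam_grid)
            lam_score = snal.selection_scores(fits, lam_grid, pw.n_pathways)
            score = -(lam_score + 1e-12 * np.abs(fits[0].beta_hat))
            thresh_sel = np.flatnonzero(lam_score > 0)
        else:
            fit = snal.snal_fit(prob)
            score = -fit.gamma
            thresh_sel = fit.selected

    if params.selection == "count":
        j = params.target_count or max(1, round(TRUTH_FRACTIONS[scenario_id] * pw.n_pathways))
        if j >= pw.n_pathways:
            raise ScenarioSelectionError(f"{scenario_id}: target_count must be < n_pathways")
        return np.sort(np.argsort(score, kind="stable")[:j])
    if thresh_sel.size == 0:
        raise ScenarioSelectionError(
            f"{scenario_id}: the selecting method flagged no pathway on the "
            "pilot phenotype; relax the selection threshold"
        )
    if thresh_sel.size >= pw.n_pathways:
        raise ScenarioSelectionError(
            f"{scenario_id}: the selecting method flagged every pathway; "
            "tighten the selection threshold"
        )
    return thresh_sel


def make_scenario(
    g: GenotypeMatrix,
    pw: PathwayMatrix,
    scenario_id: str,
    params: ScenarioParams,
) -> SimulationScenario:
    """Build the ground truth (true pathways, causal SNPs, effect sizes)
    for one scenario preset.

    Presets: "nbf-selected" / "snal-selected" / "fm-selected" run the named
    method on an internally generated pilot phenotype and adopt its
    selected pathways as truth; "random" samples J pathways uniformly;
    "size-small" / "size-large" sample uniformly among pathways with fewer
    than small_cut / more than large_cut member SNPs; "null" is "random"
    with all effects set to zero (labels exist, signal does not).
    """
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario_id {scenario_id!r}")
    rng = np.random.default_rng(params.seed)
    X = g.values @ pw.membership.astype(float)
    k = min(params.n_causal_snps, g.n_snps)
    pilot_snp_idx = np.sort(rng.choice(g.n_snps, size=k, replace=False))

    if scenario_id in ("nbf-selected", "snal-selected", "fm-selected"):
        pathway_idx = _pilot_truth(g, pw, scenario_id, pilot_snp_idx, params, rng)
    elif scenario_id in ("random", "null"):
        j = min(params.n_true_pathways, pw.n_pathways - 1)
        pathway_idx = np.sort(rng.choice(pw.n_pathways, size=j, replace=False))
    else:  # size-small / size-large
        sizes = pw.sizes()
        if scenario_id == "size-small":
            cand = np.flatnonzero(sizes < params.small_cut)
        else:
            cand = np.flatnonzero(sizes > params.large_cut)
        if cand.size == 0:
            raise ValueError(
                f"{scenario_id}: no pathway satisfies the size cut; adjust the "
                "pathway size distribution or the cut"
            )
        j = min(params.n_true_pathways, cand.size)
        pathway_idx = np.sort(rng.choice(cand, size=j, replace=False))

    effect_source = params.effect_source
    if effect_source is None:
        effect_source = "pilot-fit" if scenario_id in ("size-small", "size-large") else "target-ve"
    if effect_source not in ("target-ve", "pilot-fit"):
        raise ValueError(f"unknown effect_source {effect_source!r}")

    if effect_source == "pilot-fit":
        # the pilot phenotype plays the role of the real phenotype the
        # generating model was fitted to: its causal SNPs stay the causal
        # SNPs of the scenario, and the pathway/SNP effects and residual SD
        # are taken from the least-squares fit of y ~ [X_J | Z_K]
        snp_idx = pilot_snp_idx
        j = pathway_idx.size
        if j + k + 1 >= g.n_samples:
            raise ValueError("pilot-fit needs n_samples > J + K + 1")
        u0 = _scaled_effects(g.values, snp_idx, params.pilot_ve_snp, rng)
        y0 = g.values[:, snp_idx] @ u0 + math.sqrt(1.0 - params.pilot_ve_snp) * rng.standard_normal(g.n_samples)
        D = np.column_stack([X[:, pathway_idx], g.values[:, snp_idx]])
        D = D - D.mean(axis=0)
        y0c = y0 - y0.mean()
        coef, _, _, _ = np.linalg.lstsq(D, y0c, rcond=None)
        beta, u = coef[:j], coef[j:]
        resid = y0c - D @ coef
        sigma_eps = math.sqrt(float(resid @ resid) / max(g.n_samples - j - k - 1, 1))
    else:
        # causal SNPs: a fraction lies inside the true pathways, the rest outside
        frac = params.snp_in_truth_frac
        if frac is None:
            frac = 0.0 if scenario_id == "null" else 0.8
        members = np.flatnonzero(pw.membership[:, pathway_idx].any(axis=1))
        outside = np.setdiff1d(np.arange(g.n_snps), members)
        k_in = min(int(round(frac * k)), members.size)
        k_out = min(k - k_in, outside.size)
        snp_idx = np.sort(
            np.concatenate(
                [
                    rng.choice(members, size=k_in, replace=False),
                    rng.choice(outside, size=k_out, replace=False),
                ]
            )
        )
        null = scenario_id == "null"
        ve_path = 0.0 if null else params.ve_pathway
        ve_snp = 0.0 if null else params.ve_snp
        beta = _scaled_effects(X, pathway_idx, ve_path, rng)
        u = _scaled_effects(g.values, snp_idx, ve_snp, rng)
        sigma_eps = math.sqrt(1.0 - ve_path - ve_snp)
    return SimulationScenario(
        scenario_id=scenario_id,
        pathway_idx=pathway_idx,
        beta=beta,
        snp_idx=snp_idx,
        u=u,
        sigma_eps=sigma_eps,
        n_replicates=params.n_replicates,
        seed=int(rng.integers(2 ** 31)),
    )


def simulate_phenotypes(
    s: SimulationScenario,
    g: GenotypeMatrix,
    pw: PathwayMatrix,
    ve_pathway: float | None = None,
    ve_snp: float | None = None,
) -> np.ndarray:
    """Simulate the n_replicates x N phenotype matrix for a scenario.

    y = X_J beta + Z_K u + eps with fresh eps per replicate; with
    ``resample_effects`` the effect vectors are redrawn (and rescaled to
    the supplied variance fractions) each replicate as well.
    """
    rng = np.random.default_rng(s.seed)
    X = g.values @ pw.membership.astype(float)
    out = np.empty((s.n_replicates, g.n_samples))
    beta, u = s.beta, s.u
    for r in range(s.n_replicates):
        if s.resample_effects:
            if ve_pathway is None or ve_snp is None:
                raise ValueError("resampling effects needs ve_pathway and ve_snp")
            beta = _scaled_effects(X, s.pathway_idx, ve_pathway, rng)
            u = _scaled_effects(g.values, s.snp_idx, ve_snp, rng)
        mu = X[:, s.pathway_idx] @ beta + g.values[:, s.snp_idx] @ u
        out[r] = mu + s.sigma_eps * rng.standard_normal(g.n_samples)
    return out


def simulate_study(
    scenario_id: str,
    geno_params: GenotypeSimParams = GenotypeSimParams(),
    pathway_params: PathwaySimParams = PathwaySimParams(),
    scenario_params: ScenarioParams = ScenarioParams(),
) -> SimulatedStudy:
    """One-call pipeline: genotypes -> pathways -> scenario -> phenotypes."""
    g = simulate_genotypes(geno_params)
    pw = simulate_pathways(pathway_params, g.snp_ids)
    scen = make_scenario(g, pw, scenario_id, scenario_params)
    phen = simulate_phenotypes(scen, g, pw)
    return SimulatedStudy(
        genotype=g,
        pathways=pw,
        phenotypes=phen,
        truth=scen.truth_labels(pw.n_pathways),
        scenario=scen,
    )
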