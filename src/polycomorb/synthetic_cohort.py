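"""Synthetic discovery GWAS and target cohort generator.

Produces everything the downstream pipeline consumes without any external
download: LD-blocked biallelic genotypes, discovery summary statistics with a
polygenic true-effect architecture, demographic covariates, and five ordinal
substance-involvement measures generated from a single latent factor that
carries a genetic component.

The generative model for involvement is a graded-response construction:

    factor_i   = gamma * z(true_score_i) + c' cov_i + e_i      (unit variance)
    ystar_is   = lambda_s * factor_i + sqrt(1 - lambda_s^2) * eps_is
    level_is   = #{ t in thresholds_s : ystar_is > t }         (0..4)

Category marginals are calibrated, by default, to the observed involvement
distribution of a 2,573-person case/control cohort; covariate marginals
(56.2% female, age 38.67 (9.76), three study sites 927/557/1089) match the
same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUBSTANCES = ("alcohol", "nicotine", "cannabis", "cocaine", "opioids")

#: Observed counts per involvement level (rows: levels 0-4) used to place
#: default thresholds; columns follow SUBSTANCES order.
INVOLVEMENT_COUNTS = np.array(
    [
        [258, 595, 659, 1591, 2043],
        [517, 159, 1153, 416, 305],
        [591, 499, 312, 83, 45],
        [648, 1120, 278, 131, 52],
        [559, 180, 168, 348, 124],
    ],
    dtype=float,
)

#: Covariate calibration targets.
P_FEMALE = 0.562
AGE_MEAN = 38.67
AGE_SD = 9.76
STUDY_COUNTS = (927, 557, 1089)
N_PCS = 3

MISSING = -1  # sentinel in integer dosage matrices


def default_thresholds() -> np.ndarray:
    """Per-substance latent cutpoints matching the calibration marginals.

    Returns a (5 substances, 4 cutpoints) array of standard-normal quantiles
    of the cumulative category proportions.
    """
    props = INVOLVEMENT_COUNTS / INVOLVEMENT_COUNTS.sum(axis=0)
    cum = np.cumsum(props[:-1, :], axis=0)  # first 4 cumulative proportions
    return stats.norm.ppf(cum).T  # (5, 4)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic study."""

    n_samples: int = 2573
    n_snps: int = 2000
    n_blocks: int = 100
    within_block_r: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_discovery: int = 50_000
    prop_causal: float = 0.3
    gamma: float = 0.1
    loadings: tuple[float, ...] = (0.8, 0.8, 0.8, 0.8, 0.8)
    thresholds: np.ndarray = field(default_factory=default_thresholds)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_snps <= 0 or self.n_blocks <= 0:
            raise ValueError("n_samples, n_snps and n_blocks must be positive")
        if self.n_blocks > self.n_snps:
            raise ValueError("n_blocks may not exceed n_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.within_block_r < 1:
            raise ValueError("within_block_r must be in [0, 1)")
        if not 0 < self.prop_causal <= 1:
            raise ValueError("prop_causal must be in (0, 1]")
        if self.n_discovery <= 0:
            raise ValueError("n_discovery must be positive")
        if len(self.loadings) != len(SUBSTANCES):
            raise ValueError("need one loading per substance")
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.shape != (len(SUBSTANCES), 4):
            raise ValueError("thresholds must be 5 x 4")
        if not (np.diff(thr, axis=1) > 0).all():
            raise ValueError("thresholds must be strictly ascending per substance")
        object.__setattr__(self, "thresholds", thr)


@dataclass
class TrueModel:
    """Ground truth retained for parameter-recovery checks."""

    true_betas: np.ndarray
    true_score: np.ndarray
    latent_factor: np.ndarray


# ---------------------------------------------------------------------------
# genotypes


def _block_sizes(n_snps: int, n_blocks: int) -> np.ndarray:
    base = n_snps // n_blocks
    sizes = np.full(n_blocks, base, dtype=int)
    sizes[: n_snps - base * n_blocks] += 1
    return sizes


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw an LD-blocked dosage matrix.

    Haplotypes are Gaussian-copula draws: within a block each haplotype's
    latent normals share an equicorrelation ``within_block_r``; an allele is
    carried when the latent value falls below the MAF quantile. Two
    independent haplotypes are summed to a dosage in {0, 1, 2}.

    Returns ``(variants, dosages)`` where ``variants`` has columns
    ``id, chrom, pos, a1, a2`` (a1 is the counted allele) and ``dosages`` is
    an ``int8`` matrix of shape (n_samples, n_snps), missing entries coded
    as :data:`MISSING`.

    Blocks are laid out on chromosome 1 (others on demand), spanning < 250 kb
    each with > 500 kb between adjacent blocks, so a 500 kb clumping window
    never bridges two blocks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_snps
    sizes = _block_sizes(m, config.n_blocks)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    quantiles = stats.norm.ppf(mafs)

    dosages = np.empty((n, m), dtype=np.int8)
    block_ids = np.repeat(np.arange(config.n_blocks), sizes)
    r = config.within_block_r
    start = 0
    for size in sizes:
        sl = slice(start, start + size)
        dos = np.zeros((n, size), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            indep = rng.standard_normal((n, size))
            z = np.sqrt(r) * shared + np.sqrt(1.0 - r) * indep
            dos += (z < quantiles[sl]).astype(np.int8)
        dosages[:, sl] = dos
        start += size

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = MISSING

    # positions: block b starts at 1 + b * 1e6; SNPs every 200000/size bp
    pos = np.empty(m, dtype=np.int64)
    start = 0
    for b, size in enumerate(sizes):
        step = max(1, 200_000 // max(size, 1))
        pos[start : start + size] = 1 + b * 1_000_000 + step * np.arange(size)
        start += size

    alleles = np.array(["A", "C", "G", "T"])
    a1 = rng.choice(alleles, size=m)
    # pick a non-complementary, distinct partner so no strand-ambiguous pairs
    partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    a2 = np.array([partner[a] for a in a1])

    variants = pd.DataFrame(
        {
            "id": [f"rs{i + 1}" for i in range(m)],
            "chrom": np.ones(m, dtype=int),
            "pos": pos,
            "a1": a1,
            "a2": a2,
            "block": block_ids,
            "maf": mafs,
        }
    )
    return variants, dosages


# ---------------------------------------------------------------------------
# discovery summary statistics


def draw_true_betas(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Sparse polygenic architecture: round(prop_causal * n_snps) causal SNPs
    with N(0, 0.1^2) log-OR effects, the rest exactly zero."""
    m = config.n_snps
    n_causal = int(round(config.prop_causal * m))
    betas = np.zeros(m)
    idx = rng.choice(m, size=n_causal, replace=False)
    betas[idx] = rng.normal(0.0, 0.1, size=n_causal)
    return betas


def simulate_discovery_stats(
    config: SimConfig,
    true_betas: np.ndarray,
    variants: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Observed discovery effects: true beta plus sampling noise.

    The standard error follows the usual log-OR approximation for a balanced
    case/control design, SE = 1 / sqrt(2 * n_discovery * p(1-p)); the p-value
    is the two-sided normal tail of beta / SE.
    """
    true_betas = np.asarray(true_betas, dtype=float)
    if true_betas.shape[0] != config.n_snps:
        raise ValueError("true_betas length must equal n_snps")
    p = variants["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * config.n_discovery * p * (1.0 - p))
    beta_obs = true_betas + rng.normal(0.0, se)
    z = beta_obs / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "id": variants["id"].to_numpy(),
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "effect_allele": variants["a1"].to_numpy(),
            "other_allele": variants["a2"].to_numpy(),
            "beta": beta_obs,
            "pvalue": pvals,
        }
    )


# ---------------------------------------------------------------------------
# covariates and involvement


def simulate_covariates(
    n: int, rng: np.random.Generator, n_pcs: int = N_PCS
) -> pd.DataFrame:
    """Covariates matched to the calibration cohort's marginals."""
    study_p = np.asarray(STUDY_COUNTS, dtype=float)
    study_p /= study_p.sum()
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1}" for i in range(n)],
            "sex": (rng.random(n) < P_FEMALE).astype(int),  # 1 = female
            "age": rng.normal(AGE_MEAN, AGE_SD, size=n),
            **{
                f"pc{j + 1}": rng.standard_normal(n) for j in range(n_pcs)
            },
            "study": rng.choice(
                ["study1", "study2", "study3"], size=n, p=study_p
            ),
        }
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def simulate_involvement(
    config: SimConfig,
    true_score: np.ndarray,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
    true_betas: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TrueModel]:
    """Generate the five ordinal measures from one latent factor.

    The latent factor is gamma * standardized(true_score) plus any configured
    covariate effects (applied to z-scored covariate columns) plus a Gaussian
    residual that tops variance up to 1. Each substance's latent response is
    loading * factor + unique noise; the recorded level is the number of that
    substance's cutpoints lying below the response.
    """
    n = config.n_samples
    true_score = np.asarray(true_score, dtype=float)
    if true_score.shape[0] != n:
        raise ValueError("true_score length must equal n_samples")

    g = config.gamma * _standardize(true_score)
    cov_part = np.zeros(n)
    var_cov = 0.0
    for name, eff in config.covariate_effects.items():
        col = covariates[name].to_numpy(dtype=float)
        cov_part += eff * _standardize(col)
        var_cov += eff**2
    resid_var = 1.0 - config.gamma**2 - var_cov
    if resid_var < 0:
        raise ValueError("gamma and covariate effects imply variance > 1")
    factor = g + cov_part + rng.normal(0.0, np.sqrt(resid_var), size=n)

    levels = {}
    for s, name in enumerate(SUBSTANCES):
        lam = config.loadings[s]
        ystar = lam * factor + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
        levels[name] = (ystar[:, None] > config.thresholds[s]).sum(axis=1)
    table = pd.DataFrame(levels, dtype=int)
    table.insert(0, "sample_id", covariates["sample_id"].to_numpy())

    truth = TrueModel(
        true_betas=np.zeros(config.n_snps) if true_betas is None else true_betas,
        true_score=true_score,
        latent_factor=factor,
    )
    return table, truth


# ---------------------------------------------------------------------------
# whole-cohort convenience


@dataclass
class Cohort:
    """Bundle of everything one simulated study produces."""

    config: SimConfig
    variants: pd.DataFrame
    dosages: np.ndarray
    sumstats: pd.DataFrame
    covariates: pd.DataFrame
    involvement: pd.DataFrame
    truth: TrueModel

    @property
    def sample_ids(self) -> list[str]:
        return list(self.covariates["sample_id"])


def simulate_cohort(config: SimConfig) -> Cohort:
    """Run the full generator from a single seed: genotypes, discovery
    statistics, covariates, involvement."""
    rng = np.random.default_rng(config.seed)
    variants, dosages = simulate_genotypes(config, rng)
    true_betas = draw_true_betas(config, rng)
    sumstats = simulate_discovery_stats(config, true_betas, variants, rng)
    covariates = simulate_covariates(config.n_samples, rng)

    filled = np.where(
        dosages == MISSING, 2.0 * variants["maf"].to_numpy(), dosages
    )
    true_score = filled @ true_betas
    involvement, truth = simulate_involvement(
        config, true_score, covariates, rng, true_betas=true_betas
    )
    return Cohort(
        config=config,
        variants=variants,
        dosages=dosages,
        sumstats=sumstats,
        covariates=covariates,
        involvement=involvement,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# writers (plain-text interchange formats)


def write_sumstats_tsv(sumstats: pd.DataFrame, path: str | Path) -> None:
    out = sumstats.rename(
        columns={
            "id": "SNP",
            "chrom": "CHR",
            "pos": "BP",
            "effect_allele": "A1",
            "other_allele": "A2",
            "beta": "BETA",
            "pvalue": "P",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_dosage_tsv(
    variants: pd.DataFrame,
    dosages: np.ndarray,
    sample_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Variants in rows, samples in columns; missing written as NA."""
    df = pd.DataFrame(
        dosages.T, index=variants["id"].to_numpy(), columns=list(sample_ids)
    ).replace(MISSING, pd.NA)
    meta = variants[["id", "chrom", "pos", "a1", "a2"]].set_index("id")
    pd.concat([meta, df], axis=1).to_csv(
        path, sep="\t", index_label="id", na_rep="NA"
    )


def write_vcf(
    variants: pd.DataFrame,
    dosages: np.ndarray,
    sample_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Minimal VCF 4.2 with GT fields; a1 (counted allele) is ALT."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j, row in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(gt_map[int(d)] for d in dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.a2}\t{row.a1}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_phenotypes_tsv(
    covariates: pd.DataFrame, involvement: pd.DataFrame, path: str | Path
) -> None:
    merged = covariates.merge(involvement, on="sample_id", validate="1:1")
    merged.to_csv(path, sep="\t", index=False)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
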