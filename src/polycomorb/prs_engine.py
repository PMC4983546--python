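"""Variant QC, allele harmonization, LD clumping and polygenic scoring.

The scoring pipeline is: per-variant statistics -> QC filter (MAF, call
rate, exact HWE, MHC exclusion) -> harmonization of summary statistics
against target alleles -> greedy p-value-informed clumping -> averaged
weighted allele counts at a fixed ladder of p-value thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import MISSING

#: The fixed p-value threshold ladder used for all score profiles.
P_THRESHOLDS = (0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)

#: MHC exclusion zone: chromosome, start, end (inclusive, 1-based).
MHC_REGION = (6, 25_000_000, 35_000_000)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class QcThresholds:
    """QC rules; all comparisons are strict, as printed."""

    maf_min: float = 0.02
    call_rate_min: float = 0.98
    hwe_p_min: float = 1e-6
    mhc: tuple[int, int, int] = MHC_REGION


@dataclass(frozen=True)
class ClumpParams:
    r2_threshold: float = 0.10
    window_kb: float = 500.0

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold < 1:
            raise ValueError("r2_threshold must be in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


def hwe_exact_p(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (Wigginton-style mid-less exact test). Returns a p-value in (0, 1].
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    rare = min(n_a, n_b)

    # possible heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | n_a, n_b) up to a constant:
    #   log n! - log homA! - log h! - log homB! + h log 2
    hom_a = (n_a - het_values) // 2
    hom_b = (n_b - het_values) // 2
    from scipy.special import gammaln

    logp = (
        het_values * np.log(2.0)
        - gammaln(hom_a + 1.0)
        - gammaln(het_values + 1.0)
        - gammaln(hom_b + 1.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()

    p_obs = probs[het_values == n_het]
    if len(p_obs) == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def compute_variant_stats(
    variants: pd.DataFrame, dosages: np.ndarray
) -> pd.DataFrame:
    """Per-variant call rate, MAF (of the counted allele, folded) and exact
    HWE p-value from an integer dosage matrix with :data:`MISSING` holes."""
    n, m = dosages.shape
    out = variants[["id", "chrom", "pos", "a1", "a2"]].copy()
    observed = dosages != MISSING
    n_called = observed.sum(axis=0)
    call_rate = n_called / n

    n_hom_b = ((dosages == 0) & observed).sum(axis=0)  # 0 copies of a1
    n_het = (dosages == 1).sum(axis=0)
    n_hom_a = (dosages == 2).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (2.0 * n_hom_a + n_het) / (2.0 * n_called)
    maf = np.minimum(freq, 1.0 - freq)
    hwe = np.array(
        [
            hwe_exact_p(int(a), int(h), int(b)) if c > 0 else 1.0
            for a, h, b, c in zip(n_hom_a, n_het, n_hom_b, n_called)
        ]
    )
    out["call_rate"] = call_rate
    out["freq_a1"] = freq
    out["maf"] = maf
    out["hwe_p"] = hwe
    return out


def qc_filter(
    stats: pd.DataFrame, thresholds: QcThresholds = QcThresholds()
) -> list[str]:
    """Variant ids passing all QC rules (strict inequalities)."""
    chrom, start, end = thresholds.mhc
    chroms = pd.to_numeric(stats["chrom"], errors="coerce")
    in_mhc = (
        (chroms == chrom) & (stats["pos"] >= start) & (stats["pos"] <= end)
    )
    keep = (
        (stats["maf"] > thresholds.maf_min)
        & (stats["call_rate"] > thresholds.call_rate_min)
        & (stats["hwe_p"] > thresholds.hwe_p_min)
        & ~in_mhc
    )
    return list(stats.loc[keep, "id"])


def harmonize(sumstats: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Align discovery effects to the target's counted allele (a1).

    Resolution order per shared variant: direct match (beta kept), allele
    swap (beta negated), strand-complement match (kept), complement + swap
    (negated). Strand-ambiguous pairs (A/T, C/G) and unresolvable allele
    pairs are dropped. Returns the aligned summary statistics restricted to
    resolvable shared variants, with beta expressed per copy of a1.
    """
    if sumstats["id"].duplicated().any():
        raise ValueError("duplicate variant ids in summary statistics")
    if variants["id"].duplicated().any():
        raise ValueError("duplicate variant ids in target variants")

    merged = sumstats.merge(
        variants[["id", "a1", "a2"]], on="id", how="inner", validate="1:1"
    )
    ea = merged["effect_allele"].str.upper()
    oa = merged["other_allele"].str.upper()
    a1 = merged["a1"].str.upper()
    a2 = merged["a2"].str.upper()

    ambiguous = [
        frozenset((x, y)) in _AMBIGUOUS for x, y in zip(ea, oa)
    ]
    comp_ea = ea.map(_COMPLEMENT)
    comp_oa = oa.map(_COMPLEMENT)

    direct = (ea == a1) & (oa == a2)
    swap = (ea == a2) & (oa == a1)
    comp = (comp_ea == a1) & (comp_oa == a2)
    comp_swap = (comp_ea == a2) & (comp_oa == a1)

    keep = ~np.array(ambiguous) & (direct | swap | comp | comp_swap)
    flip = (swap | comp_swap) & ~(direct | comp)

    out = merged.loc[keep].copy()
    out.loc[flip[keep], "beta"] = -out.loc[flip[keep], "beta"]
    out["scored_allele"] = out["a1"]
    return out.drop(columns=["effect_allele", "other_allele"]).rename(
        columns={"a1": "allele_a", "a2": "allele_b"}
    )


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over samples where both calls are present;
    0 when undefined (monomorphic or no overlap)."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def clump(
    sumstats: pd.DataFrame,
    variants: pd.DataFrame,
    dosages: np.ndarray,
    params: ClumpParams = ClumpParams(),
) -> list[str]:
    """Greedy p-value-informed clumping; returns the index-variant id list.

    Repeatedly the unassigned variant with the smallest p-value becomes an
    index; every unassigned same-chromosome variant within ``window_kb`` of
    it whose genotype r² with the index is >= ``r2_threshold`` is absorbed
    into that clump. Ties on p are broken by ascending (chrom, pos) so the
    output is independent of input row order. Monomorphic variants have
    undefined r² and are never absorbed.
    """
    col = {v: j for j, v in enumerate(variants["id"])}
    missing_ids = [v for v in sumstats["id"] if v not in col]
    if missing_ids:
        raise KeyError(f"variants absent from dosage matrix: {missing_ids[:5]}")

    work = sumstats.merge(
        variants[["id", "chrom", "pos"]].rename(
            columns={"chrom": "_chrom", "pos": "_pos"}
        ),
        on="id",
    )
    work = work.sort_values(
        ["pvalue", "_chrom", "_pos"], kind="mergesort"
    ).reset_index(drop=True)

    window = params.window_kb * 1000.0
    ids = work["id"].to_numpy()
    chroms = work["_chrom"].to_numpy()
    pos = work["_pos"].to_numpy()
    assigned = np.zeros(len(work), dtype=bool)
    index_ids: list[str] = []

    for i in range(len(work)):
        if assigned[i]:
            continue
        assigned[i] = True
        index_ids.append(ids[i])
        candidates = np.flatnonzero(
            ~assigned
            & (chroms == chroms[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        if candidates.size == 0:
            continue
        xi = dosages[:, col[ids[i]]]
        for j in candidates:
            if _pairwise_r2(xi, dosages[:, col[ids[j]]]) >= params.r2_threshold:
                assigned[j] = True
    return index_ids


def score(
    aligned: pd.DataFrame,
    variants: pd.DataFrame,
    dosages: np.ndarray,
    threshold: float,
) -> tuple[np.ndarray, int]:
    """Mean weighted allele count at one p-value threshold.

    Includes variants with p < threshold (strict); per sample the score is
    sum(beta_j * dosage_ij) / m over the m included variants. Missing
    dosages are imputed as twice the scored-allele frequency among called
    samples before weighting. Returns (scores, m).
    """
    sel = aligned.loc[aligned["pvalue"] < threshold]
    m = len(sel)
    if m == 0:
        raise ValueError(f"no variants pass p-value threshold {threshold}")
    col = {v: j for j, v in enumerate(variants["id"])}
    idx = [col[v] for v in sel["id"]]
    X = dosages[:, idx].astype(float)
    obs = X != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            obs.any(axis=0), (X * obs).sum(axis=0) / (2.0 * obs.sum(axis=0)), 0.0
        )
    X = np.where(obs, X, 2.0 * freq)
    betas = sel["beta"].to_numpy()
    return X @ betas / m, m


def build_profiles(
    aligned: pd.DataFrame,
    variants: pd.DataFrame,
    dosages: np.ndarray,
    sample_ids: Sequence[str],
    thresholds: Iterable[float] = P_THRESHOLDS,
) -> pd.DataFrame:
    """One score column per threshold; attrs['n_snps_used'] maps threshold
    to the (nested, non-decreasing) count of contributing variants."""
    out = pd.DataFrame({"sample_id": list(sample_ids)})
    n_used: dict[float, int] = {}
    for t in thresholds:
        s, m = score(aligned, variants, dosages, t)
        out[f"prs_{t}"] = s
        n_used[t] = m
    out.attrs["n_snps_used"] = n_used
    return out


# ---------------------------------------------------------------------------
# I/O


def read_sumstats_tsv(path: str | Path) -> pd.DataFrame:
    """Reads SNP/CHR/BP/A1/A2 with BETA or OR (OR converted by natural log)
    and P columns."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.upper(): c for c in df.columns}
    required = ["SNP", "CHR", "BP", "A1", "A2", "P"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if "BETA" in cols:
        beta = df[cols["BETA"]].astype(float)
    elif "OR" in cols:
        beta = np.log(df[cols["OR"]].astype(float))
    else:
        raise ValueError("summary statistics need a BETA or OR column")
    return pd.DataFrame(
        {
            "id": df[cols["SNP"]].astype(str),
            "chrom": df[cols["CHR"]],
            "pos": df[cols["BP"]].astype(int),
            "effect_allele": df[cols["A1"]].astype(str),
            "other_allele": df[cols["A2"]].astype(str),
            "beta": beta,
            "pvalue": df[cols["P"]].astype(float),
        }
    )


def read_dosage_tsv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Inverse of :func:`synthetic_cohort.write_dosage_tsv`."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["id", "chrom", "pos", "a1", "a2"]
    variants = df[meta_cols].copy()
    sample_ids = [c for c in df.columns if c not in meta_cols]
    mat = df[sample_ids].to_numpy(dtype=float).T
    mat = np.where(np.isnan(mat), MISSING, mat).astype(np.int8)
    return variants, mat, sample_ids


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Parse a biallelic-SNP VCF with GT fields into (variants, dosages,
    sample_ids); the ALT allele is counted (a1)."""
    rows = []
    gts = []
    sample_ids: list[str] = []
    gt_map = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING,
              "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2, ".|.": MISSING}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                sample_ids = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[:5]
            fmt = fields[8].split(":")
            gi = fmt.index("GT")
            calls = [gt_map[f.split(":")[gi]] for f in fields[9:]]
            rows.append((vid, chrom, int(pos), alt, ref))
            gts.append(calls)
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "a1", "a2"])
    chrom_num = pd.to_numeric(variants["chrom"], errors="coerce")
    if not chrom_num.isna().any():
        variants["chrom"] = chrom_num.astype(int)
    dosages = np.array(gts, dtype=np.int8).T
    return variants, dosages, sample_ids


def write_profiles_tsv(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def write_variant_report(
    aligned: pd.DataFrame, index_ids: Sequence[str], path: str | Path
) -> None:
    rep = aligned[["id", "beta", "pvalue"]].copy()
    rep["clump_index"] = rep["id"].isin(set(index_ids))
    rep.to_csv(path, sep="\t", index=False)
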