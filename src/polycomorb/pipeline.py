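"""End-to-end orchestration: simulate/load -> QC -> clump -> score -> factor
model -> association -> permutation -> report.

A run is driven by a JSON :class:`RunConfig`. All stage outputs are written
atomically under the output directory and checksummed into a manifest;
re-running an identical config reproduces identical checksums. Randomness
flows from the single root seed through per-stage derived streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, factor_model, permutation, prs_engine
from . import synthetic_cohort as sc

log = logging.getLogger("polycomorb")

DEFAULT_SUBSTANCES = list(sc.SUBSTANCES)


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    out_dir: str
    seed: int | None = None
    sim: dict | None = None
    inputs: dict | None = None
    qc: prs_engine.QcThresholds = field(default_factory=prs_engine.QcThresholds)
    clump: prs_engine.ClumpParams = field(default_factory=prs_engine.ClumpParams)
    thresholds: tuple[float, ...] = prs_engine.P_THRESHOLDS
    perm: permutation.PermConfig = field(default_factory=permutation.PermConfig)
    substances: list[str] = field(default_factory=lambda: list(DEFAULT_SUBSTANCES))
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {
            "out_dir", "seed", "sim", "inputs", "qc", "clump",
            "thresholds", "permutation", "substances", "log_level",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigError("config requires out_dir")
        cfg = cls(
            out_dir=raw["out_dir"],
            seed=raw.get("seed"),
            sim=raw.get("sim"),
            inputs=raw.get("inputs"),
            log_level=raw.get("log_level", "INFO"),
        )
        if "qc" in raw:
            cfg.qc = prs_engine.QcThresholds(**raw["qc"])
        if "clump" in raw:
            cfg.clump = prs_engine.ClumpParams(**raw["clump"])
        if "thresholds" in raw:
            cfg.thresholds = tuple(float(t) for t in raw["thresholds"])
        if "permutation" in raw:
            cfg.perm = permutation.PermConfig(**raw["permutation"])
        if "substances" in raw:
            cfg.substances = list(raw["substances"])
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of 'sim' (synthetic mode) or 'inputs' "
                "(file mode) must be provided"
            )
        if self.sim is not None and self.seed is None and "seed" not in self.sim:
            raise ConfigError("synthetic mode requires a seed")
        if not self.substances:
            raise ConfigError("at least one substance column required")
        if not self.thresholds:
            raise ConfigError("at least one p-value threshold required")

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "sim": self.sim,
            "inputs": self.inputs,
            "qc": dataclasses.asdict(self.qc),
            "clump": dataclasses.asdict(self.clump),
            "thresholds": list(self.thresholds),
            "permutation": dataclasses.asdict(self.perm),
            "substances": self.substances,
            "log_level": self.log_level,
        }


# ---------------------------------------------------------------------------
# helpers


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**63)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# the runner


class PipelineRun:
    """Holds in-memory state while executing stages in dependency order."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "params": config.to_dict(),
            "stages": {},
        }
        self.timings: dict[str, float] = {}

    # -- stage bodies ------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config
        if cfg.sim is not None:
            sim_kwargs = dict(cfg.sim)
            sim_kwargs.setdefault("seed", _stage_seed(cfg.seed, "simulate"))
            if "thresholds" in sim_kwargs:
                sim_kwargs["thresholds"] = np.asarray(sim_kwargs["thresholds"])
            if "loadings" in sim_kwargs:
                sim_kwargs["loadings"] = tuple(sim_kwargs["loadings"])
            if "maf_range" in sim_kwargs:
                sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
            if "covariate_effects" in sim_kwargs:
                sim_kwargs["covariate_effects"] = dict(
                    sim_kwargs["covariate_effects"]
                )
            cohort = sc.simulate_cohort(sc.SimConfig(**sim_kwargs))
            self.variants = cohort.variants
            self.dosages = cohort.dosages
            self.sample_ids = cohort.sample_ids
            self.sumstats = cohort.sumstats
            self.phenotypes = cohort.covariates.merge(
                cohort.involvement, on="sample_id"
            )
            _atomic_write(
                self.out / "sumstats.tsv",
                lambda p: sc.write_sumstats_tsv(self.sumstats, p),
            )
            _atomic_write(
                self.out / "dosages.tsv",
                lambda p: sc.write_dosage_tsv(
                    self.variants, self.dosages, self.sample_ids, p
                ),
            )
            _atomic_write(
                self.out / "phenotypes.tsv",
                lambda p: self.phenotypes.to_csv(p, sep="\t", index=False),
            )
            self._record("simulate", ["sumstats.tsv", "dosages.tsv", "phenotypes.tsv"])
        else:
            inp = self.config.inputs
            for key in ("sumstats", "genotypes", "phenotypes"):
                if key not in inp:
                    raise ConfigError(f"file mode requires inputs.{key}")
                if not Path(inp[key]).exists():
                    raise ConfigError(f"missing input file: {inp[key]}")
            self.sumstats = prs_engine.read_sumstats_tsv(inp["sumstats"])
            if inp.get("format", "tsv") == "vcf":
                self.variants, self.dosages, self.sample_ids = (
                    prs_engine.read_vcf(inp["genotypes"])
                )
            else:
                self.variants, self.dosages, self.sample_ids = (
                    prs_engine.read_dosage_tsv(inp["genotypes"])
                )
            self.phenotypes = pd.read_csv(inp["phenotypes"], sep="\t")
            missing_sub = [
                s for s in self.config.substances
                if s not in self.phenotypes.columns
            ]
            if missing_sub:
                raise ConfigError(
                    f"phenotype table lacks substance columns: {missing_sub}"
                )
            self._record("simulate", [])

    def stage_qc(self) -> None:
        stats = prs_engine.compute_variant_stats(self.variants, self.dosages)
        retained = prs_engine.qc_filter(stats, self.config.qc)
        self.variant_stats = stats
        self.qc_ids = retained
        _atomic_write(
            self.out / "variant_stats.tsv",
            lambda p: stats.to_csv(p, sep="\t", index=False),
        )
        _atomic_write(
            self.out / "qc_retained.txt",
            lambda p: Path(p).write_text("\n".join(retained) + "\n"),
        )
        log.info("qc: retained %d / %d variants", len(retained), len(stats))
        self._record("qc", ["variant_stats.tsv", "qc_retained.txt"])

    def stage_clump(self) -> None:
        keep = set(self.qc_ids)
        aligned = prs_engine.harmonize(
            self.sumstats, self.variants[self.variants["id"].isin(keep)]
        )
        index_ids = prs_engine.clump(
            aligned, self.variants, self.dosages, self.config.clump
        )
        self.aligned = aligned[aligned["id"].isin(set(index_ids))].reset_index(
            drop=True
        )
        self.index_ids = index_ids
        _atomic_write(
            self.out / "clump_index.txt",
            lambda p: Path(p).write_text("\n".join(index_ids) + "\n"),
        )
        log.info("clump: %d index variants from %d aligned", len(index_ids),
                 len(aligned))
        self._record("clump", ["clump_index.txt"])

    def stage_score(self) -> None:
        profiles = prs_engine.build_profiles(
            self.aligned, self.variants, self.dosages, self.sample_ids,
            self.config.thresholds,
        )
        self.profiles = profiles
        _atomic_write(
            self.out / "prs_profiles.tsv",
            lambda p: prs_engine.write_profiles_tsv(profiles, p),
        )
        _atomic_write(
            self.out / "variant_report.tsv",
            lambda p: prs_engine.write_variant_report(
                self.aligned, self.index_ids, p
            ),
        )
        self._record("score", ["prs_profiles.tsv", "variant_report.tsv"])

    def stage_cfa(self) -> None:
        table = self.phenotypes[["sample_id"] + self.config.substances]
        model = factor_model.fit_one_factor(table)
        scores = factor_model.factor_scores(model, table)
        self.cfa = model
        self.gensub = scores.to_numpy()
        _atomic_write(
            self.out / "factor_model.json",
            lambda p: Path(p).write_text(
                json.dumps(factor_model.model_summary(model), indent=2) + "\n"
            ),
        )
        _atomic_write(
            self.out / "gensub.tsv",
            lambda p: scores.rename_axis("sample_id").to_csv(p, sep="\t"),
        )
        self._record("cfa", ["factor_model.json", "gensub.tsv"])

    def stage_assoc(self) -> None:
        covars = association.build_covariate_design(self.phenotypes)
        self.covar_design = covars
        prs_cols = [f"prs_{t}" for t in self.config.thresholds]

        ols_rows = []
        for t, col in zip(self.config.thresholds, prs_cols):
            res = association.ols_incremental(
                self.gensub, self.profiles[col], covars
            )
            ols_rows.append(
                {"threshold": t, "beta_std": res.beta_std, "se": res.se,
                 "z": res.z, "pvalue": res.pvalue, "r2_inc": res.r2_inc,
                 "n": res.n}
            )
        self.ols_results = pd.DataFrame(ols_rows)

        assoc_rows, contrast_rows = [], []
        for sub in self.config.substances:
            outcome = self.phenotypes[sub].to_numpy()
            for t, col in zip(self.config.thresholds, prs_cols):
                for adjusted in (False, True):
                    if adjusted:
                        fit = association.adjusted_rerun(
                            outcome, self.profiles[col], covars, self.gensub
                        )
                    else:
                        fit = association.multinomial_fit(
                            outcome, self.profiles[col], covars
                        )
                    tag = "gensub_adjusted" if adjusted else "raw"
                    tbl = fit.table()
                    tbl.insert(0, "substance", sub)
                    tbl.insert(1, "threshold", t)
                    tbl.insert(2, "model", tag)
                    assoc_rows.append(tbl)
                    for w in association.all_wald_pairs(fit):
                        contrast_rows.append(
                            {"substance": sub, "threshold": t, "model": tag,
                             "level_a": w.level_a, "level_b": w.level_b,
                             "chi2": w.statistic, "pvalue": w.pvalue}
                        )
        self.assoc_results = pd.concat(assoc_rows, ignore_index=True)
        self.contrasts = pd.DataFrame(contrast_rows)
        _atomic_write(
            self.out / "ols_results.tsv",
            lambda p: self.ols_results.to_csv(p, sep="\t", index=False),
        )
        _atomic_write(
            self.out / "assoc_results.tsv",
            lambda p: self.assoc_results.to_csv(p, sep="\t", index=False),
        )
        _atomic_write(
            self.out / "contrasts.tsv",
            lambda p: self.contrasts.to_csv(p, sep="\t", index=False),
        )
        self._record("assoc", ["ols_results.tsv", "assoc_results.tsv",
                               "contrasts.tsv"])

    def stage_permute(self) -> None:
        covars = self.covar_design
        prs_cols = [f"prs_{t}" for t in self.config.thresholds]
        S = self.profiles[prs_cols].to_numpy(dtype=float)
        outcomes = self.phenotypes[self.config.substances].to_numpy()
        gensub = self.gensub

        def fit_family(scores: np.ndarray) -> np.ndarray:
            zs = []
            for j in range(scores.shape[1]):
                col = scores[:, j]
                res = association.ols_incremental(gensub, col, covars)
                zs.append(res.z)
                for s in range(outcomes.shape[1]):
                    fit = association.multinomial_fit(
                        outcomes[:, s], col, covars
                    )
                    zs.extend(
                        fit.zstat(lvl) for lvl in fit.levels[1:]
                    )
            return np.asarray(zs)

        perm_cfg = self.config.perm
        if self.config.seed is not None:
            perm_cfg = permutation.PermConfig(
                n_perm=perm_cfg.n_perm, alpha=perm_cfg.alpha,
                seed=_stage_seed(self.config.seed, "permute"),
            )
        thr = permutation.permute_family(S, fit_family, perm_cfg)
        self.threshold = thr
        _atomic_write(
            self.out / "perm_threshold.json",
            lambda p: Path(p).write_text(
                json.dumps(permutation.threshold_summary(thr), indent=2) + "\n"
            ),
        )
        _atomic_write(
            self.out / "null_max_abs_z.tsv",
            lambda p: pd.DataFrame(
                {"max_abs_z": thr.null_max_abs_z}
            ).to_csv(p, sep="\t", index=False),
        )
        self._record("permute", ["perm_threshold.json", "null_max_abs_z.tsv"])

    def stage_report(self) -> None:
        missing = [
            a for a in ("ols_results", "assoc_results", "threshold")
            if not hasattr(self, a)
        ]
        if missing:
            raise RuntimeError(f"report requires completed stages for: {missing}")
        r2_table = self.ols_results[["threshold", "r2_inc", "pvalue"]].copy()
        r2_table["pct_variance"] = 100.0 * r2_table["r2_inc"]
        raw = self.assoc_results[self.assoc_results["model"] == "raw"]
        flagged = permutation.apply_threshold(raw, self.threshold)
        zgrid = flagged.pivot_table(
            index=["substance", "threshold"], columns="level", values="z"
        )
        _atomic_write(
            self.out / "r2_by_threshold.tsv",
            lambda p: r2_table.to_csv(p, sep="\t", index=False),
        )
        _atomic_write(
            self.out / "z_grid.tsv",
            lambda p: zgrid.to_csv(p, sep="\t"),
        )
        _atomic_write(
            self.out / "flagged_results.tsv",
            lambda p: flagged.to_csv(p, sep="\t", index=False),
        )
        self._record("report", ["r2_by_threshold.tsv", "z_grid.tsv",
                                "flagged_results.tsv"])

    # -- bookkeeping -------------------------------------------------------

    def _record(self, stage: str, files: list[str]) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {f: _sha256(self.out / f) for f in files}
        }

    def run_all(self) -> dict:
        logging.basicConfig(
            level=getattr(logging, self.config.log_level.upper(), logging.INFO),
            format="%(levelname)s %(name)s: %(message)s",
        )
        order = [
            ("simulate", self.stage_simulate),
            ("qc", self.stage_qc),
            ("clump", self.stage_clump),
            ("score", self.stage_score),
            ("cfa", self.stage_cfa),
            ("assoc", self.stage_assoc),
            ("permute", self.stage_permute),
            ("report", self.stage_report),
        ]
        for name, fn in order:
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                fn()
            except (ConfigError,) as exc:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
            self.timings[name] = time.perf_counter() - t0
            log.info("stage %s: done (%.2fs)", name, self.timings[name])

        _atomic_write(
            self.out / "manifest.json",
            lambda p: Path(p).write_text(
                json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
            ),
        )
        _atomic_write(
            self.out / "timings.json",
            lambda p: Path(p).write_text(
                json.dumps(self.timings, indent=2) + "\n"
            ),
        )
        return self.manifest


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    return PipelineRun(config).run_all()
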