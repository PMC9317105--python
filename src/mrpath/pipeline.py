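"""End-to-end orchestration: screen -> instruments -> MR -> consistency ->
PheWAS -> mediation, from one YAML config, with seeding, logging, a run
manifest, and plain-TSV intermediates so every stage is independently
testable and re-runnable.

A single global seed is fanned out to per-stage child seeds by stable
derivation (stage name hashed into a SeedSequence), so toggling one stage off
does not perturb another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, mediation, mr, phewas, screen, simulate, summary_io
from .errors import ConfigError, MrpathError
from .instruments import harmonize, instrument_strength, ld_prune

log = logging.getLogger(__name__)

STAGES = ("screen", "instruments", "mr", "consistency", "phewas", "mediation")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and stage-level parameters for one run."""

    workdir: str = "."
    cohort: str = "cohort.csv"
    phenome_columns: tuple[str, ...] = ("mediator",)
    phenome_categories: dict = field(default_factory=dict)
    exposure_gwas: str = "gwas_exposure_a.tsv"
    outcome_gwas_pattern: str = "gwas_{phenotype}_b.tsv"
    step2_exposure_gwas_pattern: str = "gwas_{phenotype}_a.tsv"
    disease_gwas: str = "gwas_disease_b.tsv"
    ld_matrix: str = "ld.tsv"
    dosages: str = "genotypes.raw"
    diagnoses: str = "dx.tsv"
    phenotype_map: str = ""  # empty -> built-in demo map
    phewas_variant: str = ""  # empty -> strongest instrument
    single_instrument_snp: str = ""  # empty -> strongest instrument
    stages: tuple[str, ...] = STAGES
    covariates: tuple[str, ...] = tuple(screen.DEFAULT_COVARIATES)
    s: int = 10_000
    alpha_empirical: float = 0.05
    f_min: float = 10.0
    r2_max: float = 0.1
    palindromic_eaf_window: float = 0.08
    nsim: int = 10_000
    alpha: float = 0.05
    min_cases: int = 20
    bonferroni_family: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("pipeline seed is mandatory")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        for key in ("phenome_columns", "stages", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        payload = {f.name: getattr(self, f.name) for f in fields(self)}
        for k, v in payload.items():
            if isinstance(v, tuple):
                payload[k] = list(v)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        # stable per-stage derivation: independent of which stages are enabled
        return int(
            np.random.SeedSequence(
                [int(self.seed), zlib.crc32(stage.encode())]
            ).generate_state(1)[0] % (2**31 - 1)
        )

    def path(self, name: str) -> Path:
        return Path(self.workdir) / name


def _meta(config: PipelineConfig, stage: str) -> dict:
    return {
        "pipeline_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "stage": stage,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    Each stage reads the previous stage's TSV from ``workdir``; a stage
    failure aborts the run with the failing stage named, retaining partial
    outputs.  Reruns under the same seed reproduce all numeric outputs.
    """
    manifest: dict = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": [],
    }
    runners = {
        "screen": _stage_screen,
        "instruments": _stage_instruments,
        "mr": _stage_mr,
        "consistency": _stage_consistency,
        "phewas": _stage_phewas,
        "mediation": _stage_mediation,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            rows = runners[stage](config)
        except Exception as exc:
            manifest["failed_stage"] = stage
            _write_manifest(config, manifest)
            raise MrpathError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"].append(
            {"stage": stage, "rows": rows, "runtime_s": round(time.perf_counter() - t0, 3)}
        )
        log.info("stage %-12s %5d rows  %.2fs", stage, rows, time.perf_counter() - t0)
    _write_manifest(config, manifest)
    return manifest


def _write_manifest(config: PipelineConfig, manifest: dict) -> None:
    with open(config.path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def _load_cohort(config: PipelineConfig) -> pd.DataFrame:
    cohort = summary_io.read_cohort(config.path(config.cohort))
    filtered, tally = simulate.apply_exclusions(cohort)
    pd.DataFrame(
        {"criterion": list(tally), "removed": list(tally.values())}
    ).pipe(summary_io.write_table, config.path("exclusion_tally.tsv"),
           _meta(config, "screen"))
    return filtered


def _stage_screen(config: PipelineConfig) -> int:
    cohort = _load_cohort(config)
    phenome = cohort.loc[:, list(config.phenome_columns)]
    cfg = screen.ScreenConfig(
        covariates=tuple(config.covariates), s=config.s,
        alpha_empirical=config.alpha_empirical,
        seed=config.stage_seed("screen"),
    )
    results = screen.screen_phenome(cohort, phenome, cfg)
    results["category"] = [
        config.phenome_categories.get(p, "phenotype") for p in results["phenotype"]
    ]
    summary_io.write_table(results, config.path("screen_results.tsv"),
                           _meta(config, "screen"))
    return len(results)


def _selected_phenotypes(config: PipelineConfig) -> list[str]:
    res = summary_io.read_table(config.path("screen_results.tsv"))
    return res.loc[res["significant"].astype(bool), "phenotype"].tolist()


def _select_instruments(config: PipelineConfig, sumstats: pd.DataFrame,
                        ld: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weak-instrument filter then greedy LD pruning; returns (kept, ledger)."""
    stats = instrument_strength(sumstats, f_min=config.f_min)
    strong = stats[stats["kept"]].copy()
    pruned = ld_prune(strong, ld, threshold=config.r2_max) if len(strong) else strong
    ledger = pd.concat([
        stats.loc[~stats["kept"], ["SNP", "r2", "f_stat", "reason"]],
        pruned.loc[~pruned["kept"], ["SNP", "r2", "f_stat", "reason"]]
        if len(strong) else pd.DataFrame(columns=["SNP", "r2", "f_stat", "reason"]),
    ])
    kept_ids = pruned.loc[pruned["kept"], "SNP"] if len(strong) else pd.Series([], dtype=str)
    return sumstats[sumstats["SNP"].isin(kept_ids)], ledger


def _stage_instruments(config: PipelineConfig) -> int:
    exposure = summary_io.read_sumstats(config.path(config.exposure_gwas))
    ld = summary_io.read_ld_matrix(config.path(config.ld_matrix))
    kept, ledger = _select_instruments(config, exposure, ld)
    total_pairs = 0
    for phen in _selected_phenotypes(config):
        outcome = summary_io.read_sumstats(
            config.path(config.outcome_gwas_pattern.format(phenotype=phen))
        )
        pairs, dropped = harmonize(kept, outcome, config.palindromic_eaf_window)
        summary_io.write_table(pairs, config.path(f"pairs_{phen}.tsv"),
                               _meta(config, "instruments"))
        if len(dropped):
            dropped = dropped.assign(r2=np.nan, f_stat=np.nan,
                                     reason="unharmonizable")
            ledger = pd.concat([ledger, dropped[["SNP", "r2", "f_stat", "reason"]]])
        total_pairs += len(pairs)
    summary_io.write_table(ledger, config.path("instrument_removals.tsv"),
                           _meta(config, "instruments"))
    return total_pairs


def _stage_mr(config: PipelineConfig) -> int:
    seed = config.stage_seed("mr")
    rows_multi, rows_single, pleio_rows = [], [], []
    for phen in _selected_phenotypes(config):
        pairs = summary_io.read_table(config.path(f"pairs_{phen}.tsv"))
        multi = mr.ivw(pairs)
        if len(pairs) >= 4:
            report = mr.pleiotropy_test(pairs, n_sim=config.nsim, seed=seed)
            pleio_rows.append({
                "phenotype": phen, "global_rss_p": report.global_rss_p,
                "outliers": ",".join(report.outliers), "n_sim": report.n_sim,
            })
            if report.outliers and len(report.outliers) < len(pairs):
                multi = mr.outlier_corrected_ivw(pairs, report)
        rows_multi.append({"phenotype": phen, **multi.as_dict()})
        snp = config.single_instrument_snp
        if not snp:
            strength = pairs["beta_exp"].abs() / pairs["se_exp"]
            snp = pairs.loc[strength.idxmax(), "SNP"]
        single = mr.wald_ratio(pairs.loc[pairs["SNP"] == snp].iloc[0])
        rows_single.append({"phenotype": phen, "snp": snp, **single.as_dict()})
    multi_df = pd.DataFrame(rows_multi)
    single_df = pd.DataFrame(rows_single)
    if len(multi_df):
        multi_df["q"] = mr.fdr_adjust(multi_df["p"])
        single_df["q"] = mr.fdr_adjust(single_df["p"])
    summary_io.write_table(multi_df, config.path("mr_multi.tsv"), _meta(config, "mr"))
    summary_io.write_table(single_df, config.path("mr_single.tsv"), _meta(config, "mr"))
    summary_io.write_table(pd.DataFrame(pleio_rows),
                           config.path("pleiotropy_reports.tsv"), _meta(config, "mr"))
    return len(multi_df) + len(single_df)


def _read_mr_results(path: Path) -> dict[str, mr.MRResult]:
    df = summary_io.read_table(path)
    out = {}
    for rec in df.itertuples(index=False):
        out[rec.phenotype] = mr.MRResult(
            method=rec.method, beta=rec.beta, se=rec.se,
            ci_low=rec.ci_low, ci_high=rec.ci_high, p=rec.p,
            n_instruments=rec.n_instruments,
            q=getattr(rec, "q", None),
        )
    return out


def _stage_consistency(config: PipelineConfig) -> int:
    multi = _read_mr_results(config.path("mr_multi.tsv"))
    single = _read_mr_results(config.path("mr_single.tsv"))
    kept = mr.consistency_filter(single, multi, alpha=config.alpha)
    summary_io.write_table(pd.DataFrame({"phenotype": kept}),
                           config.path("consistent_phenotypes.tsv"),
                           _meta(config, "consistency"))
    return len(kept)


def _phewas_variant(config: PipelineConfig) -> str:
    if config.phewas_variant:
        return config.phewas_variant
    removals = summary_io.read_table(config.path("instrument_removals.tsv"))
    exposure = summary_io.read_sumstats(config.path(config.exposure_gwas))
    kept = exposure[~exposure["SNP"].isin(removals.get("SNP", pd.Series([], dtype=str)))]
    strength = kept["BETA"].abs() / kept["SE"]
    return kept.loc[strength.idxmax(), "SNP"]


def _stage_phewas(config: PipelineConfig) -> int:
    dosages = summary_io.read_raw_dosages(config.path(config.dosages))
    dx = pd.read_csv(config.path(config.diagnoses), sep="\t")
    pmap = (pd.read_csv(config.path(config.phenotype_map), sep="\t")
            if config.phenotype_map else phewas.DEMO_PHENOTYPE_MAP)
    cohort = _load_cohort(config)
    ids = cohort["iid"].to_numpy()
    variant = _phewas_variant(config)
    codings, n_malformed = phewas.code_phenotypes(
        dx, pmap, ids, min_cases=config.min_cases
    )
    covs = cohort.set_index("iid").loc[:, list(config.covariates)]
    dosage = dosages.loc[pd.Index(ids).intersection(dosages.index), variant]
    results = [phewas.logistic_assoc(dosage, c, covs) for c in codings]
    results = phewas.bonferroni_flag(results, config.bonferroni_family)
    df = pd.DataFrame([r.as_dict() for r in results])
    df.insert(0, "variant", variant)
    summary_io.write_table(df, config.path("phewas.tsv"),
                           {**_meta(config, "phewas"),
                            "malformed_codes": n_malformed})
    return len(df)


def _stage_mediation(config: PipelineConfig) -> int:
    consistent = summary_io.read_table(config.path("consistent_phenotypes.tsv"))
    multi = _read_mr_results(config.path("mr_multi.tsv"))
    disease = summary_io.read_sumstats(config.path(config.disease_gwas))
    disease = disease.dropna(subset=["BETA", "SE"])
    ld = summary_io.read_ld_matrix(config.path(config.ld_matrix))
    seed = config.stage_seed("mediation")
    rows, results = [], []
    phenotypes = consistent["phenotype"].tolist() if len(consistent) else []
    for phen in phenotypes:
        step1 = multi[phen]
        med_gwas = summary_io.read_sumstats(
            config.path(config.step2_exposure_gwas_pattern.format(phenotype=phen))
        )
        kept, _ = _select_instruments(config, med_gwas, ld)
        pairs, _ = harmonize(kept, disease, config.palindromic_eaf_window)
        if len(pairs) == 0:
            log.info("mediation: no usable instruments for %s; skipped", phen)
            continue
        step2 = mr.ivw(pairs)
        if len(pairs) >= 4:
            report = mr.pleiotropy_test(pairs, n_sim=config.nsim, seed=seed)
            if report.outliers and len(report.outliers) < len(pairs):
                step2 = mr.outlier_corrected_ivw(pairs, report)
        res = mediation.two_step_mediation(
            step1, step2, labels=("alcohol_consumption", phen, "disease")
        )
        results.append(res)
        rows.append(res.as_dict())
    summary_io.write_table(pd.DataFrame(rows), config.path("mediation.tsv"),
                           _meta(config, "mediation"))
    nodes, edges = mediation.mediation_network(results)
    summary_io.write_table(nodes, config.path("network_nodes.tsv"),
                           _meta(config, "mediation"))
    summary_io.write_table(edges, config.path("network_edges.tsv"),
                           _meta(config, "mediation"))
    config.path("network.dot").write_text(
        mediation.network_to_dot(nodes, edges)
    )
    return len(rows)


def write_demo_inputs(
    outdir: str | Path,
    seed: int = 7,
    sim_config: simulate.SimulationConfig | None = None,
    s: int = 200,
    nsim: int = 1_000,
) -> PipelineConfig:
    """Generate the synthetic fixture and a matching run config on disk.

    The cohort gains two pure-noise phenome columns next to the planted
    mediator so the screen stage has something to reject, and diseased
    individuals receive alcohol-related ICD10 codes (plus unrelated background
    codes) so the PheWAS stage has case groups to test.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = (sim_config or simulate.SimulationConfig()).with_seed(seed)
    geno = simulate.simulate_genotypes(cfg)
    cohort, truth = simulate.simulate_cohort(cfg, geno)
    rng = np.random.default_rng([seed, 6])
    cohort["noise_biomarker"] = rng.normal(50.0, 10.0, len(cohort))
    cohort["noise_lifestyle"] = rng.normal(0.0, 1.0, len(cohort))

    filtered, _ = simulate.apply_exclusions(cohort)
    ids_a, ids_b = simulate.split_cohort(filtered, 0.5, seed)
    geno_a, geno_b = geno.subset(ids_a), geno.subset(ids_b)

    summary_io.write_cohort(cohort, outdir / "cohort.csv")
    summary_io.write_raw_dosages(geno, outdir / "genotypes.raw")
    summary_io.write_ld_matrix(geno_a.empirical_ld(), outdir / "ld.tsv")

    exp_a = simulate.gwas_linear(filtered.loc[ids_a, "exposure"].to_numpy(), geno_a)
    summary_io.write_sumstats(exp_a, outdir / "gwas_exposure_a.tsv")
    phenome = ("mediator", "noise_biomarker", "noise_lifestyle")
    for phen in phenome:
        for tag, ids, g in (("a", ids_a, geno_a), ("b", ids_b, geno_b)):
            stats = simulate.gwas_linear(filtered.loc[ids, phen].to_numpy(), g)
            summary_io.write_sumstats(stats, outdir / f"gwas_{phen}_{tag}.tsv")
    dis_b = simulate.gwas_logistic(filtered.loc[ids_b, "disease"].to_numpy(), geno_b)
    summary_io.write_sumstats(dis_b.dropna(subset=["BETA", "SE"]),
                              outdir / "gwas_disease_b.tsv")

    diseased = cohort.loc[cohort["disease"] == 1, "iid"].to_numpy()
    dx_rows = [(iid, "F10.2") for iid in diseased]
    dx_rows += [(iid, "K70.3") for iid in diseased[rng.random(len(diseased)) < 0.5]]
    background = cohort["iid"].to_numpy()
    dx_rows += [(iid, "M76.0") for iid in background[rng.random(len(background)) < 0.02]]
    dx_rows += [(iid, "I10") for iid in background[rng.random(len(background)) < 0.05]]
    pd.DataFrame(dx_rows, columns=["iid", "code"]).to_csv(
        outdir / "dx.tsv", sep="\t", index=False
    )

    run_cfg = PipelineConfig(
        workdir=str(outdir),
        phenome_columns=phenome,
        phenome_categories={"mediator": "biomarker",
                            "noise_biomarker": "biomarker",
                            "noise_lifestyle": "lifestyle"},
        s=s, nsim=nsim, seed=seed,
    )
    payload = {f.name: getattr(run_cfg, f.name) for f in fields(run_cfg)}
    for k, v in payload.items():
        if isinstance(v, tuple):
            payload[k] = list(v)
    (outdir / "run.yaml").write_text(yaml.safe_dump(payload))
    (outdir / "truth.json").write_text(json.dumps({
        "indirect": truth.indirect,
        "path_a": truth.path_a,
        "path_b": truth.path_b,
        "causal_effect_disease": truth.causal_effect_disease,
        "pleiotropic_snps": geno.variants.loc[truth.pleiotropic_idx, "SNP"].tolist(),
    }, indent=2))
    return run_cfg


def run_demo(outdir: str | Path, seed: int = 7,
             sim_config: simulate.SimulationConfig | None = None,
             s: int = 200, nsim: int = 1_000) -> dict:
    """Generate the synthetic fixture, run every stage, and build the report."""
    config = write_demo_inputs(outdir, seed=seed, sim_config=sim_config, s=s, nsim=nsim)
    manifest = run_pipeline(config)
    make_report(config)
    return manifest


def make_report(config: PipelineConfig) -> dict[str, Path]:
    """Summary plots and tables for a completed run.

    Produces a Manhattan-style plot of the screen stage (-log10 observed p by
    phenotype category), a forest-style TSV of MR betas and CIs, and the
    mediation network rendering.  Empty results produce an empty report with
    a warning rather than an error.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out: dict[str, Path] = {}
    screen_path = config.path("screen_results.tsv")
    if screen_path.exists():
        res = summary_io.read_table(screen_path)
        if len(res) == 0:
            log.warning("make_report: empty screen results")
        else:
            fig, ax = plt.subplots(figsize=(8, 4))
            categories = res.get("category", pd.Series(["phenotype"] * len(res)))
            for i, cat in enumerate(sorted(categories.unique())):
                sub = res[categories == cat]
                ax.scatter(sub.index, -np.log10(sub["p_observed"]), label=cat, s=18)
            ax.set_xlabel("phenotype")
            ax.set_ylabel(r"$-\log_{10}$ observed p")
            ax.legend(fontsize=7)
            fig.tight_layout()
            path = config.path("screen_manhattan.png")
            fig.savefig(path, dpi=120)
            plt.close(fig)
            out["manhattan"] = path
    mr_path = config.path("mr_multi.tsv")
    if mr_path.exists():
        multi = summary_io.read_table(mr_path)
        forest = multi[["phenotype", "method", "beta", "ci_low", "ci_high", "p", "q"]].copy() \
            if len(multi) else multi
        if len(forest):
            forest["p_display"] = [mr.format_pvalue(p) for p in forest["p"]]
        fpath = config.path("mr_forest.tsv")
        summary_io.write_table(forest, fpath, _meta(config, "report"))
        out["forest"] = fpath
    dot = config.path("network.dot")
    if dot.exists():
        out["network"] = dot
    if not out:
        log.warning("make_report: no results found; empty report")
    return out
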