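"""Configuration-driven end-to-end pipeline.

Runs simulate -> genotype QC -> GRM -> GREML -> connectivity -> second-level
inference and writes the analog result tables: per-ROI variance components
with LRTs, per-ROI response and degree statistics, pairwise connection
proportions, the bivariate genetic-correlation matrix of the subnetwork
ROIs, GWAS threshold counts, trend fits, the count-statistic JSON and a run
log.  Every output table carries a header line naming the config hash and
seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import SUBNETWORK_ROIS, SimConfig, degree_coupled_h2
from .connectivity import (connection_proportions, connectivity_graph,
                           degree_population_stats, percent_bsc,
                           standardize_phenotypes)
from .exceptions import ConfigError, PipelineError
from .genotypes import apply_sample_qc, apply_snp_qc
from .greml import GREML, BivariateGREML
from .grm import compute_grm, grm_pca, prune_related, write_grm
from .gwas import gwas_scan, snp_count_by_threshold
from .inference import (classify_subnetworks, fit_linear_trend,
                        fit_quadratic_trend, mc_count_pvalue, split_half_means,
                        split_half_r2)
from .synth import (simulate_bold_cohort, simulate_genotypes,
                    simulate_multiroi_phenotypes)


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with the study's thresholds as defaults."""

    outdir: str = "pipeline_out"
    seed: int = 0
    # synthetic cohort
    n_subjects: int = 300
    n_snps: int = 2000
    n_causal: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_mode: str = "degree-coupled"  # or "uniform"
    target_h2: float = 0.5
    missing_rate: float = 0.01
    # QC thresholds
    miss_max: float = 0.05
    hwe_p_min: float = 1e-4
    maf_min: float = 0.01
    call_rate_min: float = 0.97
    relatedness_cutoff: float = 0.05
    n_pcs: int = 10
    # connectivity / inference
    r_min: float = 0.3
    alpha: float = 0.05
    n_realizations: int = 50_000
    coupling_r: float = 0.5
    # module toggles
    genetics: bool = True
    connectivity: bool = True
    gwas: bool = True
    bivariate: bool = True
    max_bivariate_pairs: int = 6
    write_plink: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every enabled stage; returns a name -> path map of artifacts."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    rng = np.random.default_rng(cfg.seed)

    sim = SimConfig(
        n_subjects=cfg.n_subjects, n_snps=cfg.n_snps, n_causal=cfg.n_causal,
        maf_range=cfg.maf_range, target_h2=cfg.target_h2, seed=cfg.seed,
        missing_rate=cfg.missing_rate, coupling_r=cfg.coupling_r,
    )
    if cfg.h2_mode == "degree-coupled":
        sim.target_h2 = degree_coupled_h2(
            sim.pair_connection_prob, h2_max=cfg.target_h2,
            subject_sd=sim.subject_connectivity_sd,
        )
    elif cfg.h2_mode != "uniform":
        raise ConfigError(f"unknown h2_mode {cfg.h2_mode!r}")

    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))
    artifacts["config"] = outdir / "config.yaml"

    pheno_std = None
    grm = None
    panel = None

    if cfg.genetics:
        stage = "genetics"
        try:
            geno = simulate_genotypes(sim, rng)
            geno, snp_report = apply_snp_qc(
                geno, miss_max=cfg.miss_max, hwe_p_min=cfg.hwe_p_min,
                maf_min=cfg.maf_min,
            )
            geno, sample_report = apply_sample_qc(
                geno, call_rate_min=cfg.call_rate_min
            )
            qc = pd.concat([snp_report.to_frame(), sample_report.to_frame()])
            _write_table(qc, outdir / "qc_report.tsv", cfg)
            artifacts["qc_report"] = outdir / "qc_report.tsv"

            grm = compute_grm(geno)
            kept = prune_related(grm, cutoff=cfg.relatedness_cutoff)
            idx = kept.index.to_numpy()
            grm = grm.take(idx)
            geno = geno.take_samples(
                np.isin(np.arange(len(geno.sample_ids)), idx)
            )
            write_grm(grm, outdir / "cohort")
            artifacts["grm"] = outdir / "cohort.grm"
            n_pcs = min(cfg.n_pcs, grm.n - 1)
            pcs, _ = grm_pca(grm, k=n_pcs)
            _write_table(pcs, outdir / "pca.tsv", cfg)
            artifacts["pca"] = outdir / "pca.tsv"
            if cfg.write_plink:
                from .genotypes import write_plink_text

                write_plink_text(geno, outdir / "cohort")
                artifacts["ped"] = outdir / "cohort.ped"

            panel = simulate_multiroi_phenotypes(geno, sim, rng)
            pheno_std = standardize_phenotypes(panel.table)
            _write_table(pheno_std, outdir / "phenotypes.tsv", cfg)
            artifacts["phenotypes"] = outdir / "phenotypes.tsv"
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, "stage-failed", str(exc)) from exc

    graphs_amb = None
    bsc = None
    if cfg.connectivity:
        stage = "connectivity"
        try:
            cohort = simulate_bold_cohort(sim, rng)
            graphs_amb = [connectivity_graph(ts, "ambiguous",
                                             r_min=cfg.r_min)
                          for ts in cohort]
            bsc = pd.DataFrame([percent_bsc(ts, "ambiguous")
                                for ts in cohort])
            deg_stats = degree_population_stats(graphs_amb)
            table1 = deg_stats.copy()
            table1.insert(0, "bsc_mean", bsc.mean(axis=0))
            table1.insert(1, "bsc_sd", bsc.std(axis=0, ddof=0))
            _write_table(table1, outdir / "table1_analog.tsv", cfg,
                         index=True)
            artifacts["table1"] = outdir / "table1_analog.tsv"

            prop = connection_proportions(graphs_amb)
            _write_table(prop, outdir / "table2_analog.tsv", cfg, index=True)
            artifacts["table2"] = outdir / "table2_analog.tsv"

            nets = classify_subnetworks(deg_stats)
            _write_table(nets.labels.to_frame(), outdir / "subnetworks.tsv",
                         cfg, index=True)
            artifacts["subnetworks"] = outdir / "subnetworks.tsv"
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, "stage-failed", str(exc)) from exc

    if cfg.genetics:
        stage = "greml"
        try:
            roi_cols = list(sim.roi_names)
            covars = np.column_stack([
                pheno_std["sex"].to_numpy(dtype=float),
                pcs[[f"PC{i + 1}" for i in range(n_pcs)]].to_numpy(),
            ])
            rows = []
            for r, col in enumerate(roi_cols):
                model = GREML(pheno_std[col].to_numpy(), covars, grm=grm)
                res = model.fit()
                lrt = res.lrt()
                rows.append({
                    "roi": col, "vg": res.vg, "ve": res.ve, "vp": res.vp,
                    "ratio": res.ratio, "se_ratio": res.se_ratio,
                    "loglike": res.loglike, "lrt": lrt.statistic,
                    "p": lrt.p_value, "h2_true": sim.h2_per_roi()[r],
                    "converged": res.converged,
                })
            greml_tab = pd.DataFrame(rows)
            _write_table(greml_tab, outdir / "greml_univariate.tsv", cfg)
            artifacts["greml"] = outdir / "greml_univariate.tsv"

            observed = int((greml_tab["p"] < cfg.alpha).sum())
            corr = pheno_std[roi_cols].corr().to_numpy()
            null = mc_count_pvalue(
                corr, observed, alpha=cfg.alpha,
                n_realizations=cfg.n_realizations,
                seed=np.random.default_rng(cfg.seed + 1),
            )
            count_json = {
                "config": cfg.config_hash(), "seed": cfg.seed,
                "alpha": null.alpha, "observed_count": null.observed_count,
                "n_realizations": null.n_realizations,
                "p_value": null.p_value,
                "histogram": null.histogram.tolist(),
            }
            (outdir / "count_test.json").write_text(
                json.dumps(count_json, indent=2)
            )
            artifacts["count_test"] = outdir / "count_test.json"

            # split-half reproducibility of the regional %BSC profile
            # (raw responses; site z-scored columns have no profile left)
            r2_split = None
            if bsc is not None:
                a, b = split_half_means(bsc, seed=cfg.seed + 2, id_cols=())
                r2_split = split_half_r2(a, b)

            trends = []
            if graphs_amb is not None:
                deg_stats = degree_population_stats(graphs_amb)
                lin = fit_linear_trend(deg_stats["degree_sd"],
                                       greml_tab["ratio"])
                trends.append(("h2_vs_degree_sd", "linear", lin))
                quad = fit_quadratic_trend(deg_stats["degree_mean"],
                                           deg_stats["degree_sd"])
                trends.append(("degree_sd_vs_degree_mean", "quadratic", quad))
            if trends:
                tr = pd.DataFrame([
                    {
                        "name": name, "kind": kind,
                        "r_squared": f.r_squared,
                        "f": f.f_statistic, "df1": f.df1, "df2": f.df2,
                        "p": f.p_value,
                        "coefficients": ",".join(
                            f"{c:.6g}" for c in f.coefficients),
                    }
                    for name, kind, f in trends
                ])
                if r2_split is not None:
                    tr.loc[len(tr)] = {
                        "name": "split_half", "kind": "r2",
                        "r_squared": r2_split, "f": np.nan, "df1": 0,
                        "df2": 0, "p": np.nan, "coefficients": "",
                    }
                _write_table(tr, outdir / "trends.tsv", cfg)
                artifacts["trends"] = outdir / "trends.tsv"

            if cfg.gwas:
                counts_rows = []
                for r, col in enumerate(roi_cols):
                    scan = gwas_scan(geno, pheno_std[col].to_numpy(), covars)
                    counts = snp_count_by_threshold(scan)
                    row = {"roi": col, "ratio": greml_tab["ratio"].iat[r]}
                    row.update({f"p_lt_{t}": c for t, c in counts.items()})
                    counts_rows.append(row)
                fig2 = pd.DataFrame(counts_rows)
                _write_table(fig2, outdir / "fig2_analog.tsv", cfg)
                artifacts["fig2"] = outdir / "fig2_analog.tsv"

            if cfg.bivariate:
                pairs = []
                names = [r for r in SUBNETWORK_ROIS if r in roi_cols]
                for i in range(len(names)):
                    for j in range(i + 1, len(names)):
                        pairs.append((names[i], names[j]))
                pairs = pairs[: cfg.max_bivariate_pairs]
                brows = []
                for r1, r2 in pairs:
                    biv = BivariateGREML(
                        pheno_std[r1].to_numpy(), pheno_std[r2].to_numpy(),
                        covars, grm=grm,
                    ).fit()
                    brows.append({
                        "roi1": r1, "roi2": r2, "rg": biv.rg,
                        "se_rg": biv.se_rg, "cov_g": biv.cov_g,
                        "p_cov_g": biv.p_cov_g, "unstable": biv.unstable,
                    })
                if brows:
                    _write_table(pd.DataFrame(brows),
                                 outdir / "tableS4_analog.tsv", cfg)
                    artifacts["bivariate"] = outdir / "tableS4_analog.tsv"
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, "stage-failed", str(exc)) from exc

    log = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "wall_time_s": round(time.time() - t0, 3),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    artifacts["log"] = outdir / "run_log.json"
    return artifacts
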