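"""End-to-end sex-stratified analysis: preprocess → descriptives →
bivariate → multivariate → stepwise → volcano.

Every stage writes its artifact as delimited text into the output
directory; a plain-text manifest records the configuration, seed, and
per-stage wall time, so any stochastic stage can be reproduced in
isolation. The whole bundle is deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dataio import (
    COVARIATE_NAMES,
    MetaboliteMatrix,
    PhenotypeTable,
    write_results,
)
from .preprocess import (
    impute_random_forest,
    preprocess_matrix,
    residualize_frame,
    confounder_columns,
    sex_stratified_scores,
    vdw_scores_frame,
)
from .bivariate import (
    correlate_all,
    pathway_summary_frame,
    results_to_frame,
    summarize_by_pathway,
    top_table,
)
from .pls_rankproduct import (
    PLSRunConfig,
    outer_rank_products,
    permutation_significance,
    volcano_table,
)
from .stepwise_selection import run_approach
from .cohort_descriptives import quarter_summary_table, summaries_to_frame

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    output_dir: str | Path = "crfmet_out"
    seed: int = 0
    min_detection_freq: float = 0.20
    pls: PLSRunConfig = field(default_factory=PLSRunConfig)
    stepwise_repeats: int = 1000
    stepwise_threshold: float = 0.05
    stepwise_max_steps: int | None = 15
    calibration_fraction: float = 0.8
    top_k: int = 10

    def stage_seed(self, stage: str) -> int:
        # stable per-stage substreams, printed in the manifest
        return (self.seed * 1009 + sum(map(ord, stage))) % (2**31)


def run_pipeline(matrix: MetaboliteMatrix, pheno: PhenotypeTable,
                 config: PipelineConfig) -> dict:
    """Run the full analysis for every sex present; returns the bundle
    as a dict of in-memory results (everything is also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = [f"crfmet {__version__}", f"seed\t{config.seed}"]
    bundle: dict = {}
    t0 = time.perf_counter()

    # -- cohort-wide preprocessing --------------------------------------
    filtered, report = preprocess_matrix(matrix, pheno, config.min_detection_freq)
    pheno_imp, imp_report = impute_random_forest(
        pheno, seed=config.stage_seed("impute"))
    report = report.merge(imp_report) if imp_report.imputed_cells else report
    write_results(report.to_frame(), outdir / "preprocess_report.tsv")
    manifest.append(f"preprocess\tanalytes {report.n_analytes_in}->"
                    f"{report.n_analytes_out}\t{time.perf_counter() - t0:.2f}s")
    bundle["report"] = report
    bundle["matrix"] = filtered
    bundle["phenotypes"] = pheno_imp

    sexes = [s for s in ("F", "M")
             if (pheno_imp.data["sex"] == s).sum() >= 8]
    for sex in sexes:
        t_sex = time.perf_counter()
        tag = sex.lower()
        sub_pheno = pheno_imp.subset(sex)

        # descriptives
        summaries = quarter_summary_table(pheno_imp, sex)
        write_results(summaries_to_frame(summaries),
                      outdir / f"quarter_summary_{tag}.tsv")

        # scores + confounder adjustment
        scores, y_adj = sex_stratified_scores(filtered, pheno_imp, sex)
        conf = confounder_columns(pheno_imp, sex)
        cov_scores = vdw_scores_frame(sub_pheno.covariates())
        cov_adj = residualize_frame(cov_scores, conf)

        # bivariate: star (confounders already removed) and doublestar
        star = correlate_all(scores, y_adj)
        double_cov = cov_adj[list(COVARIATE_NAMES)]
        double = correlate_all(scores.scores, y_adj, double_cov)
        write_results(results_to_frame(star), outdir / f"correlations_star_{tag}.tsv")
        write_results(results_to_frame(double),
                      outdir / f"correlations_doublestar_{tag}.tsv")
        write_results(top_table(double, config.top_k),
                      outdir / f"top_table_{tag}.tsv")
        pathways = summarize_by_pathway(star, double, filtered.analytes)
        write_results(pathway_summary_frame(pathways),
                      outdir / f"pathway_summary_{tag}.tsv")

        # multivariate: rank products + permutations on adjusted inputs
        pls_config = PLSRunConfig(
            n_outer_splits=config.pls.n_outer_splits,
            calibration_fraction=config.pls.calibration_fraction,
            inner_folds=config.pls.inner_folds,
            max_components=config.pls.max_components,
            n_permutations=config.pls.n_permutations,
            alpha=config.pls.alpha,
            seed=config.stage_seed(f"pls_{sex}"),
            permutation_mode=config.pls.permutation_mode)
        observed = outer_rank_products(scores, y_adj, pls_config)
        rp = permutation_significance(scores.scores, y_adj, observed, pls_config)
        write_results(rp.to_frame(), outdir / f"rank_products_{tag}.tsv")
        volcano = volcano_table(star, rp, filtered.analytes)
        write_results(volcano, outdir / f"volcano_{tag}.tsv")

        # stepwise approaches 1-3 on the pooled adjusted variable set
        all_vars = pd.concat([cov_adj, scores.scores], axis=1)
        finals = {}
        for approach in (1, 2, 3):
            path, freqs, final = run_approach(
                approach, list(COVARIATE_NAMES), scores.variable_ids,
                y_adj, all_vars,
                n_repeats=config.stepwise_repeats,
                calibration_fraction=config.calibration_fraction,
                threshold=config.stepwise_threshold,
                seed=config.stage_seed(f"stepwise_{sex}_{approach}"),
                max_steps=config.stepwise_max_steps, sex=sex)
            write_results(path.to_frame(),
                          outdir / f"stepwise_path_a{approach}_{tag}.tsv")
            write_results(freqs.to_frame(),
                          outdir / f"stepwise_frequencies_a{approach}_{tag}.tsv")
            write_results(final.to_frame(),
                          outdir / f"final_model_a{approach}_{tag}.tsv")
            finals[approach] = (path, freqs, final)

        bundle[sex] = {"summaries": summaries, "star": star, "double": double,
                       "pathways": pathways, "rank_products": rp,
                       "volcano": volcano, "stepwise": finals}
        manifest.append(f"sex_{sex}\tdone\t{time.perf_counter() - t_sex:.2f}s")

    manifest.append(f"total\t\t{time.perf_counter() - t0:.2f}s")
    (Path(config.output_dir) / "manifest.txt").write_text("\n".join(manifest) + "\n")
    bundle["manifest"] = manifest
    return bundle
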