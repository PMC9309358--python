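"""End-to-end pipeline orchestration: preprocess -> group stats -> coupling
-> mediation, with every output written as TSV/JSON plus a manifest recording
the package version, configuration hash and seed.  Identical config + seed
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coupling import (
    build_coupling,
    compare_coupling,
    fdr_across,
    partial_correlation,
    pairwise_screen,
    subset_stratified_comparison,
)
from .datatypes import MCCB_DOMAINS, PhenotypeTable
from .group_stats import (
    ancova_group_test,
    bh_fdr,
    chi_square_2x2,
    differential_expression,
    mann_whitney_z,
    student_t,
)
from .io import (
    FLOAT_FORMAT,
    PipelineConfig,
    read_annotation,
    read_counts,
    read_phenotypes,
    read_thickness,
    write_annotation,
    write_counts,
    write_phenotypes,
    write_thickness,
)
from .mediation import bootstrap_mediation
from .preprocess import average_hemispheres, filter_counts, log2_rpm, select_signature_genes

log = logging.getLogger("trimodal")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index=index)


def _demographics(ph: PhenotypeTable) -> pd.DataFrame:
    """Table-1-style demographics: normally distributed continuous variables
    by Student's t, non-normal by Mann-Whitney (Shapiro-Wilk dispatch at
    alpha = 0.05 in both groups), binary variables by chi-square."""
    df = ph.frame
    fes = df[df["group"] == "FES"]
    hc = df[df["group"] == "HC"]
    rows = []
    for var in ("age", "education"):
        x = fes[var].dropna().to_numpy()
        y = hc[var].dropna().to_numpy()
        normal = (sps.shapiro(x).pvalue >= 0.05) and (sps.shapiro(y).pvalue >= 0.05)
        res = student_t(x, y, var) if normal else mann_whitney_z(x, y, var)
        rows.append(res)
    for var, pos in (("sex", "male"), ("smoker", True)):
        table = np.array([
            [(fes[var] == pos).sum(), (fes[var] != pos).sum()],
            [(hc[var] == pos).sum(), (hc[var] != pos).sum()],
        ])
        rows.append(chi_square_2x2(table, var))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full analysis and write all result tables under ``outdir``.

    Returns the manifest (also written to ``manifest.json``).  On a stage
    failure, partial outputs are removed and :class:`StageError` is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# trimodal {_version()} config={config.digest()} seed={config.seed}"
    written: list[Path] = []
    manifest: dict = {
        "version": _version(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }

    def emit(name: str, path: Path) -> Path:
        written.append(path)
        manifest["stages"].setdefault(name, []).append(path.name)
        return path

    try:
        stage = "inputs"
        if config.synthetic:
            from .synthetic import default_config, generate_cohort

            gcfg = default_config(config.preset, seed=config.seed)
            cohort = generate_cohort(gcfg)
            phenotypes, counts = cohort.phenotypes, cohort.counts
            annotation, thickness = cohort.annotation, cohort.thickness
            write_phenotypes(phenotypes, emit(stage, outdir / "phenotypes.tsv"))
            write_counts(counts, emit(stage, outdir / "counts.tsv"))
            write_annotation(annotation, emit(stage, outdir / "annotation.tsv"))
            write_thickness(thickness, emit(stage, outdir / "thickness.tsv"))
        else:
            missing = [k for k in ("phenotypes", "counts", "annotation", "thickness")
                       if getattr(config, k) is None]
            if missing:
                raise ValueError(f"missing input path(s) {missing} and synthetic flag not set")
            phenotypes = read_phenotypes(config.phenotypes)
            counts = read_counts(config.counts)
            annotation = read_annotation(config.annotation)
            thickness = read_thickness(config.thickness, mode=config.thickness_mode)

        stage = "preprocess"
        totals = counts.frame.sum(axis=0)
        filtered, report = filter_counts(counts, config.min_mean_count, config.var_percentile)
        expr_all = log2_rpm(filtered, config.pseudocount, library_totals=totals)
        expr = select_signature_genes(expr_all, annotation)
        thickness_avg = (average_hemispheres(thickness)
                         if thickness.mode == "left+right" else thickness)
        _write_tsv(expr.frame, emit(stage, outdir / "expression.tsv"), header)
        _write_tsv(thickness_avg.frame, emit(stage, outdir / "thickness_averaged.tsv"), header)
        with open(emit(stage, outdir / "filter_report.json"), "w") as fh:
            json.dump(dataclasses.asdict(report), fh, indent=2, sort_keys=True)

        stage = "group_stats"
        _write_tsv(_demographics(phenotypes), emit(stage, outdir / "demographics.tsv"),
                   header, index=False)
        ph = phenotypes.frame
        group = ph["group"].to_numpy()
        cov_cog = phenotypes.covariate_matrix(config.cognition_covariates)
        cov_basic = phenotypes.covariate_matrix(config.covariates)
        ancova_rows = []
        mccb_results = []
        for dom in list(MCCB_DOMAINS) + ["composite"]:
            res = ancova_group_test(ph[f"mccb_{dom}"].to_numpy(dtype=float), group,
                                    cov_cog, outcome=f"mccb_{dom}")
            (mccb_results if dom != "composite" else ancova_rows).append(res)
        q = bh_fdr(np.array([r.p_value for r in mccb_results]))
        for r, qi in zip(mccb_results, q):
            r.q_value = float(qi)
        pct_results = []
        for sub in ("classical", "intermediate", "nonclassical"):
            col = ph[f"pct_{sub}"]
            if col.notna().sum() >= 10:
                pct_results.append(ancova_group_test(col.to_numpy(dtype=float), group,
                                                     cov_basic, outcome=f"pct_{sub}"))
        qp = bh_fdr(np.array([r.p_value for r in pct_results])) if pct_results else []
        for r, qi in zip(pct_results, qp):
            r.q_value = float(qi)
        shared = [s for s in phenotypes.subjects if s in set(thickness_avg.subjects)]
        mean_thick = thickness_avg.frame.loc[shared].mean(axis=1)
        sub_ph = PhenotypeTable(ph.set_index("subject_id").loc[shared].reset_index())
        ancova_rows.append(ancova_group_test(
            mean_thick.to_numpy(), sub_ph.frame["group"].to_numpy(),
            sub_ph.covariate_matrix(config.covariates), outcome="mean_thickness"))
        rows = mccb_results + pct_results + ancova_rows
        anc_df = pd.DataFrame([{
            "outcome": r.outcome,
            "adjusted_mean_HC": r.adjusted_means["HC"],
            "adjusted_mean_FES": r.adjusted_means["FES"],
            "F": r.f_statistic, "p": r.p_value, "q": r.q_value, "n": r.n_used,
        } for r in rows])
        _write_tsv(anc_df, emit(stage, outdir / "ancova.tsv"), header, index=False)
        shared_expr = [s for s in expr.subjects if s in set(phenotypes.subjects)]
        ph_expr = PhenotypeTable(ph.set_index("subject_id").loc[shared_expr].reset_index())
        de = differential_expression(
            expr.frame[shared_expr].to_numpy(), expr.genes,
            ph_expr.frame["group"].to_numpy(),
            ph_expr.covariate_matrix(config.covariates))
        de_df = pd.DataFrame([dataclasses.asdict(d) for d in de])
        _write_tsv(de_df, emit(stage, outdir / "differential_expression.tsv"),
                   header, index=False)

        stage = "coupling"
        matrices = {}
        for grp in ("HC", "FES"):
            matrices[grp] = build_coupling(
                expr, thickness_avg, phenotypes, grp,
                covariates=config.covariates,
                cognition_covariates=config.cognition_covariates,
                annotation=annotation)
            for key, cm in matrices[grp].items():
                _write_tsv(cm.to_frame("z"),
                           emit(stage, outdir / f"zr_{grp}_{key}.tsv"), header)
        scopes = [compare_coupling(matrices["HC"][k], matrices["FES"][k])
                  for k in ("gene-gene", "cortex-cortex", "gene-cortex",
                            "gene-cognition", "cortex-cognition")]
        fdr_across(scopes)
        strat = []
        for k in ("gene-cortex", "gene-cognition"):
            strat.extend(subset_stratified_comparison(
                matrices["HC"][k], matrices["FES"][k], annotation))
        fdr_across(strat)
        comp_df = pd.DataFrame([dataclasses.asdict(c) for c in scopes + strat])
        _write_tsv(comp_df, emit(stage, outdir / "paired_comparisons.tsv"),
                   header, index=False)
        screen_rows = []
        for grp in ("HC", "FES"):
            for k in ("gene-cortex", "gene-cognition"):
                for hit in pairwise_screen(matrices[grp][k], config.alpha_nominal,
                                           config.alpha):
                    screen_rows.append({"group": grp, "scope": k,
                                        **dataclasses.asdict(hit)})
        screen_df = pd.DataFrame(screen_rows)
        _write_tsv(screen_df, emit(stage, outdir / "screen_hits.tsv"), header, index=False)

        stage = "mediation"
        med = _mediation_stage(matrices, expr, thickness_avg, phenotypes, config)
        with open(emit(stage, outdir / "mediation.json"), "w") as fh:
            json.dump(med, fh, indent=2, sort_keys=True)

        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc


def _mediation_stage(matrices, expr, thickness_avg, phenotypes, config) -> dict:
    """Mediation of the top patient-group gene-cortex pair on cognition.

    Mirrors the study's procedure: take the most significant gene x region
    partial correlation in the FES group, use that region as mediator of the
    gene's effect on the MCCB domain most associated with the region, with
    age, sex and education as covariates.
    """
    hits = pairwise_screen(matrices["FES"]["gene-cortex"], config.alpha_nominal, config.alpha)
    if not hits:
        return {"selected": None, "note": "no gene-cortex pair at the nominal alpha"}
    top = hits[0]
    ph = phenotypes.frame
    fes_ids = [s for s in ph.loc[ph["group"] == "FES", "subject_id"]
               if s in set(expr.subjects) and s in set(thickness_avg.subjects)]
    sub = PhenotypeTable(ph.set_index("subject_id").loc[fes_ids].reset_index())
    cov = sub.covariate_matrix(config.cognition_covariates)
    m_vec = thickness_avg.frame.loc[fes_ids, top.feature].to_numpy()
    best_dom, best_r, best_p = None, 0.0, 1.0
    for dom in MCCB_DOMAINS:
        y = sub.frame[f"mccb_{dom}"].to_numpy(dtype=float)
        try:
            r, p, _ = partial_correlation(m_vec, y, cov)
        except ValueError:
            continue
        if p < best_p:
            best_dom, best_r, best_p = dom, r, p
    if best_dom is None:
        return {"selected": None, "note": "no usable cognition domain"}
    x_vec = expr.frame.loc[top.gene, fes_ids].to_numpy(dtype=float)
    y_vec = sub.frame[f"mccb_{best_dom}"].to_numpy(dtype=float)
    res = bootstrap_mediation(x_vec, m_vec, y_vec, cov,
                              n_boot=config.n_boot, seed=config.seed + 1)
    return {
        "selected": {"x_gene": top.gene, "m_region": top.feature, "y_domain": best_dom,
                     "screen_r": top.r, "screen_q": top.q_value,
                     "mediator_outcome_r": best_r, "mediator_outcome_p": best_p},
        "result": dataclasses.asdict(res),
    }


def _version() -> str:
    from . import __version__

    return __version__
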