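"""End-to-end orchestration of the dual-tracer analysis.

Chains the stages: simulate (or load) -> elliptical Fourier analysis ->
shape indices -> confound statistics -> F_ST -> DAPC -> supervised assignment
for both tracers, and gathers everything into one JSON-serializable report
that juxtaposes the genetic and otolith assignment matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import efd as efdmod
from .assignment import AssignmentResult, run_assignment
from .contour import SHAPE_INDEX_NAMES, Contour, redundancy_screen, shape_index_table
from .popgen import GenotypeMatrix, bootstrap_fst_ci, dapc_fit, dapc_xval
from .shapestats import anova_type3, fit_index_model, rda_fit, rda_permutation_test, tukey_hsd
from .simulate import SimulationConfig, simulate_otoliths

log = logging.getLogger("soletrace")

__all__ = ["ShapeAnalysis", "analyze_shapes", "run_pipeline"]


@dataclass
class ShapeAnalysis:
    """EFDs, adjusted harmonic count, shape PCA and index table for a sample."""

    efds: list
    n_harmonics: int
    shape_matrix: efdmod.ShapeMatrix
    index_table: pd.DataFrame
    retained_indices: list[str]
    index_correlations: pd.DataFrame


def analyze_shapes(
    contours: list[Contour],
    k_max: int = efdmod.DEFAULT_K_MAX,
    power_threshold: float = efdmod.DEFAULT_POWER_THRESHOLD,
    var_threshold: float = 0.99,
) -> ShapeAnalysis:
    """Elliptical Fourier analysis plus shape indices for a contour sample."""
    efds = [efdmod.normalize_efd(efdmod.compute_efd(c, k_max=k_max)) for c in contours]
    n = efdmod.adjust_harmonics(efds, threshold=power_threshold)
    shape_matrix = efdmod.shape_pca(efds, var_threshold=var_threshold, n=n)
    idx = shape_index_table(contours)
    retained, corr = redundancy_screen(idx)
    return ShapeAnalysis(
        efds=efds,
        n_harmonics=n,
        shape_matrix=shape_matrix,
        index_table=idx,
        retained_indices=retained,
        index_correlations=corr,
    )


def run_pipeline(
    config: SimulationConfig,
    n_boot: int = 1000,
    n_perm: int = 999,
    k_folds: int = 3,
    n_repeats: int = 10,
    max_pc: int = 30,
    xval_reps: int = 50,
    holdout: float = 0.1,
    seed: int | None = None,
) -> dict:
    """Simulate a dataset and run every analysis stage; return the JSON report."""
    seed = config.seed if seed is None else seed
    log.info("simulating dataset (seed=%d)", config.seed)
    ds = simulate_otoliths(config)
    log.info("elliptical Fourier analysis of %d contours", len(ds.contours))
    shapes = analyze_shapes(ds.contours)
    oto = ds.otolith_table

    log.info("RDA permutation test (n_perm=%d)", n_perm)
    rda = rda_fit(shapes.shape_matrix.scores, oto)
    rda_table = rda_permutation_test(rda, n_perm=n_perm, seed=seed)

    anova_tables = {}
    hsd_tables = {}
    for name in SHAPE_INDEX_NAMES:
        fit = fit_index_model(shapes.index_table[name].values, oto)
        anova_tables[name] = anova_type3(fit)
        hsd_tables[name] = tukey_hsd(fit, "Subunit")

    log.info("Weir-Cockerham F_ST with %d bootstrap replicates", n_boot)
    fst = bootstrap_fst_ci(ds.genotypes, n_boot=n_boot, seed=seed)

    log.info("DAPC cross-validation (max_pc=%d)", max_pc)
    best_pc, xval_table = dapc_xval(
        ds.genotypes, max_pc=max_pc, n_rep=xval_reps, holdout=holdout, seed=seed
    )
    dapc = dapc_fit(ds.genotypes, n_pc=best_pc)
    dapc_self = float(np.mean(dapc.assignments.values == ds.genotypes.subunits))

    log.info("supervised assignment, K=%d folds", k_folds)
    genetic = run_assignment(
        ds.genotypes.imputed(),
        ds.genotypes.subunits,
        K=k_folds,
        seed=seed,
        preprocess="pca",
        n_repeats=n_repeats,
        ids=ds.genotypes.sample_ids,
    )
    idx_features = shapes.index_table[list(SHAPE_INDEX_NAMES)].to_numpy(float)
    otolith = run_assignment(
        idx_features,
        oto["subunit"].to_numpy(),
        K=k_folds,
        seed=seed,
        preprocess="residualize",
        n_repeats=n_repeats,
        ids=list(shapes.index_table.index),
        design=oto,
    )
    return build_report(
        config, shapes, rda_table, anova_tables, hsd_tables, fst, best_pc,
        xval_table, dapc_self, genetic, otolith, seed,
    )


def build_report(
    config, shapes, rda_table, anova_tables, hsd_tables, fst, best_pc,
    xval_table, dapc_self, genetic: AssignmentResult, otolith: AssignmentResult, seed,
) -> dict:
    def mat(df: pd.DataFrame) -> dict:
        return {r: {c: float(df.loc[r, c]) for c in df.columns} for r in df.index}

    return {
        "seed": int(seed),
        "n_fish": int(sum(config.n_per_subunit.values())),
        "n_loci": int(config.n_loci),
        "shape": {
            "n_harmonics": int(shapes.n_harmonics),
            "n_shape_pcs": int(shapes.shape_matrix.n_components),
            "cum_explained_variance": float(
                shapes.shape_matrix.explained_variance_ratio.sum()
            ),
            "retained_indices": shapes.retained_indices,
        },
        "rda": rda_table.to_dict(orient="records"),
        "anova_type3": {
            k: v.to_dict(orient="records") for k, v in anova_tables.items()
        },
        "tukey_subunit": {
            k: v.to_dict(orient="records") for k, v in hsd_tables.items()
        },
        "fst": {
            "global": float(fst.global_theta),
            "global_ci": list(fst.global_ci),
            "global_significant": bool(fst.global_significant),
            "pairwise": fst.pairwise.to_dict(orient="records"),
            "n_boot": int(fst.n_boot),
        },
        "dapc": {
            "best_n_pc": int(best_pc),
            "xval": xval_table.to_dict(orient="records"),
            "self_assignment": float(dapc_self),
        },
        "assignment": {
            "genetic": {
                "matrix_mean": mat(genetic.matrix_mean),
                "matrix_sd": mat(genetic.matrix_sd),
                "mean_self_assignment": genetic.mean_self_assignment,
                "n_ties": int(genetic.n_ties),
            },
            "otolith": {
                "matrix_mean": mat(otolith.matrix_mean),
                "matrix_sd": mat(otolith.matrix_sd),
                "mean_self_assignment": otolith.mean_self_assignment,
                "n_ties": int(otolith.n_ties),
            },
        },
    }


REPORT_REQUIRED_KEYS = {
    "seed", "n_fish", "n_loci", "shape", "rda", "anova_type3",
    "tukey_subunit", "fst", "dapc", "assignment",
}


def validate_report(report: dict) -> None:
    """Structural check of a pipeline report (raises on missing sections)."""
    missing = REPORT_REQUIRED_KEYS - set(report)
    if missing:
        raise ValueError(f"report missing sections: {sorted(missing)}")
    for tracer in ("genetic", "otolith"):
        block = report["assignment"][tracer]
        for key in ("matrix_mean", "matrix_sd", "mean_self_assignment"):
            if key not in block:
                raise ValueError(f"assignment.{tracer} missing {key}")
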