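"""End-to-end orchestration of the two expression -> imaging analyses.

Model-1 predicts the regional group contrast of cortical thickness
(one response column: Welch t of control minus patient CT in the
left-hemisphere regions) from the region x gene expression matrix, then
runs enrichment on the component-1 gene weights.

Model-2 predicts the regions x clinical-features matrix of regression
t-statistics (thickness on score plus age, per cell) from the same
expression matrix with a multi-response fit, and runs enrichment per
retained component.

Both entry points exist twice: an in-memory form operating on package
objects (used by tests and the acceptance script) and a file-based form
behind the command line that reads the documented on-disk layout and
writes tidy TSVs plus a JSON run manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gsea import GeneSetCollection, gsea_preranked, read_gmt
from .imaging import ct_clinical_regression, regional_group_contrast, t_matrix
from .mapping import PipelineError, RegionExpressionMatrix, aggregate_expression, assign_samples
from .pls import CVResult, PLSFit, explained_variance, fit_pls, gene_weights, loo_cv, score_response_report
from .synthetic import (
    CLINICAL_FEATURES,
    DonorSamples,
    ParcellationGrid,
    SyntheticScenario,
    ct_column,
    read_donor_dir,
)

MIN_COMMON_REGIONS = 10


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run (YAML-serializable)."""

    parcellation: str = ""
    donors: str = ""
    ct: str = ""
    clinical: str = ""
    gmt: str = ""
    out: str = "."
    tolerance_mm: float = 2.0
    n_components_model1: int = 1
    n_components_model2: int = 3
    retain_components_model2: int = 2
    run_cv: bool = True
    max_cv_components: int = 5
    scale: bool = False
    gsea_n_perm: int = 10_000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    gsea_exponent: float = 1.0
    seed: int = 0
    clinical_features: list[str] = field(default_factory=lambda: list(CLINICAL_FEATURES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class Model1Result:
    expression: RegionExpressionMatrix
    contrast_bilateral: pd.DataFrame
    contrast_left: pd.DataFrame
    common_regions: list[int]
    dropped_x: list[int]
    dropped_y: list[int]
    fit: PLSFit
    cv: CVResult | None
    component_report: pd.DataFrame
    response_report: pd.DataFrame
    enrichment: pd.DataFrame


@dataclass
class Model2Result:
    regression: pd.DataFrame
    t_matrix: pd.DataFrame
    common_regions: list[int]
    fit: PLSFit
    cv: CVResult | None
    retained_components: list[int]
    component_report: pd.DataFrame
    response_report: pd.DataFrame
    enrichment: dict[int, pd.DataFrame]


def build_expression_matrix(
    donors: list[DonorSamples],
    parcellation: ParcellationGrid,
    tolerance_mm: float = 2.0,
) -> tuple[RegionExpressionMatrix, pd.DataFrame]:
    """Map samples to parcels and aggregate; returns (matrix, assignments)."""
    assignments = assign_samples(donors, parcellation, tolerance_mm)
    if assignments.empty:
        raise PipelineError("no samples to assign")
    rem = aggregate_expression(donors, assignments, parcellation.region_ids)
    return rem, assignments


def _join_regions(
    rem: RegionExpressionMatrix,
    y_table: pd.DataFrame,
    parcellation: ParcellationGrid,
    y_region_col: str = "region",
) -> tuple[list[int], list[int], list[int]]:
    """Reconcile X regions (ids) with Y regions (left-hemisphere column
    names) via the parcellation name map; returns (common ids, dropped
    from X, dropped from Y as ids)."""
    name_to_id = {v: k for k, v in parcellation.names.items()}
    y_ids = []
    for col in y_table[y_region_col]:
        name = col[3:] if col.startswith(("lh_", "rh_")) else col
        if name in name_to_id:
            y_ids.append(name_to_id[name])
    x_ids = set(rem.region_ids)
    common = sorted(x_ids & set(y_ids))
    dropped_x = sorted(x_ids - set(y_ids))
    dropped_y = sorted(set(y_ids) - x_ids)
    return common, dropped_x, dropped_y


def run_model1_core(
    donors: list[DonorSamples],
    parcellation: ParcellationGrid,
    ct: pd.DataFrame,
    collection: GeneSetCollection,
    config: PipelineConfig,
) -> Model1Result:
    """Expression -> group-contrast PLS -> enrichment, in memory."""
    rem, _ = build_expression_matrix(donors, parcellation, config.tolerance_mm)

    region_names_ord = [parcellation.names[rid] for rid in parcellation.region_ids]
    bilateral_cols = [ct_column(n, h) for h in ("lh", "rh") for n in region_names_ord]
    contrast_bilateral, _ = regional_group_contrast(ct, bilateral_cols)
    left_cols = [ct_column(n, "lh") for n in region_names_ord]
    contrast_left, _ = regional_group_contrast(ct, left_cols)

    common, dropped_x, dropped_y = _join_regions(rem, contrast_left, parcellation)
    if len(common) < MIN_COMMON_REGIONS:
        raise PipelineError(
            f"only {len(common)} regions shared between expression and CT "
            f"(need >= {MIN_COMMON_REGIONS})"
        )
    X = rem.expression.loc[common]
    t_by_id = {
        rid: contrast_left.set_index("region")["t"][ct_column(parcellation.names[rid], "lh")]
        for rid in common
    }
    y = np.array([t_by_id[rid] for rid in common])

    fit = fit_pls(
        X.to_numpy(),
        y,
        config.n_components_model1,
        scale=config.scale,
        x_names=list(X.columns),
        y_names=["t_delta_ct"],
    )
    cv = None
    if config.run_cv:
        kmax = min(config.max_cv_components, len(common) - 2, X.shape[1])
        cv = loo_cv(X.to_numpy(), y, kmax, scale=config.scale)
    comp_report, resp_report = score_response_report(fit, y)
    weights = pd.Series(gene_weights(fit, 1), index=X.columns)
    enrichment = gsea_preranked(
        weights,
        collection,
        n_perm=config.gsea_n_perm,
        seed=config.seed,
        min_size=config.gsea_min_size,
        max_size=config.gsea_max_size,
        exponent=config.gsea_exponent,
    )
    return Model1Result(
        expression=rem,
        contrast_bilateral=contrast_bilateral,
        contrast_left=contrast_left,
        common_regions=common,
        dropped_x=dropped_x,
        dropped_y=dropped_y,
        fit=fit,
        cv=cv,
        component_report=comp_report,
        response_report=resp_report,
        enrichment=enrichment,
    )


def run_model2_core(
    donors: list[DonorSamples],
    parcellation: ParcellationGrid,
    ct: pd.DataFrame,
    clinical: pd.DataFrame,
    collection: GeneSetCollection,
    config: PipelineConfig,
) -> Model2Result:
    """Expression -> clinical-regression-t PLS -> per-component enrichment."""
    rem, _ = build_expression_matrix(donors, parcellation, config.tolerance_mm)
    region_names_ord = [parcellation.names[rid] for rid in parcellation.region_ids]
    left_cols = [ct_column(n, "lh") for n in region_names_ord]
    features = [f for f in config.clinical_features if f in clinical.columns]
    if not features:
        raise PipelineError("no configured clinical feature present in the table")
    regression = ct_clinical_regression(ct, clinical, left_cols, features)
    usable = regression[regression["flag"].isna()]
    kept_features = [
        f for f in features if set(left_cols) <= set(usable.loc[usable["feature"] == f, "region"])
    ]
    if not kept_features:
        raise PipelineError("no clinical feature has complete regional coverage")
    tmat = t_matrix(usable[usable["feature"].isin(kept_features)])
    tmat = tmat.loc[left_cols, kept_features]

    tmat_ids = tmat.rename(
        index={ct_column(n, "lh"): rid for rid, n in parcellation.names.items()}
    )
    common = sorted(set(rem.region_ids) & set(tmat_ids.index))
    if len(common) < MIN_COMMON_REGIONS:
        raise PipelineError(
            f"only {len(common)} regions shared between expression and the "
            f"regression matrix (need >= {MIN_COMMON_REGIONS})"
        )
    X = rem.expression.loc[common]
    Y = tmat_ids.loc[common]

    fit = fit_pls(
        X.to_numpy(),
        Y.to_numpy(),
        config.n_components_model2,
        scale=config.scale,
        x_names=list(X.columns),
        y_names=list(Y.columns),
    )
    cv = None
    if config.run_cv:
        kmax = min(config.max_cv_components, len(common) - 2, X.shape[1])
        cv = loo_cv(X.to_numpy(), Y.to_numpy(), kmax, scale=config.scale)
    comp_report, resp_report = score_response_report(fit, Y.to_numpy())
    retained = list(
        range(1, min(config.retain_components_model2, fit.n_components) + 1)
    )
    enrichment = {}
    for k in retained:
        weights = pd.Series(gene_weights(fit, k), index=X.columns)
        enrichment[k] = gsea_preranked(
            weights,
            collection,
            n_perm=config.gsea_n_perm,
            seed=config.seed + k,
            min_size=config.gsea_min_size,
            max_size=config.gsea_max_size,
            exponent=config.gsea_exponent,
        )
    return Model2Result(
        regression=regression,
        t_matrix=tmat,
        common_regions=common,
        fit=fit,
        cv=cv,
        retained_components=retained,
        component_report=comp_report,
        response_report=resp_report,
        enrichment=enrichment,
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _fit_tables(fit: PLSFit, region_ids: list[int]) -> dict[str, pd.DataFrame]:
    K = fit.n_components
    comp_cols = [f"component{k}" for k in range(1, K + 1)]
    ev = explained_variance(fit)
    return {
        "scores": pd.DataFrame(fit.T, index=region_ids, columns=comp_cols).rename_axis("region"),
        "gene_weights": pd.DataFrame(fit.R, index=fit.x_names, columns=comp_cols).rename_axis("gene"),
        "y_loadings": pd.DataFrame(fit.Q, index=fit.y_names, columns=comp_cols).rename_axis("response"),
        "explained_variance": pd.DataFrame(
            {
                "component": range(1, K + 1),
                "x_pct": ev["x_pct"],
                "y_pct": ev["y_pct"],
                "inner_coef": fit.inner_coefs,
            }
        ),
    }


def _manifest(config: PipelineConfig, extra: dict) -> dict:
    return {"ctxpls_version": __version__, "config": asdict(config), **extra}


def run_model1(config: PipelineConfig) -> Path:
    """File-based model-1 run; returns the output directory."""
    parcellation = ParcellationGrid.load(config.parcellation)
    donors = read_donor_dir(config.donors)
    ct = pd.read_csv(config.ct, sep="\t")
    collection = read_gmt(config.gmt)
    result = run_model1_core(donors, parcellation, ct, collection, config)

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.expression.expression, out / "expression_matrix.tsv", index=True)
    _write_tsv(result.expression.counts.rename_axis("donor"), out / "sample_counts.tsv", index=True)
    _write_tsv(result.contrast_bilateral, out / "contrast_bilateral.tsv")
    _write_tsv(result.contrast_left, out / "contrast_left.tsv")
    for name, table in _fit_tables(result.fit, result.common_regions).items():
        _write_tsv(table, out / f"model1_{name}.tsv", index=name != "explained_variance")
    if result.cv is not None:
        _write_tsv(
            pd.DataFrame(
                {
                    "components": range(len(result.cv.press)),
                    "press": result.cv.press,
                    "rmsep": result.cv.rmsep,
                }
            ),
            out / "model1_cv.tsv",
        )
    _write_tsv(result.component_report, out / "model1_component_report.tsv")
    _write_tsv(result.response_report, out / "model1_response_report.tsv")
    _write_tsv(result.enrichment, out / "model1_enrichment.tsv")
    manifest = _manifest(
        config,
        {
            "model": 1,
            "n_common_regions": len(result.common_regions),
            "dropped_expression_regions": result.dropped_x,
            "dropped_response_regions": result.dropped_y,
            "regions_dropped_empty": result.expression.dropped_regions,
            "cv_optimal_components": None if result.cv is None else result.cv.optimal_components,
        },
    )
    (out / "model1_manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def run_model2(config: PipelineConfig) -> Path:
    """File-based model-2 run; returns the output directory."""
    parcellation = ParcellationGrid.load(config.parcellation)
    donors = read_donor_dir(config.donors)
    ct = pd.read_csv(config.ct, sep="\t")
    clinical = pd.read_csv(config.clinical, sep="\t")
    collection = read_gmt(config.gmt)
    result = run_model2_core(donors, parcellation, ct, clinical, collection, config)

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.regression, out / "clinical_regression.tsv")
    _write_tsv(result.t_matrix, out / "clinical_t_matrix.tsv", index=True)
    for name, table in _fit_tables(result.fit, result.common_regions).items():
        _write_tsv(table, out / f"model2_{name}.tsv", index=name != "explained_variance")
    if result.cv is not None:
        _write_tsv(
            pd.DataFrame(
                {
                    "components": range(len(result.cv.press)),
                    "press": result.cv.press,
                    "rmsep": result.cv.rmsep,
                }
            ),
            out / "model2_cv.tsv",
        )
    _write_tsv(result.component_report, out / "model2_component_report.tsv")
    _write_tsv(result.response_report, out / "model2_response_report.tsv")
    for k, enr in result.enrichment.items():
        _write_tsv(enr, out / f"model2_enrichment_component{k}.tsv")
    manifest = _manifest(
        config,
        {
            "model": 2,
            "n_common_regions": len(result.common_regions),
            "retained_components": result.retained_components,
            "cv_optimal_components": None if result.cv is None else result.cv.optimal_components,
        },
    )
    (out / "model2_manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
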