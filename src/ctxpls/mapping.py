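"""Assign point expression samples to parcellation regions and build
the region x gene predictor matrix.

Assignment follows the containment-then-nearest rule: a sample whose
containing voxel is labeled takes that voxel's region; otherwise it
takes the region of the nearest labeled voxel center within a
millimeter tolerance (default 2 mm), else it stays unassigned. Distances
are Euclidean, in mm, from the sample point to voxel centers; ties at
equal distance resolve to the lower region id for determinism.

Aggregation is two-level: samples are averaged within each
(donor, region) cell, then cells are averaged across the donors that
contributed at least one sample to the region. Empty cells are excluded
from the donor mean rather than imputed (zero is not a valid expression
value), and regions empty across all donors are dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic import DonorSamples, ParcellationGrid

UNASSIGNED = 0  # region id used for unassigned samples

# slack for "equal distance" when breaking ties between regions
_TIE_EPS = 1e-9


class PipelineError(RuntimeError):
    """Unrecoverable data problem in a pipeline stage."""


def assign_coordinates(
    coords_mm: np.ndarray,
    parcellation: ParcellationGrid,
    tolerance_mm: float = 2.0,
) -> pd.DataFrame:
    """Assign mm-space points to parcel regions.

    Returns a frame with one row per point: ``region`` (0 when
    unassigned) and ``distance_mm`` to the nearest labeled voxel center.
    """
    coords_mm = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    if coords_mm.ndim != 2 or coords_mm.shape[1] != 3:
        raise ValueError("coordinates must be (n, 3)")
    if not np.all(np.isfinite(coords_mm)):
        raise ValueError("non-finite sample coordinates")
    if tolerance_mm < 0:
        raise ValueError("tolerance_mm must be >= 0")

    labels = parcellation.labels
    vox_idx, vox_labels = parcellation.labeled_voxels()
    if len(vox_idx) == 0:
        raise PipelineError("parcellation has no labeled voxels")
    centers = parcellation.voxel_to_mm(vox_idx)
    tree = cKDTree(centers)

    n = len(coords_mm)
    region = np.zeros(n, dtype=int)
    dist, _ = tree.query(coords_mm)

    vox_f = parcellation.mm_to_voxel(coords_mm)
    vox_i = np.rint(vox_f).astype(int)
    in_bounds = np.all((vox_i >= 0) & (vox_i < np.asarray(labels.shape)), axis=1)
    for s in range(n):
        if in_bounds[s]:
            lab = int(labels[tuple(vox_i[s])])
            if lab > 0:
                region[s] = lab
                continue
        if dist[s] <= tolerance_mm:
            near = tree.query_ball_point(coords_mm[s], dist[s] + _TIE_EPS)
            d_near = np.linalg.norm(centers[near] - coords_mm[s], axis=1)
            at_min = d_near <= d_near.min() + _TIE_EPS
            region[s] = int(vox_labels[np.asarray(near)[at_min]].min())
    return pd.DataFrame({"region": region, "distance_mm": dist})


def assign_samples(
    donors: list[DonorSamples],
    parcellation: ParcellationGrid,
    tolerance_mm: float = 2.0,
) -> pd.DataFrame:
    """Assign every donor sample; rows carry donor and sample ids."""
    frames = []
    for donor in donors:
        coords = donor.annotation[["mni_x", "mni_y", "mni_z"]].to_numpy()
        if len(coords) == 0:
            continue
        assigned = assign_coordinates(coords, parcellation, tolerance_mm)
        assigned.insert(0, "sample_id", donor.annotation["sample_id"].to_numpy())
        assigned.insert(0, "donor", donor.donor)
        frames.append(assigned)
    if not frames:
        return pd.DataFrame(columns=["donor", "sample_id", "region", "distance_mm"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class RegionExpressionMatrix:
    """Two-level averaged predictor matrix plus its QC bookkeeping."""

    expression: pd.DataFrame  # regions (index) x genes (columns)
    counts: pd.DataFrame  # donors (index) x regions (columns), contributing samples
    dropped_regions: list[int]

    @property
    def region_ids(self) -> list[int]:
        return list(self.expression.index)


def aggregate_expression(
    donors: list[DonorSamples],
    assignments: pd.DataFrame,
    region_ids: list[int] | None = None,
) -> RegionExpressionMatrix:
    """Average sample expression into a region x gene matrix.

    Genes are put in canonical (sorted) order so the result is invariant
    to the input panel ordering; all donors must share the same panel.
    """
    if region_ids is None:
        region_ids = sorted(set(assignments["region"]) - {UNASSIGNED})
    if not region_ids:
        raise PipelineError("no regions requested")
    gene_index = None
    donor_means: dict[str, dict[int, np.ndarray]] = {}
    counts = pd.DataFrame(
        0, index=[d.donor for d in donors], columns=region_ids, dtype=int
    )
    for donor in donors:
        expr = donor.expression.sort_index()
        if gene_index is None:
            gene_index = expr.index
        elif not gene_index.equals(expr.index):
            raise PipelineError(f"gene panel of {donor.donor} differs from the first donor")
        rows = assignments[assignments["donor"] == donor.donor]
        by_region: dict[int, np.ndarray] = {}
        for rid in region_ids:
            ids = rows.loc[rows["region"] == rid, "sample_id"]
            if len(ids) == 0:
                continue
            by_region[rid] = expr[list(ids)].to_numpy().mean(axis=1)
            counts.loc[donor.donor, rid] = len(ids)
        donor_means[donor.donor] = by_region
    values = []
    kept, dropped = [], []
    for rid in region_ids:
        cell_means = [m[rid] for m in donor_means.values() if rid in m]
        if not cell_means:
            dropped.append(rid)
            continue
        kept.append(rid)
        values.append(np.mean(cell_means, axis=0))
    if not kept:
        raise PipelineError("every requested region is empty of samples")
    expression = pd.DataFrame(values, index=kept, columns=gene_index)
    expression.index.name = "region"
    return RegionExpressionMatrix(
        expression=expression, counts=counts[kept], dropped_regions=dropped
    )
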