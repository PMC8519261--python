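"""Synthetic imaging-transcriptomics datasets with planted structure.

The generator emulates the three data modalities the pipeline consumes:

* multi-donor point expression samples scattered inside a labeled
  parcellation volume, carrying a low-rank spatial gradient
  (``expression[s, j] = mu_j + a_j * g_i + noise`` for a sample ``s``
  in region ``i``),
* a two-group cortical-thickness (CT) cohort with per-region planted
  group effects, and
* clinical scores generated from patient CT through known coefficients
  plus an age term.

Every output is a pure function of the scenario (including its seed), so
downstream stages can be tested for parameter recovery against the
stored ground truth without any external download.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import region_names

# Independent random streams, so regenerating one modality never
# perturbs another.
_STREAM_DEFAULTS = 0
_STREAM_SAMPLES = 2
_STREAM_CT = 3
_STREAM_CLINICAL = 4

#: The nine numeric clinical features of the motor/non-motor assessment
#: battery (disease onset age, composite non-dopaminergic score, the four
#: MDS-UPDRS parts and their total, levodopa-equivalent dose, and MMSE).
CLINICAL_FEATURES = [
    "AGEONSET",
    "SENSPDSC",
    "MDS_UPDRS_1",
    "MDS_UPDRS_2",
    "MDS_UPDRS_3",
    "MDS_UPDRS_4",
    "UPDRSTOTSCR",
    "LED",
    "MMSE",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(stream), int(seed)])


class SizingError(ValueError):
    """Requested region count does not fit in the voxel grid."""


@dataclass
class ParcellationGrid:
    """Integer-labeled voxel volume with a voxel-index -> mm affine.

    ``labels`` uses 0 for background and k > 0 for region ids; the
    affine maps 0-based voxel indices to mm coordinates.
    """

    labels: np.ndarray
    affine: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        present = set(np.unique(self.labels)) - {0}
        missing = set(self.names) - present
        if missing:
            raise ValueError(f"regions without voxels: {sorted(missing)}")
        extra = present - set(self.names)
        if extra:
            raise ValueError(f"unnamed labels in volume: {sorted(extra)}")

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.names)

    def labeled_voxels(self) -> tuple[np.ndarray, np.ndarray]:
        """(voxel indices of labeled voxels, their region labels)."""
        idx = np.argwhere(self.labels > 0)
        return idx, self.labels[tuple(idx.T)]

    def voxel_to_mm(self, voxels: np.ndarray) -> np.ndarray:
        voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
        return voxels @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, mm: np.ndarray) -> np.ndarray:
        mm = np.atleast_2d(np.asarray(mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return mm @ inv[:3, :3].T + inv[:3, 3]

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.affine)
        nib.save(img, str(path))
        names_path = Path(path).with_suffix("").with_suffix("")
        with open(f"{names_path}_names.json", "w") as fh:
            json.dump({str(k): v for k, v in self.names.items()}, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path, names: dict[int, str] | None = None) -> "ParcellationGrid":
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(int)
        if names is None:
            names_path = Path(path).with_suffix("").with_suffix("")
            names_file = Path(f"{names_path}_names.json")
            if names_file.exists():
                with open(names_file) as fh:
                    names = {int(k): v for k, v in json.load(fh).items()}
            else:
                ids = sorted(set(np.unique(labels)) - {0})
                fallback = region_names(len(ids))
                names = dict(zip(ids, fallback))
        return cls(labels=labels, affine=img.affine, names=names)


@dataclass
class SyntheticScenario:
    """Ground truth of one synthetic study.

    Array-valued fields left at ``None`` are filled deterministically
    from the seed; ``region_gradient`` defaults to a zero-mean linear
    ramp over region index (the planted caudal-to-rostral axis).

    Defaults mirror the study design the pipeline targets: 34
    left-hemisphere cortical regions, six expression donors, and a
    patient/control MRI cohort of 149 vs 369 subjects.
    """

    n_regions: int = 34
    n_genes: int = 1000
    n_donors: int = 6
    n_patients: int = 149
    n_controls: int = 369
    region_gradient: np.ndarray | None = None
    gene_loadings: np.ndarray | None = None
    ct_effect: np.ndarray | None = None
    clinical_coefficients: np.ndarray | None = None  # (n_features, n_regions)
    noise_sd_expression: float = 0.5
    noise_sd_ct: float = 0.2
    seed: int = 0

    # secondary knobs, all with documented defaults
    baseline_expression: np.ndarray | None = None  # mu_j, log2 intensity scale
    ct_baseline: np.ndarray | None = None  # mm
    hemisphere_asymmetry: np.ndarray | None = None  # extra left thinning, patients
    age_coefficients: np.ndarray | None = None  # gamma_j
    zero_sample_prob: float = 0.1
    mean_samples_per_cell: float = 4.0
    patient_age_range: tuple[float, float] = (45.0, 85.0)
    control_age_range: tuple[float, float] = (45.0, 85.0)
    patient_male_fraction: float = 0.657
    control_male_fraction: float = 0.481
    ct_truncation_mm: float = 0.5
    clinical_noise_sd: float = 1.0
    clinical_missing_rate: float = 0.25
    clinical_features: list[str] = field(default_factory=lambda: list(CLINICAL_FEATURES))
    region_names: list[str] | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_genes", "n_donors", "n_patients", "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd_expression < 0 or self.noise_sd_ct < 0:
            raise ValueError("noise SDs must be >= 0")
        rng = _rng(self.seed, _STREAM_DEFAULTS)
        if self.region_gradient is None:
            self.region_gradient = (
                np.linspace(-1.0, 1.0, self.n_regions)
                if self.n_regions > 1
                else np.zeros(1)
            )
        self.region_gradient = np.asarray(self.region_gradient, dtype=float)
        if self.region_gradient.shape != (self.n_regions,):
            raise ValueError("region_gradient must have length n_regions")
        if abs(self.region_gradient.mean()) > 1e-8:
            raise ValueError("region_gradient must have zero mean")
        if self.gene_loadings is None:
            self.gene_loadings = rng.normal(0.0, 0.3, self.n_genes)
        self.gene_loadings = np.asarray(self.gene_loadings, dtype=float)
        if self.baseline_expression is None:
            self.baseline_expression = rng.normal(7.0, 1.5, self.n_genes)
        self.baseline_expression = np.asarray(self.baseline_expression, dtype=float)
        if self.ct_effect is None:
            # planted atrophy follows the gradient; |delta| <= ~0.1 mm
            self.ct_effect = 0.08 * self.region_gradient
        self.ct_effect = np.asarray(self.ct_effect, dtype=float)
        if self.ct_baseline is None:
            self.ct_baseline = np.full(self.n_regions, 2.5)
        self.ct_baseline = np.asarray(self.ct_baseline, dtype=float)
        if self.hemisphere_asymmetry is None:
            self.hemisphere_asymmetry = np.zeros(self.n_regions)
        self.hemisphere_asymmetry = np.asarray(self.hemisphere_asymmetry, dtype=float)
        n_feat = len(self.clinical_features)
        if self.clinical_coefficients is None:
            self.clinical_coefficients = np.zeros((n_feat, self.n_regions))
        self.clinical_coefficients = np.asarray(self.clinical_coefficients, dtype=float)
        if self.clinical_coefficients.shape != (n_feat, self.n_regions):
            raise ValueError("clinical_coefficients must be (n_features, n_regions)")
        if self.age_coefficients is None:
            self.age_coefficients = np.zeros(n_feat)
        self.age_coefficients = np.asarray(self.age_coefficients, dtype=float)
        if self.region_names is None:
            self.region_names = region_names(self.n_regions)
        if len(self.region_names) != self.n_regions:
            raise ValueError("region_names length mismatch")
        if self.gene_ids is None:
            self.gene_ids = [f"G{j:05d}" for j in range(1, self.n_genes + 1)]
        if len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length mismatch")

    def to_json(self) -> str:
        payload = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            payload[f.name] = v
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticScenario":
        payload = json.loads(text)
        return cls(**payload)


@dataclass
class DonorSamples:
    """One donor's point samples: annotation plus genes x samples matrix."""

    donor: str
    annotation: pd.DataFrame  # sample_id, mni_x/y/z, region_true
    expression: pd.DataFrame  # genes x sample ids


def _lattice_dims(n: int) -> tuple[int, int, int]:
    nx = max(1, math.ceil(n ** (1.0 / 3.0)))
    ny = max(1, math.ceil(math.sqrt(n / nx)))
    nz = max(1, math.ceil(n / (nx * ny)))
    return nx, ny, nz


def make_parcellation(
    scenario: SyntheticScenario,
    shape: tuple[int, int, int] | None = None,
    voxel_size_mm: float = 2.0,
    block: int = 3,
    gap: int = 1,
) -> ParcellationGrid:
    """Lay out ``n_regions`` cuboid parcels on a background grid.

    Parcels are ``block``-sided voxel cubes separated by at least ``gap``
    background voxels, with region ids increasing along the first grid
    axis so the planted gradient has a spatial direction. The affine is
    diagonal (isotropic ``voxel_size_mm``) and centers the volume on the
    mm origin.
    """
    n = scenario.n_regions
    if shape is None:
        dims = _lattice_dims(n)
        shape = tuple(d * (block + gap) + gap for d in dims)
    else:
        cap = [(s - gap) // (block + gap) for s in shape]
        if min(cap) < 1 or cap[0] * cap[1] * cap[2] < n:
            raise SizingError(
                f"grid {shape} holds at most {max(0, cap[0] * cap[1] * cap[2])} "
                f"parcels of side {block}; {n} requested"
            )
        dims = tuple(cap)
    labels = np.zeros(shape, dtype=np.int16)
    region = 0
    for bx in range(dims[0]):
        for by in range(dims[1]):
            for bz in range(dims[2]):
                if region >= n:
                    break
                region += 1
                ox = gap + bx * (block + gap)
                oy = gap + by * (block + gap)
                oz = gap + bz * (block + gap)
                labels[ox : ox + block, oy : oy + block, oz : oz + block] = region
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    names = dict(zip(range(1, n + 1), scenario.region_names))
    return ParcellationGrid(labels=labels, affine=affine, names=names)


def make_donor_samples(
    scenario: SyntheticScenario, parcellation: ParcellationGrid
) -> list[DonorSamples]:
    """Scatter expression samples inside the parcels for each donor.

    Per donor and region the sample count is 0 with probability
    ``zero_sample_prob`` (exercising the missing-donor averaging path)
    and otherwise ``1 + Poisson(mean_samples_per_cell - 1)``. Sample
    coordinates are uniform within a randomly chosen voxel of the
    region; expression is ``mu_j + a_j * g_i`` plus iid Gaussian noise.
    """
    rng = _rng(scenario.seed, _STREAM_SAMPLES)
    region_voxels = {
        rid: np.argwhere(parcellation.labels == rid) for rid in parcellation.region_ids
    }
    donors: list[DonorSamples] = []
    for d in range(1, scenario.n_donors + 1):
        donor_id = f"donor{d}"
        coords: list[np.ndarray] = []
        regions: list[int] = []
        blocks: list[np.ndarray] = []
        for rid in parcellation.region_ids:
            if rng.random() < scenario.zero_sample_prob:
                count = 0
            else:
                count = 1 + rng.poisson(max(scenario.mean_samples_per_cell - 1.0, 0.0))
            if count == 0:
                continue
            vox = region_voxels[rid]
            picks = vox[rng.integers(0, len(vox), size=count)]
            jitter = rng.uniform(-0.5, 0.5, size=(count, 3))
            coords.append(parcellation.voxel_to_mm(picks + jitter))
            regions.extend([rid] * count)
            g_i = scenario.region_gradient[rid - 1]
            mean = scenario.baseline_expression + scenario.gene_loadings * g_i
            noise = rng.normal(0.0, scenario.noise_sd_expression, (scenario.n_genes, count))
            blocks.append(mean[:, None] + noise)
        if coords:
            xyz = np.vstack(coords)
            expr = np.hstack(blocks)
        else:  # a donor can end up with zero samples on tiny scenarios
            xyz = np.empty((0, 3))
            expr = np.empty((scenario.n_genes, 0))
        sample_ids = [f"{donor_id}_s{k:04d}" for k in range(1, len(regions) + 1)]
        annotation = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "mni_x": xyz[:, 0],
                "mni_y": xyz[:, 1],
                "mni_z": xyz[:, 2],
                "region_true": regions,
            }
        )
        expression = pd.DataFrame(expr, index=scenario.gene_ids, columns=sample_ids)
        donors.append(DonorSamples(donor=donor_id, annotation=annotation, expression=expression))
    return donors


def ct_column(region_name: str, hemisphere: str) -> str:
    return f"{hemisphere}_{region_name}"


def make_ct_cohort(scenario: SyntheticScenario) -> pd.DataFrame:
    """Two-group regional CT table, one lh/rh column pair per region.

    Controls draw ``Normal(base_i, noise_sd_ct)``; patients draw
    ``Normal(base_i - delta_i, noise_sd_ct)`` with extra left-hemisphere
    thinning ``hemisphere_asymmetry``. Draws are truncated from below at
    ``ct_truncation_mm`` (thickness is physically positive).
    """
    rng = _rng(scenario.seed, _STREAM_CT)
    n_p, n_c, n_r = scenario.n_patients, scenario.n_controls, scenario.n_regions
    subjects = [f"P{k:04d}" for k in range(1, n_p + 1)] + [
        f"C{k:04d}" for k in range(1, n_c + 1)
    ]
    group = ["patient"] * n_p + ["control"] * n_c
    age = np.concatenate(
        [
            rng.uniform(*scenario.patient_age_range, n_p),
            rng.uniform(*scenario.control_age_range, n_c),
        ]
    )
    sex = np.concatenate(
        [
            np.where(rng.random(n_p) < scenario.patient_male_fraction, "M", "F"),
            np.where(rng.random(n_c) < scenario.control_male_fraction, "M", "F"),
        ]
    )
    table = pd.DataFrame({"subject": subjects, "group": group, "age": age, "sex": sex})
    is_patient = np.asarray([g == "patient" for g in group])
    for hemi in ("lh", "rh"):
        for i, name in enumerate(scenario.region_names):
            mean = np.full(n_p + n_c, scenario.ct_baseline[i])
            mean[is_patient] -= scenario.ct_effect[i]
            if hemi == "lh":
                mean[is_patient] -= scenario.hemisphere_asymmetry[i]
            vals = rng.normal(mean, scenario.noise_sd_ct)
            table[ct_column(name, hemi)] = np.maximum(vals, scenario.ct_truncation_mm)
    return table


def make_clinical(scenario: SyntheticScenario, ct: pd.DataFrame) -> pd.DataFrame:
    """Clinical scores of the patient group, generated from left CT.

    ``score_j = sum_i beta1(j, i) * CT_lh(s, i) + gamma_j * age + noise``
    with entries blanked at ``clinical_missing_rate`` (written as empty
    TSV fields, never zero).
    """
    patients = ct[ct["group"] == "patient"]
    if patients.empty:
        raise ValueError("ct table contains no patients")
    rng = _rng(scenario.seed, _STREAM_CLINICAL)
    lh_cols = [ct_column(name, "lh") for name in scenario.region_names]
    ct_lh = patients[lh_cols].to_numpy()
    scores = (
        ct_lh @ scenario.clinical_coefficients.T
        + patients["age"].to_numpy()[:, None] * scenario.age_coefficients[None, :]
        + rng.normal(0.0, scenario.clinical_noise_sd, (len(patients), len(scenario.clinical_features)))
    )
    mask = rng.random(scores.shape) < scenario.clinical_missing_rate
    scores = np.where(mask, np.nan, scores)
    out = pd.DataFrame(scores, columns=scenario.clinical_features)
    out.insert(0, "subject", patients["subject"].to_numpy())
    return out


def write_dataset(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Materialize one full scenario on disk in the documented layout.

    Writes the NIfTI label volume, per-donor ``SampleAnnot.csv`` and
    ``Expression.csv`` (genes x samples, AHBA-style), CT and clinical
    TSVs, and a JSON sidecar with the complete ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    parcellation = make_parcellation(scenario)
    donors = make_donor_samples(scenario, parcellation)
    ct = make_ct_cohort(scenario)
    clinical = make_clinical(scenario, ct)

    paths: dict[str, Path] = {}
    parc_path = outdir / "parcellation.nii.gz"
    parcellation.save(parc_path)
    paths["parcellation"] = parc_path
    donors_dir = outdir / "donors"
    for donor in donors:
        ddir = donors_dir / donor.donor
        ddir.mkdir(parents=True, exist_ok=True)
        annot = donor.annotation.copy()
        annot.insert(0, "donor", donor.donor)
        annot.to_csv(ddir / "SampleAnnot.csv", index=False)
        donor.expression.to_csv(ddir / "Expression.csv", index_label="gene")
    paths["donors"] = donors_dir
    ct_path = outdir / "ct.tsv"
    ct.to_csv(ct_path, sep="\t", index=False)
    paths["ct"] = ct_path
    clin_path = outdir / "clinical.tsv"
    clinical.to_csv(clin_path, sep="\t", index=False, na_rep="")
    paths["clinical"] = clin_path
    scen_path = outdir / "scenario.json"
    scen_path.write_text(scenario.to_json())
    paths["scenario"] = scen_path
    return paths


def detection_study(
    seed: int,
    planted: bool = True,
    n_genes: int = 1000,
    n_sets: int = 20,
    set_size: int = 25,
) -> tuple[SyntheticScenario, dict[str, list[str]]]:
    """Scenario plus gene-set collection for an end-to-end detection run.

    The planted variant couples a 25-gene "atrophy" set (loading 0.6 on
    the spatial gradient) to a gradient-proportional CT group effect, so
    the full single-response pipeline should rank that set first with a
    positive direction. The null variant zeroes both the loadings and
    the CT effect, leaving nothing to detect. The remaining sets are
    random draws from the unloaded background genes.
    """
    loadings = np.zeros(n_genes)
    if planted:
        loadings[:set_size] = 0.6
    scenario = SyntheticScenario(
        n_regions=34,
        n_genes=n_genes,
        n_donors=6,
        n_patients=60,
        n_controls=60,
        gene_loadings=loadings,
        ct_effect=None if planted else np.zeros(34),
        noise_sd_expression=0.3,
        noise_sd_ct=0.2,
        seed=seed,
    )
    rng = _rng(seed, 5)
    gene_ids = scenario.gene_ids
    sets = {"planted": gene_ids[:set_size]}
    background = np.arange(set_size, n_genes)
    for k in range(n_sets - 1):
        picks = rng.choice(background, size=set_size, replace=False)
        sets[f"background{k:02d}"] = [gene_ids[i] for i in picks]
    return scenario, sets


def read_donor_dir(path: str | Path) -> list[DonorSamples]:
    """Read the per-donor CSV layout written by :func:`write_dataset`."""
    path = Path(path)
    donors = []
    for ddir in sorted(p for p in path.iterdir() if p.is_dir()):
        annotation = pd.read_csv(ddir / "SampleAnnot.csv")
        expression = pd.read_csv(ddir / "Expression.csv", index_col="gene")
        donor = str(annotation["donor"].iloc[0]) if len(annotation) else ddir.name
        donors.append(
            DonorSamples(
                donor=donor,
                annotation=annotation.drop(columns=["donor"], errors="ignore"),
                expression=expression,
            )
        )
    return donors
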