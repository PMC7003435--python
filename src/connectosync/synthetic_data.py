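"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the four data families the pipeline
consumes: (i) a labeled brain volume plus per-tract path-count volumes whose
ROI-boundary mass encodes planted tract-ROI connections; (ii) multi-region
gene expression with planted cross-region correlated gene blocks (shared
latent factors) and covariate confounding; (iii) subject phenotype tables
with planted diagnosis effects on tract diffusion measures; and (iv)
probe-level blood expression with a planted gene-set effect on a chosen
diffusion measure.  Planted truth is exported separately and is never read
by any pipeline stage.

Randomness: a single master seed fans out to independent child generators
via ``numpy.random.default_rng([seed, stream])`` (PCG64), one stream per
dataset, so regenerating one dataset never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from connectosync.exceptions import ConfigError
from connectosync.reach_probability import LabelVolume, TractPathVolume
from connectosync.ttc import RegionExpressionSet

# child-RNG stream indices (stable part of the on-disk contract)
STREAM_TRACTS = 1
STREAM_EXPRESSION = 2
STREAM_PHENOTYPES = 3
STREAM_BLOOD = 4

#: The 18 white-matter tracts of the tractography protocol.
DEFAULT_TRACTS = (
    "FMajor", "FMinor",
    "L-ATR", "L-CAB", "L-CCG", "L-CST", "L-ILF", "L-SLFP", "L-SLFT", "L-UNC",
    "R-ATR", "R-CAB", "R-CCG", "R-CST", "R-ILF", "R-SLFP", "R-SLFT", "R-UNC",
)

DEFAULT_MEASURES = ("volume", "length", "AxD", "RD", "MD", "FA")

TARGET_GENESET_ID = "toll_receptor_signaling"


@dataclass(frozen=True)
class PlantedSync:
    """One planted cross-region synchronized gene block."""

    region_a: str
    region_b: str
    n_genes_a: int
    n_genes_b: int
    rho: float


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with study-condition defaults.

    Defaults mirror the original study where it states a value: 18 tracts,
    82 atlas ROIs at full scale (desk-scale volumes are smaller), 17
    expression regions sharing 30-51 subjects (40 here), ADNI3-like
    phenotype cohort of 499 subjects with CN/MCI/Dementia 347/118/34, and a
    blood cohort of 102 subjects with a 49-gene target set.
    """

    seed: int = 0
    # structural connectome
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_rois: int = 6
    n_tracts: int = 3
    planted_connections: list[tuple[str, int, float]] = field(
        default_factory=list
    )
    leak_rate: float = 0.0
    total_paths: int = 20000
    # region expression
    n_regions: int = 6
    n_genes_per_region: int = 100
    n_subjects: int = 40
    planted_sync: list[PlantedSync] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.2, "braak": 0.2}
    )
    noise_sd: float = 1.0
    # phenotypes
    n_pheno_subjects: int = 499
    diagnosis_proportions: tuple[float, float, float] = (
        347 / 499,
        118 / 499,
        34 / 499,
    )
    pheno_tracts: tuple[str, ...] = DEFAULT_TRACTS
    measures: tuple[str, ...] = DEFAULT_MEASURES
    diagnosis_effects: dict[tuple[str, str], float] = field(
        default_factory=dict
    )
    pheno_covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.3, "sex": 0.1, "TBV": 0.3}
    )
    pheno_noise_sd: float = 1.0
    # blood
    n_blood_subjects: int = 102
    n_blood_genes: int = 120
    n_target_genes: int = 49
    n_probes_per_gene: tuple[int, int] = (1, 3)
    geneset_effect: tuple[str, str, float] | None = None
    blood_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ConfigError("grid_shape entries must be >= 8")
        if self.n_rois < 2:
            raise ConfigError("need at least 2 ROIs")
        for tract, roi, f in self.planted_connections:
            if not 0.0 <= f <= 1.0:
                raise ConfigError(
                    f"planted fraction {f} for ({tract}, {roi}) not in [0, 1]"
                )
        if not 0.0 <= self.leak_rate < 1.0:
            raise ConfigError("leak_rate must be in [0, 1)")
        for sync in self.planted_sync:
            if not 0.0 < sync.rho < 1.0:
                raise ConfigError(
                    f"within-block correlation {sync.rho} outside (0, 1)"
                )
            if max(sync.n_genes_a, sync.n_genes_b) > self.n_genes_per_region:
                raise ConfigError("sync block larger than n_genes_per_region")
        if self.n_subjects < 10:
            raise ConfigError("n_subjects must be >= 10")
        if self.n_target_genes > self.n_blood_genes:
            raise ConfigError("target gene set larger than blood gene pool")
        if self.n_probes_per_gene[0] < 1:
            raise ConfigError("n_probes_per_gene must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @property
    def tract_ids(self) -> list[str]:
        planted = [t for t, _, _ in self.planted_connections]
        out = list(dict.fromkeys(planted))
        i = 1
        while len(out) < self.n_tracts:
            name = f"tract{i:02d}"
            if name not in out:
                out.append(name)
            i += 1
        return out

    @property
    def region_ids(self) -> list[str]:
        return [f"region{i + 1:02d}" for i in range(self.n_regions)]

    @property
    def roi_labels(self) -> list[int]:
        return list(range(2, 2 + self.n_rois))


@dataclass
class PlantedTruth:
    """Ground truth exported next to the data, never consumed by stages."""

    connections: pd.DataFrame  # tract, roi, fraction
    sync_blocks: list[dict]
    diagnosis_beta: dict[str, float]  # "tract:measure" -> beta
    geneset: dict | None = None

    def to_json(self, path) -> None:
        payload = {
            "connections": self.connections.to_dict(orient="records"),
            "sync_blocks": self.sync_blocks,
            "diagnosis_beta": self.diagnosis_beta,
            "geneset": self.geneset,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# label and tract volumes


def generate_label_volume(config: SyntheticConfig) -> LabelVolume:
    """Deterministic label layout: a white-matter slab below an ROI layer.

    White matter fills z < nz//2; ROIs are 2x2x2 blocks tiled in the x-y
    plane sitting directly on the slab, so every ROI has a 2x2 sheet of
    voxels face-adjacent to white matter (its boundary mask).  Raises a
    sizing error naming the first ROI that does not fit.
    """
    nx, ny, nz = config.grid_shape
    vol = np.zeros(config.grid_shape, dtype=np.int32)
    z_wm = nz // 2
    vol[:, :, :z_wm] = 1
    cells = [
        (cx, cy)
        for cx in range(0, nx - 1, 2)
        for cy in range(0, ny - 1, 2)
    ]
    labels = config.roi_labels
    if len(labels) > len(cells):
        raise ConfigError(
            f"grid {config.grid_shape} too small to place ROI label "
            f"{labels[len(cells)]}"
        )
    for label, (cx, cy) in zip(labels, cells):
        vol[cx : cx + 2, cy : cy + 2, z_wm : z_wm + 2] = label
    return LabelVolume(values=vol)


def _spread_mass(
    counts: np.ndarray, voxels: tuple[np.ndarray, ...], mass: int
) -> None:
    """Deposit ``mass`` integer counts as evenly as possible over voxels."""
    k = len(voxels[0])
    if k == 0 or mass <= 0:
        return
    base, rem = divmod(int(mass), k)
    add = np.full(k, base, dtype=np.int64)
    add[:rem] += 1
    counts[voxels] += add


def generate_tract_volumes(
    config: SyntheticConfig, labels: LabelVolume
) -> list[TractPathVolume]:
    """Per-tract path-count volumes realizing the planted connections.

    For each planted (tract, roi, f), a fraction f of the tract's total path
    mass lands in the ROI's boundary mask; ``leak_rate`` of the mass is
    scattered over unplanted boundary voxels (multinomial); the remainder
    sits on white matter.  With leak 0, unplanted boundary masses are
    exactly zero.
    """
    from connectosync.reach_probability import boundary_mask

    rng = config.rng(STREAM_TRACTS)
    planted_by_tract: dict[str, list[tuple[int, float]]] = {
        t: [] for t in config.tract_ids
    }
    for tract, roi, f in config.planted_connections:
        if tract not in planted_by_tract:
            raise ConfigError(f"planted connection names unknown tract {tract!r}")
        if roi not in labels.roi_labels:
            raise ConfigError(f"planted connection names unknown ROI {roi!r}")
        planted_by_tract[tract].append((roi, f))

    masks = {roi: boundary_mask(labels, roi) for roi in labels.roi_labels}
    wm_voxels = np.nonzero(labels.values == labels.wm_label)

    volumes = []
    for tract in config.tract_ids:
        planted = planted_by_tract[tract]
        f_sum = sum(f for _, f in planted)
        if f_sum > 1.0 + 1e-12:
            raise ConfigError(
                f"tract {tract!r}: planted fractions sum to {f_sum:.3f} > 1"
            )
        if f_sum + config.leak_rate > 1.0 + 1e-12:
            raise ConfigError(
                f"tract {tract!r}: planted fractions plus leak exceed 1"
            )
        counts = np.zeros(config.grid_shape, dtype=np.int64)
        total = config.total_paths
        used = 0
        for roi, f in planted:
            mass = round(f * total)
            _spread_mass(counts, np.nonzero(masks[roi]), mass)
            used += mass
        leak_mass = round(config.leak_rate * total)
        if leak_mass > 0:
            planted_rois = {roi for roi, _ in planted}
            leak_targets = np.nonzero(
                np.logical_or.reduce(
                    [
                        masks[roi]
                        for roi in labels.roi_labels
                        if roi not in planted_rois
                    ]
                )
            )
            k = len(leak_targets[0])
            if k:
                counts[leak_targets] += rng.multinomial(
                    leak_mass, np.full(k, 1.0 / k)
                )
                used += leak_mass
        wm_mass = total - used
        k = len(wm_voxels[0])
        counts[wm_voxels] += rng.multinomial(wm_mass, np.full(k, 1.0 / k))
        volumes.append(TractPathVolume(tract_id=tract, counts=counts))
    return volumes


def default_region_map(config: SyntheticConfig) -> pd.DataFrame:
    """Map expression region i to atlas ROI label 2+i (one-to-one)."""
    if config.n_regions > config.n_rois:
        raise ConfigError("more expression regions than atlas ROIs")
    return pd.DataFrame(
        {
            "region_id": config.region_ids,
            "roi_id": config.roi_labels[: config.n_regions],
        }
    )


# ---------------------------------------------------------------------------
# region expression


def _expression_covariates(
    rng: np.random.Generator, subjects: list[str]
) -> pd.DataFrame:
    n = len(subjects)
    return pd.DataFrame(
        {
            "age": rng.normal(75.0, 9.0, n).round(1),
            "sex": rng.choice(["M", "F"], n),
            "PMI": np.clip(rng.normal(8.0, 3.0, n), 0.5, None).round(1),
            "pH": rng.normal(6.5, 0.25, n).round(2),
            "ethnicity": rng.choice(["EUR", "AFR", "HIS"], n, p=[0.6, 0.3, 0.1]),
            "braak": rng.integers(0, 7, n),
        },
        index=subjects,
    )


def _covariate_signal(
    cov: pd.DataFrame, effects: dict[str, float]
) -> np.ndarray:
    """Linear combination of standardized covariates (categoricals coded by
    level index) used as the planted confounder."""
    signal = np.zeros(len(cov))
    for name, eff in effects.items():
        if name not in cov.columns or eff == 0:
            continue
        col = cov[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            codes = pd.Categorical(col).codes.astype(float)
        else:
            codes = col.to_numpy(dtype=float)
        sd = codes.std()
        z = (codes - codes.mean()) / (sd if sd > 0 else 1.0)
        signal += eff * z
    return signal


def generate_region_expression(
    config: SyntheticConfig,
) -> tuple[RegionExpressionSet, PlantedTruth]:
    """Per-region gene x subject expression with planted synchronized blocks.

    Every gene is unit-variance Gaussian noise plus a shared covariate
    confounder; genes inside a planted block additionally load sqrt(rho) on
    a block-specific latent factor, so the cross-region correlation of
    block gene pairs equals rho before the covariate term (and again after
    covariate residualization).  Non-planted cross-region gene pairs are
    independent given covariates.
    """
    rng = config.rng(STREAM_EXPRESSION)
    subjects = [f"S{i:03d}" for i in range(config.n_subjects)]
    cov = _expression_covariates(rng, subjects)
    confound = _covariate_signal(cov, config.covariate_effects)
    genes = [f"G{i:04d}" for i in range(config.n_genes_per_region)]

    data = {
        region: rng.standard_normal((config.n_genes_per_region, config.n_subjects))
        for region in config.region_ids
    }
    offsets = {region: 0 for region in config.region_ids}
    sync_records = []
    for sync in config.planted_sync:
        for region in (sync.region_a, sync.region_b):
            if region not in data:
                raise ConfigError(f"planted sync names unknown region {region!r}")
        factor = rng.standard_normal(config.n_subjects)
        block = {}
        for region, size in (
            (sync.region_a, sync.n_genes_a),
            (sync.region_b, sync.n_genes_b),
        ):
            start = offsets[region]
            if start + size > config.n_genes_per_region:
                raise ConfigError(
                    f"planted sync blocks exhaust genes of region {region!r}"
                )
            rows = slice(start, start + size)
            noise = rng.standard_normal((size, config.n_subjects))
            data[region][rows] = (
                np.sqrt(sync.rho) * factor + np.sqrt(1 - sync.rho) * noise
            )
            block[region] = genes[rows]
            offsets[region] = start + size
        sync_records.append(
            {
                "region_a": sync.region_a,
                "region_b": sync.region_b,
                "rho": sync.rho,
                "genes_a": block[sync.region_a],
                "genes_b": block[sync.region_b],
            }
        )

    expression = {}
    for region, mat in data.items():
        mat = config.noise_sd * mat + confound[None, :]
        expression[region] = pd.DataFrame(mat, index=genes, columns=subjects)

    truth = PlantedTruth(
        connections=pd.DataFrame(
            config.planted_connections, columns=["tract", "roi", "fraction"]
        ),
        sync_blocks=sync_records,
        diagnosis_beta={
            f"{t}:{m}": b for (t, m), b in config.diagnosis_effects.items()
        },
    )
    return (
        RegionExpressionSet(expression=expression, covariates=cov),
        truth,
    )


# ---------------------------------------------------------------------------
# subject phenotypes


def generate_subject_phenotypes(config: SyntheticConfig) -> pd.DataFrame:
    """ADNI-like phenotype table with planted diagnosis effects.

    Diagnosis severity is coded CN=0, MCI=1, Dementia=2 and acts as a
    numeric covariate: each (tract, measure) value is
    beta * severity + covariate effects + Gaussian noise, with beta taken
    from ``config.diagnosis_effects`` (0 where unspecified).
    """
    rng = config.rng(STREAM_PHENOTYPES)
    n = config.n_pheno_subjects
    age = rng.normal(73.8, 8.4, n).round(1)
    sex = rng.choice(["M", "F"], n, p=[0.46, 0.54])
    tbv = rng.normal(1500.0, 150.0, n).round(1)
    dx = rng.choice(
        ["CN", "MCI", "Dementia"], n, p=np.asarray(config.diagnosis_proportions)
    )
    table = pd.DataFrame(
        {
            "subject_id": [f"P{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "TBV": tbv,
            "diagnosis": dx,
        }
    )
    severity = pd.Series(dx).map({"CN": 0, "MCI": 1, "Dementia": 2}).to_numpy()
    confound = _covariate_signal(
        table[["age", "sex", "TBV"]], config.pheno_covariate_effects
    )
    columns = {}
    for tract in config.pheno_tracts:
        for measure in config.measures:
            beta = config.diagnosis_effects.get((tract, measure), 0.0)
            columns[f"{tract}:{measure}"] = (
                beta * severity
                + confound
                + rng.normal(0.0, config.pheno_noise_sd, n)
            )
    return pd.concat([table, pd.DataFrame(columns)], axis=1)


# ---------------------------------------------------------------------------
# blood expression


@dataclass
class BloodDataset:
    probes: pd.DataFrame  # probe x subject
    probe_map: pd.DataFrame  # probe_id, gene
    covariates: pd.DataFrame  # subject-indexed: sex, age, RIN, plate
    phenotypes: pd.DataFrame  # subject_id + "tract:measure" columns
    gene_sets: dict[str, list[str]]
    target_set: str = TARGET_GENESET_ID


def generate_blood_dataset(config: SyntheticConfig) -> tuple[BloodDataset, PlantedTruth]:
    """Probe-level blood expression with a planted gene-set effect.

    Each gene has a latent subject profile; its probes are noisy copies with
    probe-specific offsets (so mean-max collapse is exercised).  When
    ``config.geneset_effect = (set_id, "tract:measure", b)`` is given, the
    designated measure receives b times the standardized mean latent of the
    target-set genes on top of covariate effects and noise.
    """
    rng = config.rng(STREAM_BLOOD)
    n = config.n_blood_subjects
    subjects = [f"B{i:03d}" for i in range(n)]
    cov = pd.DataFrame(
        {
            "sex": rng.choice(["M", "F"], n),
            "age": rng.normal(73.0, 7.0, n).round(1),
            "RIN": rng.normal(7.0, 0.5, n).round(2),
            "plate": rng.choice(["plate1", "plate2", "plate3", "plate4"], n),
        },
        index=subjects,
    )
    target_genes = [f"TLR{i:03d}" for i in range(config.n_target_genes)]
    decoy_genes = [
        f"BG{i:04d}"
        for i in range(config.n_blood_genes - config.n_target_genes)
    ]
    all_genes = target_genes + decoy_genes

    rin_z = (cov.RIN - cov.RIN.mean()).to_numpy() / max(cov.RIN.std(), 1e-9)
    latents = {}
    probe_rows = []
    probe_ids = []
    probe_map_rows = []
    p_counter = 0
    lo, hi = config.n_probes_per_gene
    for gene in all_genes:
        latent = rng.standard_normal(n) + 0.1 * rin_z
        latents[gene] = latent
        for _ in range(int(rng.integers(lo, hi + 1))):
            pid = f"PR{p_counter:05d}"
            p_counter += 1
            offset = rng.normal(6.0, 1.0)
            probe_rows.append(latent + offset + rng.normal(0.0, 0.3, n))
            probe_ids.append(pid)
            probe_map_rows.append({"probe_id": pid, "gene": gene})
    probes = pd.DataFrame(probe_rows, index=probe_ids, columns=subjects)
    probe_map = pd.DataFrame(probe_map_rows)

    gene_sets = {TARGET_GENESET_ID: list(target_genes)}
    decoys = np.array(decoy_genes)
    for i in range(3):
        size = min(20, len(decoys))
        gene_sets[f"decoy_set_{i + 1}"] = sorted(
            rng.choice(decoys, size=size, replace=False).tolist()
        )

    geneset_truth = None
    effect_measure = None
    effect = 0.0
    if config.geneset_effect is not None:
        set_id, effect_measure, effect = config.geneset_effect
        if set_id not in gene_sets:
            raise ConfigError(f"gene set {set_id!r} not in pathway DB")
        set_latent = np.mean([latents[g] for g in gene_sets[set_id]], axis=0)
        set_latent = (set_latent - set_latent.mean()) / max(
            set_latent.std(), 1e-9
        )
        geneset_truth = {
            "set_id": set_id,
            "measure": effect_measure,
            "effect": effect,
            "genes": gene_sets[set_id],
        }

    confound = _covariate_signal(
        cov[["age", "sex"]], {"age": 0.2, "sex": 0.1}
    )
    pheno_cols = {"subject_id": subjects}
    for tract in config.pheno_tracts:
        for measure in config.measures:
            col = f"{tract}:{measure}"
            y = confound + rng.normal(0.0, config.blood_noise_sd, n)
            if effect_measure == col:
                y = y + effect * set_latent
            pheno_cols[col] = y
    pheno = pd.DataFrame(pheno_cols)

    dataset = BloodDataset(
        probes=probes,
        probe_map=probe_map,
        covariates=cov,
        phenotypes=pheno,
        gene_sets=gene_sets,
    )
    truth = PlantedTruth(
        connections=pd.DataFrame(columns=["tract", "roi", "fraction"]),
        sync_blocks=[],
        diagnosis_beta={},
        geneset=geneset_truth,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# persistence


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sorted(gene_sets.items()):
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def write_dataset(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Generate every dataset and write it under ``outdir``.

    Volumes go to NIfTI (.nii.gz), matrices and tables to TSV, gene sets to
    GMT, and the combined planted truth to ``truth.json`` (data files never
    reference it).  Returns the path map.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    labels = generate_label_volume(config)
    affine = np.eye(4)
    nib.save(
        nib.Nifti1Image(labels.values.astype(np.int16), affine),
        outdir / "labels.nii.gz",
    )
    paths["labels"] = str(outdir / "labels.nii.gz")

    tract_dir = outdir / "tracts"
    tract_dir.mkdir(exist_ok=True)
    for tract in generate_tract_volumes(config, labels):
        p = tract_dir / f"{tract.tract_id}.nii.gz"
        nib.save(
            nib.Nifti1Image(tract.counts.astype(np.int32), affine), p
        )
        paths[f"tract:{tract.tract_id}"] = str(p)

    expr_set, truth = generate_region_expression(config)
    expr_dir = outdir / "expression"
    expr_dir.mkdir(exist_ok=True)
    for region, mat in expr_set.expression.items():
        p = expr_dir / f"{region}.tsv"
        mat.to_csv(p, sep="\t", index_label="gene")
        paths[f"expression:{region}"] = str(p)
    expr_set.covariates.to_csv(
        expr_dir / "covariates.tsv", sep="\t", index_label="subject_id"
    )
    paths["expression_covariates"] = str(expr_dir / "covariates.tsv")

    default_region_map(config).to_csv(
        outdir / "region_map.tsv", sep="\t", index=False
    )
    paths["region_map"] = str(outdir / "region_map.tsv")

    pheno = generate_subject_phenotypes(config)
    pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    paths["phenotypes"] = str(outdir / "phenotypes.tsv")

    blood, blood_truth = generate_blood_dataset(config)
    blood_dir = outdir / "blood"
    blood_dir.mkdir(exist_ok=True)
    blood.probes.to_csv(
        blood_dir / "probes.tsv", sep="\t", index_label="probe_id"
    )
    blood.probe_map.to_csv(blood_dir / "probe_map.tsv", sep="\t", index=False)
    blood.covariates.to_csv(
        blood_dir / "covariates.tsv", sep="\t", index_label="subject_id"
    )
    blood.phenotypes.to_csv(
        blood_dir / "phenotypes.tsv", sep="\t", index=False
    )
    write_gmt(blood.gene_sets, blood_dir / "gene_sets.gmt")
    for key in ("probes", "probe_map", "covariates", "phenotypes"):
        paths[f"blood_{key}"] = str(blood_dir / f"{key}.tsv")
    paths["blood_gene_sets"] = str(blood_dir / "gene_sets.gmt")

    truth.geneset = blood_truth.geneset
    truth.to_json(outdir / "truth.json")
    paths["truth"] = str(outdir / "truth.json")
    return paths


def config_from_yaml(path) -> SyntheticConfig:
    """Load a SyntheticConfig from a YAML file (CLI entry point)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "grid_shape" in raw:
        raw["grid_shape"] = tuple(raw["grid_shape"])
    if "planted_connections" in raw:
        raw["planted_connections"] = [
            (str(t), int(r), float(f)) for t, r, f in raw["planted_connections"]
        ]
    if "planted_sync" in raw:
        raw["planted_sync"] = [
            PlantedSync(**entry) for entry in raw["planted_sync"]
        ]
    if "diagnosis_effects" in raw:
        raw["diagnosis_effects"] = {
            (k.split(":")[0], k.split(":")[1]): float(v)
            for k, v in raw["diagnosis_effects"].items()
        }
    if "geneset_effect" in raw and raw["geneset_effect"] is not None:
        s, m, e = raw["geneset_effect"]
        raw["geneset_effect"] = (str(s), str(m), float(e))
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return SyntheticConfig(**raw)
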