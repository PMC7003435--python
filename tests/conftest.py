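import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from connectosync import reach_probability as rp
from connectosync import synthetic_data as syn

PLANTED = [
    ("tract01", 2, 0.30),
    ("tract01", 3, 0.25),
    ("tract02", 4, 0.40),
    ("tract03", 5, 0.35),
    ("tract03", 6, 0.20),
]


@pytest.fixture
def small_config():
    """Desk-scale study: 3 tracts, 6 ROIs, 5 regions, planted structure."""
    return syn.SyntheticConfig(
        seed=7,
        planted_connections=list(PLANTED),
        n_regions=5,
        n_genes_per_region=60,
        n_subjects=40,
        planted_sync=[
            syn.PlantedSync("region01", "region02", 20, 20, 0.9),
            syn.PlantedSync("region01", "region02", 20, 20, 0.9),
        ],
        n_pheno_subjects=150,
        pheno_tracts=("tract01", "tract02", "tract03"),
        diagnosis_effects={("tract01", "FA"): 1.0},
        pheno_noise_sd=0.5,
        n_blood_subjects=60,
        n_blood_genes=30,
        n_target_genes=8,
        geneset_effect=("toll_receptor_signaling", "tract01:FA", 1.0),
    )


@pytest.fixture
def label_volume(small_config):
    return syn.generate_label_volume(small_config)


@pytest.fixture
def tract_volumes(small_config, label_volume):
    return syn.generate_tract_volumes(small_config, label_volume)


@pytest.fixture
def reach_matrix(tract_volumes, label_volume):
    return rp.reach_probability_matrix(tract_volumes, label_volume)


@pytest.fixture
def phenotypes(small_config):
    return syn.generate_subject_phenotypes(small_config)


def random_label_grid(rng, shape=(5, 5, 5), n_rois=2):
    """Random small label grid guaranteed to contain white matter."""
    vol = rng.integers(0, n_rois + 2, size=shape).astype(np.int32)
    vol.flat[0] = 1  # force a white-matter voxel
    return rp.LabelVolume(values=vol)


def brute_force_reach(tract, labels, rois, connectivity=6):
    """Voxel-loop oracle for reach probability (no vectorization)."""
    from itertools import product

    shape = labels.values.shape
    offsets = [
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
    ]
    if connectivity == 26:
        offsets = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]

    def mask_of(roi):
        out = set()
        for idx in product(*(range(s) for s in shape)):
            if labels.values[idx] != roi:
                continue
            for off in offsets:
                nb = tuple(i + o for i, o in zip(idx, off))
                if all(0 <= c < s for c, s in zip(nb, shape)):
                    if labels.values[nb] == labels.wm_label:
                        out.add(idx)
                        break
        return out

    masks = {roi: mask_of(roi) for roi in rois}
    support = set()
    for idx in product(*(range(s) for s in shape)):
        if labels.values[idx] == labels.wm_label:
            support.add(idx)
    for m in masks.values():
        support |= m
    total = sum(float(tract.counts[idx]) for idx in support)
    row = {}
    for roi, mask in masks.items():
        if not mask:
            row[roi] = 0.0
            continue
        row[roi] = sum(float(tract.counts[idx]) / total for idx in mask) / len(
            mask
        )
    return pd.Series(row)


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return np.clip(q, 0, 1)


def set_partitions(items):
    """All set partitions (oracle for exhaustive modularity maximization)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition
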