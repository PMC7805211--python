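import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from methylcontrast.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic cohort shared by read-only tests."""
    cfg = SimConfig(
        n_probes=120,
        n_patients_per_group=8,
        tumors_per_patient=2,
        n_normal=2,
        n_slides=4,
        chrom_layout=(("chr1", 2_000_000), ("chr2", 1_000_000)),
        mean_gap_bp=20_000,
        frac_dmp=0.1,
        group_effect_delta=1.5,
        detection_fail_rate=0.01,
        seed=101,
    )
    bm, samples, manifest, truth = simulate_cohort(cfg)
    return cfg, bm, samples, manifest, truth


@pytest.fixture(scope="session")
def glmm_design():
    """Fixed 60-sample nested design used by model-fitting tests."""
    n_pat, tumors, n_slides = 30, 2, 8
    patient = np.repeat(np.arange(n_pat), tumors)
    slide = patient % n_slides
    group = (patient >= n_pat // 2).astype(float)
    rng = np.random.default_rng(77)
    age = rng.uniform(20, 70, n_pat * tumors)
    sex = rng.integers(0, 2, n_pat * tumors).astype(float)
    return {
        "patient": patient,
        "slide": slide,
        "group": group,
        "age": age,
        "sex": sex,
        "n": n_pat * tumors,
        "n_slides": n_slides,
        "n_patients": n_pat,
    }


def simulate_probe(design, delta, sigma_slide, sigma_patient, phi, rng, baseline=-0.5):
    """Draw one probe's beta vector from the generative model."""
    us = rng.normal(0.0, sigma_slide, design["n_slides"])
    up = rng.normal(0.0, sigma_patient, design["n_patients"])
    eta = baseline + delta * design["group"] + us[design["slide"]] + up[design["patient"]]
    mu = expit(eta)
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    return np.clip(y, 1e-6, 1.0 - 1e-6)


def design_matrix(design, with_group=True):
    cols = [np.ones(design["n"])]
    if with_group:
        cols.append(design["group"])
    cols += [(design["age"] - design["age"].mean()) / 10.0, design["sex"]]
    return np.column_stack(cols)


@pytest.fixture(scope="session")
def manifest_tiny():
    """Hand-built manifest for filter-semantics tests."""
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * 6,
            "pos": [100, 5000, 10_000, 50_000, 120_000, 150_000],
            "relation": ["island", "shore", "shelf", "open_sea", "open_sea", "open_sea"],
            "gene": ["GA", "GA", "GB", "GB", "GC", ""],
            "promoter": [True, False, False, False, True, False],
            "enhancer": [False, True, False, False, False, False],
            "blacklist": [False, False, True, False, False, False],
        },
        index=pd.Index([f"cg{i}" for i in range(6)], name="probe_id"),
    )
    return df
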