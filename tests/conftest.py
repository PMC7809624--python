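import numpy as np
import pytest

import hipshape as hs


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture(scope="session")
def template():
    return hs.make_template()


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noiseless cohort with no genetic effects and no offsets."""
    cfg = hs.SimulationConfig(
        n_subjects=80, seed=11, landmark_noise_sd=0.0,
        nuisance_rotation_deg=0.0, nuisance_scale_range=(1.0, 1.0),
        nuisance_translation=0.0, snps=(), score_offsets={},
    )
    dataset, truth = hs.simulate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Realistic cohort: noise, nuisance transforms, planted SNP effects."""
    cfg = hs.SimulationConfig(n_subjects=400, seed=7)
    dataset, truth = hs.simulate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def trained_model(default_cohort):
    cfg, dataset, _ = default_cohort
    gpa = hs.generalized_procrustes(dataset.landmarks)
    return hs.build_model(gpa, K=10)


def random_landmark_set(rng, subject_id="s", n_points=53, scale=10.0):
    pts = rng.normal(0.0, scale, size=(n_points, 2))
    return hs.LandmarkSet(subject_id, pts)


def perturbed_template_set(rng, subject_id="s", spread=0.05):
    """A realistic random shape: template plus small smooth-ish noise."""
    base = hs.make_template().points
    pts = base + rng.normal(0.0, spread * 100.0 / 53, size=base.shape)
    return hs.LandmarkSet(subject_id, pts)
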