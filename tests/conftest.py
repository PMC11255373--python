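"""Shared fixtures: scenes, cameras, analytic paths, cohorts."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from pierisflight.morphometrics import summarize_morphology
from pierisflight.synthetic import SceneConfig, generate_cohort


@pytest.fixture(scope="session")
def scene() -> SceneConfig:
    return SceneConfig()


@pytest.fixture(scope="session")
def noisy_scene() -> SceneConfig:
    return SceneConfig(pixel_noise_px=0.5)


@pytest.fixture(scope="session")
def cams(scene):
    return scene.cameras()


@pytest.fixture(scope="session")
def cohort():
    """Default study-composition cohort at a fixed seed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(seed=42)


@pytest.fixture(scope="session")
def morpho_table(cohort) -> pd.DataFrame:
    tab = pd.DataFrame([summarize_morphology(lm).to_dict()
                        for lm in cohort.landmarks])
    return tab.merge(cohort.specimens[["specimen_id", "species", "form",
                                       "sex"]], on="specimen_id")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
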