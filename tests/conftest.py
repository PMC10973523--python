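"""Shared fixtures: synthetic patches/slides reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from pdl1score.config import PipelineConfig
from pdl1score.synthetic import SynthConfig, generate_patch, generate_slide


@pytest.fixture(scope="session")
def default_patch():
    """Default-config patch at seed 7 (image, truth)."""
    return generate_patch(SynthConfig(rng_seed=7))


@pytest.fixture(scope="session")
def single_cell_patch():
    """A patch holding exactly one tumor nucleus of radius 8."""
    cfg = SynthConfig(
        rng_seed=1,
        cells_per_patch=1,
        class_mix={"tumor": 1.0},
        nucleus_radius_range={"tumor": (8.0, 8.0), "small_lymphocyte": (3.0, 5.0)},
        positive_fraction={"tumor": 0.0},
    )
    return generate_patch(cfg)


def a1_slide_config(seed: int, positive_fraction: float) -> SynthConfig:
    """Study conditions for the score-recovery cohort: tumor-dominant slides
    where tumor nuclei are strictly larger than small lymphocytes and ~5% of
    cells are oversized non-tumor."""
    return SynthConfig(
        rng_seed=seed,
        class_mix={"tumor": 0.85, "small_lymphocyte": 0.10, "large_nontumor": 0.05},
        positive_fraction={"tumor": positive_fraction, "small_lymphocyte": 0.05, "large_nontumor": 0.2},
    )


@pytest.fixture(scope="session")
def recovery_cohort():
    """20 full-pipeline slides (>=4000 cells each) spanning true TPS 0-100%.

    Returns a list of (truth, PipelineResult) pairs; built once per session
    because it drives several independent checks.
    """
    from pdl1score.pipeline import run_pipeline

    config = PipelineConfig()
    fractions = np.linspace(0.0, 1.0, 20)
    cohort = []
    for i, p in enumerate(fractions):
        tiles, truth = generate_slide(a1_slide_config(1000 + i, float(p)), grid=(7, 7))
        result = run_pipeline(tiles, annotations=[], config=config)
        cohort.append((truth, result))
    return cohort
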