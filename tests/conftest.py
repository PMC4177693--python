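"""Shared fixtures: synthetic fixture bundles are generated once per session
(everything is seeded, so tests see identical data on every run)."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from myomir.pipeline import PipelineConfig, run_pipeline
from myomir.simulate import simulate_dataset, vertebrate_scenario_preset


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140925)


@pytest.fixture(scope="session")
def preset_bundle(tmp_path_factory):
    """The scripted vertebrate-scenario fixture (genomes + GFF3 + truth)."""
    cfg, template = vertebrate_scenario_preset(seed=1)
    out = tmp_path_factory.mktemp("preset_fixture")
    bundle = simulate_dataset(cfg, out)
    return cfg, template, bundle


@pytest.fixture(scope="session")
def preset_run(tmp_path_factory):
    """One full pipeline run on the scripted scenario (the expensive path:
    mapping, context, synteny, bootstrapped trees, events, folds, targets)."""
    out = tmp_path_factory.mktemp("preset_run")
    cfg = PipelineConfig(out_dir=str(out), seed=7, synthetic="vertebrate")
    logging.disable(logging.INFO)
    try:
        manifest = run_pipeline(cfg)
    finally:
        logging.disable(logging.NOTSET)
    return cfg, manifest, out
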