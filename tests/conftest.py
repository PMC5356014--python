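"""Shared fixtures: small synthetic records reused across test modules."""

from dataclasses import replace

import numpy as np
import pytest

import pixelsr as px


@pytest.fixture(scope="session")
def cfg():
    """Reference acquisition condition (5 GSa/s vs 11.6142 MHz)."""
    return px.DEFAULT_CONFIG


@pytest.fixture(scope="session")
def cfg_small(cfg):
    """Same condition, 64-line records for fast tests."""
    return replace(cfg, n_lines=64)


@pytest.fixture(scope="session")
def cfg_cohort(cfg):
    """192-line records: the smallest field that fits every object class."""
    return replace(cfg, n_lines=192)


@pytest.fixture(scope="session")
def background_record(cfg):
    """Background-only record: envelope + free-running clock + mild noise."""
    return px.synth_record(None, cfg, noise_sd=0.01, ratio_perturb=3e-5, seed=11)


@pytest.fixture(scope="session")
def scene_record(cfg):
    """Single textured two-daughter colony in the field, mild noise."""
    geom = px.geometry(cfg)
    h = cfg.n_lines * geom.dy
    obj = px.SceneObject("colony2", (32.0, h / 2), (5.0, 2.5),
                         orientation=0.9, contrast=0.45, texture_amp=0.25)
    scene = px.SceneSpec(width=64.0, height=h, objects=(obj,))
    return px.synth_record(scene, cfg, noise_sd=0.02, ratio_perturb=2e-5, seed=7)


@pytest.fixture(scope="session")
def registered(scene_record):
    return px.register(scene_record)
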