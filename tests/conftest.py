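"""Shared fixtures: small synthetic worlds built once per session.

Worlds are built at a reduced grid resolution (the estimator is stable in
resolution; see docs/methods.md) so the whole suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import nichedyn as nd


def build_world(preset: str, seed: int, grid_resolution: int = 120,
                buffer_deg: float = 0.3):
    """Simulate a preset scenario and build the full E-space state.

    Returns a dict with the scenario spec, climate stacks, occurrences,
    per-range climate tables, the shared EnvSpace, per-range occurrence
    scores, and per-range NicheDensity objects.
    """
    spec = nd.make_scenario(preset, seed)
    stacks = {h.range_label: nd.make_climate(spec, h.region)
              for h in spec.niches}
    occs = nd.sample_scenario(spec)
    env = {k: nd.extract_env(occs[k], stacks[k]) for k in stacks}
    bkgs = [nd.build_background(occs[k], stacks[k], buffer_deg)
            for k in stacks]
    space = nd.pca_env(bkgs, grid_resolution=grid_resolution)
    scores, dens = {}, {}
    for k in stacks:
        s = space.transform(env[k].values)
        scores[k] = s
        dens[k] = nd.occurrence_density(
            s, space.background_scores[k], space, range_label=k)
    return {"spec": spec, "stacks": stacks, "occs": occs, "env": env,
            "space": space, "scores": scores, "densities": dens}


@pytest.fixture(scope="session")
def identical_world():
    return build_world("identical", seed=3)


@pytest.fixture(scope="session")
def shifted_world():
    return build_world("shifted", seed=3)


@pytest.fixture(scope="session")
def disjoint_world():
    return build_world("disjoint", seed=3)


@pytest.fixture(scope="session")
def toy_stack():
    """Tiny 4x5 two-variable raster with one NoData cell."""
    data = np.zeros((2, 4, 5))
    data[0] = np.arange(20).reshape(4, 5)
    data[1] = 100 - np.arange(20).reshape(4, 5)
    data[:, 1, 2] = np.nan
    return nd.ClimateStack(variables=["v1", "v2"], data=data,
                           west=10.0, north=50.0, cell_size=0.5,
                           region="toy")
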