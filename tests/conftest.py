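"""Shared fixtures: cached chamber solves and the design height sweep.

The full chamber pipeline at refinement level 2 takes a few seconds per
configuration, so solves are cached per session and shared across tests.
"""

from __future__ import annotations

import pytest

import zonesim as zs


@pytest.fixture(scope="session")
def chamber():
    """Factory returning cached (config, mesh, flow, conc) chamber solves.

    ``chamber(height, level=2, **overrides)`` runs the full pipeline at the
    given insert height with optional config overrides; repeated calls with
    identical arguments return the same objects.
    """
    cache: dict = {}

    def get(height: float = 0.0, level: int = 2, **overrides):
        key = (height, level, tuple(sorted(overrides.items())))
        if key not in cache:
            cfg = zs.build_geometry(insert_height=height, **overrides)
            mesh = zs.build_mesh(cfg, level)
            flow = zs.solve_flow(cfg, mesh)
            conc = zs.solve_oxygen(cfg, mesh, flow)
            cache[key] = (cfg, mesh, flow, conc)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def design_sweep():
    """The design height sweep at defaults: 1 mm steps, 15 % O2 target."""
    return zs.height_sweep(zs.build_geometry(), target_pct=15.0, step=1e-3, refinement_level=2)
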