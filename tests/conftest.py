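"""Shared fixtures.

The expensive DVMS runs (water, methyl radical, hydrogen fluoride at
equilibrium and stretched) are session-scoped so the property tests and the
acceptance tests draw on the same converged models.
"""

import numpy as np
import pytest

from dvms.fixtures import (
    bond_electron_feature, packaged_fixture,
)
from dvms.sampler import SamplerConfig, run_dvms, sample_tile
from dvms.subtiles import run_dvms_with_subtiles


@pytest.fixture(scope="session")
def water_wf():
    return packaged_fixture("water_rhf_631gd")


@pytest.fixture(scope="session")
def methyl_wf():
    return packaged_fixture("methyl_uhf_631gd")


@pytest.fixture(scope="session")
def water_runs(water_wf):
    """Four independent converged water runs (sites + diagnostics)."""
    out = []
    for seed in (3, 11, 19, 27):
        cfg = SamplerConfig(n_walkers=600, max_sweeps=2500, seed=seed)
        sites, cloud, diag = run_dvms(water_wf, cfg)
        samples, _ = sample_tile(water_wf, sites, cloud, cfg, 30,
                                 np.random.default_rng(seed + 5))
        out.append({"sites": sites, "cloud": cloud, "diag": diag,
                    "samples": samples, "config": cfg})
    return out


@pytest.fixture(scope="session")
def methyl_models(methyl_wf):
    """Independent methyl-radical sub-tile models (mirror pairs)."""
    out = []
    for seed in (3, 13, 23):
        cfg = SamplerConfig(n_walkers=800, max_sweeps=1200, seed=seed)
        model, samples, diag = run_dvms_with_subtiles(methyl_wf, cfg)
        out.append({"model": model, "samples": samples, "diag": diag,
                    "config": cfg})
    return out


def _hf_subtile_run(R, seed=7):
    wf = packaged_fixture(f"hf_2cfg_{R}")
    h_pos = wf.geometry.coords[1]

    def feat(site):
        return [(e, 2) for e in bond_electron_feature(site, h_pos)]

    cfg = SamplerConfig(n_walkers=800, max_sweeps=1600, seed=seed)
    model, samples, diag = run_dvms_with_subtiles(
        wf, cfg, feature=feat, harvest_sweeps=120, selection_points=8000)
    return {"wf": wf, "model": model, "samples": samples, "diag": diag}


@pytest.fixture(scope="session")
def hf_equilibrium_run():
    return _hf_subtile_run("0.91")


@pytest.fixture(scope="session")
def hf_stretched_run():
    return _hf_subtile_run("1.11")
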