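"""Shared fixtures: synthetic panels at the study conditions."""

import warnings

import numpy as np
import pytest

import biasdx as bx


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    # weak partial agonists routinely trip slope-bound / EC50-range warnings;
    # tests assert on results, not on warning chatter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def noiseless_cfg():
    return bx.SimConfig(seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_panels(noiseless_cfg):
    return bx.simulate_panels(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_kds(noiseless_cfg):
    return noiseless_cfg.kds()


@pytest.fixture(scope="session")
def injected_cfg():
    # 10-fold efficacy drop injected for one ligand in pathway B only
    return bx.SimConfig(seed=2, noise_sd=0.0, bias_map={"L06": 0.1})


@pytest.fixture(scope="session")
def injected_panels(injected_cfg):
    return bx.simulate_panels(injected_cfg)


@pytest.fixture(scope="session")
def noisy_panels():
    cfg = bx.SimConfig(seed=7, noise_sd=0.02)
    return bx.simulate_panels(cfg)


def make_logistic3_curve(ligand="LIG", assay="assay", e_max=1.0, n=1.0, ec50=1e-7,
                         conc=None, noise_sd=0.0, seed=0, resp_sd=None):
    """Exact (optionally noise-corrupted) 3-parameter logistic curve."""
    if conc is None:
        conc = np.geomspace(1e-10, 1e-4, 8)
    conc = np.asarray(conc, float)
    resp = e_max / (1.0 + (ec50 / conc) ** n)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, conc.size)
    sd = np.full(conc.size, resp_sd if resp_sd is not None else noise_sd)
    return bx.CRCurve(ligand, assay, conc, resp, sd)


def make_operational_curve(ligand="LIG", assay="assay", r_max=1.0, n=1.0, tau=10.0,
                           kd=1e-6, conc=None):
    """Exact operational-model curve."""
    if conc is None:
        conc = np.geomspace(1e-11, 1e-3, 10)
    conc = np.asarray(conc, float)
    resp = r_max * (tau * conc) ** n / ((conc + kd) ** n + (tau * conc) ** n)
    return bx.CRCurve(ligand, assay, conc, resp, np.zeros(conc.size))
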