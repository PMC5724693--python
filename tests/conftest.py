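import warnings

import pytest

from metaepi import (
    McmcConfig,
    MetaEpiDataset,
    ModelSpec,
    TrialRecord,
    TruthConfig,
    fit,
    generate,
    relabel,
)


def make_tiny_dataset() -> MetaEpiDataset:
    """Three small meta-analyses, one characteristic, built by hand."""
    rows = [
        # meta, trial, rc, nc, rt, nt, X
        ("m1", "t1", 10, 50, 8, 50, 1),
        ("m1", "t2", 12, 60, 9, 55, 1),
        ("m1", "t3", 20, 80, 15, 80, 0),
        ("m1", "t4", 9, 40, 7, 45, 0),
        ("m1", "t5", 14, 70, 11, 70, 0),
        ("m2", "t1", 5, 30, 4, 30, 1),
        ("m2", "t2", 7, 35, 5, 30, 0),
        ("m2", "t3", 11, 50, 9, 50, 0),
        ("m2", "t4", 6, 25, 6, 25, 0),
        ("m3", "t1", 8, 40, 6, 40, 1),
        ("m3", "t2", 10, 45, 9, 45, 1),
        ("m3", "t3", 13, 60, 10, 60, 0),
        ("m3", "t4", 4, 20, 3, 20, 0),
    ]
    trials = [
        TrialRecord(m, t, rc, nc, rt, nt, (x,)) for m, t, rc, nc, rt, nt, x in rows
    ]
    return MetaEpiDataset(trials=trials, characteristic_names=["flag"])


@pytest.fixture
def tiny_dataset() -> MetaEpiDataset:
    return make_tiny_dataset()


# ---------------------------------------------------------------------------
# session-scoped fits shared by the heavier recovery checks
# ---------------------------------------------------------------------------

RECOVERY_TRUTH = dict(b0=-0.2, phi=0.15, lam=2.0)


@pytest.fixture(scope="session")
def recovery_data():
    cfg = TruthConfig(
        n_meta=60,
        b0=(RECOVERY_TRUTH["b0"],),
        phi=(RECOVERY_TRUTH["phi"],),
        lam=(RECOVERY_TRUTH["lam"],),
        tau2_dist=(-2.5, 0.8),
        seed=42,
    )
    return generate(cfg)


def _quiet_fit(dataset, spec, config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit(dataset, spec, config)


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    dataset, _ = recovery_data
    config = McmcConfig(n_iter=20000, n_burnin=5000, n_chains=3, seed=7)
    return _quiet_fit(dataset, ModelSpec(), config)


@pytest.fixture(scope="session")
def relabelled_fit(recovery_data):
    dataset, _ = recovery_data
    config = McmcConfig(n_iter=20000, n_burnin=5000, n_chains=3, seed=7)
    return _quiet_fit(relabel(dataset, "X1"), ModelSpec(), config)


@pytest.fixture(scope="session")
def additive_fit():
    cfg = TruthConfig(
        n_meta=20,
        b0=(-0.2,),
        phi=(0.15,),
        structure="additive",
        kappa=(0.15,),
        lam=None,
        tau2_dist=(-2.5, 0.8),
        seed=11,
    )
    dataset, truth = generate(cfg)
    config = McmcConfig(n_iter=8000, n_burnin=2000, n_chains=3, seed=3)
    return dataset, _quiet_fit(dataset, ModelSpec(structure="additive"), config)


def quiet_fit(dataset, spec, config):
    return _quiet_fit(dataset, spec, config)
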