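import pytest

from sulfarisk import SimConfig, generate_study, generic_registry


@pytest.fixture(scope="session")
def default_study():
    """Full-schema synthetic study: 29 compounds x 71 descriptors, 20/9 split."""
    return generate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_table(default_study):
    return default_study[0]


def recovery_config(seed: int, **overrides) -> SimConfig:
    """Planted-signal conditions for variable-selection recovery checks.

    20 anonymous descriptors, 3 planted large effects, 2% relative noise,
    independent columns, and a fixed molecular weight so the per-gram response
    stays exactly linear in the descriptors (variable weight would fold 1/mw
    variation into the per-gram scale that no descriptor explains).
    """
    kw = dict(
        n_compounds=29, registry=generic_registry(20), n_informative=3,
        informative_ids=("d03", "d11", "d17"), rel_noise_sd=0.02,
        block_correlation=0.0, mw_range=(275.0, 275.0), missing_cells=[],
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def planted_study():
    """One instance of the planted-signal conditions."""
    return generate_study(recovery_config(seed=42))
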