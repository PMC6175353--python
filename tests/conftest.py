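import pytest

import subdose as sd


@pytest.fixture(scope="session")
def grid() -> sd.DoseGrid:
    return sd.default_grid()


@pytest.fixture(scope="session")
def policy() -> sd.EscalationPolicy:
    return sd.default_policy()


@pytest.fixture(scope="session")
def nicholson() -> sd.ToxicityDataset:
    return sd.nicholson_data()


@pytest.fixture(scope="session")
def pseudo_spec() -> sd.PseudoDataSpec:
    return sd.default_pseudo_spec()


@pytest.fixture(scope="session")
def pseudo_data(pseudo_spec) -> sd.ToxicityDataset:
    return sd.expand_pseudo_data(pseudo_spec)


@pytest.fixture(scope="session")
def slab(pseudo_data, grid) -> sd.SlabPrior:
    return sd.derive_slab(pseudo_data, grid)


@pytest.fixture(scope="session")
def pooled_fit(nicholson, grid) -> sd.DoseToxicityFit:
    return sd.fit_model(nicholson, sd.ModelSpec(), grid)


@pytest.fixture(scope="session")
def scenarios(pooled_fit, grid) -> list[sd.ScenarioTruth]:
    return sd.build_scenarios(pooled_fit, grid)


@pytest.fixture(scope="session")
def trial_config(grid, policy, pseudo_spec):
    def make(method: str, **kwargs) -> sd.TrialConfig:
        return sd.TrialConfig(
            grid=grid, policy=policy, pseudo=pseudo_spec, method=method, **kwargs
        )

    return make
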