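import pytest

import mixtox as m


def printed_fits(context: str, endpoint: str = "testosterone") -> list[m.HillFit]:
    """Reported single-chemical fits (significant only) for a mixture context."""
    mixture_id = "Mixture 1" if context == "mixture1" else "Mixture 2"
    return [
        m.truth_to_fit(t)
        for t in m.find_truths(endpoint=endpoint, context=context)
        if t.direction != "none" and t.chemical_id != mixture_id
    ]


@pytest.fixture(scope="session")
def mixture1() -> m.MixtureDefinition:
    return m.load_packaged_mixture("mixture1")


@pytest.fixture(scope="session")
def mixture2() -> m.MixtureDefinition:
    return m.load_packaged_mixture("mixture2")


@pytest.fixture(scope="session")
def m1_testosterone_fits() -> list[m.HillFit]:
    return printed_fits("mixture1")


@pytest.fixture(scope="session")
def m2_testosterone_fits() -> list[m.HillFit]:
    return printed_fits("mixture2")


def make_fit(
    top: float,
    ec50: float,
    chemical_id: str = "chem",
    endpoint: str = "testosterone",
) -> m.HillFit:
    direction = "inhibitory" if top < 100 else "stimulatory"
    return m.HillFit(
        chemical_id=chemical_id,
        endpoint=endpoint,
        direction=direction,
        top=top,
        ec50=ec50,
        significant=True,
        p_value=0.001,
    )


def make_dataset(
    top: float,
    ec50: float,
    sd: float = 0.0,
    seed: int = 0,
    n_rep: int = 3,
    chemical_id: str = "chem",
) -> m.ResponseDataset:
    truth = m.TruthRecord(
        chemical_id,
        "testosterone",
        "inhibitory" if top < 100 else "stimulatory",
        top,
        ec50,
        "synthetic",
        source="synthetic",
    )
    return m.generate_single(truth, n_rep=n_rep, noise=m.NoiseModel(sd=sd, seed=seed))
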