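import numpy as np
import pytest

from trialgraph import (
    SynthConfig,
    TrialRecord,
    build_graph,
    generate_registry,
)


def make_record(nct, affiliations, *, conditions=("Diabetes",), title="A trial",
                interventions=(("DRUG", "Metformin"),), countries=("United States",),
                year=None):
    return TrialRecord(
        nct_id=nct,
        title=title,
        conditions=tuple(conditions),
        interventions=tuple(interventions),
        affiliations=tuple(affiliations),
        countries=tuple(countries),
        year=year,
    )


@pytest.fixture
def toy_records():
    """Five trials over four affiliations, two disease areas, with years."""
    return [
        make_record("NCT1", ["A", "B"], year=2019),
        make_record("NCT2", ["A", "B", "C"], year=2020,
                    conditions=("Stroke",), title="Stroke rehab study"),
        make_record("NCT3", ["C"], year=2021),
        make_record("NCT4", ["A", "D"], year=2022),
        make_record("NCT5", ["B", "C"], year=2022, conditions=("Diabetes",)),
    ]


@pytest.fixture
def toy_graph(toy_records):
    return build_graph(toy_records)


@pytest.fixture(scope="session")
def synth_small():
    """A small planted-block registry shared by slower tests."""
    config = SynthConfig(
        n_affiliations=60, n_trials=160, n_blocks=2, p_within=0.9,
        attribute_coupling=0.9, seed=42,
    )
    records, truth = generate_registry(config)
    return records, truth, config


def random_records(rng, n_trials=20, n_affils=8):
    """Random record sets for conservation/property tests."""
    names = [f"Org{i}" for i in range(n_affils)]
    records = []
    for t in range(n_trials):
        k = int(rng.integers(1, min(5, n_affils) + 1))
        team = list(rng.choice(names, size=k, replace=False))
        interventions = (
            (("DRUG", "x"),) if rng.random() < 0.7 else ()
        )
        records.append(
            make_record(f"NCT{t:04d}", team, interventions=interventions,
                        year=int(rng.integers(2015, 2023)))
        )
    return records
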