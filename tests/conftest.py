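import numpy as np
import pytest

from uqscreen.data_prep import ActivityRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_record(
    record_id="R0",
    compound_id="C0",
    target_id="T0",
    parameter="Ki",
    relation="=",
    value=10.0,
    unit="nM",
    smiles=None,
    organism=None,
):
    return ActivityRecord(
        record_id, compound_id, target_id, parameter, relation, value, unit, smiles, organism
    )


@pytest.fixture
def toy_records():
    """20 raw records with known composition for filter-count checks.

    Composition (hand-constructed):
      - 12 clean 'Ki = x nM' records (survive both modes)
      - 2 records with relation '<' (dropped under strict, kept extended)
      - 1 record with relation '>' (dropped under strict, kept extended)
      - 1 record with parameter 'EC50' (dropped at parameter stage)
      - 1 record with unit 'µg/mL' (dropped at unit stage)
      - 1 pKi record with a spurious unit 'nM' (dropped at unit stage)
      - 1 record with organism 'Rattus norvegicus' (dropped at organism stage)
      - 1 record with non-finite value (dropped at value stage)
    """
    recs = [
        make_record(f"R{i:02d}", f"C{i:02d}", value=float(i + 1)) for i in range(12)
    ]
    recs.append(make_record("R12", "C12", relation="<", value=5.0))
    recs.append(make_record("R13", "C13", relation="<", value=6.0))
    recs.append(make_record("R14", "C14", relation=">", value=7.0))
    recs.append(make_record("R15", "C15", parameter="EC50", value=8.0))
    recs.append(make_record("R16", "C16", unit="µg/mL", value=9.0))
    recs.append(make_record("R17", "C17", parameter="pKi", unit="nM", value=7.5))
    recs.append(make_record("R18", "C18", organism="Rattus norvegicus", value=10.0))
    recs.append(make_record("R19", "C19", value=float("nan")))
    return recs


@pytest.fixture(scope="session")
def small_synth():
    """A small clustered synthetic dataset shared by fast tests."""
    from uqscreen.synth import SynthConfig, make_dataset

    return make_dataset(
        SynthConfig(
            n_compounds=200,
            n_bits=128,
            n_clusters=8,
            noise_sd=0.1,
            measurements_mean=2.0,
            measurement_sd=0.1,
            seed=7,
        )
    )
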