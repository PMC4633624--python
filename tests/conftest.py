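import numpy as np
import pytest

from mutkit import deepcall, simulate


@pytest.fixture(scope="session")
def amplicon_experiment():
    """Standard spiked amplicon truth set (10 sites at 5%, depth 1000)."""
    return simulate.simulate_amplicon_experiment(seed=42)


def to_amplicon_reads(records, sidecar):
    return deepcall.reads_from_records(records, sidecar)


@pytest.fixture(scope="session")
def called_experiment(amplicon_experiment):
    """The standard truth set run through the full caller at Q>=30."""
    exp = amplicon_experiment
    table, calls = deepcall.run_caller(
        to_amplicon_reads(exp["sample_reads"], exp["sample_offsets"]),
        to_amplicon_reads(exp["control_reads"], exp["control_offsets"]),
        exp["ref"],
    )
    return exp, table, calls
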