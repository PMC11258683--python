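import numpy as np
import pytest

from kinproof import build_network
from kinproof.synth import reference_rates

#: representative initial conditions (nM) and horizons (s) per network kind
STANDARD_CONDITIONS = {
    "template_binding": ({"ML": 8.0, "T": 10.0}, 6_000.0),
    "template_recovery": ({"MT": 8.0, "P": 50.0, "RQ": 20.0}, 6_000.0),
    "full_discard": ({"ML": 8.0, "P": 50.0, "RQ": 20.0, "T": 4.0}, 20_000.0),
    "dimerization": (
        {"ML": 8.0, "N": 10.0, "P": 50.0, "RQ": 20.0, "T": 2.0},
        50_000.0,
    ),
    "snp_detection": (
        {"X": 15.0, "RQ": 20.0, "S": 20.0, "Psnp": 20.0, "PL": 10.0},
        50_000.0,
    ),
}


def default_variant(kind: str) -> str:
    return "TS" if kind == "snp_detection" else "M1"


@pytest.fixture(scope="session")
def networks():
    return {kind: build_network(kind) for kind in STANDARD_CONDITIONS}


@pytest.fixture(scope="session")
def rate_sets():
    return {
        kind: reference_rates(kind, default_variant(kind))
        for kind in STANDARD_CONDITIONS
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240701)
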