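"""Shared fixtures: protocols and noiseless reference simulations.

The heavier simulate-and-analyse round trips are session-scoped so the suite
pays for each of them once.
"""

import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from hergkit.analysis import analyse_optimised
from hergkit.model import NOISELESS_CELL, WT_GATING, simulate_current
from hergkit.protocols import build_classical_protocols, build_optimised_protocol
from hergkit.variants import make_variant_params


@pytest.fixture(scope="session")
def optimised_protocol():
    return build_optimised_protocol()


@pytest.fixture(scope="session")
def classical_protocols():
    return build_classical_protocols()


@pytest.fixture(scope="session")
def wt_bundle(optimised_protocol):
    return simulate_current(WT_GATING, optimised_protocol, NOISELESS_CELL)


@pytest.fixture(scope="session")
def wt_result(wt_bundle, optimised_protocol):
    return analyse_optimised(wt_bundle, optimised_protocol)


@pytest.fixture(scope="session")
def variant_results(optimised_protocol, wt_result):
    """Noiseless simulate→analyse round trip for every registry variant."""
    from hergkit.variants import VARIANT_NAMES

    out = {"WT": wt_result}
    for name in VARIANT_NAMES:
        gating = make_variant_params(name).to_gating(WT_GATING)
        bundle = simulate_current(gating, optimised_protocol, NOISELESS_CELL, variant=name)
        out[name] = analyse_optimised(
            bundle, optimised_protocol,
            wt_reference_density=wt_result.density_pA_per_pF,
        )
    return out
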