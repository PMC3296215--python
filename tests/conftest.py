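import numpy as np
import pytest

from mrsikit.signal_model import EchoGrid, EchoSignal, evaluate_model
from mrsikit.synthetic_data import metabolite_components

TRUE_AMPLITUDES = {"NAA": 48.0, "Cr": 36.0, "Cho": 24.0}


@pytest.fixture
def grid256() -> EchoGrid:
    return EchoGrid(256, 2000.0)


@pytest.fixture
def grid1024() -> EchoGrid:
    return EchoGrid(1024, 2000.0)


@pytest.fixture
def triplet():
    """Factory: the three-singlet NAA/Cr/Cho model for a given lineshape."""

    def make(kind="lorentzian"):
        return metabolite_components(kind=kind)

    return make


@pytest.fixture
def triplet_echo(triplet):
    """Factory: noise-free triplet echo of a given lineshape and length."""

    def make(kind="lorentzian", n_points=256, sw=2000.0):
        grid = EchoGrid(n_points, sw)
        comps = triplet(kind)
        return EchoSignal(evaluate_model(comps, grid), grid), comps

    return make


def max_rel_amplitude_error(result, truth_components) -> float:
    """Worst relative amplitude error after frequency-sorted matching."""
    truth = sorted(truth_components, key=lambda c: c.frequency)
    fitted = result.sorted_by_frequency()
    assert len(fitted) == len(truth), (
        f"expected {len(truth)} components, fit returned {len(fitted)}"
    )
    errs = [
        abs(f.amplitude - t.amplitude) / t.amplitude for f, t in zip(fitted, truth)
    ]
    return max(errs)
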