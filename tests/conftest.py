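import numpy as np
import pytest

from vibspec import (
    AnharmonicConstants,
    LineShapeParams,
    ModeBasis,
    build_transition_ledger,
    constant_intensity,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def three_modes():
    return ModeBasis.from_wavenumbers(
        [700.0, 1650.0, 3050.0], ["gammaCH", "deltaring", "nuCH"]
    )


@pytest.fixture
def three_mode_chi():
    chi = np.array(
        [
            [-8.0, 1.5, -2.0],
            [1.5, -10.0, 0.5],
            [-2.0, 0.5, -32.0],
        ]
    )
    return AnharmonicConstants(chi)


@pytest.fixture
def small_ledger(three_modes, three_mode_chi):
    return build_transition_ledger(
        three_modes, three_mode_chi, constant_intensity(2.0), max_order=2
    )


@pytest.fixture
def mir_lineshape():
    return LineShapeParams(8.0, 8.0, "area-proportional")
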