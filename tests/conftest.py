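import numpy as np
import pytest

import spheredose as sd
from spheredose.simulate import SimulationDesign


@pytest.fixture
def dense_noiseless_design():
    """Factory: noise-free design densely sampled over 10 physical half-lives.

    Early times are geometrically spaced so fast uptake phases (e.g. blood)
    are resolved; the remainder is linear out to 10 half-lives.
    """

    def make(nuclide: str, kinetics=None) -> SimulationDesign:
        if kinetics is None:
            kinetics = sd.default_design().kinetics
        t_end_h = 10 * sd.get_nuclide(nuclide).half_life_s / 3600.0
        times = np.unique(
            np.concatenate(
                [np.geomspace(0.02, 6.0, 120), np.linspace(6.0, t_end_h, 500)]
            )
        )
        return SimulationDesign(
            kinetics=kinetics,
            nuclide=nuclide,
            timepoints_h=tuple(times),
            n_per_timepoint=1,
            noise_cv=0.0,
            seed=0,
        )

    return make
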