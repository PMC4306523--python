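import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from rivaldcm.forward import InputTimeline, parameters_from_masks  # noqa: E402
from rivaldcm.model_space import enumerate_model_space  # noqa: E402

STANDARD_A = {
    ("r-V5", "r-pSPL"): 0.35, ("r-pSPL", "r-V5"): 0.15,
    ("r-pSPL", "r-aSPL"): 0.35, ("r-aSPL", "r-pSPL"): 0.15,
}
ALL_B_CONNECTIONS = (
    ("r-aSPL", "r-pSPL"), ("r-pSPL", "r-aSPL"),
    ("r-pSPL", "r-V5"), ("r-V5", "r-pSPL"),
)


@pytest.fixture(scope="session")
def model_space():
    return enumerate_model_space()


@pytest.fixture(scope="session")
def winning(model_space):
    """Bidirectional structure: all four modulations, V5-only switch input."""
    return model_space[15]


@pytest.fixture(scope="session")
def make_params(winning):
    """Factory for ground-truth parameters on the winning-model masks."""

    def _make(b_rivalry=None, b_replay=None, c_stim=0.04, c_switch=0.15):
        b_values = {}
        for (s, t), val in (b_rivalry or {}).items():
            b_values[("rivalry_switch", s, t)] = val
        for (s, t), val in (b_replay or {}).items():
            b_values[("replay_switch", s, t)] = val
        return parameters_from_masks(
            winning,
            a_values=STANDARD_A,
            b_values=b_values,
            c_values={("stimulation", "r-V5"): c_stim,
                      ("rivalry_switch", "r-V5"): c_switch,
                      ("replay_switch", "r-V5"): c_switch},
        )

    return _make


@pytest.fixture(scope="session")
def make_run_timeline():
    """Factory for a trial-structured input timeline with random switch times.

    Trials alternate rivalry/replay (31.5 s stimulation + 11 s fixation after
    a 10.5 s lead-in); switch pulses are drawn from the dominance-duration
    gamma at mean 4.5 s.
    """

    def _make(rng, dt=0.15, n_trials=6, pulse_width=1.0):
        dur = 10.5 + n_trials * 42.5
        box_f, box_s = [(0.0, 10.5)], []
        swr, swp = [], []
        t0 = 10.5
        for k in range(n_trials):
            box_s.append((t0, 31.5))
            sw = t0 + np.cumsum(rng.gamma(20.66, 0.2178, 12))
            sw = sw[sw < t0 + 31.0]
            (swr if k % 2 == 0 else swp).extend(sw)
            box_f.append((t0 + 31.5, 11.0))
            t0 += 42.5
        return InputTimeline.from_events(
            boxcars={"fixation": box_f, "stimulation": box_s},
            pulses={"rivalry_switch": swr, "replay_switch": swp},
            duration=dur, dt=dt, pulse_width=pulse_width)

    return _make
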