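import numpy as np
import pytest

from fmpy import AgentSpec, MazeGeometry, TurnSequence, simulate_turns


@pytest.fixture
def geom() -> MazeGeometry:
    return MazeGeometry(("A", "B", "C"), "ccw_is_left", frozenset({"centre"}))


@pytest.fixture
def fair_1000() -> TurnSequence:
    """An iid fair 1000-turn sequence, fixed seed."""
    return simulate_turns(AgentSpec("iid", seed=1), 1000)


@pytest.fixture
def timed_session() -> TurnSequence:
    """A timed hour-long sequence: 600 turns evenly spread over 3600 s."""
    turns = simulate_turns(AgentSpec("markov1", p_alternate=0.75, seed=5), 600).turns
    times = np.arange(600) * 6.0 + 3.0  # 3 s, 9 s, ..., 3597 s: 100 turns per 10-min bin
    return TurnSequence("timed", turns, times, session_duration=3600.0)
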