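import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cytocomb import EventTable, MarkerDef, MarkerPanel

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def panel_ab() -> MarkerPanel:
    """Two 2-state markers A and B, gated at 5.0, no OOB limits."""
    return MarkerPanel(
        (
            MarkerDef("A", (5.0,)),
            MarkerDef("B", (5.0,)),
        )
    )


@pytest.fixture
def panel_abc() -> MarkerPanel:
    """Three 2-state markers with OOB limits on A."""
    return MarkerPanel(
        (
            MarkerDef("A", (5.0,), oob_limit=100.0),
            MarkerDef("B", (5.0,)),
            MarkerDef("C", (5.0,)),
        )
    )


def events_from_states(sample_id: str, states, panel: MarkerPanel) -> EventTable:
    """Build an event table whose discretization is exactly ``states``.

    Uses the midpoint of each state's threshold interval (intervals are taken
    as unit-width around the gate values used in these fixtures).
    """
    states = np.asarray(states)
    vals = np.empty(states.shape, dtype=float)
    for j, m in enumerate(panel):
        thr = (0.0,) + m.thresholds
        for s in range(1, m.n_states + 1):
            lo = thr[s - 1]
            hi = m.thresholds[s - 1] if s <= len(m.thresholds) else lo + 2.0
            vals[states[:, j] == s, j] = (lo + hi) / 2.0
    return EventTable(sample_id, pd.DataFrame(vals, columns=panel.names))
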