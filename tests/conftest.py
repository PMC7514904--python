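"""Shared fixtures: the worked-example event log and canonical room codes."""

from datetime import datetime

import pytest

from visitropy import SensorEvent, build_code_map

BASE_DAY = datetime(2025, 1, 6)


@pytest.fixture(scope="session")
def canonical_map():
    return build_code_map(
        ["Living room", "Bedroom", "Bathroom", "Kitchen", "Corridor"]
    )


@pytest.fixture(scope="session")
def worked_example_events():
    """The published one-hour example: five dwells 09:00-10:00 plus a
    simultaneous Living-room/Bathroom activation where the first logged
    sensor wins."""
    d = BASE_DAY
    return [
        SensorEvent(d.replace(hour=9, minute=0, second=1), "Bedroom"),
        SensorEvent(d.replace(hour=9, minute=5, second=22), "Corridor"),
        SensorEvent(d.replace(hour=9, minute=6, second=0), "Living room"),
        SensorEvent(d.replace(hour=9, minute=6, second=0), "Bathroom"),
        SensorEvent(d.replace(hour=9, minute=9, second=59), "Corridor"),
        SensorEvent(d.replace(hour=9, minute=11, second=0), "Living room"),
        SensorEvent(d.replace(hour=10, minute=0, second=0), "Kitchen"),
    ]


@pytest.fixture(scope="session")
def worked_example_sequence():
    """The encoded 60-sample vector the example produces."""
    return [3] * 5 + [9] + [1] * 4 + [9] + [1] * 49
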