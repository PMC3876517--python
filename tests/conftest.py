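import pandas as pd
import pytest

from trisscore.registry_io import COLUMNS


def make_row(patient_id="P1", **overrides):
    """A valid registry row as a dict; override any field."""
    row = {
        "patient_id": patient_id,
        "age": 30,
        "sex": "male",
        "trauma_type": "blunt",
        "cause": "vehicle_accident",
        "gcs": 15,
        "sbp": 120.0,
        "rr": 16.0,
        "ais_head_neck": 2,
        "ais_face": 0,
        "ais_chest": 3,
        "ais_abdomen": 0,
        "ais_extremities": 1,
        "ais_external": 0,
        "outcome": "lived",
        "length_of_stay": 5.0,
    }
    row.update(overrides)
    return row


def make_frame(rows):
    return pd.DataFrame(rows, columns=list(COLUMNS))


@pytest.fixture
def tiny_frame():
    return make_frame([
        make_row("P1"),
        make_row("P2", age=70, sex="female", gcs=8, sbp=70.0, rr=4.0,
                 ais_head_neck=4, outcome="died"),
        make_row("P3", age=10, trauma_type="penetrating", cause="assault",
                 length_of_stay=None),
    ])


@pytest.fixture
def tiny_csv(tmp_path, tiny_frame):
    path = tmp_path / "registry.csv"
    tiny_frame.to_csv(path, index=False)
    return path
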