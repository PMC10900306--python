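import pandas as pd
import pytest

from resptraj import RunConfig


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def eras_frame():
    """Build a one-person era frame from (class, start, end) triples."""

    def _make(triples, person_id="P0"):
        return pd.DataFrame(
            [(person_id, c, s, e, e - s + 1) for c, s, e in triples],
            columns=["person_id", "drug_class", "start_day", "end_day", "duration_days"],
        )

    return _make


@pytest.fixture
def traj_frame():
    """Build a trajectory frame from label tuples (empty tuple = untreated)."""

    def _make(label_tuples, depth=5):
        rows = []
        for i, labels in enumerate(label_tuples):
            row = {"person_id": f"P{i}", "treated": bool(labels), "labels": tuple(labels)}
            for k in range(depth):
                row[f"label_{k + 1}"] = labels[k] if k < len(labels) else ""
            rows.append(row)
        return pd.DataFrame(rows)

    return _make
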