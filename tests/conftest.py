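import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_ct_table(rows):
    """rows: (sample_id, pair_id, tissue_class, assay_id, ct-or-None)."""
    return pd.DataFrame(
        [(s, p, t, a, np.nan if c is None else float(c)) for s, p, t, a, c in rows],
        columns=["sample_id", "pair_id", "tissue_class", "assay_id", "ct"],
    )


@pytest.fixture
def toy_pair_table():
    """Two pairs x two assays plus three controls, fully detected."""
    rows = []
    controls = {"ctrl-1": 20.0, "ctrl-2": 21.0, "ctrl-3": 22.0}
    targets = {"miR-a": 25.0, "miR-b": 30.0}
    for pair in ("P1", "P2"):
        for klass, suffix in (("lesion", "T"), ("control", "N")):
            sample = f"{pair}-{suffix}"
            for assay, ct in {**controls, **targets}.items():
                rows.append((sample, pair, klass, assay, ct))
    return make_ct_table(rows)
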