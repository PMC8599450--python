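import numpy as np
import pandas as pd
import pytest

from tcrdyn.io import Repertoire, SampleMeta


def make_repertoire(counts, patient="P1", timepoint="pre", compartment="tumor",
                    region="R1", cdr3=None):
    """Build a Repertoire from a {clone_key: count} mapping."""
    keys = sorted(counts)
    table = pd.DataFrame(
        {
            "clone_key": keys,
            "cdr3_aa": [cdr3[k] if cdr3 else f"CASS{k.upper()}GELF" for k in keys],
            "v_call": "TRBV5",
            "j_call": "TRBJ2",
            "umi_count": [counts[k] for k in keys],
        }
    )
    meta = SampleMeta(patient_id=patient, timepoint=timepoint,
                      compartment=compartment, region_id=region)
    return Repertoire(meta=meta, table=table)


@pytest.fixture
def rep_90_10():
    return make_repertoire({"a": 90, "b": 10})


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
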