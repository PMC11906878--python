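import datetime as dt

import numpy as np
import pandas as pd
import pytest

from anthropause.ingest import OccurrenceRecord, PeriodWindow


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def write_occurrences(tmp_path):
    """Write rows (list of dicts) to a TSV occurrence file; returns path."""

    def _write(rows, name="occ.tsv", sep="\t"):
        cols = ["id", "countryCode", "eventDate", "decimalLatitude",
                "decimalLongitude", "basisOfRecord", "datasetTag",
                "observerId"]
        frame = pd.DataFrame([[r.get(c, "") for c in cols] for r in rows],
                             columns=cols)
        path = tmp_path / name
        frame.to_csv(path, sep=sep, index=False)
        return path

    return _write


def occ_row(i=0, code="US", date="2020-03-20", lat="40.0", lon="-100.0",
            basis="HUMAN_OBSERVATION", tag="ebird", obs="obs1"):
    return {"id": f"r{i}", "countryCode": code, "eventDate": date,
            "decimalLatitude": lat, "decimalLongitude": lon,
            "basisOfRecord": basis, "datasetTag": tag, "observerId": obs}


def record(code="US", date=dt.date(2020, 3, 20), lat=40.0, lon=-100.0,
           tag="ebird", obs="obs1", rid="r0"):
    return OccurrenceRecord(record_id=rid, country_code=code,
                            event_date=date, lat=lat, lon=lon,
                            basis="human_observation", dataset_tag=tag,
                            observer_id=obs)
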