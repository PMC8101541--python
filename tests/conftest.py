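import numpy as np
import pytest

from sharkcast.core_data import IncidentRecord, ScaledRateSeries


@pytest.fixture
def five_records():
    """One record per filter-relevant combination, for hand enumeration."""
    return [
        IncidentRecord(1950, "NSW", "white", fatal=True, provoked=False),
        IncidentRecord(1951, "QLD", "tiger", fatal=False, provoked=True),
        IncidentRecord(1952, "WA", "bull", fatal=False, provoked=False),
        IncidentRecord(1953, "SA", "whaler", fatal=True, provoked=True),
        IncidentRecord(1954, "NSW", "unknown", fatal=False, provoked=False),
    ]


@pytest.fixture
def noiseless_sinusoid_series():
    """Exact y = 0.5 + 0.3 cos(2*pi/100 * t + 1.0) over 120 years."""
    years = np.arange(1900, 2020)
    t = years - years[0]
    y = 0.5 + 0.3 * np.cos(2 * np.pi / 100 * t + 1.0)
    return ScaledRateSeries("NSW", years, y, 1.0)


@pytest.fixture
def incidents_csv(tmp_path):
    path = tmp_path / "incidents.csv"
    path.write_text(
        "year,region,species,fatal,provoked\n"
        "1950,NSW,white,1,0\n"
        "1960,QLD,tiger,false,true\n"
        "1970,WA,bull,0,0\n")
    return path
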