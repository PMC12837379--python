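import numpy as np
import pytest

from combodex import datasets
from combodex.dose_response import inhibition_fraction
from combodex.median_effect import fit_median_effect
from combodex.synthetic_data import DrugParams, default_config


@pytest.fixture
def q_fit():
    """Median-effect fit of the packaged quercetin series."""
    s = datasets.q_series()
    mask = s.doses > 0
    fa = [inhibition_fraction(v) for v in s.viabilities[mask]]
    return fit_median_effect(s.doses[mask], fa)


@pytest.fixture
def gem_fit():
    s = datasets.gem_series()
    mask = s.doses > 0
    fa = [inhibition_fraction(v) for v in s.viabilities[mask]]
    return fit_median_effect(s.doses[mask], fa)


@pytest.fixture
def equal_slope_config():
    """Noise-free screen whose two agents share a slope, so a Loewe-
    additive fixed-ratio mixture is itself exactly a median-effect curve."""
    return default_config(
        seed=1,
        noise_cv=0.0,
        drug_a=DrugParams(name="Q", dm=85.0, m=1.2),
        drug_b=DrugParams(name="GEM", dm=6.5, m=1.2),
    )


@pytest.fixture
def wells_csv(tmp_path):
    """Write a small tidy wells CSV and return its path."""

    def _write(rows, header="agent_a,dose_a,agent_b,dose_b,replicate,response,response_kind"):
        path = tmp_path / "wells.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write


def series_fa(series):
    mask = series.doses > 0
    return series.doses[mask], np.array(
        [inhibition_fraction(v) for v in series.viabilities[mask]]
    )
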