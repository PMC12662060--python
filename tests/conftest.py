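import pandas as pd
import pytest

from reefbleach.simulate import (
    GenusProfile,
    SimulationConfig,
    default_config,
    gen_survey,
)
from reefbleach.survey_io import SiteDesign, SurveyDataset, SurveyDesign

TOY_CSV = """site,station,period,quadrat,genus,category,count
Ambola,Manangatse,during,q1,Acropora,C1,4
Ambola,Manangatse,during,q1,Acropora,C5,1
Ambola,Manangatse,during,q1,Pocillopora,C3,2
"""


@pytest.fixture
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(TOY_CSV)
    return path


@pytest.fixture
def toy_dataset(toy_csv):
    from reefbleach.survey_io import read_survey

    return read_survey(toy_csv)


def make_dataset(rows, design=None):
    """Build a SurveyDataset from (site, station, period, quadrat, genus,
    category, count) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["site", "station", "period", "quadrat", "genus", "category", "count"],
    )
    return SurveyDataset(df, design)


@pytest.fixture
def small_config():
    """A small but structured scenario: 2 sites, 3 stations, 8 quadrats."""
    design = SurveyDesign(
        (
            SiteDesign("North", ("N1", "N2"), quadrats_per_station=8),
            SiteDesign("South", ("S1",), quadrats_per_station=8),
        )
    )
    profiles = (
        GenusProfile("Acropora", 0.5, (0.3, 0.2, 0.2, 0.1, 0.15, 0.05), 0.6, 0.1),
        GenusProfile("Galaxea", 0.3, (0.8, 0.08, 0.05, 0.03, 0.02, 0.02), 0.5, 0.05),
        GenusProfile("Others", 0.2, (0.6, 0.1, 0.1, 0.1, 0.05, 0.05), 0.5, 0.1),
    )
    return SimulationConfig(
        design=design, genus_profiles=profiles, quadrat_mean=12.0,
        quadrat_dispersion=6.0, seed=42,
    )


@pytest.fixture
def small_dataset(small_config):
    return gen_survey(small_config)


@pytest.fixture
def default_dataset():
    """The package's full default scenario (11 stations, ~8,000 colonies)."""
    return gen_survey(default_config(seed=7))
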