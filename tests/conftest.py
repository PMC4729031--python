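import numpy as np
import pandas as pd
import pytest

from tickcomm import SimulationConfig, default_config, simulate_survey


def flat_two_taxon_config(
    mean_a: float = 2.0,
    mean_b: float = 5.0,
    multiplier: float = 1.0,
    theta: float = 1.5,
    months: int = 12,
    steers: int = 12,
) -> SimulationConfig:
    """One site, two taxa, season-flat means; multiplier acts A -> Rm."""
    prefs = (0.08, 0.10, 0.32, 0.35, 0.15)
    return SimulationConfig(
        site_areas={"1X": "area1"},
        taxon_pools={"1X": ("A_VARIEGATUM", "R_MICROPLUS")},
        months=months,
        steers_per_site=steers,
        schedule={
            ("1X", "A_VARIEGATUM"): (mean_a,) * months,
            ("1X", "R_MICROPLUS"): (mean_b,) * months,
        },
        nb_size=theta,
        multipliers=(
            {("A_VARIEGATUM", "R_MICROPLUS"): multiplier} if multiplier != 1.0 else {}
        ),
        attachment_preferences={
            "A_VARIEGATUM": prefs,
            "R_MICROPLUS": prefs,
        },
        area_start_month={"area1": 2},
        rainfall={"area1": (0.0,) * 12},
        temperature={"area1": (27.0,) * 12},
    )


def seasonal_one_taxon_config(
    means_by_month: tuple[float, ...],
    theta: float = 1.5,
    steers: int = 12,
) -> SimulationConfig:
    """One site, one taxon, arbitrary monthly mean schedule."""
    months = len(means_by_month)
    return SimulationConfig(
        site_areas={"1X": "area1"},
        taxon_pools={"1X": ("R_MICROPLUS",)},
        months=months,
        steers_per_site=steers,
        schedule={("1X", "R_MICROPLUS"): tuple(means_by_month)},
        nb_size=theta,
        attachment_preferences={"R_MICROPLUS": (0.08, 0.10, 0.32, 0.35, 0.15)},
        area_start_month={"area1": 2},
        rainfall={"area1": (0.0,) * 12},
        temperature={"area1": (27.0,) * 12},
    )


@pytest.fixture(scope="session")
def default_survey():
    """One draw of the full reference design (12 sites, 12 steers, 12 months)."""
    survey, climate, truth = simulate_survey(default_config(), seed=20)
    return survey, climate, truth


@pytest.fixture()
def tiny_survey():
    """Hand-built two-site survey with known counts."""
    rows = [
        # area, site, month_index, calendar_month, steer, taxon, part, count
        ("a1", "s1", 1, 2, "x1", "R_MICROPLUS", "flank", 3),
        ("a1", "s1", 1, 2, "x2", "R_MICROPLUS", "tail", 2),
        ("a1", "s1", 1, 2, "x1", "A_VARIEGATUM", "perineum", 1),
        ("a1", "s1", 2, 3, "x1", "R_MICROPLUS", np.nan, 0),
        ("a1", "s2", 1, 2, "y1", "HYALOMMA_SPP", "head", 4),
        ("a1", "s2", 2, 3, "y1", "R_MICROPLUS", "legs", 1),
        ("a1", "s2", 2, 3, "y2", "UNIDENTIFIED", np.nan, 2),
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "area",
            "site",
            "month_index",
            "calendar_month",
            "steer",
            "taxon",
            "attachment_site",
            "count",
        ],
    )
    from tickcomm import SurveyTable

    return SurveyTable.from_frame(
        df,
        roster={"s1": ("x1", "x2"), "s2": ("y1", "y2")},
    )
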