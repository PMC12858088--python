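"""Reference-survey constants for comparison reports.

Printed estimates from the national reference surveys used as comparison
baselines: the PNADC-2022 household-survey sociodemographic distributions
(post-stratification targets and out-of-calibration checks) and the
PNS-2019 health-survey prevalences of chronic noncommunicable diseases,
self-rated health, and health behaviours.  The companion chain-referral
web-survey columns are included as fixture constants so the comparison
arithmetic can be exercised end to end; those respondent-level data are not
public and cannot be recomputed here.

All values are percentages with 95% confidence bounds as printed.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "pnadc_2022_poststrat",
    "pnadc_2022_other",
    "pns_2019_health",
    "rds_survey_poststrat",
    "rds_survey_other",
    "rds_survey_health",
]


def _table(rows, columns=("indicator", "pct", "ci_low", "ci_high")) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(columns))


def pnadc_2022_poststrat() -> pd.DataFrame:
    """PNADC-2022 distributions of the four post-stratification variables."""
    return _table(
        [
            ("sex:men", 48.1, 47.9, 53.1),
            ("sex:women", 51.9, 51.7, 57.3),
            ("race:white", 43.4, 42.9, 48.3),
            ("race:nonwhite", 56.6, 56.1, 62.8),
            ("education3:some_hs_or_less", 44.5, 44.0, 49.4),
            ("education3:hs_some_college", 38.2, 37.8, 42.3),
            ("education3:college_plus", 17.3, 16.9, 19.6),
            ("age_group:18-39", 45.9, 45.5, 50.8),
            ("age_group:40-59", 34.0, 33.8, 37.7),
            ("age_group:60+", 20.1, 19.8, 22.4),
        ]
    )


def pnadc_2022_other() -> pd.DataFrame:
    """PNADC-2022 distributions of variables outside the calibration."""
    return _table(
        [
            ("region:north", 8.1, 7.9, 8.4),
            ("region:northeast", 26.3, 25.9, 26.8),
            ("region:southeast", 43.3, 42.8, 43.9),
            ("region:south", 14.6, 14.2, 14.9),
            ("region:midwest", 7.7, 7.5, 7.9),
            ("residence:capital", 24.8, 24.4, 25.3),
            ("residence:noncapital", 75.2, 74.7, 75.6),
            ("education4:some_elementary", 30.5, 30.1, 30.8),
            ("education4:elementary_some_hs", 14.0, 13.8, 14.3),
            ("education4:hs_some_college", 38.2, 37.8, 38.5),
            ("education4:college_plus", 17.4, 16.9, 17.9),
        ]
    )


def pns_2019_health() -> pd.DataFrame:
    """PNS-2019 prevalences: chronic diseases, self-rated health, behaviours."""
    return _table(
        [
            ("hypertension", 23.9, 23.4, 24.4),
            ("diabetes", 7.7, 7.4, 8.0),
            ("heart_disease", 5.3, 5.0, 5.6),
            ("asthma", 5.3, 5.0, 5.6),
            ("cancer", 2.6, 2.4, 2.7),
            ("depression", 10.2, 9.9, 10.6),
            ("any_ncd", 50.8, 50.1, 51.4),
            ("self_rated_health:good", 66.1, 65.5, 66.7),
            ("self_rated_health:fair", 28.1, 27.6, 28.6),
            ("self_rated_health:poor", 5.8, 5.5, 6.0),
            ("current_smoking", 12.6, 12.2, 13.0),
            ("alcohol_weekly", 26.4, 25.8, 27.0),
            ("physical_activity_recommended", 30.1, 29.4, 30.7),
            ("screen_3h_plus", 22.2, 21.6, 22.8),
            ("fruit_yesterday", 67.3, 66.7, 67.9),
            ("vegetable_yesterday", 70.9, 70.4, 71.5),
            ("ultraprocessed_yesterday", 72.0, 71.5, 72.6),
        ]
    )


def rds_survey_poststrat() -> pd.DataFrame:
    """Chain-referral web-survey (2023, n=3,805) weighted distributions of
    the post-stratification variables, as printed; fixture constants."""
    rows = [
        ("sex:men", 1787, 47.0, 41.5, 52.5),
        ("sex:women", 1974, 51.9, 47.1, 56.7),
        ("sex:other", 44, 1.1, 0.4, 3.4),
        ("race:white", 1651, 43.4, 39.2, 47.7),
        ("race:nonwhite", 2154, 56.6, 52.3, 60.8),
        ("education3:some_hs_or_less", 1692, 44.5, 35.4, 54.0),
        ("education3:hs_some_college", 1452, 38.1, 32.3, 44.3),
        ("education3:college_plus", 661, 17.4, 13.6, 21.9),
        ("age_group:18-39", 1746, 45.9, 38.4, 53.6),
        ("age_group:40-59", 1295, 34.0, 30.3, 38.0),
        ("age_group:60+", 764, 20.1, 14.7, 26.8),
    ]
    return _table(rows, columns=("indicator", "n", "pct", "ci_low", "ci_high"))


def rds_survey_other() -> pd.DataFrame:
    """Web-survey weighted distributions outside the calibration; fixtures."""
    rows = [
        ("region:north", 297, 8.1, 5.0, 13.0),
        ("region:northeast", 1283, 35.0, 23.7, 48.2),
        ("region:southeast", 1329, 36.2, 27.1, 46.4),
        ("region:south", 458, 12.5, 4.8, 28.8),
        ("region:midwest", 303, 8.2, 4.7, 14.1),
        ("residence:capital", 1629, 42.8, 35.7, 50.2),
        ("residence:noncapital", 2176, 57.2, 49.8, 64.3),
        ("education4:some_elementary", 820, 21.6, 15.9, 28.6),
        ("education4:elementary_some_hs", 872, 22.9, 18.6, 27.8),
        ("education4:hs_some_college", 1452, 38.2, 32.3, 44.3),
        ("education4:college_plus", 661, 17.4, 13.6, 21.9),
    ]
    return _table(rows, columns=("indicator", "n", "pct", "ci_low", "ci_high"))


def rds_survey_health() -> pd.DataFrame:
    """Web-survey weighted health prevalences; fixture constants."""
    return _table(
        [
            ("hypertension", 22.0, 17.8, 26.9),
            ("diabetes", 8.9, 6.9, 11.4),
            ("heart_disease", 4.3, 2.8, 6.7),
            ("asthma", 8.5, 6.9, 10.6),
            ("cancer", 2.4, 1.5, 3.9),
            ("depression", 14.7, 12.6, 17.1),
            ("any_ncd", 55.4, 51.5, 59.4),
            ("self_rated_health:good", 62.0, 57.5, 66.2),
            ("self_rated_health:fair", 33.2, 29.4, 37.3),
            ("self_rated_health:poor", 4.8, 3.2, 7.1),
            ("current_smoking", 12.1, 9.6, 15.1),
            ("alcohol_weekly", 21.9, 18.6, 25.6),
            ("physical_activity_recommended", 32.7, 28.6, 37.2),
            ("screen_3h_plus", 46.1, 41.1, 51.2),
            ("fruit_yesterday", 65.8, 62.6, 68.9),
            ("vegetable_yesterday", 66.8, 63.2, 70.2),
            ("ultraprocessed_yesterday", 73.1, 68.9, 76.9),
        ]
    )
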