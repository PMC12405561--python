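import pandas as pd
import pytest

from nppdb import SynthConfig, generate_database, generate_worked_example


@pytest.fixture(scope="session")
def small_db():
    """60-site synthetic database with default noise and some injected
    incompleteness."""
    return generate_database(SynthConfig(n_sites=60, seed=11))


@pytest.fixture(scope="session")
def clean_db():
    """60-site synthetic database with zero noise and no incompleteness."""
    return generate_database(
        SynthConfig(n_sites=60, seed=11, noise_model=0.0, incomplete_fraction=0.0)
    )


@pytest.fixture(scope="session")
def worked_example_db():
    return generate_worked_example()


def minimal_tables() -> dict[str, pd.DataFrame]:
    """One-site, two-record canonical table set that validates cleanly.

    Tests mutate copies of this to force specific validation failures.
    """
    return {
        "site_information": pd.DataFrame(
            [{"site_id": "A1", "latitude": 45.0, "longitude": 7.0,
              "elevation": 300.0, "biome": "forest", "management": "unmanaged",
              "climate_region": "temperate", "study_type": "field_assessment",
              "species_info": "Fagus sylvatica", "fertility": "M"}]
        ),
        "npp_estimates": pd.DataFrame(
            [
                {"record_id": "r1", "site_id": "A1", "component": "stem",
                 "value": 400.0, "unit": "g_dry_mass", "carbon_content": None,
                 "year_start": 2000, "year_end": 2002, "series_length": 3,
                 "method_id": "AG_INC", "component_absent_flag": 0,
                 "includes_reproductive": 0, "original_label": "stemwood"},
                {"record_id": "r2", "site_id": "A1", "component": "fine_root",
                 "value": 350.0, "unit": "g_dry_mass", "carbon_content": None,
                 "year_start": 2000, "year_end": 2000, "series_length": 1,
                 "method_id": "BG_INGROWTH", "component_absent_flag": 0,
                 "includes_reproductive": 0, "original_label": None},
            ]
        ),
        "methodology_aboveground": pd.DataFrame(
            [{"method_id": "AG_INC", "name": "Sum of increments in live biomass",
              "scope": "aboveground", "rf": 0.3}]
        ),
        "methodology_belowground": pd.DataFrame(
            [{"method_id": "BG_INGROWTH", "name": "Ingrowth core (fine roots)",
              "scope": "belowground", "rf": 0.3}]
        ),
    }


def write_tables(tables: dict[str, pd.DataFrame], path) -> str:
    path.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(path / f"{name}.csv", index=False)
    return str(path)
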