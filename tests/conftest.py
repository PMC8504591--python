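import pytest
from hypothesis import HealthCheck, settings

import slitfield as sf

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def chest_geom():
    """Chest-wall-side camera geometry of the clinical prototype."""
    return sf.SlitGeometry(
        y_foil=63.5, y_slit=31.35, x_slit=33.0,
        y_source=661.2, x_source=23.6, side="chest_wall",
    )


@pytest.fixture(scope="session")
def right_geom():
    """Right-side camera geometry of the clinical prototype."""
    return sf.SlitGeometry(
        y_foil=63.5, y_slit=31.35, x_slit=50.0,
        y_source=661.2, x_source=133.7, side="right",
    )


#: Published measurement table: (view, x_edge mm, x_fov mm, diff-to-mammo mm)
CHEST_WALL_VIEWS = [
    ("Mammo., 24x29", 69.74, -7.68, 0.00),
    ("DBT proj., -6.4", 69.49, -7.41, 0.28),
    ("DBT proj., -4.3", 69.37, -7.27, 0.42),
    ("DBT proj., -2.1", 69.47, -7.38, 0.30),
    ("DBT proj., 0", 69.36, -7.25, 0.43),
    ("DBT proj., +2.1", 69.31, -7.20, 0.48),
    ("DBT proj., +4.3", 69.44, -7.35, 0.34),
    ("DBT proj., +7.5", 69.22, -7.10, 0.58),
]

RIGHT_SIDE_VIEWS = [
    ("Mammo., 24x29", 94.14, -8.97, 0.00),
    ("Mammo., 18x24", 67.89, 20.82, 29.79),
    ("DBT proj., -6.4", 89.02, -3.16, 5.81),
    ("DBT proj., -4.3", 90.01, -4.28, 4.69),
    ("DBT proj., -2.1", 92.35, -6.94, 2.03),
    ("DBT proj., 0", 94.40, -9.26, -0.29),
    ("DBT proj., +2.1", 96.21, -11.32, -2.35),
    ("DBT proj., +4.3", 98.59, -14.02, -5.05),
    ("DBT proj., +7.5", 100.15, -15.78, -6.81),
]


@pytest.fixture(scope="session")
def mammo_spectrum():
    """39 kVp W-anode beam with 60 um Ag filtration (mammography setting)."""
    return sf.generate_spectrum(39.0, filters=[("Ag", 60.0)])


@pytest.fixture(scope="session")
def radiographic_spectrum():
    """100 kVp W-anode beam with 2.5 mm Al filtration."""
    return sf.generate_spectrum(100.0, filters=[("Al", 2500.0)])


@pytest.fixture
def scenario_factory(chest_geom):
    """Build a synthetic chest-wall scenario with overridable fields."""

    def make(**kwargs):
        params = dict(geom=chest_geom, x_fov_true=-7.68, seed=0)
        params.update(kwargs)
        return sf.ScenarioConfig(**params)

    return make
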