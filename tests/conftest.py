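import numpy as np
import pytest

from xyfsom import (
    GridSpec,
    TrainingParams,
    TripTable,
    default_fleet_config,
    fit,
    generate_logbook,
)


@pytest.fixture(scope="session")
def small_fleet() -> TripTable:
    """~350-trip default synthetic fleet, shared across tests."""
    return generate_logbook(default_fleet_config(scale=0.05, seed=11))


@pytest.fixture(scope="session")
def toy_table() -> TripTable:
    """Tiny hand-sized logbook: 3 gears x 2 seasons x 2 years, 2 trips/cell."""
    rng = np.random.default_rng(5)
    rows = []
    for gear, base in (("BL", (40.0, 5.0, 0.0)), ("VL", (0.0, 50.0, 5.0)), ("VL_SBL", (5.0, 30.0, 60.0))):
        for season in ("cold", "warm"):
            for year in (2007, 2008):
                for k in range(2):
                    rows.append((gear, season, year, base))
    n = len(rows)
    catch = np.array([r[3] for r in rows]) + rng.uniform(0, 2, size=(n, 3))
    return TripTable(
        trip_id=np.array([f"t{i}" for i in range(n)], dtype=object),
        year=np.array([r[2] for r in rows]),
        season=np.array([r[1] for r in rows], dtype=object),
        gear=np.array([r[0] for r in rows], dtype=object),
        catch=catch,
        species_names=("catfish", "snapper", "shark"),
    )


@pytest.fixture(scope="session")
def toy_map(toy_table):
    """Small trained map on the toy logbook (gear-only classes)."""
    return fit(
        toy_table,
        GridSpec(4, 4),
        TrainingParams(rlen=60, seed=3),
        factors=("gear",),
    )
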