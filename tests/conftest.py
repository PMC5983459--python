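import pytest
from shapely.geometry import box

from agromapa.geo_core import LandraceRecord, Territory
from agromapa.pipeline import run_on_scene
from agromapa.synth_data import worked_fixture

KM = 1000.0


@pytest.fixture(scope="session")
def fixture_scene():
    scene, expected = worked_fixture()
    return scene, expected


@pytest.fixture(scope="session")
def fixture_result(fixture_scene):
    scene, _ = fixture_scene
    return run_on_scene(scene)


@pytest.fixture
def square_territory():
    def make(side_km: float, origin_km: tuple[float, float] = (0.0, 0.0)):
        x0, y0 = origin_km
        return Territory(
            boundary=box(x0 * KM, y0 * KM, (x0 + side_km) * KM, (y0 + side_km) * KM)
        )

    return make


def make_record(rid, landrace, species, x, y):
    return LandraceRecord(rid, landrace, species, float(x), float(y))
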