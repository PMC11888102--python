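import pytest
from hypothesis import settings

import patientcost as pc
from patientcost.geo_model import Authority, Facility, Geography, Region, RoadNetwork

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def params():
    return pc.CostParameters()


@pytest.fixture(scope="session")
def geo_seed1():
    """Default-sized synthetic province, seed 1: 10 urban + 10 rural regions."""
    return pc.generate_synthetic_geography(n_regions=20, urban_fraction=0.5, seed=1)


@pytest.fixture(scope="session")
def travel_seed1(geo_seed1):
    return pc.route_all(geo_seed1)


@pytest.fixture(scope="session")
def agg_seed1(travel_seed1):
    return pc.aggregate_travel(travel_seed1, by="authority")


@pytest.fixture
def tiny_geo():
    """Hand-built 8-node network, 2 facilities, 4 regions; small enough for
    exhaustive path enumeration."""
    net = RoadNetwork()
    coords = {
        "a": (49.00, -123.00),
        "b": (49.00, -122.90),
        "c": (49.05, -122.95),
        "d": (49.05, -122.85),
        "e": (49.10, -122.90),
        "f": (49.10, -123.00),
        "g": (48.95, -122.95),
        "h": (48.95, -123.05),
    }
    for n, (lat, lon) in coords.items():
        net.add_node(n, lat, lon)
    edges = [
        ("a", "b", 9.0, 50), ("a", "c", 8.0, 50), ("b", "c", 8.0, 60),
        ("b", "d", 7.0, 50), ("c", "d", 9.0, 80), ("c", "f", 7.5, 60),
        ("d", "e", 8.0, 80), ("e", "f", 9.5, 50), ("a", "g", 7.0, 80),
        ("g", "h", 9.0, 50),
    ]
    for u, v, l, s in edges:
        net.add_edge(u, v, l, s)
    regions = [
        Region(id="r1", name="R1", authority_id="ha0", class_code=2,
               population=30_000, lat=coords["a"][0], lon=coords["a"][1]),
        Region(id="r2", name="R2", authority_id="ha0", class_code=3,
               population=20_000, lat=coords["e"][0], lon=coords["e"][1]),
        Region(id="r3", name="R3", authority_id="ha1", class_code=6,
               population=2_000, lat=coords["h"][0], lon=coords["h"][1]),
        Region(id="r4", name="R4", authority_id="ha1", class_code=5,
               population=4_000, lat=coords["d"][0], lon=coords["d"][1]),
    ]
    authorities = [
        Authority(id="ha0", name="Auth 0", region_ids=["r1", "r2"]),
        Authority(id="ha1", name="Auth 1", region_ids=["r3", "r4"]),
    ]
    facilities = [
        Facility(id="f1", lat=coords["b"][0], lon=coords["b"][1]),
        Facility(id="f2", lat=coords["f"][0], lon=coords["f"][1]),
    ]
    return Geography(regions, authorities, facilities, net,
                     centroid_nodes={"r1": "a", "r2": "e", "r3": "h", "r4": "d"})
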