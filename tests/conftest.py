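import numpy as np
import pandas as pd
import pytest

from iadfnet.synthetic_data import (
    ARCHETYPES,
    DEFAULT_SPECIES,
    default_scenario,
    generate_climate,
    generate_network,
)
from iadfnet.tree_ring_io import RingSeries, SiteMeta


@pytest.fixture(scope="session")
def small_network():
    """A reduced network (3 sites per archetype) shared across tests."""
    scenario = default_scenario(3)
    return scenario, *generate_network(scenario, 20230729)


@pytest.fixture()
def demo_site():
    return SiteMeta("DEMO", 43.0, 5.0, 400.0, "Testland")


@pytest.fixture()
def demo_climate(demo_site):
    return generate_climate(demo_site, range(1961, 2001), ARCHETYPES["cluster1_humid"], 11)


def make_series(core_id, first_year, widths, flags=None, **kw):
    kw.setdefault("tree_id", core_id)
    kw.setdefault("site_id", "S1")
    kw.setdefault("species_code", "PIHA")
    return RingSeries(
        core_id=core_id, first_year=first_year,
        widths=np.asarray(widths, dtype=float),
        iadf_flags=None if flags is None else np.asarray(flags, dtype=int), **kw,
    )


@pytest.fixture()
def zaga_simulator():
    """Draws (table, true coefficient dict) from the hurdle-gamma model itself."""

    def simulate(seed, n=2000, sigma=0.4, nu=0.3, temp_slope_b=-0.08):
        rng = np.random.default_rng(seed)
        alt = rng.uniform(0, 1500, n)
        lat = rng.uniform(35, 62, n)
        rw = rng.uniform(50, 400, n)
        tp = rng.normal(800, 200, n)
        temp = rng.normal(10, 3, n)
        spei = rng.normal(0, 1, n)
        species = rng.choice(["AA", "BB"], n)
        cluster = rng.choice(["c1", "c2"], n)
        true = {
            "alt": -4e-4,
            "species[BB]": 0.3,
            "tp": 3e-4,
            "tp:species[BB]": -5e-4,
            "temp": 0.08,
            "temp:species[BB]": temp_slope_b,
            "spei": 0.15,
            "spei:species[BB]": -0.15,
            "cluster[c2]": -0.4,
        }
        is_b = species == "BB"
        eta = (
            0.2
            + true["alt"] * (alt - alt.mean())
            + 0.3 * np.sin((lat - 35) / 27 * 2 * np.pi)
            + 0.4 * np.log(rw / 200)
            + true["tp"] * (tp - tp.mean())
            + true["temp"] * (temp - temp.mean())
            + true["spei"] * spei
            + is_b
            * (
                true["species[BB]"]
                + true["tp:species[BB]"] * (tp - tp.mean())
                + true["temp:species[BB]"] * (temp - temp.mean())
                + true["spei:species[BB]"] * spei
            )
            + (cluster == "c2") * true["cluster[c2]"]
        )
        mu = np.exp(eta)
        y = np.where(
            rng.uniform(size=n) < nu, 0.0, rng.gamma(1 / sigma**2, mu * sigma**2)
        )
        table = pd.DataFrame(
            dict(
                site_id="sim", species=species, cluster=cluster, year=2000,
                response=y, alt=alt, lat=lat, rw=rw, tp=tp, temp=temp,
                spei=spei, weight=1.0,
            )
        )
        return table, true

    return simulate
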