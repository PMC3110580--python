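import numpy as np
import pandas as pd
import pytest

import traitgrad as tg
from traitgrad.cli import fixture_config


def make_table(occ_rows, plant_rows, plot_rows, traits=("x",)):
    """Build an OccurrenceTable from plain tuples (test helper)."""
    occ = pd.DataFrame(occ_rows, columns=["species", "plot", "abundance"])
    plants = pd.DataFrame(
        plant_rows, columns=["plant_id", "species", "plot", "site", *traits])
    plants["imputed"] = False
    plots = pd.DataFrame(plot_rows, columns=["plot", "site", "habitat"])
    return tg.OccurrenceTable(occ, plants, plots, trait_names=list(traits))


@pytest.fixture
def three_tip_tree():
    return tg.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def two_plot_table():
    """Worked example: plot p1 holds A (t=2) and B (t=4), plot p2 only A."""
    return make_table(
        [("A", "p1", 1.0), ("B", "p1", 1.0), ("A", "p2", 1.0)],
        [("i1", "A", "p1", "s", 2.0), ("i2", "B", "p1", "s", 4.0),
         ("i3", "A", "p2", "s", 2.0)],
        [("p1", "s", "h1"), ("p2", "s", "h1")],
    )


@pytest.fixture(scope="session")
def fixture_scenario():
    """The packaged 12-species, 6-plot synthetic dataset."""
    return tg.generate_scenario(fixture_config())


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory, fixture_scenario):
    out = tmp_path_factory.mktemp("fixture")
    return tg.write_scenario(fixture_scenario, out)


def random_occurrence_table(rng, n_species=8, n_plots=5):
    """Small random but valid occurrence table with one trait."""
    rows, plant_rows = [], []
    k = 0
    for s in range(n_species):
        plots = rng.choice(n_plots, size=rng.integers(1, n_plots + 1),
                           replace=False)
        for p in plots:
            a = rng.integers(1, 11) / 10.0
            rows.append((f"sp{s}", f"p{p}", a))
            k += 1
            plant_rows.append((f"i{k}", f"sp{s}", f"p{p}", "s",
                               rng.normal()))
    plot_rows = [(f"p{p}", "s", "h") for p in range(n_plots)]
    return make_table(rows, plant_rows, plot_rows)
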