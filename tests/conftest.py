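import logging

import numpy as np
import pandas as pd
import pytest

from periltools.simulate import SimConfig, simulate_fauna, simulate_tree
from periltools.types import ShelfGrid, SpeciesRecord

# validation chatter (rejected rows, dropped intervals) is exercised on purpose
logging.getLogger("periltools").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def balanced_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — the smallest tree with sister structure."""
    from periltools.treeutils import FamilyTree

    return FamilyTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def sim_tree64():
    return simulate_tree(64, seed=5)


@pytest.fixture(scope="session")
def small_grid():
    """4 x 3 grid of 50 km cells with a monotone SST gradient along y."""
    rows = []
    for j in range(3):
        for i in range(4):
            rows.append(
                {
                    "cell_id": f"c{i}_{j}",
                    "cx": (i + 0.5) * 50.0,
                    "cy": (j + 0.5) * 50.0,
                    "sst_mean": 28.0 - 2.0 * j,
                    "climate_zone": None,
                    "region": None,
                }
            )
    return ShelfGrid(pd.DataFrame(rows), cell_size_km=50.0)


@pytest.fixture(scope="session")
def fauna_medium():
    """One fauna reused across tests: 600 species, 40 families, default effects."""
    cfg = SimConfig(seed=11, n_species=600, n_families=40)
    tree = simulate_tree(40, 11)
    records, occ, grid, truth = simulate_fauna(cfg, tree)
    return {"cfg": cfg, "tree": tree, "records": records, "occ": occ,
            "grid": grid, "truth": truth}


def make_records(qhats, areas, trs, exploited=None, families=None, **kw):
    """Minimal species records from parallel trait lists."""
    n = len(qhats)
    exploited = exploited or [False] * n
    families = families or [f"F{i}" for i in range(n)]
    return [
        SpeciesRecord(
            species_id=f"s{i}",
            family=families[i],
            exploited=exploited[i],
            qhat=qhats[i],
            geographic_range_area=areas[i],
            thermal_range=trs[i],
            **kw,
        )
        for i in range(n)
    ]
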