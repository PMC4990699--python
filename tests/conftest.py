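import logging

import numpy as np
import pandas as pd
import pytest

from kinflux.io_formats import RatioTable
from kinflux.simulate import SimConfig

logging.disable(logging.INFO)

CONTRAST = "treat_vs_ctrl"


def make_ratio_table(replicates, contrast=CONTRAST, residues=None):
    """Build a RatioTable from a list of per-site replicate tuples."""
    n_rep = max(len(r) for r in replicates)
    rows = []
    for i, reps in enumerate(replicates):
        row = {
            "protein": f"P{i + 1:03d}",
            "position": 10 + i,
            "residue": (residues[i] if residues else "S"),
            "window": "near-terminus",
        }
        for j in range(n_rep):
            row[f"{contrast}_r{j + 1}"] = (
                reps[j] if j < len(reps) and reps[j] is not None else np.nan
            )
        rows.append(row)
    return RatioTable(df=pd.DataFrame(rows), contrasts=[contrast], n_replicates=n_rep)


@pytest.fixture
def sim_config():
    return SimConfig(seed=7)


@pytest.fixture
def phospho_study(sim_config):
    """A small simulated phospho experiment with aggregated statistics."""
    from kinflux.ratio_stats import add_site_statistics, compute_experiment_stats
    from kinflux.simulate import gen_kinase_map, gen_phospho_experiment, gen_proteome

    proteome, catalogue = gen_proteome(sim_config)
    kmap = gen_kinase_map(catalogue)
    table, truth = gen_phospho_experiment(sim_config, kmap, catalogue)
    table = add_site_statistics(table)
    stats = compute_experiment_stats(table, CONTRAST)
    return {
        "proteome": proteome,
        "catalogue": catalogue,
        "kmap": kmap,
        "table": table,
        "truth": truth,
        "stats": stats,
    }
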