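import warnings

import numpy as np
import pytest

import rockisc as rk
from rockisc import celltype, preprocess, syndata, trajectory
from rockisc.matrix import concat_cells

warnings.filterwarnings("ignore", message="principal curve did not converge")


@pytest.fixture(scope="session")
def small_config():
    return rk.SimulationConfig(n_cells_per_sample=500, n_genes=400, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return rk.simulate_study(small_config)


@pytest.fixture(scope="session")
def control_sample(small_study):
    return small_study["Control-6D-"]


@pytest.fixture(scope="session")
def treatment_pair_state():
    """Fully preprocessed treatment pair at the default study conditions:
    QC, Pearson residuals, cell-cycle regression, HVG/PCA, donor
    integration and EM typing, shared across tests."""
    sim = rk.SimulationConfig(seed=5)
    samples = {}
    for cls in ("Control-6D-", "ROCKi-6D+"):
        em, _ = syndata.simulate_sample(sim, cls)
        samples[cls], _ = rk.run_qc(em)
    m = concat_cells([samples[c] for c in samples])
    nm = preprocess.pearson_normalize(m)
    logx = preprocess.log_normalize(m)
    s_genes, g2m_genes = syndata.cell_cycle_gene_sets()
    cc = preprocess.cell_cycle_scores(logx, m.gene_symbols, s_genes, g2m_genes,
                                      seed=0)
    nm = preprocess.regress_out(nm, cc["cc_difference"].to_numpy())
    hvg = preprocess.select_hvg(nm, 500)
    emb = preprocess.run_pca(nm, hvg, n_components=30, seed=0)
    emb = preprocess.integrate_donors(emb, seed=0)
    assignment = celltype.classify_em(nm, seed=0)
    return dict(matrix=m, nm=nm, embedding=emb, assignment=assignment,
                samples=m.cell_meta["sample"].to_numpy(),
                true_type=m.cell_meta["true_type"].to_numpy(),
                true_pt=m.cell_meta["true_pseudotime"].to_numpy())
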