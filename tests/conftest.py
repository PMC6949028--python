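import numpy as np
import pandas as pd
import pytest

from scplacenta import (RunConfig, ScSimConfig, BulkSimConfig, simulate_sc_dataset,
                        simulate_bulk_longitudinal, simulate_bulk_crosssection,
                        filter_cells_genes, log_normalize)


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def sc_default(cfg):
    """Default-condition single-cell simulation with truth and labels."""
    adata, truth = simulate_sc_dataset(ScSimConfig(seed=11))
    labels = truth.cells.set_index("barcode")["true_cluster"]
    return adata, truth, labels


@pytest.fixture(scope="session")
def sc_filtered(sc_default, cfg):
    adata, truth, labels = sc_default
    filtered, report = filter_cells_genes(adata, cfg)
    return filtered, truth, labels.reindex(filtered.obs["barcode"]), report


@pytest.fixture(scope="session")
def sc_normalized(sc_filtered, cfg):
    filtered, truth, labels, _ = sc_filtered
    return log_normalize(filtered, cfg), truth, labels


@pytest.fixture(scope="session")
def bulk_longitudinal():
    return simulate_bulk_longitudinal(BulkSimConfig(seed=21))


@pytest.fixture(scope="session")
def bulk_crosssection():
    return simulate_bulk_crosssection(BulkSimConfig(seed=22, design="crosssection_preterm"))


def truth_signature_frames(truth):
    """GroundTruth signature gene sets as the dict-of-frames signature format."""
    return {s: pd.DataFrame({"gene_id": genes, "log_fc": np.nan})
            for s, genes in truth.signature_genes.items()}
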