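import numpy as np
import pandas as pd
import pytest

from isoplex import (
    CellMetadata,
    CountMatrix,
    TranscriptInfo,
    compute_all_metrics,
    create_scht,
    generate_dataset,
    preset_scenarios,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_iso_matrix():
    """6 isoforms of 3 genes x 8 cells, hand-countable raw matrix."""
    counts = np.array(
        [
            [5, 0, 3, 0, 2, 1, 0, 4],   # GA-I1
            [1, 2, 0, 0, 3, 0, 0, 2],   # GA-I2
            [0, 4, 4, 1, 0, 2, 3, 0],   # GB-I1
            [2, 2, 0, 3, 1, 0, 2, 1],   # GB-I2
            [0, 0, 1, 0, 0, 0, 0, 0],   # GB-I3
            [3, 1, 2, 2, 4, 3, 1, 2],   # GC-I1 (single-isoform gene)
        ],
        dtype=float,
    )
    cells = [f"c{i}" for i in range(8)]
    features = ["GA-I1", "GA-I2", "GB-I1", "GB-I2", "GB-I3", "GC-I1"]
    return CountMatrix.from_dense(counts, features, cells)


@pytest.fixture()
def tiny_info():
    return TranscriptInfo(
        pd.DataFrame(
            {
                "transcript_id": ["GA-I1", "GA-I2", "GB-I1", "GB-I2", "GB-I3", "GC-I1"],
                "gene_id": ["GA", "GA", "GB", "GB", "GB", "GC"],
                "gene_name": ["GeneA", "GeneA", "GeneB", "GeneB", "GeneB", "GeneC"],
            }
        )
    )


@pytest.fixture()
def tiny_meta():
    cells = [f"c{i}" for i in range(8)]
    return CellMetadata(pd.Series(["T0"] * 4 + ["T1"] * 4, index=cells))


@pytest.fixture(scope="session")
def quadrants_run():
    """One full pipeline run on the quadrants preset (shared across tests)."""
    cfg = preset_scenarios(seed=11)["quadrants"]
    gene, iso, meta, info, truth = generate_dataset(cfg)
    scht, run_log = create_scht(gene, iso, info, meta)
    table = compute_all_metrics(scht)
    return {
        "config": cfg,
        "gene": gene,
        "iso": iso,
        "meta": meta,
        "info": info,
        "truth": truth,
        "scht": scht,
        "run_log": run_log,
        "table": table,
    }
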