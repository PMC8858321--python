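import numpy as np
import pandas as pd
import pytest

import senescreen as ss


@pytest.fixture(scope="session")
def small_lib() -> ss.SgRNALibrary:
    """40 genes x 5-6 guides + 30 controls; deterministic."""
    return ss.generate_library(40, (5, 6), 30, seed=42)


@pytest.fixture(scope="session")
def planted_screen(small_lib):
    """A small screen with three planted bypass genes and its enrichment table."""
    bypass = frozenset(small_lib.genes[:3])
    truth = ss.ScreenTruth(bypass_genes=bypass, efficacy=0.95)
    cfg = ss.SimConfig(depth_per_sgrna=300, n_replicates=2, seed=7)
    counts, _ = ss.simulate_screen(small_lib, truth, cfg)
    table = ss.enrichment_table(counts, small_lib)
    return {"lib": small_lib, "bypass": bypass, "counts": counts, "table": table}
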