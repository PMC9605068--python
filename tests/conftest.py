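from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from orbiscan.model import (
    CountMatrix,
    PanelDefinition,
    Probe,
    ProbeClass,
    Stage,
)


@pytest.fixture
def small_panel() -> PanelDefinition:
    """4 endogenous, 2 housekeeping, 2 positive, 3 negative probes."""
    return PanelDefinition((
        Probe("GENE_A", ProbeClass.ENDOGENOUS),
        Probe("GENE_B", ProbeClass.ENDOGENOUS),
        Probe("GENE_C", ProbeClass.ENDOGENOUS),
        Probe("GENE_D", ProbeClass.ENDOGENOUS),
        Probe("HK_01", ProbeClass.HOUSEKEEPING),
        Probe("HK_02", ProbeClass.HOUSEKEEPING),
        Probe("POS_A(128)", ProbeClass.POSITIVE, 128.0),
        Probe("POS_B(32)", ProbeClass.POSITIVE, 32.0),
        Probe("NEG_01", ProbeClass.NEGATIVE),
        Probe("NEG_02", ProbeClass.NEGATIVE),
        Probe("NEG_03", ProbeClass.NEGATIVE),
    ))


def random_raw_matrix(
    panel: PanelDefinition, n_samples: int, rng: np.random.Generator
) -> CountMatrix:
    """Random RAW matrix over a panel: negatives at background scale,
    everything else well above it (so the normalization chain is well-posed)."""
    neg = set(panel.names(ProbeClass.NEGATIVE))
    rows = []
    for name in panel.names():
        if name in neg:
            rows.append(rng.integers(1, 30, size=n_samples))
        else:
            rows.append(rng.integers(500, 5000, size=n_samples))
    values = pd.DataFrame(
        np.array(rows, dtype=float),
        index=panel.names(),
        columns=[f"S{i + 1:02d}" for i in range(n_samples)],
    )
    return CountMatrix(values, Stage.RAW, panel)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20221020)
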