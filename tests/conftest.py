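import numpy as np
import pandas as pd
import pytest

import phenoscreen as ps


@pytest.fixture(scope="session")
def vocab():
    return ps.default_vocabulary()


@pytest.fixture(scope="session")
def noiseless_screen():
    """30-chemical noiseless screen with planted truth, run end to end."""
    cfg = ps.PipelineConfig(seed=101)
    wells, truth = ps.generate_screen(cfg, n_chemicals=30, noise_sd=0.0,
                                      seed=101)
    hist = ps.generate_historical_controls(noise_sd=0.0, seed=102)
    result = ps.run_pipeline(cfg, wells, hist, None)
    return cfg, wells, truth, result


@pytest.fixture(scope="session")
def zero_envelope(vocab):
    """Degenerate (0, 0) envelope for every endpoint: any non-zero value is
    significant.  Matches what noiseless historical controls produce."""
    bounds = pd.DataFrame(
        {"lower": 0.0, "upper": 0.0},
        index=pd.Index(vocab.endpoint_ids, name="endpoint_id"),
    )
    return ps.HistoricalEnvelope(bounds, 0.95)


def profile_matrix(rows: dict[tuple[str, float], dict[str, float]],
                   endpoints: list[str]) -> ps.ProfileMatrix:
    """Build a small ProfileMatrix from {(sample, conc): {endpoint: value}}."""
    data = [
        [vals.get(e, 0.0) for e in endpoints] for vals in rows.values()
    ]
    index = pd.MultiIndex.from_tuples(list(rows.keys()),
                                      names=["sample_id", "concentration"])
    return ps.ProfileMatrix(pd.DataFrame(data, index=index, columns=endpoints))
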