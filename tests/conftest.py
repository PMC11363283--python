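import datetime as dt

import numpy as np
import pytest

from dielpath.dataio import SampleGrid, TranscriptSeries, make_diel_grid


@pytest.fixture
def grid13() -> SampleGrid:
    """2-h sampling over 24 h (13 timepoints), dawn 06:00 / dusk 18:00."""
    return make_diel_grid(dt.datetime(2015, 3, 20, 6), condition="sun", season="March")


def series_from_log2(grid: SampleGrid, log2_levels, n_reps: int = 6,
                     obs_sd: float = 0.0, seed: int = 0,
                     gene: str = "g") -> TranscriptSeries:
    """Build a TranscriptSeries from latent log2 levels plus replicate noise."""
    rng = np.random.default_rng(seed)
    lv = np.asarray(log2_levels, dtype=float)
    y = lv[:, None] + rng.normal(0.0, obs_sd, (len(lv), n_reps))
    return TranscriptSeries(gene, grid, np.ma.asarray(2.0**y))


@pytest.fixture
def series_builder():
    return series_from_log2
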