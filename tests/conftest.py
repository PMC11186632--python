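import numpy as np
import pandas as pd
import pytest

import pclong as pl


@pytest.fixture(scope="session")
def demo_repertoire():
    """Small multi-mouse repertoire with spiked public clones."""
    cfg = pl.RepertoireSimConfig(
        n_mice=3, n_clones_per_sample=80, reads_per_sample=1600,
        n_public_clones=10, seed=42,
    )
    rows, meta, public_keys = pl.gen_repertoire(cfg)
    return rows, meta, public_keys


def build_all_samples(rows: pd.DataFrame, meta: pd.DataFrame, **kwargs):
    samples = []
    for m in meta.sort_values("sample_id").itertuples():
        samples.append(
            pl.build_clones(
                rows[rows["sample_id"] == m.sample_id],
                sample_id=m.sample_id,
                mouse_id=m.mouse_id,
                subset=m.subset,
                tissue=m.tissue,
                **kwargs,
            )
        )
    return samples


@pytest.fixture(scope="session")
def demo_samples(demo_repertoire):
    rows, meta, _ = demo_repertoire
    return build_all_samples(rows, meta)


def make_track(positions, dt=3.0, yfp=100.0, tomato=100.0, track_id="t0", **meta):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    return pl.Track(
        track_id=track_id,
        t=np.arange(n) * dt,
        positions=positions,
        ch_yfp=np.full(n, yfp),
        ch_tomato=np.full(n, tomato),
        metadata=meta,
    )
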