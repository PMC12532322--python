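"""Shared fixtures: cached desk-scale end-to-end runs.

The desk preset (600 cells, 300 genes, 600 peaks, 3 cell types) trains
the full pipeline on one CPU in a few minutes; runs are cached per seed
at session scope so the integration-level tests can share them.
"""

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

DESK = dict(n_cells=600, n_genes=300, n_peaks=600, n_types=3)
DESK_SEEDS = (0, 1, 2)


def _run_desk(seed: int) -> SimpleNamespace:
    from attune.data_model import preprocess
    from attune.decoder import (DecoderConfig, compute_global_attention,
                                train_decoder)
    from attune.encoders import EncoderParams
    from attune.pretrain import (ContrastiveConfig, compute_embeddings,
                                 train_pretrain)
    from attune.synthetic import generate_multiome

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, truth = generate_multiome(seed=seed, **DESK)
        proc = preprocess(ds)
        random_params = EncoderParams.init(len(proc.genes), len(proc.peaks),
                                           seed=seed)
        emb_random = compute_embeddings(random_params, proc)
        params, history = train_pretrain(proc, ContrastiveConfig(epochs=20,
                                                                 seed=seed))
        emb = compute_embeddings(params, proc)
        dec, dec_history = train_decoder(params, proc, DecoderConfig(seed=seed))
        attn = compute_global_attention(params, dec, proc)
    return SimpleNamespace(dataset=ds, truth=truth, proc=proc, params=params,
                           history=history, emb=emb, emb_random=emb_random,
                           dec=dec, dec_history=dec_history, attn=attn)


@pytest.fixture(scope="session")
def desk_runs():
    """Memoized accessor: desk_runs(seed) -> full pipeline artifacts."""
    cache: dict[int, SimpleNamespace] = {}

    def get(seed: int) -> SimpleNamespace:
        if seed not in cache:
            cache[seed] = _run_desk(seed)
        return cache[seed]

    return get
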