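"""Tiny helper: hand-built PosteriorDraws for closed-form oracle tests."""

import numpy as np

from credsurv.model import PosteriorDraws


def make_draws(h, cutpoints, beta=None, n_prognostic=0):
    h = np.atleast_2d(np.asarray(h, dtype=float))
    M = h.shape[0]
    beta = np.zeros((M, 0)) if beta is None else np.atleast_2d(np.asarray(beta, float))
    return PosteriorDraws(
        beta=beta,
        h={0: h},
        cutpoints=np.asarray(cutpoints, dtype=float),
        column_names=tuple(f"b{i}" for i in range(beta.shape[1])),
        n_prognostic=n_prognostic,
        stratified=False,
        acceptance={"beta": np.ones(beta.shape[1]), "h": {0: np.ones(h.shape[1])}},
        seed=0,
        burn_in=0,
        thin=1,
    )
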