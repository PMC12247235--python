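"""Shared helpers for the test suite."""

import numpy as np

from medbias.weat import WeatInputs


def random_weat_inputs(rng: np.random.Generator, n=3, m=4, dim=10) -> WeatInputs:
    """Random continuous vector sets; zero-norm rows are essentially impossible."""
    return WeatInputs(
        X=rng.standard_normal((n, dim)),
        Y=rng.standard_normal((n, dim)),
        A=rng.standard_normal((m, dim)),
        B=rng.standard_normal((m, dim)),
    )
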