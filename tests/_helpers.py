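"""Small shared test utilities."""

import numpy as np


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / (a.sum() + b.sum())
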