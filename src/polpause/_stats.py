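"""Small shared numerics."""

from __future__ import annotations

import numpy as np


def pearson_rows(matrix: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``matrix`` with ``y``.

    Rows (or ``y``) with zero variance yield NaN rather than raising.
    """
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    y = np.asarray(y, dtype=float)
    mc = m - m.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = mc @ yc
    den = np.sqrt((mc * mc).sum(axis=1) * (yc * yc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den
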