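"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def ttest_unpaired(sample_a, sample_b) -> dict[str, float]:
    """Classical two-sided unpaired Student's t-test (equal variances).

    Edge convention when the pooled variance is zero: equal means give
    ``t = 0, p = 1``; unequal means give ``t = +/-inf, p = 0``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    pooled_var = (
        ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    ) / (a.size + b.size - 2)
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0}
        return {"t": float(np.sign(a.mean() - b.mean()) * np.inf), "p": 0.0}
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "p": float(p)}
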