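"""Built-in worked-example data.

The Anscombe (1973) quartet: four bivariate samples of n = 11 sharing
identical first-order statistics (mean(x) = 9, var(x) = 11, mean(y) = 7.5,
var(y) ~ 4.12, Pearson r ~ 0.82) while differing completely in structure —
the canonical demonstration of why correlations must be inspected for
linearity and outliers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["anscombe"]

_ANSCOMBE_X = (10.0, 8.0, 13.0, 9.0, 11.0, 14.0, 6.0, 4.0, 12.0, 7.0, 5.0)

_ANSCOMBE = {
    1: (_ANSCOMBE_X,
        (8.04, 6.95, 7.58, 8.81, 8.33, 9.96, 7.24, 4.26, 10.84, 4.82, 5.68)),
    2: (_ANSCOMBE_X,
        (9.14, 8.14, 8.74, 8.77, 9.26, 8.10, 6.13, 3.10, 9.13, 7.26, 4.74)),
    3: (_ANSCOMBE_X,
        (7.46, 6.77, 12.74, 7.11, 7.81, 8.84, 6.08, 5.39, 8.15, 6.42, 5.73)),
    4: ((8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 19.0, 8.0, 8.0, 8.0),
        (6.58, 5.76, 7.71, 8.84, 8.47, 7.04, 5.25, 12.50, 5.56, 7.91, 6.89)),
}


def anscombe() -> list[tuple[np.ndarray, np.ndarray]]:
    """Return the four Anscombe pairs as ``[(x1, y1), ..., (x4, y4)]``.

    Pair 1 is close to bivariate normal; pair 2 is a noiseless parabola
    (non-linear, non-monotonic); pair 3 is an exact line plus one marginal
    outlier; pair 4 has ten identical x-values plus one bivariate outlier
    at (19, 12.5).
    """
    return [(np.array(x), np.array(y)) for x, y in _ANSCOMBE.values()]
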