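"""Independent brute-force oracles shared by test modules."""

import numpy as np


def exhaustive_thresholded_maxima(values: np.ndarray) -> int:
    """Loop-based count of strict 8-neighbour maxima above the 75th
    percentile (top-quartile thresholding)."""
    q75 = np.percentile(values, 75)
    v = np.where(values >= q75, values, 0.0)
    n1, n2 = v.shape
    count = 0
    for i in range(n1):
        for j in range(n2):
            if v[i, j] <= 0:
                continue
            is_max = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < n1 and 0 <= b < n2 and values[a, b] >= v[i, j]:
                        is_max = False
            if is_max:
                count += 1
    return count
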