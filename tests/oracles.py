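"""Independent reference implementations used only to check the package.

These deliberately avoid the KD-tree / difference-array machinery of the
implementation: distances are recomputed per centre, ranges evaluated one at
a time, contingency tables tallied by explicit case enumeration.
"""

import numpy as np


def khat_border_bruteforce(xy, side, h_values):
    """Border-corrected K by a per-centre double loop.

    Closed-ball neighbours (d <= h), strictly interior centres (bd > h),
    λ̂ = n/|A| with the full-window count n.  Returns (khat, n_centers);
    khat is NaN where no centre is eligible.
    """
    xy = np.asarray(xy, float)
    n = xy.shape[0]
    area = side * side
    bd = np.minimum(np.minimum(xy[:, 0], side - xy[:, 0]),
                    np.minimum(xy[:, 1], side - xy[:, 1]))
    khat, n_centers = [], []
    for h in h_values:
        total, m = 0, 0
        for i in range(n):
            if bd[i] > h:
                m += 1
                d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
                total += int((d <= h).sum()) - 1  # exclude the centre itself
        khat.append(area / n * total / m if m > 0 else np.nan)
        n_centers.append(m)
    return np.array(khat), np.array(n_centers)


def dhat_bruteforce(pattern, h_values):
    side = pattern.window.side_length
    kc, _ = khat_border_bruteforce(pattern.xy[pattern.is_case], side, h_values)
    kk, _ = khat_border_bruteforce(pattern.xy[~pattern.is_case], side, h_values)
    return kc - kk


def phi_from_table(a, b, c, d):
    """Phi coefficient from the 2×2 contingency table (a, b; c, d)."""
    num = a * d - b * c
    den = np.sqrt(float((a + b) * (c + d) * (a + c) * (b + d)))
    return num / den
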