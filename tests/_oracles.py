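"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_otsu(hu_int):
    """Try every cut between adjacent occupied integer bins, compute the
    between-class variance explicitly, keep the best (lowest on ties);
    returns the midpoint of the two occupied values the cut separates."""
    hu_int = np.asarray(hu_int).ravel()
    occupied = np.unique(hu_int)
    best_thr, best_var = None, -1.0
    for k in range(len(occupied) - 1):
        cut = occupied[k]  # classes: <= cut, > cut
        left = hu_int[hu_int <= cut]
        right = hu_int[hu_int > cut]
        var = left.size * right.size * (left.mean() - right.mean()) ** 2
        if var > best_var + 1e-9:
            best_var = var
            best_thr = (occupied[k] + occupied[k + 1]) / 2.0
    return best_thr


def pairwise_auc(values, labels, positive="copd"):
    """Mean over all (case, control) pairs of 1[case > control], ties
    counting one half."""
    cases = [v for v, l in zip(values, labels) if l == positive]
    controls = [v for v, l in zip(values, labels) if l != positive]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))
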