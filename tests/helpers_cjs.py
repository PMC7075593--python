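"""Independent CJS oracle: per-history likelihood by fate enumeration.

Computes Pr(history | first release) by summing over unobserved death
times, never touching the package's m-array code path.
"""

import numpy as np


def history_log_likelihood(histories, phi, p):
    """Sum of per-history CJS log-likelihoods for scalar phi, p."""
    ll = 0.0
    for h in histories:
        h = np.asarray(h, dtype=int)
        seen = np.flatnonzero(h)
        first, last = seen[0], seen[-1]
        t = len(h)
        pr = 1.0
        for j in range(first, last):  # alive throughout, detections known
            pr *= phi
            pr *= p if h[j + 1] else (1 - p)
        chi = 1.0  # Pr(never seen after `last`), built backwards
        for _ in range(t - 1 - last):
            chi = (1 - phi) + phi * (1 - p) * chi
        ll += np.log(pr * chi)
    return ll


def enumerate_toy_histories(t, rng, n):
    """n random non-empty detection histories over t occasions."""
    out = []
    while len(out) < n:
        h = rng.integers(0, 2, t)
        if h.sum() > 0:
            out.append(h)
    return out
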