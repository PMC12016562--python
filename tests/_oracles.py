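"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_auroc(labels, scores):
    """All-pairs Mann–Whitney AUROC; ties count half a win."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
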