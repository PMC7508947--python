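"""Shared fixtures and helpers for the test suite."""

import numpy as np
import pytest

from optoplaque import synth


def match_particles(ground_truth, particles, max_dist_px=6.0):
    """Greedy one-to-one matching of detected particles to ground-truth blobs.

    Returns (n_matched, n_missed, n_spurious).
    """
    truth = list(zip(ground_truth["y_px"], ground_truth["x_px"]))
    remaining = list(particles)
    matched = 0
    for ty, tx in truth:
        best, best_d = None, np.inf
        for p in remaining:
            d = np.hypot(p.centroid_rc[0] - ty, p.centroid_rc[1] - tx)
            if d < best_d:
                best, best_d = p, d
        if best is not None and best_d <= max_dist_px:
            matched += 1
            remaining.remove(best)
    return matched, len(truth) - matched, len(remaining)


@pytest.fixture(scope="session")
def default_micrograph():
    """One synthetic micrograph with defaults, plus ground truth."""
    return synth.generate_micrograph(synth.SynthImageParams(seed=42))
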