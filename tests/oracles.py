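"""Independent brute-force oracles used by the test suite."""

import itertools

import numpy as np

from dopseqkit.detect import SpacingModel, _log_emissions


def brute_force_path(gaps, model: SpacingModel, switch_penalty: float) -> np.ndarray:
    """Exhaustive enumeration of all 2^n state paths; returns the best one.

    Scores each path by initial-state probability (mixture weights), the
    symmetric switch penalty, and the exponential emission densities — the
    same objective the dynamic program optimizes, computed independently.
    """
    gaps = np.asarray(gaps, dtype=float)
    emis = _log_emissions(gaps, model)
    init = np.array([np.log(model.mixing_weight), np.log1p(-model.mixing_weight)])
    log_stay = np.log1p(-switch_penalty)
    log_switch = np.log(switch_penalty)
    best, best_ll = None, -np.inf
    for path in itertools.product([0, 1], repeat=len(gaps)):
        ll = init[path[0]] + emis[0, path[0]]
        for i in range(1, len(gaps)):
            ll += (log_stay if path[i] == path[i - 1] else log_switch) + emis[i, path[i]]
        if ll > best_ll:
            best_ll, best = ll, path
    return np.array(best, dtype=np.int8)
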