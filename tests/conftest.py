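import numpy as np
import pytest

from vns_chrono import (
    default_subject,
    detect_r_peaks,
    extract_responses,
    lhs_sample,
    simulate_experiment,
)
from vns_chrono.io import ranges_for


def match_peaks(truth: np.ndarray, detected: np.ndarray, tol_s: float):
    """Greedy one-to-one matching of detected peaks to truth within ±tol.

    Returns (n_matched, n_truth, n_detected).  Sensitivity is
    matched/truth, positive predictivity matched/detected.
    """
    truth = np.asarray(truth)
    used = np.zeros(len(truth), dtype=bool)
    matched = 0
    for t in detected:
        i = np.searchsorted(truth, t)
        best, bd = -1, tol_s
        for j in (i - 1, i):
            if 0 <= j < len(truth) and not used[j] and abs(truth[j] - t) <= bd:
                best, bd = j, abs(truth[j] - t)
        if best >= 0:
            used[best] = True
            matched += 1
    return matched, len(truth), len(detected)


@pytest.fixture(scope="session")
def vagotomy_subject_run():
    """One vagotomized subject through the full ECG-level pipeline.

    Shared across test modules to avoid repeating the ~3 s simulation.
    """
    design = lhs_sample(ranges_for("vagotomy"), 40, seed=5)
    model = default_subject("vagotomy", seed=5)
    sim = simulate_experiment(model, design, seed=5)
    peaks = detect_r_peaks(sim.recording)
    onsets = [t for t, _ in sim.recording.stim_events]
    responses = extract_responses(peaks, design, onsets)
    return {
        "design": design,
        "model": model,
        "sim": sim,
        "peaks": peaks,
        "responses": responses,
    }
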