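import numpy as np
import pytest

import camdce


@pytest.fixture(scope="session")
def noisefree_study():
    """Default synthetic study without noise, with its ground truth."""
    cfg = camdce.SyntheticConfig(snr_db=None, seed=7)
    return camdce.generate_synthetic_study(cfg)


@pytest.fixture(scope="session")
def noisy_study():
    """Default synthetic study at 30 dB SNR, with its ground truth."""
    cfg = camdce.SyntheticConfig(snr_db=30.0, seed=7)
    return camdce.generate_synthetic_study(cfg)


@pytest.fixture(scope="session")
def processed_noisefree(noisefree_study):
    series, truth = noisefree_study
    processed, report = camdce.preprocess(series, mask=truth.mask)
    return processed, report, truth


@pytest.fixture(scope="session")
def processed_noisy(noisy_study):
    series, truth = noisy_study
    processed, report = camdce.preprocess(series, mask=truth.mask)
    return processed, report, truth


def truth_basis_processed(truth, drop_frames: int = 4) -> np.ndarray:
    """True compartment curves on the retained frames, sum-normalized."""
    basis = truth.basis[drop_frames:]
    return basis / basis.sum(axis=0, keepdims=True)


def pure_pixel_curves(processed, report, truth):
    """Mean pure-pixel curve per compartment, sum-normalized.

    This is the estimation protocol of the validation design: parameters
    are recovered from the time-courses of designated pure-volume pixels.
    """
    pos = {orig: col for col, orig in enumerate(report.retained_index)}
    curves = []
    for idx in truth.pure_pixel_index:
        cols = [pos[i] for i in idx if i in pos]
        assert cols, "pure pixels must survive preprocessing"
        curve = processed.values[:, cols].mean(axis=1)
        curves.append(curve / curve.sum())
    return curves
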