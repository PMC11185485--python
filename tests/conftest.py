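import numpy as np
import pytest

from neuropipe import synth
from neuropipe.design import StimulusDesign


@pytest.fixture(scope="session")
def visual_design() -> StimulusDesign:
    return synth.gen_stimulus_design("visual_block", seed=0)


@pytest.fixture(scope="session")
def opto_ephys_design() -> StimulusDesign:
    return synth.gen_stimulus_design("opto_ephys", seed=0)


@pytest.fixture(scope="session")
def short_tastant_design() -> StimulusDesign:
    """5 tastant trials of 2 s with a compressed 10-s ISI (keeps video small)."""
    return synth.gen_tastant_design("quinine", n_trials=5, trial_s=2.0,
                                    isi_s=10.0, baseline_s=10.0)


def hand_pearson(x, y):
    """Textbook Pearson correlation, independent of the library helpers."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def hand_bh(p, alpha):
    """Benjamini-Hochberg step-up, written from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= alpha * (np.arange(1, m + 1) / m)
    k = np.flatnonzero(below).max() + 1 if below.any() else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject
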