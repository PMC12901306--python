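import numpy as np
import pytest

import seqsampler as ss


@pytest.fixture(scope="session")
def space():
    return ss.build_colour_space()


@pytest.fixture(scope="session")
def small_guess_design(space):
    """24 GUESS sequences in 4 blocks — the workhorse for fitting tests."""
    cfg = ss.DatasetConfig("mini-guess", (ss.GUESS,), 24, 4, "option")
    return ss.generate_experiment(cfg, rng=11, space=space)


@pytest.fixture(scope="session")
def small_two_condition_design(space):
    cfg = ss.DatasetConfig("mini-two", (ss.MATCH, ss.GUESS), 12, 4, "option")
    return ss.generate_experiment(cfg, rng=13, space=space)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sequence(space, rng, length=None, no_zero_revisit=False):
    """A random (choices, shades, c_tar) triple on the colour grid.

    ``no_zero_revisit=True`` redraws until no previously-chosen option sits at
    exactly zero accumulated evidence when it could be revisited (the
    knife-edge state where the initial phase triggers for any positive
    threshold draw).
    """
    while True:
        L = int(length or rng.choice(ss.SEQUENCE_LENGTHS))
        choices = rng.integers(1, 3, L)
        shades = rng.choice(space.shades, L)
        c_tar = int(rng.choice([-1, 0, 1]))
        if not no_zero_revisit:
            return choices, shades, c_tar
        xhat = np.zeros(2)
        ok = True
        for t in range(L):
            if t >= 1 and abs(xhat[choices[t - 1] - 1]) < 1e-9:
                ok = False
                break
            xhat[choices[t] - 1] += space.loglr_scale * shades[t]
        if ok:
            return choices, shades, c_tar
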