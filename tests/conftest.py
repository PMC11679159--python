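import numpy as np
import pytest

import lagfoci as lf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_channel_rec(rng):
    """Independent white-noise pair at 100 Hz, 60 s."""
    data = rng.standard_normal((2, 6000))
    return lf.Recording(["A", "B"], data, 100.0)


@pytest.fixture
def delayed_pair_rec():
    """Noiseless pure-delay pair: B repeats A after exactly 30 ms (100 Hz)."""
    cfg = lf.SynthConfig(
        channels=lf.ElectrodeArray(["A", "B"], [[0, 0, 0], [30, 0, 0]]),
        sources=[lf.SourceSpec(position=(0, 0, 0), waveform="bandlimited_noise")],
        duration_s=20.0,
        rate=100.0,
        model=lf.PropagationModel(velocity=1.0),  # 30 mm -> 30 ms
        noise_sd_uv=0.0,
        seed=7,
    )
    rec, _ = lf.generate_recording(cfg)
    return rec


def naive_lagged_r(p, q, shift):
    """Double-loop evaluation of the lagged product-moment coefficient.

    Independent oracle: computes the means and the three sums explicitly
    over the aligned pairs (p_i, q_{i+shift}).
    """
    n = min(len(p), len(q) - shift)
    pm = sum(p[i] for i in range(n)) / n
    qm = sum(q[i + shift] for i in range(n)) / n
    num = sum((p[i] - pm) * (q[i + shift] - qm) for i in range(n)) / n
    vp = sum((p[i] - pm) ** 2 for i in range(n)) / n
    vq = sum((q[i + shift] - qm) ** 2 for i in range(n)) / n
    return num / (vp**0.5 * vq**0.5)
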