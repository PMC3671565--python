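import numpy as np
import pytest

import sarcfit as sf


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def sine43():
    """The reference working input: sin(2 pi i / 4.3), N = 50."""
    return sf.make_sine_line(50, 4.3)


@pytest.fixture
def recovery_spec():
    """Realistic 2-D recovery fixture: tilted lattice, background trend,
    2% noise and one deep occlusion band (carbon-fibre stand-in)."""
    return sf.StriationSpec(
        width=140, height=100, period_px=4.32, orientation_deg=4.72,
        trend_row=(0.0, 0.01), trend_col=(0.2, 0.005),
        noise_sigma=0.02, occlusions=((30.0, 8.0, 1.0),), seed=1,
    )


@pytest.fixture
def heterogeneous_lines():
    """ROI-like line set with per-line period/phase/amplitude variation
    and mild noise; sum and per-line-mean estimates differ slightly."""
    r = np.random.default_rng(11)
    lines = np.vstack([
        a * sf.make_sine_line(54, p, ph)
        for p, ph, a in zip(r.normal(4.32, 0.08, 31),
                            r.uniform(0, 2 * np.pi, 31),
                            r.uniform(0.5, 1.5, 31))
    ])
    return lines + r.normal(0, 0.03, lines.shape)
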