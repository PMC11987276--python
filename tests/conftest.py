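import numpy as np
import pytest

from plusquant.phantom import PhantomSpec, SineVesselCurve, _stamp_curve, generate_phantom


@pytest.fixture(scope="session")
def phantom_default():
    """One default phantom (image + truth), shared across tests."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def render_sine_tube(amplitude, wavelength=60.0, width=6.0, length=250.0,
                     angle=0.9, phase=0.7, shape=(700, 700)):
    """Render a single sine-perturbed tube; returns (curve, binary mask)."""
    curve = SineVesselCurve(
        origin=(shape[0] / 2.0, shape[1] / 2.0),
        angle=angle,
        amplitude=amplitude,
        wavelength=wavelength,
        phase=phase,
        t_max=length,
        width0=width,
        width_decay=0.0,
    )
    canvas = np.zeros(shape)
    _stamp_curve(canvas, curve)
    return curve, canvas >= 0.5
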