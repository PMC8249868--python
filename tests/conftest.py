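import pytest

from stereopupil import calibration as cal
from stereopupil import synthetic as syn


@pytest.fixture(scope="session")
def pattern():
    return cal.CalibrationPattern()


@pytest.fixture(scope="session")
def reference_cfg():
    """The full-resolution reference rig (2048x1536, fx 14493)."""
    return syn.SimConfig()


@pytest.fixture(scope="session")
def reference_rig(reference_cfg):
    return syn.build_rig(reference_cfg.rig)


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down camera for image-based tests (fast rendering)."""
    cfg = syn.SimConfig()
    cfg.rig.image_size = (640, 480)
    cfg.rig.fx = cfg.rig.fy = 4500.0
    return cfg


@pytest.fixture(scope="session")
def stereo_views(reference_cfg, pattern):
    """30 paired noiseless pattern views of the reference rig."""
    return syn.generate_pattern_views(
        reference_cfg, pattern, n_views=30, corner_px_sd=0.0, seed=11, stereo=True
    )


@pytest.fixture(scope="session")
def reference_sequence(reference_cfg):
    """3000-frame reference-object sequence with default artifact levels."""
    cfg = syn.SimConfig(seed=5)
    return syn.simulate_reference_sequence(cfg, 3000)
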