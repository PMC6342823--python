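import numpy as np
import pytest

import miroct as m


@pytest.fixture(scope="session")
def flat_source():
    return m.make_source_spectrum((3576.0, 4625.0), "flat")


@pytest.fixture(scope="session")
def spectrometer():
    return m.SpectrometerModel()


@pytest.fixture(scope="session")
def calibration(flat_source, spectrometer):
    """Default two-interferogram calibration of the virtual bench."""
    frames = m.generate_calibration_frames(spectrometer, flat_source,
                                           (300.0, 900.0))
    fr_a = m.preprocess(frames.frame_a, frames.dark, frames.reference)
    fr_b = m.preprocess(frames.frame_b, frames.dark, frames.reference)
    return m.build_calibration(fr_a, fr_b, frames.opd_a_um, frames.opd_b_um,
                               spectrometer)


@pytest.fixture(scope="session")
def mirror_ascan_factory(flat_source, spectrometer, calibration):
    """Reconstructed A-scan of a single weak mirror at a requested OPD."""

    def factory(z_um, *, r=0.05, window="none", zero_pad_factor=4,
                mismatch_phase=None, keep_complex=False):
        triple = m.synth_interferogram(
            m.ReflectorStack.single_mirror(z_um, r), flat_source, spectrometer,
            noise=False, mismatch_phase=mismatch_phase)
        fringe = m.preprocess(triple.sample, triple.dark, triple.reference)
        return m.reconstruct_ascan(fringe, calibration, window=window,
                                   zero_pad_factor=zero_pad_factor,
                                   keep_complex=keep_complex)

    return factory


@pytest.fixture(scope="session")
def time_grid():
    return m.TimeGrid()
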