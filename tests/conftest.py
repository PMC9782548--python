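import pytest

import hankelmrs as hm


@pytest.fixture(scope="session")
def p31_table():
    return hm.default_peak_table("P31")


@pytest.fixture(scope="session")
def h1_table():
    return hm.default_peak_table("H1")


@pytest.fixture(scope="session")
def toy_acq():
    """Small grid for fast fits: 256 points, 2 kHz, 100 MHz carrier."""
    return hm.AcquisitionParams(
        n_points=256, spectral_width=2000.0, spectrometer_freq=100.0,
        nucleus="P31", ref_ppm=0.0,
    )


@pytest.fixture(scope="session")
def toy_table():
    """Three well-separated singlets."""
    return hm.PeakTable(
        (
            hm.ResonanceLine("A", -3.0, 1.0, 8.0),
            hm.ResonanceLine("B", 0.0, 0.8, 8.0),
            hm.ResonanceLine("C", 4.0, 0.5, 8.0),
        ),
        "P31",
    )


@pytest.fixture(scope="session")
def toy_truth(toy_table, toy_acq):
    return hm.synthesize_fid(toy_table, toy_acq)


@pytest.fixture(scope="session")
def toy_basis(toy_table, toy_acq):
    return hm.BasisSet.from_peak_table(toy_table, toy_acq)


TOY_WINDOW = (-8.0, 8.0)


@pytest.fixture(scope="session")
def toy_window():
    return TOY_WINDOW


@pytest.fixture(scope="session")
def p31_small_acq():
    """31P bandwidth on a shorter grid, for fast full-pipeline runs."""
    return hm.AcquisitionParams(
        n_points=512, spectral_width=16025.64, spectrometer_freq=161.98,
        nucleus="P31", ref_ppm=0.0,
    )
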