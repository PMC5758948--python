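import numpy as np
import pytest

import acodopt


# Published nine-run screening values used as oracles throughout the suite.
BGP_MEAN = np.array([167.39, 240.01, 270.99, 136.28, 104.02, 86.54,
                     17.07, 25.55, 140.11])
BGP_SD = np.array([16.92, 5.25, 7.87, 3.18, 5.83, 10.15, 0.92, 1.51, 0.31])
BMP_MEAN = np.array([79.58, 124.09, 126.78, 67.76, 61.64, 41.11,
                     9.34, 13.62, 69.98])
CODS_MEAN = np.array([68.81, 69.85, 57.69, -123.25, -81.33, 80.57,
                      -263.42, -91.95, 77.44])
SNR_BGP = np.array([44.34, 47.60, 48.65, 42.68, 40.30, 38.56,
                    24.60, 28.10, 42.93])
SNR_BMP = np.array([37.87, 41.83, 42.03, 36.35, 35.70, 31.86,
                    18.96, 21.81, 36.83])
SNR_CODS = np.array([36.35, 36.40, 35.18, 33.26, 35.89, 38.12,
                     48.41, 37.81, 37.75])


@pytest.fixture(scope="session")
def design():
    return acodopt.build_l9()


@pytest.fixture(scope="session")
def run_table():
    return acodopt.packaged_run_table()


@pytest.fixture(scope="session")
def printed_snr():
    return acodopt.packaged_snr_table()


@pytest.fixture(scope="session")
def printed_effects(printed_snr, design):
    return acodopt.effects_table(printed_snr, design)
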