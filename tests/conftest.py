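import numpy as np
import pandas as pd
import pytest

from eegqual.io import ClassLabel
from eegqual.simulate import SyntheticConfig, make_unimodal_study
from eegqual.evaluate import unimodal_feature_tables


def write_minimal_edf(path, data, rate, labels):
    """Write a minimal standard-header EDF file (synthetic test fixture).

    1-second records, 16-bit samples, physical range +/-1000 uV.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    spr = int(rate)
    n_records = n_samp // spr
    hdr = b""
    hdr += b"0".ljust(8)
    hdr += b"X X X X".ljust(80)
    hdr += b"Startdate 01-JAN-2020 X X X".ljust(80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(256 + 256 * n_ch).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += str(n_records).encode().ljust(8)
    hdr += b"1".ljust(8)
    hdr += str(n_ch).encode().ljust(4)

    def field(vals, width):
        return b"".join(str(v).encode().ljust(width) for v in vals)

    hdr += field(labels, 16)
    hdr += field([""] * n_ch, 80)
    hdr += field(["uV"] * n_ch, 8)
    hdr += field([-1000] * n_ch, 8)
    hdr += field([1000] * n_ch, 8)
    hdr += field([-32768] * n_ch, 8)
    hdr += field([32767] * n_ch, 8)
    hdr += field([""] * n_ch, 80)
    hdr += field([spr] * n_ch, 8)
    hdr += field([""] * n_ch, 32)
    assert len(hdr) == 256 + 256 * n_ch
    scale = 65535 / 2000.0
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            for ch in range(n_ch):
                seg = data[ch, r * spr:(r + 1) * spr]
                fh.write(np.round(seg * scale).astype("<i2").tobytes())


def gaussian_feature_tables(n_per_class=200, n_features=3, mu=10.0, sd=1.0,
                            seed=0):
    """Idealised fully separated feature tables: C at +mu, N at -mu, R an
    even mixture of the two generating distributions."""
    rng = np.random.default_rng(seed)
    names = [f"f{i}" for i in range(n_features)]

    def draw(center, n):
        return pd.DataFrame(
            rng.normal(center, sd, size=(n, n_features)), columns=names
        )

    half = n_per_class // 2
    raw = pd.concat(
        [draw(mu, half), draw(-mu, n_per_class - half)], ignore_index=True
    )
    return {
        ClassLabel.CLEAN: draw(mu, n_per_class),
        ClassLabel.RAW: raw,
        ClassLabel.NOISE: draw(-mu, n_per_class),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down synthetic study used across tests (2 subjects, 8 EEG
    channels, 1-minute sessions, 20-s epochs)."""
    return SyntheticConfig(seed=7, n_subjects=2, n_channels=8, duration_s=60.0)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return make_unimodal_study(small_cfg)


@pytest.fixture(scope="session")
def small_study_tables(small_study):
    return unimodal_feature_tables(small_study, epoch_seconds=20.0)
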