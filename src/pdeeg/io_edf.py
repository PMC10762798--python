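"""Minimal single-channel EDF writer plus recording I/O helpers.

Recordings are interchanged as 16-bit EDF (physical unit uV, one signal per
file, 1 s data records) with a sidecar CSV of per-second condition labels,
or as plain CSV.  Reading goes through :func:`mne.io.read_raw_edf`, an
independent, widely used EDF reader, which also serves as the round-trip
check on the writer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_DMIN, _DMAX = -32768, 32767


def write_edf(path: str | Path, samples: np.ndarray, fs: int,
              channel_label: str = "EEG Fp1-Fp2",
              patient_id: str = "X") -> None:
    """Write one channel of uV samples as a 16-bit EDF file.

    The signal is padded with its last value to a whole number of 1 s data
    records; the physical range is the data range, so quantization error is
    bounded by (max - min) / 65535.
    """
    sig = np.asarray(samples, dtype=float)
    if sig.ndim != 1:
        raise ValueError("write_edf handles a single channel")
    n_rec = int(np.ceil(sig.size / fs))
    sig = np.pad(sig, (0, n_rec * fs - sig.size), mode="edge")
    pmin, pmax = float(sig.min()), float(sig.max())
    if pmax <= pmin:
        pmax = pmin + 1.0

    header = ("0".ljust(8)                       # version
              + str(patient_id)[:80].ljust(80)   # patient id
              + "synthetic recording".ljust(80)  # recording id
              + "01.01.00" + "00.00.00"          # start date/time
              + str(256 + 256).ljust(8)          # header bytes
              + "".ljust(44)                     # reserved
              + str(n_rec).ljust(8)              # number of data records
              + "1".ljust(8)                     # record duration, s
              + "1".ljust(4))                    # number of signals
    sig_header = (channel_label[:16].ljust(16)
                  + "".ljust(80)                 # transducer
                  + "uV".ljust(8)
                  + f"{pmin:.8g}"[:8].ljust(8)
                  + f"{pmax:.8g}"[:8].ljust(8)
                  + str(_DMIN).ljust(8)
                  + str(_DMAX).ljust(8)
                  + "".ljust(80)                 # prefiltering
                  + str(fs).ljust(8)             # samples per record
                  + "".ljust(32))
    digital = np.round((sig - pmin) / (pmax - pmin)
                       * (_DMAX - _DMIN) + _DMIN).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(sig_header.encode("ascii"))
        fh.write(digital.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a single-channel EDF; rejects multi-channel files."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if len(raw.ch_names) != 1:
        raise ValueError(
            f"expected a single-channel recording, file has "
            f"{len(raw.ch_names)} channels: {raw.ch_names}")
    return raw.get_data(units="uV")[0], int(round(raw.info["sfreq"]))


def write_recording_csv(path: str | Path, samples: np.ndarray,
                        fs: int) -> None:
    # %.17g round-trips float64 exactly
    pd.DataFrame({"time_s": np.arange(len(samples)) / fs,
                  "uV": samples}).to_csv(path, index=False,
                                         float_format="%.17g")


def read_recording_csv(path: str | Path) -> tuple[np.ndarray, int]:
    df = pd.read_csv(path, float_precision="round_trip")
    dt = np.diff(df["time_s"].to_numpy()[:2])[0]
    return df["uV"].to_numpy(), int(round(1.0 / dt))


def write_labels(path: str | Path, labels: list[str]) -> None:
    pd.DataFrame({"second": np.arange(len(labels)),
                  "condition": labels}).to_csv(path, index=False)


def read_labels(path: str | Path) -> list[str]:
    return pd.read_csv(path)["condition"].tolist()
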