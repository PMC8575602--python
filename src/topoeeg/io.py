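"""File formats: EDF and delimited-text recordings, matrices, barcodes.

Recordings travel either as European Data Format (EDF, 16-bit) or as a plain
tab-separated text format with one row per channel and ``#``-prefixed header
lines; stimulus markers go to a ``<path>.markers.tsv`` sidecar in both cases
(plain EDF has no annotation channel). EDF files are written by a minimal
single-purpose writer and read back through :mod:`mne`, which also serves as
the independent check on the writer in the test suite.
"""

from __future__ import annotations

import pathlib

import numpy as np

from .connectivity import ConnectivityMatrix
from .recording import EEGRecording, Marker
from .topology import Bar, BarcodeSet, EulerCurve

_DIG_MAX = 32767


# ---------------------------------------------------------------------------
# markers sidecar

def write_markers(markers: list[Marker], path) -> None:
    lines = ["sample\tcondition\tevent"]
    lines += [f"{m.sample}\t{m.condition}\t{m.event}" for m in markers]
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_markers(path) -> list[Marker]:
    lines = pathlib.Path(path).read_text().strip().splitlines()
    out = []
    for line in lines[1:]:
        sample, condition, event = line.split("\t")
        out.append(Marker(int(sample), condition, event))
    return out


def _sidecar(path) -> pathlib.Path:
    return pathlib.Path(str(path) + ".markers.tsv")


# ---------------------------------------------------------------------------
# delimited text recordings

def write_text_recording(recording: EEGRecording, path) -> None:
    """One row per channel, tab-separated; fs and labels in ``#`` headers."""
    path = pathlib.Path(path)
    with path.open("w") as fh:
        fh.write("# topoeeg recording\n")
        fh.write(f"# fs_hz={recording.fs:g}\n")
        fh.write(f"# channels={','.join(recording.channel_labels)}\n")
        np.savetxt(fh, recording.data, fmt="%.10g", delimiter="\t")
    write_markers(recording.markers, _sidecar(path))


def read_text_recording(path) -> EEGRecording:
    path = pathlib.Path(path)
    fs, labels = None, None
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# fs_hz="):
                fs = float(line.split("=", 1)[1])
            elif line.startswith("# channels="):
                labels = line.split("=", 1)[1].strip().split(",")
    if fs is None:
        raise ValueError(f"{path}: missing '# fs_hz=' header")
    data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    markers = read_markers(_sidecar(path)) if _sidecar(path).exists() else []
    return EEGRecording(data, fs, labels or [], markers)


# ---------------------------------------------------------------------------
# EDF

def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % x
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {x} in {width} ascii bytes")


def write_edf(recording: EEGRecording, path) -> None:
    """Minimal 16-bit EDF export: 1-second data records, per-channel
    symmetric physical range recorded in the header.

    The sampling rate must be an integer; the last partial second, if any,
    is zero-padded. Markers go to the text sidecar.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    m, n = recording.n_channels, recording.n_samples
    n_rec = int(np.ceil(n / spr))

    phys_max = np.abs(recording.data).max(axis=1)
    phys_max[phys_max == 0] = 1.0
    scaled = np.zeros((m, n_rec * spr), dtype=np.int16)
    scaled[:, :n] = np.round(
        recording.data / phys_max[:, None] * _DIG_MAX).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X X X X", 80))                    # patient id
        fh.write(_ascii("Startdate X X X X", 80))          # recording id
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(256 * (1 + m), 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(n_rec, 8))
        fh.write(_ascii("1", 8))
        fh.write(_ascii(m, 4))
        for lab in recording.channel_labels:
            fh.write(_ascii(lab[:16], 16))
        for _ in range(m):
            fh.write(_ascii("AgAgCl electrode", 80))
        for _ in range(m):
            fh.write(_ascii("uV", 8))
        for p in phys_max:
            fh.write(_ascii(_fmt_float(-p), 8))
        for p in phys_max:
            fh.write(_ascii(_fmt_float(p), 8))
        for _ in range(m):
            fh.write(_ascii(-_DIG_MAX, 8))
        for _ in range(m):
            fh.write(_ascii(_DIG_MAX, 8))
        for _ in range(m):
            fh.write(_ascii("", 80))
        for _ in range(m):
            fh.write(_ascii(spr, 8))
        for _ in range(m):
            fh.write(_ascii("", 32))
        for r in range(n_rec):
            block = scaled[:, r * spr:(r + 1) * spr]
            fh.write(block.astype("<i2").tobytes())
    write_markers(recording.markers, _sidecar(path))


def read_edf(path) -> EEGRecording:
    """Read an EDF recording through mne; markers from the sidecar."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne scales uV channels to Volts
    markers = read_markers(_sidecar(path)) if _sidecar(path).exists() else []
    return EEGRecording(data, float(raw.info["sfreq"]),
                        list(raw.ch_names), markers)


def read_recording(path) -> EEGRecording:
    """Dispatch on extension: ``.edf`` via mne, anything else as text."""
    if str(path).lower().endswith(".edf"):
        return read_edf(path)
    return read_text_recording(path)


# ---------------------------------------------------------------------------
# connectivity matrices, barcodes, Euler curves

def write_matrix(matrix: ConnectivityMatrix, path, band: str = "") -> None:
    path = pathlib.Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind={matrix.kind} band={band} "
                 f"normalized={int(matrix.normalized)} "
                 f"channels={','.join(matrix.channel_labels)}\n")
        np.savetxt(fh, matrix.values, fmt="%.12g", delimiter="\t")


def read_matrix(path) -> ConnectivityMatrix:
    path = pathlib.Path(path)
    header = path.open().readline()
    if not header.startswith("# kind="):
        raise ValueError(f"{path}: missing matrix header")
    fields = dict(part.split("=", 1) for part in header[2:].split())
    values = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    labels = [c for c in fields.get("channels", "").split(",") if c]
    return ConnectivityMatrix(values, fields["kind"],
                              normalized=bool(int(fields["normalized"])),
                              channel_labels=labels)


def write_barcode(barcode: BarcodeSet, path) -> None:
    path = pathlib.Path(path)
    with path.open("w") as fh:
        fh.write(f"# max_filtration={barcode.max_filtration:.12g}\n")
        fh.write("dim\tbirth\tdeath\n")
        for b in barcode.bars:
            death = "inf" if b.essential else f"{b.death:.12g}"
            fh.write(f"{b.dim}\t{b.birth:.12g}\t{death}\n")


def read_barcode(path) -> BarcodeSet:
    lines = pathlib.Path(path).read_text().strip().splitlines()
    max_filtration = float(lines[0].split("=", 1)[1])
    bars = []
    for line in lines[2:]:
        dim, birth, death = line.split("\t")
        bars.append(Bar(int(dim), float(birth), float(death)))
    return BarcodeSet(bars, max_filtration)


def write_euler_curve(curve: EulerCurve, path) -> None:
    path = pathlib.Path(path)
    with path.open("w") as fh:
        tp = "" if curve.transition_point is None else \
            f"{curve.transition_point:.12g}"
        fh.write(f"# transition_point={tp}\n")
        fh.write("eps\tchi\tS\n")
        for e, c, s in zip(curve.grid, curve.chi, curve.entropy):
            fh.write(f"{e:.12g}\t{c}\t{s:.12g}\n")
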