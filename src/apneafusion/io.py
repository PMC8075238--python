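"""Reading, writing and segmenting single-lead ECG records.

Records live on disk as a WFDB-compatible subset: a plain-text ``.hea``
header, a little-endian 16-bit ``.dat`` signal file (WFDB "format 16"),
and an optional plain-text per-minute annotation file ``<record>.apn.txt``
holding one label character per line (``N`` = normal, ``A`` = apnea).

Only single-signal records are supported; that is all the per-minute apnea
detection pipeline consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NORMAL = "N"
APNEA = "A"

_VALID_LABELS = frozenset({NORMAL, APNEA})

#: adu per millivolt used when writing fixture records
DEFAULT_GAIN = 200.0


class AnnotationError(ValueError):
    """Raised when per-minute annotations are inconsistent with the signal."""


@dataclass
class ECGRecord:
    """A single-lead ECG signal with optional per-minute apnea labels.

    Attributes
    ----------
    record_id : str
        Base name of the record.
    sampling_rate : float
        Samples per second; the apnea databases this package targets use 100 Hz.
    samples : ndarray
        Signal amplitudes in millivolt.
    minute_labels : list of str
        One label (``"N"`` or ``"A"``) per annotated minute, in temporal order.
        Empty when the record carries no annotations.
    """

    record_id: str
    sampling_rate: float
    samples: np.ndarray
    minute_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        bad = set(self.minute_labels) - _VALID_LABELS
        if bad:
            raise AnnotationError(f"unknown annotation codes: {sorted(bad)}")
        max_minutes = int(len(self.samples) // (60 * self.sampling_rate))
        if len(self.minute_labels) > max_minutes:
            raise AnnotationError(
                f"{len(self.minute_labels)} minute labels for a record of only "
                f"{max_minutes} full minutes"
            )

    @property
    def duration_minutes(self) -> float:
        return len(self.samples) / (60.0 * self.sampling_rate)


@dataclass
class Segment:
    """One labeled minute of ECG.

    ``samples`` has length ``60 * sampling_rate``; ``minute_index`` is 0-based,
    label ``i`` covering samples ``[i*60*fs, (i+1)*60*fs)``.
    """

    samples: np.ndarray
    label: str
    record_id: str
    minute_index: int
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        expected = int(round(60 * self.sampling_rate))
        if len(self.samples) != expected:
            raise ValueError(
                f"segment must hold exactly one minute ({expected} samples at "
                f"{self.sampling_rate} Hz), got {len(self.samples)}"
            )
        if self.label not in _VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(_VALID_LABELS)}")


def write_record(record: ECGRecord, directory: str | Path, gain: float = DEFAULT_GAIN) -> Path:
    """Write ``record`` as a WFDB format-16 header/signal pair (plus annotations).

    Returns the path of the ``.hea`` file. Amplitudes are quantized to
    ``round(mV * gain)`` 16-bit integers, the usual WFDB convention.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    adc = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    fs = record.sampling_rate
    fs_text = f"{fs:g}"
    header = (
        f"{name} 1 {fs_text} {len(adc)}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 16 0 {adc[0] if len(adc) else 0} 0 0 ECG\n"
    )
    (directory / f"{name}.hea").write_text(header)
    if record.minute_labels:
        (directory / f"{name}.apn.txt").write_text("\n".join(record.minute_labels) + "\n")
    return directory / f"{name}.hea"


def _parse_gain(token: str) -> float:
    # WFDB gain token may look like "200", "200/mV" or "200(0)/mV"
    token = token.split("/")[0]
    token = token.split("(")[0]
    gain = float(token)
    return gain if gain != 0 else DEFAULT_GAIN


def read_record(path: str | Path) -> ECGRecord:
    """Read a WFDB-subset record (``.hea`` + format-16 ``.dat``).

    ``path`` may point at the header file or at the extensionless record name.
    A sidecar ``<record>.apn.txt`` per-minute annotation file is read when
    present; otherwise ``minute_labels`` is empty.
    """
    path = Path(path)
    header_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not header_path.exists():
        raise FileNotFoundError(f"no header file {header_path}")
    lines = [
        ln for ln in header_path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_id = rec_fields[0]
    n_sig = int(rec_fields[1])
    if n_sig != 1:
        raise ValueError(f"only single-signal records supported, got {n_sig} signals")
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else -1

    sig_fields = lines[1].split()
    dat_name, fmt = sig_fields[0], sig_fields[1]
    if fmt != "16":
        raise ValueError(f"unsupported WFDB signal format {fmt!r}; only format 16 is handled")
    gain = _parse_gain(sig_fields[2]) if len(sig_fields) > 2 else DEFAULT_GAIN

    dat_path = header_path.parent / dat_name
    if not dat_path.exists():
        raise FileNotFoundError(f"missing signal file {dat_path}")
    adc = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if n_samples >= 0:
        if len(adc) < n_samples:
            raise OSError(
                f"signal file {dat_path} truncated: header declares {n_samples} "
                f"samples, file holds {len(adc)}"
            )
        adc = adc[:n_samples]
    samples = adc.astype(np.float64) / gain

    ann_path = header_path.with_suffix("").parent / f"{record_id}.apn.txt"
    labels: list[str] = []
    if ann_path.exists():
        labels = [ln.strip() for ln in ann_path.read_text().splitlines() if ln.strip()]

    return ECGRecord(record_id=record_id, sampling_rate=fs, samples=samples, minute_labels=labels)


def segment_record(record: ECGRecord) -> list[Segment]:
    """Cut a record into labeled, non-overlapping one-minute segments.

    One segment per annotated minute, in temporal order. Trailing partial
    minutes and minutes without a label are dropped. Concatenating the
    returned segments reproduces a prefix of ``record.samples`` exactly.
    """
    spm = int(round(60 * record.sampling_rate))
    full_minutes = len(record.samples) // spm
    n = min(int(full_minutes), len(record.minute_labels))
    if n == 0:
        warnings.warn(
            f"record {record.record_id}: no labeled full minutes, returning no segments",
            stacklevel=2,
        )
        return []
    return [
        Segment(
            samples=record.samples[i * spm : (i + 1) * spm],
            label=record.minute_labels[i],
            record_id=record.record_id,
            minute_index=i,
            sampling_rate=record.sampling_rate,
        )
        for i in range(n)
    ]
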