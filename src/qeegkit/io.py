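"""Reading and writing recordings (EDF) and amplitude tables (CSV).

EDF files are read through :func:`mne.io.read_raw_edf`; writing uses a
small self-contained EDF encoder (16-bit samples, one header block), since
no EDF writer ships with the scientific stack this package targets.  The
round trip is therefore cross-checked against an independent reader.

Amplitude tables are long-format CSV with columns
``patient_id, sex, age, channel, band, amplitude_uV`` — one amplitude per
row, UTF-8, comma-separated.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, normalize_band
from .errors import FormatError, UnitError, ValidationError
from .profiles import AmplitudeProfile, PatientRecord, normalize_channel
from .recording import COMMON_AVERAGE, Recording

logger = logging.getLogger(__name__)

_DIG_MIN, _DIG_MAX = -32768, 32767
_ACCEPTED_DIMS = {"UV", "µV".upper(), "MV", "V"}
_REF_PREFIX = "Ref:"

CSV_COLUMNS = ["patient_id", "sex", "age", "channel", "band", "amplitude_uV"]


def _ascii(value: str, width: int) -> bytes:
    """Space-padded fixed-width ASCII field."""
    raw = value.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def _fmt8(value: float) -> str:
    """Decimal string for an EDF numeric field (max 8 chars)."""
    for spec in (".6g", ".4g", ".2g"):
        s = format(value, spec)
        if len(s) <= 8:
            return s
    raise ValidationError(f"cannot encode {value} in an 8-char EDF field")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` as a plain EDF file.

    Samples are quantised to 16 bits over a symmetric physical range per
    channel, so the worst-case round-trip error is one quantisation step.
    The reference label is stored in the recording-identification header
    field (``Ref:<label>``), which readers ignore.

    Raises
    ------
    ValidationError
        If any sample is non-finite.
    """
    if not np.all(np.isfinite(recording.samples)):
        raise ValidationError("recording contains non-finite samples; refusing to write")

    fs = recording.sampling_rate
    n = recording.n_samples
    # Prefer 1 s data records; fall back to a single record covering the
    # whole signal when fs is non-integer or does not divide the length.
    if float(fs).is_integer() and n % int(fs) == 0:
        spr, n_records, rec_dur = int(fs), n // int(fs), 1.0
    else:
        spr, n_records, rec_dur = n, 1, n / fs

    labels = recording.channel_labels
    ns = len(labels)
    # Per-channel symmetric physical range; re-parse the formatted strings
    # so the scale used for encoding matches what a reader will compute.
    pmaxs = []
    for row in recording.samples:
        peak = float(np.max(np.abs(row)))
        pmaxs.append(float(_fmt8(peak if peak > 0 else 1.0)))

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii(_REF_PREFIX + recording.reference_label, 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (1 + ns)), 8),
            _ascii("", 44),
            _ascii(str(n_records), 8),
            _ascii(_fmt8(rec_dur), 8),
            _ascii(str(ns), 4),
        ]
    )
    header += b"".join(_ascii(lab, 16) for lab in labels)
    header += b"".join(_ascii("", 80) for _ in labels)
    header += b"".join(_ascii("uV", 8) for _ in labels)
    header += b"".join(_ascii(_fmt8(-p), 8) for p in pmaxs)
    header += b"".join(_ascii(_fmt8(p), 8) for p in pmaxs)
    header += b"".join(_ascii(str(_DIG_MIN), 8) for _ in labels)
    header += b"".join(_ascii(str(_DIG_MAX), 8) for _ in labels)
    header += b"".join(_ascii("", 80) for _ in labels)
    header += b"".join(_ascii(str(spr), 8) for _ in labels)
    header += b"".join(_ascii("", 32) for _ in labels)

    digital = np.empty((ns, n), dtype="<i2")
    for i, (row, pmax) in enumerate(zip(recording.samples, pmaxs)):
        step = (2 * pmax) / (_DIG_MAX - _DIG_MIN)
        digital[i] = np.clip(
            np.round((row + pmax) / step) + _DIG_MIN, _DIG_MIN, _DIG_MAX
        ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def _peek_edf_header(path: Path) -> tuple[list[str], list[str], str]:
    """Raw channel labels, physical dimensions and recording-id from an EDF header."""
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        recording_id = fixed[88:168].decode("ascii", errors="replace").strip()
        try:
            ns = int(fixed[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: unreadable signal count") from exc
        var = fh.read(ns * 256)
        if len(var) < ns * 256:
            raise FormatError(f"{path}: truncated EDF signal headers")
    labels = [
        var[i * 16 : (i + 1) * 16].decode("ascii", errors="replace").strip()
        for i in range(ns)
    ]
    dim_off = ns * (16 + 80)
    dims = [
        var[dim_off + i * 8 : dim_off + (i + 1) * 8]
        .decode("ascii", errors="replace")
        .strip()
        for i in range(ns)
    ]
    return labels, dims, recording_id


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` in microvolts.

    Channel labels are normalised to upper-case 10-20 names; annotation
    channels are dropped.  The physical-dimension field must declare a
    voltage unit for every signal.

    Raises
    ------
    FormatError
        If the file is not readable EDF.
    UnitError
        If a signal has no (or a non-voltage) physical dimension.
    ValidationError
        If channel labels are duplicated.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")

    raw_labels, dims, recording_id = _peek_edf_header(path)
    keep = [
        (lab, dim)
        for lab, dim in zip(raw_labels, dims)
        if "ANNOTATION" not in lab.upper()
    ]
    norm = [normalize_channel(lab) for lab, _ in keep]
    if len(set(norm)) != len(norm):
        raise ValidationError(f"{path}: duplicate channel labels {norm}")
    for (lab, dim), name in zip(keep, norm):
        if dim.upper() not in _ACCEPTED_DIMS:
            raise UnitError(
                f"{path}: channel {name} has physical dimension {dim!r}; "
                "expected a voltage unit (uV, mV or V)"
            )

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except ValidationError:
        raise
    except Exception as exc:  # mne raises a mix of OSError/ValueError
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc

    picks = [
        ch
        for ch in raw.ch_names
        if "ANNOTATION" not in ch.upper() and "STIM" not in ch.upper()
    ]
    data = raw.get_data(picks=picks) * 1e6  # mne holds volts internally

    reference = COMMON_AVERAGE
    if recording_id.startswith(_REF_PREFIX):
        reference = recording_id[len(_REF_PREFIX) :].strip() or COMMON_AVERAGE

    return Recording(
        channel_labels=[normalize_channel(ch) for ch in picks],
        sampling_rate=float(raw.info["sfreq"]),
        samples=data,
        reference_label=reference,
    )


def read_amplitude_csv(path: str | Path, scheme_id: str = "nf-standard-0.5-30") -> list[PatientRecord]:
    """Read a long-format amplitude table into patient records.

    Patients lacking either central electrode (C3/C4) cannot enter the
    hemispheric rule evaluation and are excluded with a logged warning.

    Raises
    ------
    FormatError
        If required columns are missing.
    ValidationError
        If a band name is not in the six-band scheme, or amplitudes are
        invalid.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty amplitude table", path)
        return []
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if table.empty:
        logger.warning("%s: amplitude table has a header but no rows", path)
        return []

    records: list[PatientRecord] = []
    for pid, group in table.groupby("patient_id", sort=False):
        entries = {
            (normalize_channel(str(row.channel)), normalize_band(str(row.band))): float(
                row.amplitude_uV
            )
            for row in group.itertuples()
        }
        channels = {c for c, _ in entries}
        if not {"C3", "C4"} <= channels:
            logger.warning(
                "patient %s: missing C3 or C4; excluded from rule evaluation", pid
            )
            continue
        profile = AmplitudeProfile(patient_id=str(pid), scheme_id=scheme_id, entries=entries)
        records.append(
            PatientRecord(
                patient_id=str(pid),
                sex=str(group["sex"].iloc[0]),
                age=float(group["age"].iloc[0]),
                profile=profile,
            )
        )
    return records


def write_amplitude_csv(records: list[PatientRecord], path: str | Path) -> None:
    """Write patient records as a long-format CSV (inverse of the reader)."""
    rows = []
    for rec in records:
        for channel in rec.profile.channels:
            for band in BAND_NAMES:
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "sex": rec.sex,
                        "age": rec.age,
                        "channel": channel,
                        "band": band,
                        "amplitude_uV": rec.profile.amplitude(channel, band),
                    }
                )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
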