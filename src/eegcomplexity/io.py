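"""Reading, writing and validating condition-segmented resting-state EEG.

The package works on cleaned, condition-segmented recordings (eyes closed,
``EC``, or eyes open, ``EO``): one ``channels x samples`` matrix per subject
and condition, with a sampling rate and an electrode -> region-of-interest
(ROI) map.  Two on-disk representations are supported:

* a delimited text matrix (one column per channel, header row of channel
  names) plus a JSON sidecar carrying ``fs``, ``channel_names``, ``roi_map``,
  ``subject_id`` and ``condition`` — the lossless text format;
* 16-bit EDF, the clinical interchange format, with the same JSON sidecar for
  the ROI map and condition label (EDF headers cannot carry them).

Electrodes that should not contribute to any scalp region (neck, ears,
cheeks) are mapped to the reserved ROI label ``"excluded"`` and skipped by
all feature computations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The ten scalp regions of interest, in canonical serialization order.
ROI_LABELS: tuple[str, ...] = tuple(
    f"{region}_{side}"
    for region in ("frontal", "central", "parietal", "temporal", "occipital")
    for side in ("left", "right")
)

#: Reserved ROI label for electrodes excluded from all analyses.
EXCLUDED = "excluded"

CONDITIONS = ("EC", "EO")

#: Shortest recording accepted for analysis, in seconds.  Recordings of at
#: least 180 s are preferred; between 170 and 180 s entropy estimates are
#: empirically indistinguishable, below 170 s the recording is rejected.
MIN_DURATION_S = 170.0
PREFERRED_DURATION_S = 180.0


class ValidationError(ValueError):
    """Raised when a recording or its metadata violates the data contract."""


@dataclass
class EEGRecording:
    """One subject x condition multichannel EEG segment.

    Parameters
    ----------
    subject_id : str
        Cohort-unique subject identifier.
    condition : {"EC", "EO"}
        Eyes-closed or eyes-open resting condition.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per row of ``data``.
    roi_map : dict
        Maps every channel name to an ROI label from :data:`ROI_LABELS`
        or to ``"excluded"``.
    """

    subject_id: str
    condition: str
    data: np.ndarray
    fs: float
    channel_names: list[str]
    roi_map: dict[str, str] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self, min_duration_s: float = MIN_DURATION_S) -> "EEGRecording":
        """Check the structural invariants; return self for chaining."""
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D channels x samples matrix")
        if len(self.channel_names) != self.n_channels:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} data rows"
            )
        missing = [c for c in self.channel_names if c not in self.roi_map]
        if missing:
            raise ValidationError(
                f"channels without ROI assignment: {missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}"
            )
        bad = {
            c: r
            for c, r in self.roi_map.items()
            if r not in ROI_LABELS and r != EXCLUDED
        }
        if bad:
            raise ValidationError(f"unknown ROI labels: {bad}")
        if self.duration_s < min_duration_s:
            raise ValidationError(
                f"recording of {self.duration_s:.1f} s is shorter than the "
                f"minimum of {min_duration_s:.0f} s required for stable "
                "entropy estimates"
            )
        return self

    def included_channels(self) -> list[str]:
        return [c for c in self.channel_names if self.roi_map.get(c) != EXCLUDED]


def synthetic_montage(
    n_channels: int, n_excluded: int = 0
) -> tuple[list[str], dict[str, str]]:
    """Build channel names and an ROI lookup for a synthetic montage.

    The first ``n_channels - n_excluded`` electrodes are distributed as
    evenly as possible over the ten ROIs (in :data:`ROI_LABELS` order); the
    remaining ``n_excluded`` are labelled ``"excluded"``.
    """
    if n_channels < len(ROI_LABELS) + n_excluded:
        raise ValueError(
            f"need at least {len(ROI_LABELS) + n_excluded} channels to cover "
            "all 10 ROIs"
        )
    n_mapped = n_channels - n_excluded
    names: list[str] = []
    roi_map: dict[str, str] = {}
    counts = np.full(len(ROI_LABELS), n_mapped // len(ROI_LABELS))
    counts[: n_mapped % len(ROI_LABELS)] += 1
    for roi, k in zip(ROI_LABELS, counts):
        for i in range(int(k)):
            name = f"{roi}_{i + 1:02d}"
            names.append(name)
            roi_map[name] = roi
    for i in range(n_excluded):
        name = f"excluded_{i + 1:02d}"
        names.append(name)
        roi_map[name] = EXCLUDED
    return names, roi_map


def roi_average(
    values: Mapping[str, float], roi_map: Mapping[str, str]
) -> dict[str, float]:
    """Arithmetic mean of a per-channel scalar within each ROI.

    Channels labelled ``"excluded"`` are skipped.  ROIs with no mapped
    channel are absent from the result (never reported as zero).  A mapped
    channel without a value is an error.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for channel, roi in roi_map.items():
        if roi == EXCLUDED:
            continue
        if channel not in values:
            raise ValidationError(f"no value for mapped channel {channel!r}")
        sums[roi] = sums.get(roi, 0.0) + float(values[channel])
        counts[roi] = counts.get(roi, 0) + 1
    return {roi: sums[roi] / counts[roi] for roi in sums}


# ---------------------------------------------------------------------------
# Delimited matrix + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_delimited(rec: EEGRecording, path: str | Path) -> Path:
    """Write ``rec`` as a TSV matrix (columns = channels) plus JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "roi_map": rec.roi_map,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _read_delimited(path: Path) -> EEGRecording:
    sidecar = json.loads(_sidecar_path(path).read_text())
    df = pd.read_csv(path, sep="\t")
    names = list(df.columns)
    if names != list(sidecar["channel_names"]):
        raise ValidationError(
            "channel names in matrix header and sidecar disagree"
        )
    return EEGRecording(
        subject_id=sidecar["subject_id"],
        condition=sidecar["condition"],
        data=np.ascontiguousarray(df.to_numpy(dtype=float).T),
        fs=float(sidecar["fs"]),
        channel_names=names,
        roi_map=dict(sidecar["roi_map"]),
    )


# ---------------------------------------------------------------------------
# EDF (16-bit)
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a minimal 16-bit EDF file (1-second data records).

    The trailing partial second, if any, is dropped; physical ranges are
    symmetric per channel, so quantization error is bounded by
    ``max|x| / 32767`` per channel.  The ROI map and condition go to the
    usual JSON sidecar, since EDF headers cannot represent them.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * fs]
    ns = rec.n_channels

    # Per-channel symmetric physical range, rounded to fit 8 ascii chars.
    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    pmax = np.array([float(f"{v:.4g}") for v in pmax * 1.0001])
    # EDF affine convention: phys = physmin + (dig - digmin) * cal
    cal = 2.0 * pmax / 65535.0
    digital = np.clip(
        np.rint((data + pmax[:, None]) / cal[:, None]) - 32768,
        -32768,
        32767,
    ).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(rec.subject_id[:80], 80),
            _edf_field(f"condition {rec.condition}"[:80], 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (1 + ns)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(ns), 4),
        ]
    )
    sig = b"".join(_edf_field(c[:16], 16) for c in rec.channel_names)
    sig += b"".join(_edf_field("", 80) for _ in range(ns))
    sig += b"".join(_edf_field("uV", 8) for _ in range(ns))
    sig += b"".join(_edf_field(f"{-v:.4g}", 8) for v in pmax)
    sig += b"".join(_edf_field(f"{v:.4g}", 8) for v in pmax)
    sig += b"".join(_edf_field("-32768", 8) for _ in range(ns))
    sig += b"".join(_edf_field("32767", 8) for _ in range(ns))
    sig += b"".join(_edf_field("", 80) for _ in range(ns))
    sig += b"".join(_edf_field(str(fs), 8) for _ in range(ns))
    sig += b"".join(_edf_field("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # record-major layout: all channels' samples for record r, in order
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())

    sidecar = {
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "fs": float(fs),
        "channel_names": rec.channel_names,
        "roi_map": rec.roi_map,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; recordings are in uV
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
        roi_map = dict(sidecar["roi_map"])
        subject_id = sidecar["subject_id"]
        condition = sidecar["condition"]
        names = list(sidecar["channel_names"])
        if len(names) != data.shape[0]:
            raise ValidationError(
                f"sidecar lists {len(names)} channels, EDF has {data.shape[0]}"
            )
    else:
        raise ValidationError(
            f"EDF recording {path} has no JSON sidecar; the ROI map and "
            "condition label cannot be recovered from the EDF header"
        )
    return EEGRecording(
        subject_id=subject_id,
        condition=condition,
        data=np.ascontiguousarray(data),
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        roi_map=roi_map,
    )


def read_recording(
    path: str | Path, min_duration_s: float = MIN_DURATION_S
) -> EEGRecording:
    """Read and validate a recording (EDF or delimited matrix + sidecar).

    The format is chosen by suffix: ``.edf`` for EDF, anything else for the
    delimited text matrix.  Recordings shorter than ``min_duration_s``
    (default 170 s) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path)
    else:
        rec = _read_delimited(path)
    return rec.validate(min_duration_s=min_duration_s)


def write_recording(
    rec: EEGRecording, path: str | Path, format: str = "delimited"
) -> Path:
    if format == "edf":
        return write_edf(rec, path)
    if format == "delimited":
        return write_delimited(rec, path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

def write_manifest(
    entries: Mapping[str, Mapping[str, str]], path: str | Path
) -> Path:
    """Write a cohort manifest: subject_id -> {condition -> recording path}."""
    path = Path(path)
    path.write_text(json.dumps(entries, indent=1, sort_keys=True))
    return path


def read_manifest(path: str | Path) -> dict[str, dict[str, str]]:
    return json.loads(Path(path).read_text())


def iter_manifest_recordings(
    manifest: Mapping[str, Mapping[str, str]],
    root: str | Path = ".",
    min_duration_s: float = MIN_DURATION_S,
) -> Iterable[EEGRecording]:
    """Yield validated recordings listed in a manifest, subject by subject."""
    root = Path(root)
    for subject_id in sorted(manifest):
        for condition in CONDITIONS:
            entry = manifest[subject_id].get(condition)
            if entry is None:
                continue
            yield read_recording(root / entry, min_duration_s=min_duration_s)
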