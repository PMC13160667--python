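"""File formats: EDF records, annotation CSV/JSON, manifests, YAML configs.

Records are written as single-channel EDF (European Data Format), one file
per 0.5 h interval, with physical dimension µV and a 1 s data-record
length.  The implementation covers exactly the subset of EDF this package
produces (one signal, integer-second duration, 16-bit samples); files read
back with standard EDF tooling.  The subject id is stored in the patient
field and the post-implant latency of the first sample in the recording
field (``t0_days=<days>``).

Annotations are CSV with the fixed header
``subject_id,klass,phase,start_s,duration_s`` (``start_s`` absolute
seconds since implant) plus a JSON mirror that additionally carries
``interval_index`` and ``event_id`` (which groups the phases of one
seizure).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import yaml

from .synthetic import (
    Cohort,
    CohortConfig,
    EEGRecord,
    EventAnnotation,
    IntervalInfo,
    SeizureParams,
    SubjectData,
    SubjectProfile,
    SWDParams,
    seizure_events,
)

__all__ = [
    "write_edf",
    "read_edf",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_annotations_json",
    "read_annotations_json",
    "write_manifest",
    "read_manifest",
    "write_cohort",
    "load_cohort",
    "write_predictions_csv",
    "config_to_yaml",
    "config_from_yaml",
]

ANNOTATION_HEADER = ["subject_id", "klass", "phase", "start_s", "duration_s"]


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(record: EEGRecord, path: str | Path) -> None:
    """Write a single-channel record as 16-bit EDF."""
    n_per_rec = int(round(record.fs))
    if abs(n_per_rec - record.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    if record.samples.size % n_per_rec:
        raise ValueError("EDF export requires an integer-second record")
    nr = record.samples.size // n_per_rec

    phys_max = float(np.ceil(max(np.max(np.abs(record.samples)), 1.0)))
    dig_max = 32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(record.samples.astype(np.float64) * scale),
                      -dig_max, dig_max).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad(record.subject_id, 80),
        _pad(f"Startdate 01-JAN-2000 t0_days={record.t0_days:.6f}", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * 2), 8),
        _pad("", 44),
        _pad(str(nr), 8),
        _pad("1", 8),
        _pad("1", 4),
        # per-signal header (one signal)
        _pad(record.channel, 16),
        _pad("", 80),
        _pad("uV", 8),
        _pad(str(-int(phys_max)), 8),
        _pad(str(int(phys_max)), 8),
        _pad(str(-dig_max), 8),
        _pad(str(dig_max), 8),
        _pad("", 80),
        _pad(str(n_per_rec), 8),
        _pad("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def read_edf(path: str | Path) -> EEGRecord:
    """Read a single-channel EDF written by :func:`write_edf`."""
    raw = Path(path).read_bytes()
    hdr = raw[:256]
    ns = int(hdr[252:256])
    if ns != 1:
        raise ValueError(f"expected a single-channel EDF, found {ns} signals")
    subject_id = hdr[8:88].decode("ascii").strip()
    recording = hdr[88:168].decode("ascii").strip()
    nr = int(hdr[236:244])
    rec_dur = float(hdr[244:252])

    sig = raw[256:512]
    channel = sig[0:16].decode("ascii").strip()
    phys_min = float(sig[104:112])
    phys_max = float(sig[112:120])
    dig_min = float(sig[120:128])
    dig_max = float(sig[128:136])
    n_per_rec = int(sig[216:224])

    data = np.frombuffer(raw[512:512 + 2 * nr * n_per_rec], dtype="<i2")
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    samples = phys_min + (data.astype(np.float64) - dig_min) * gain

    m = re.search(r"t0_days=([0-9.+-eE]+)", recording)
    t0_days = float(m.group(1)) if m else 0.0
    fs = n_per_rec / rec_dur
    return EEGRecord(subject_id, samples.astype(np.float32), fs=fs,
                     t0_days=t0_days, channel=channel)


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------

def write_annotations_csv(annotations: list[EventAnnotation],
                          path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ANNOTATION_HEADER)
        for a in annotations:
            w.writerow([a.subject_id, a.klass, a.phase,
                        f"{a.start_s:.4f}", f"{a.duration_s:.4f}"])


def read_annotations_csv(path: str | Path) -> list[EventAnnotation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(EventAnnotation(
                row["subject_id"], row["klass"], row["phase"],
                float(row["start_s"]), float(row["duration_s"])))
    return out


def write_annotations_json(annotations: list[EventAnnotation],
                           path: str | Path) -> None:
    payload = [dataclasses.asdict(a) for a in annotations]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations_json(path: str | Path) -> list[EventAnnotation]:
    return [EventAnnotation(**row)
            for row in json.loads(Path(path).read_text())]


# --------------------------------------------------------------------------
# manifest / cohort tree
# --------------------------------------------------------------------------

def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_cohort(cohort: Cohort, outdir: str | Path,
                 records: bool = True) -> dict:
    """Write a cohort tree: EDF per interval, annotations, manifest.

    Layout::

        outdir/
          manifest.json
          annotations.csv / annotations.json
          <subject_id>/interval_0000.edf ...

    Returns the manifest (with file paths added).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(cohort.manifest)
    files: dict[str, list[str]] = {}
    for sid in sorted(cohort.subjects):
        subj = cohort.subjects[sid]
        sdir = outdir / sid
        if records and subj.records:
            sdir.mkdir(exist_ok=True)
        files[sid] = []
        if records:
            for idx in sorted(subj.records):
                rel = f"{sid}/interval_{idx:04d}.edf"
                write_edf(subj.records[idx], outdir / rel)
                files[sid].append(rel)
    write_annotations_csv(cohort.annotations, outdir / "annotations.csv")
    write_annotations_json(cohort.annotations, outdir / "annotations.json")
    manifest["files"] = files
    manifest["annotations_csv"] = "annotations.csv"
    manifest["annotations_json"] = "annotations.json"
    write_manifest(manifest, outdir / "manifest.json")
    return manifest


def load_cohort(indir: str | Path) -> Cohort:
    """Load a cohort tree written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = read_manifest(indir / "manifest.json")
    annotations = read_annotations_json(indir / manifest["annotations_json"])
    by_subject: dict[str, list[EventAnnotation]] = {}
    for a in annotations:
        by_subject.setdefault(a.subject_id, []).append(a)

    subjects: dict[str, SubjectData] = {}
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        records: dict[int, EEGRecord] = {}
        for rel in manifest.get("files", {}).get(sid, []):
            idx = int(Path(rel).stem.split("_")[-1])
            records[idx] = read_edf(indir / rel)
        intervals = [IntervalInfo(idx, rec.t0_days)
                     for idx, rec in sorted(records.items())]
        anns = sorted(by_subject.get(sid, []), key=lambda a: a.start_s)
        events = seizure_events(anns)
        n_early = sum(s / 86400.0 <= 5.0 for _sid, _iv, s, _e in events)
        n_late = len(events) - n_early
        profile = SubjectProfile(
            group=entry["group"], has_early=entry.get("has_early", n_early > 0),
            has_late=entry.get("has_late", n_late > 0),
            n_early=n_early, n_late=n_late)
        subjects[sid] = SubjectData(sid, profile, intervals, records, anns)
    return Cohort(subjects=subjects, manifest=manifest)


PREDICTION_HEADER = ["subject_id", "interval_index", "epoch_index",
                     "label", "confidence"]


def write_predictions_csv(predictions, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PREDICTION_HEADER)
        for p in predictions:
            w.writerow([p.subject_id, p.interval_index, p.epoch_index,
                        p.label, f"{p.confidence:.6f}"])


# --------------------------------------------------------------------------
# YAML config
# --------------------------------------------------------------------------

def config_to_yaml(config: CohortConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["group_sizes"] = dict(d["group_sizes"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_from_yaml(path: str | Path) -> CohortConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key, cls in (("early_params", SeizureParams),
                     ("late_params", SeizureParams),
                     ("swd_params", SWDParams)):
        if key in d and isinstance(d[key], dict):
            sub = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in d[key].items()}
            d[key] = cls(**sub)
    for key in ("swd_rate_params",):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return CohortConfig(**d)
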