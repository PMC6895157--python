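"""File formats: WAV, annotation CSV, manifest CSV, feature-table CSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .params import FEATURE_TABLE_COLUMNS
from .synth import CallRecording, NLPAnnotation

ANNOTATION_COLUMNS = ("call_id", "phenomenon", "start_s", "end_s")
MANIFEST_COLUMNS = ("call_id", "individual_id", "context", "valence",
                    "wav_path")


def write_wav(path: str | Path, samples: np.ndarray,
              sample_rate: int) -> None:
    """PCM 16-bit mono WAV."""
    x = np.clip(np.asarray(samples, float), -1.0, 1.0)
    wavfile.write(str(path), sample_rate, (x * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file; integer PCM is rescaled to float in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, int(rate)


def write_dataset(recordings: list[CallRecording], out_dir: str | Path,
                  ) -> tuple[Path, Path]:
    """Write WAVs plus manifest and annotation CSVs; returns their paths."""
    out = Path(out_dir)
    wav_dir = out / "wav"
    wav_dir.mkdir(parents=True, exist_ok=True)
    man_rows, ann_rows = [], []
    for rec in recordings:
        wav_path = wav_dir / f"{rec.call_id}.wav"
        write_wav(wav_path, rec.samples, rec.sample_rate)
        man_rows.append({"call_id": rec.call_id,
                         "individual_id": rec.individual_id,
                         "context": rec.context, "valence": rec.valence,
                         "wav_path": str(wav_path.relative_to(out))})
        for ph, s, e in rec.annotation.events:
            ann_rows.append({"call_id": rec.call_id, "phenomenon": ph,
                             "start_s": s, "end_s": e})
    man_path = out / "manifest.csv"
    ann_path = out / "annotations.csv"
    pd.DataFrame(man_rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        man_path, index=False)
    pd.DataFrame(ann_rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        ann_path, index=False)
    return man_path, ann_path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    return df


def read_annotations(path: str | Path) -> dict[str, NLPAnnotation]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file lacks columns {sorted(missing)}")
    out: dict[str, NLPAnnotation] = {}
    for cid, sub in df.groupby("call_id"):
        events = [(r.phenomenon, float(r.start_s), float(r.end_s))
                  for r in sub.itertuples()]
        out[str(cid)] = NLPAnnotation(call_id=str(cid), events=events)
    return out


def load_dataset(manifest_path: str | Path,
                 annotations_path: str | Path) -> list[CallRecording]:
    """Reassemble CallRecordings from a manifest + annotation CSV pair."""
    man = read_manifest(manifest_path)
    anns = read_annotations(annotations_path)
    base = Path(manifest_path).parent
    recs = []
    for r in man.itertuples():
        samples, rate = read_wav(base / r.wav_path)
        ann = anns.get(str(r.call_id), NLPAnnotation(call_id=str(r.call_id)))
        recs.append(CallRecording(
            call_id=str(r.call_id), individual_id=str(r.individual_id),
            context=str(r.context), valence=str(r.valence),
            samples=samples, sample_rate=rate, annotation=ann))
    return recs


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=list(FEATURE_TABLE_COLUMNS))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    return df


def read_pitch_bounds(path: str | Path) -> dict[str, tuple[float, float]]:
    """Per-individual pitch settings: individual_id, floor_hz, ceiling_hz."""
    df = pd.read_csv(path)
    need = {"individual_id", "floor_hz", "ceiling_hz"}
    if not need <= set(df.columns):
        raise ValueError(f"pitch-bounds table needs columns {sorted(need)}")
    return {str(r.individual_id): (float(r.floor_hz), float(r.ceiling_hz))
            for r in df.itertuples()}
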