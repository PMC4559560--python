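"""Minimal WFDB (.hea/.dat/.atr) reading and writing, plus dataset CSV I/O.

Supports the subset of the PhysioNet waveform-database format family the
pipeline needs: header parsing, signal formats 16 (little-endian int16) and
212 (packed 12-bit pairs, the MIT-BIH arrhythmia format), and the standard
MIT annotation format including SKIP/NUM/SUB/CHN/AUX pseudo-annotations.
Annotation sample indices become R peaks; only beat annotations are kept, and
the class-symbol map is N -> NORMAL, L -> LBBB, R -> RBBB, everything else
OTHER (excluded downstream).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import BEAT_LENGTH, BeatDataset, CLASS_MAP, EcgRecord, SYMBOL_TO_CLASS

# MIT annotation codes <-> symbols (beat annotations only)
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 34: "e", 35: "n", 38: "f",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}
_BEAT_CODES = set(_CODE_TO_SYMBOL)
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


# ---------------------------------------------------------------------------
# annotations

def read_annotations(path: Path) -> tuple[list[int], list[str]]:
    """Read an MIT-format annotation file; returns (samples, symbols) of beat
    annotations only."""
    data = Path(path).read_bytes()
    samples: list[int] = []
    symbols: list[str] = []
    time = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            if i + 3 >= len(data):
                break
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            time += (hi << 16) | lo
        elif code == _AUX:
            n = interval + (interval & 1)  # aux strings are padded to even length
            i += n
        elif code in (_NUM, _SUB, _CHN):
            pass
        else:
            time += interval
            if code in _BEAT_CODES:
                samples.append(time)
                symbols.append(_CODE_TO_SYMBOL[code])
    return samples, symbols


def write_annotations(path: Path, samples, symbols) -> None:
    """Write beat annotations in MIT format (SKIP words for long intervals)."""
    out = bytearray()
    prev = 0
    for sample, symbol in zip(samples, symbols):
        code = _SYMBOL_TO_CODE.get(symbol, 13)  # unknown beats -> Q
        interval = int(sample) - prev
        if interval > 1023 or interval < 0:
            out += int((_SKIP << 10)).to_bytes(2, "little")
            out += ((interval >> 16) & 0xFFFF).to_bytes(2, "little")
            out += (interval & 0xFFFF).to_bytes(2, "little")
            interval = 0
        out += ((code << 10) | interval).to_bytes(2, "little")
        prev = int(sample)
    out += (0).to_bytes(2, "little")
    Path(path).write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# signals

def _read_dat(path: Path, fmt: int, n_sig: int, n_samp: int) -> np.ndarray:
    raw = Path(path).read_bytes()
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2")
        return flat[: n_sig * n_samp].reshape(-1, n_sig)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        n_pairs = len(b) // 3
        b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0 = np.where(s0 > 2047, s0 - 4096, s0)
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        flat = np.empty(2 * n_pairs, dtype=np.int32)
        flat[0::2] = s0
        flat[1::2] = s1
        return flat[: n_sig * n_samp].reshape(-1, n_sig)
    raise ValueError(f"unsupported WFDB signal format {fmt}")


def read_wfdb_record(path_or_id: str | Path) -> EcgRecord:
    """Read a WFDB record (header + first signal channel + beat annotations).

    ``path_or_id`` is the record path without extension.  A missing annotation
    file yields a record with empty r_peaks and a warning.
    """
    base = Path(path_or_id)
    header = (base.with_suffix(".hea")).read_text().splitlines()
    lines = [ln for ln in header if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    record_id = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    sig_line = lines[1].split()
    dat_name, fmt_field = sig_line[0], sig_line[1]
    fmt = int(fmt_field.split("x")[0].split(":")[0].split("+")[0])
    gain, baseline = 200.0, 0
    if len(sig_line) > 2:
        g = sig_line[2].split("/")[0]
        if "(" in g:
            g, b = g.split("(")
            baseline = int(b.rstrip(")"))
        if float(g) != 0:
            gain = float(g)
    adc = _read_dat(base.parent / dat_name, fmt, n_sig, n_samp)
    signal = (adc[:, 0].astype(float) - baseline) / gain

    atr = base.with_suffix(".atr")
    if atr.exists():
        samples, symbols = read_annotations(atr)
        keep = [(s, sym) for s, sym in zip(samples, symbols) if 0 <= s < len(signal)]
        samples = [s for s, _ in keep]
        symbols = [sym for _, sym in keep]
        if not samples:
            warnings.warn(f"annotation file for {record_id} contains no beat annotations")
    else:
        warnings.warn(f"no annotation file for record {record_id}")
        samples, symbols = [], []
    return EcgRecord(
        record_id=record_id,
        sampling_rate=fs,
        signal=signal,
        r_peaks=np.asarray(samples, dtype=int),
        beat_symbols=symbols,
    )


def write_wfdb_record(record: EcgRecord, directory: str | Path, gain: float = 200.0) -> Path:
    """Write a record as .hea/.dat (format 16) plus .atr beat annotations."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / record.record_id
    adc = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    base.with_suffix(".dat").write_bytes(adc.tobytes())
    fs = record.sampling_rate
    fs_txt = f"{fs:g}"
    base.with_suffix(".hea").write_text(
        f"{record.record_id} 1 {fs_txt} {len(adc)}\n"
        f"{record.record_id}.dat 16 {gain:g}/mV 16 0 {int(adc[0])} 0 0 ECG\n"
    )
    write_annotations(base.with_suffix(".atr"), record.r_peaks, record.beat_symbols)
    return base


# ---------------------------------------------------------------------------
# beat counting and dataset CSV

def count_beats_by_class(records: list[EcgRecord]) -> pd.DataFrame:
    """Interior-beat counts per record and class, with a TOTAL row.

    The first and last annotated beat of each record are excluded — they have
    no previous/next RR interval, matching the segmentation convention — and
    only N/L/R symbols are counted.
    """
    rows = {}
    for record in records:
        counts = {"NORMAL": 0, "LBBB": 0, "RBBB": 0}
        for symbol in record.beat_symbols[1:-1]:
            cls = SYMBOL_TO_CLASS.get(symbol)
            if cls is not None:
                counts[cls] += 1
        rows[record.record_id] = counts
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    table.loc["TOTAL"] = table.sum()
    return table


def write_dataset_csv(dataset: BeatDataset, path: str | Path) -> None:
    """Dataset CSV: 200 feature columns s001..s200 plus a label column."""
    names = [f"s{i:03d}" for i in range(1, BEAT_LENGTH + 1)]
    frame = pd.DataFrame(dataset.matrix, columns=names)
    inverse = dataset.class_names()
    frame["label"] = [inverse[code] for code in dataset.labels]
    frame.to_csv(path, index=False, float_format="%.12g")


def read_dataset_csv(path: str | Path) -> BeatDataset:
    frame = pd.read_csv(path)
    labels = frame.pop("label").map(CLASS_MAP)
    if labels.isna().any():
        raise ValueError("dataset CSV contains labels outside NORMAL/LBBB/RBBB")
    return BeatDataset(matrix=frame.to_numpy(dtype=float), labels=labels.to_numpy(dtype=int))


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")
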