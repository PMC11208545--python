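"""Minimal WFDB format support: headers, signal formats 212/16, MIT annotations.

Covers what arrhythmia-database records need — the ``.hea`` header grammar,
the packed 12-bit (format 212) and 16-bit little-endian (format 16) signal
encodings, and the MIT annotation byte stream — plus writers for format-16
records so fixtures can be produced and round-tripped without a download.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

# MIT annotation code <-> symbol table (beat + non-beat codes)
_CODE_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_CODE = {s: c for c, s in _CODE_SYMBOL.items()}

#: annotation symbols that mark heartbeats (as opposed to rhythm or quality events)
BEAT_SYMBOLS = frozenset("NLRBAaJSVrFejnE/fQ?")

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def read_header(path) -> dict:
    """Parse a ``.hea`` file; returns record name, n_sig, fs, n_samples and
    per-signal format/gain/baseline."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing WFDB header file: {path}")
    lines = [
        ln.strip() for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec = lines[0].split()
    record_name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, None
        if len(tok) > 2:
            g = tok[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        signals.append(
            {"file": fname, "fmt": int(fmt), "gain": gain, "baseline": baseline}
        )
    return {
        "record_name": record_name, "n_sig": n_sig, "fs": fs,
        "n_samples": n_samples, "signals": signals,
    }


def _decode_212(raw: np.ndarray, n_values: int) -> np.ndarray:
    raw = raw[: (len(raw) // 3) * 3].reshape(-1, 3).astype(np.int32)
    first = ((raw[:, 1] & 0x0F) << 8) | raw[:, 0]
    second = ((raw[:, 1] & 0xF0) << 4) | raw[:, 2]
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    out = np.empty(raw.shape[0] * 2, dtype=np.int32)
    out[0::2], out[1::2] = first, second
    return out[:n_values]


def read_signal(path, header: dict) -> np.ndarray:
    """Read all channels of a record into an (n_samples, n_sig) mV array.

    Assumes all signals live in a single .dat file (true of mitdb and of the
    package's own writer)."""
    path = Path(path)
    n_sig = header["n_sig"]
    dat = path.parent / header["signals"][0]["file"]
    if not dat.exists():
        raise FileNotFoundError(f"missing WFDB signal file: {dat}")
    raw = np.fromfile(dat, dtype=np.uint8)
    fmt = header["signals"][0]["fmt"]
    if fmt == 212:
        flat = _decode_212(raw, header["n_samples"] * n_sig)
    elif fmt == 16:
        flat = raw.view("<i2").astype(np.int32)[: header["n_samples"] * n_sig]
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    n = flat.shape[0] // n_sig
    dig = flat[: n * n_sig].reshape(n, n_sig).astype(np.float64)
    for ch, s in enumerate(header["signals"]):
        dig[:, ch] = (dig[:, ch] - s["baseline"]) / s["gain"]
    return dig


def read_annotations(path) -> list:
    """Decode a MIT-format annotation file into [(sample_index, symbol), ...]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing WFDB annotation file: {path}")
    raw = np.fromfile(path, dtype=np.uint8)
    out, t, i = [], 0, 0
    while i + 1 < len(raw):
        b0, b1 = int(raw[i]), int(raw[i + 1])
        code = b1 >> 2
        delta = ((b1 & 0x03) << 8) | b0
        i += 2
        if code == 0 and delta == 0:
            break
        if code == _SKIP:
            if i + 4 > len(raw):
                break
            jump = int.from_bytes(
                bytes([raw[i + 2], raw[i + 3], raw[i], raw[i + 1]]),
                "big", signed=True,
            )
            t += jump
            i += 4
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += delta + (delta & 1)
        else:
            t += delta
            out.append((t, _CODE_SYMBOL.get(code, "Q")))
    return out


def write_record(path, samples: np.ndarray, fs: float, annotations,
                 gain: float = 200.0) -> None:
    """Write a single-channel format-16 WFDB record (.hea/.dat/.atr)."""
    path = Path(path)
    samples = np.asarray(samples, dtype=np.float64)
    dig = np.clip(np.round(samples * gain), -32768, 32767).astype("<i2")
    name = path.name
    path.with_suffix(".dat").write_bytes(dig.tobytes())
    hea = (
        f"{name} 1 {fs:g} {len(samples)}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(dig[0]) if len(dig) else 0} 0 0 ECG\n"
    )
    path.with_suffix(".hea").write_text(hea)
    write_annotations(path.with_suffix(".atr"), annotations)


def write_annotations(path, annotations) -> None:
    """Write [(sample_index, symbol), ...] as a MIT-format annotation file."""
    buf = bytearray()
    prev = 0
    for idx, sym in annotations:
        code = _SYMBOL_CODE.get(sym, _SYMBOL_CODE["Q"])
        delta = int(idx) - prev
        while delta > 1023:  # emit a SKIP word for long gaps
            buf += bytes([0, _SKIP << 2])
            jump = delta - 1023
            b = jump.to_bytes(4, "big", signed=True)
            buf += bytes([b[2], b[3], b[0], b[1]])
            prev += jump
            delta = int(idx) - prev
        buf += bytes([delta & 0xFF, (code << 2) | ((delta >> 8) & 0x03)])
        prev = int(idx)
    buf += bytes([0, 0])
    Path(path).write_bytes(bytes(buf))
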