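"""WFDB/MIT-style record and annotation I/O.

Implements the subset of the WFDB conventions needed for ambulatory ECG
work: text headers (``.hea``), signal files in format 212 (packed 12-bit
pairs) and format 16 (little-endian int16), and MIT annotation files with
their time-delta encoding (SKIP/AUX pseudo-annotations included).  Sample
indices are 0-based and annotation times are stored in samples throughout.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, FormatError, IntegrityError

__all__ = [
    "EcgRecord",
    "AnnotationSet",
    "BEAT_SYMBOLS",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
    "count_beats",
]

#: MIT-BIH beat-class symbols (includes paced and fusion classes).  Codes
#: such as '+', '~', '|' mark rhythm changes or artifacts, not beats.
BEAT_SYMBOLS = frozenset("NLRejAaJSVEF/fQ")

# MIT annotation code <-> symbol table (standard WFDB code assignment).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class EcgRecord:
    """A multichannel sampled ECG in physical units (mV).

    ``signals`` has shape ``(n_channels, n_samples)``.  ``adc_gain`` is in
    ADC units per mV and ``baseline`` is the ADC value of 0 mV, both per
    channel; they are retained so records can be re-digitized losslessly.
    """

    record_name: str
    fs: float
    signals: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    adc_gain: np.ndarray | None = None
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=np.float64))
        n_ch = self.signals.shape[0]
        if self.fs <= 0:
            raise ConfigError(f"sampling frequency must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n_ch)]
        if len(self.channel_names) != n_ch:
            raise ConfigError("channel_names length does not match signal channels")
        if self.adc_gain is None:
            self.adc_gain = np.full(n_ch, 200.0)
        self.adc_gain = np.asarray(self.adc_gain, dtype=np.float64)
        if np.any(self.adc_gain <= 0):
            raise ConfigError("adc_gain must be positive per channel")
        if self.baseline is None:
            self.baseline = np.zeros(n_ch)
        self.baseline = np.asarray(self.baseline, dtype=np.float64)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


@dataclass
class AnnotationSet:
    """Ordered beat/rhythm labels at sample positions.

    ``sample_indices`` are strictly ascending 0-based positions, ``symbols``
    one MIT annotation code per position, and ``aux_labels`` optional rhythm
    strings (e.g. ``"(AFIB"``) attached to individual annotations.
    """

    sample_indices: np.ndarray
    symbols: list[str]
    aux_labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_indices = np.asarray(self.sample_indices, dtype=np.int64)
        self.symbols = list(self.symbols)
        if len(self.symbols) != len(self.sample_indices):
            raise ConfigError("symbols and sample_indices must have equal length")
        if not self.aux_labels:
            self.aux_labels = [None] * len(self.symbols)
        self.aux_labels = list(self.aux_labels)
        if len(self.aux_labels) != len(self.symbols):
            raise ConfigError("aux_labels length mismatch")
        if len(self.sample_indices) > 1 and np.any(np.diff(self.sample_indices) <= 0):
            raise ConfigError("sample_indices must be strictly ascending")
        if len(self.sample_indices) and self.sample_indices[0] < 0:
            raise ConfigError("sample_indices must be non-negative")
        unknown = {s for s in self.symbols if s not in _SYMBOL_TO_CODE}
        if unknown:
            raise ConfigError(f"unknown annotation symbols: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.sample_indices)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            np.array_equal(self.sample_indices, other.sample_indices)
            and self.symbols == other.symbols
            and self.aux_labels == other.aux_labels
        )

    def beats(self, beat_symbols: frozenset[str] = BEAT_SYMBOLS) -> "AnnotationSet":
        """Return the subset of annotations whose symbol is a beat class."""
        keep = [i for i, s in enumerate(self.symbols) if s in beat_symbols]
        return AnnotationSet(
            self.sample_indices[keep],
            [self.symbols[i] for i in keep],
            [self.aux_labels[i] for i in keep],
        )


# ---------------------------------------------------------------------------
# Format 212 / 16 sample packing
# ---------------------------------------------------------------------------

def _pack_212(samples: np.ndarray) -> bytes:
    """Pack a flat stream of 12-bit two's-complement samples, 2 per 3 bytes."""
    s = np.asarray(samples, dtype=np.int64)
    if np.any(s < -2048) or np.any(s > 2047):
        raise ConfigError("format 212 samples must fit in 12 bits")
    if s.size % 2:
        s = np.concatenate([s, [0]])
    u = np.where(s < 0, s + 4096, s).astype(np.uint16)
    s0, s1 = u[0::2], u[1::2]
    out = np.empty(3 * s0.size, dtype=np.uint8)
    out[0::3] = s0 & 0xFF
    out[1::3] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
    out[2::3] = s1 & 0xFF
    return out.tobytes()

def _unpack_212(data: bytes, n: int) -> np.ndarray:
    """Unpack ``n`` samples from format-212 bytes."""
    raw = np.frombuffer(data, dtype=np.uint8)
    if raw.size % 3:
        raise IntegrityError("format 212 stream length is not a multiple of 3")
    b0, b1, b2 = raw[0::3].astype(np.int64), raw[1::3].astype(np.int64), raw[2::3]
    s0 = ((b1 & 0x0F) << 8) | b0
    s1 = ((b1 & 0xF0) << 4) | b2
    flat = np.empty(2 * s0.size, dtype=np.int64)
    flat[0::2], flat[1::2] = s0, s1
    flat = np.where(flat > 2047, flat - 4096, flat)
    if flat.size < n:
        raise IntegrityError("format 212 stream shorter than declared sample count")
    return flat[:n]


# ---------------------------------------------------------------------------
# Header parsing / writing
# ---------------------------------------------------------------------------

_GAIN_RE = re.compile(r"^([0-9.eE+-]+)(?:\((-?\d+)\))?(?:/(\S+))?$")


def _parse_header(path: str) -> dict:
    try:
        with open(path, "r") as fh:
            lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    except OSError as exc:
        raise FormatError(f"cannot read header {path}: {exc}") from exc
    if not lines:
        raise FormatError(f"empty header file {path}")
    first = lines[0].split()
    if len(first) < 3:
        raise FormatError(f"garbled header record line: {lines[0]!r}")
    try:
        name = first[0].split("/")[0]
        n_sig = int(first[1])
        fs = float(first[2].split("/")[0])
        n_samples = int(first[3]) if len(first) > 3 else None
    except ValueError as exc:
        raise FormatError(f"garbled header record line: {lines[0]!r}") from exc
    if len(lines) < 1 + n_sig:
        raise FormatError("header declares more signals than it describes")
    sigs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"garbled signal line: {ln!r}")
        fname = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        adc_zero = 0
        if len(tok) > 2:
            m = _GAIN_RE.match(tok[2])
            if not m:
                raise FormatError(f"garbled gain field: {tok[2]!r}")
            gain = float(m.group(1)) or 200.0
            baseline = int(m.group(2)) if m.group(2) is not None else None
            units = m.group(3) or "mV"
        if len(tok) > 4:
            try:
                adc_zero = int(tok[4])
            except ValueError:
                pass
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(sigs)}"
        sigs.append(
            dict(
                fname=fname,
                fmt=fmt,
                gain=gain,
                baseline=baseline if baseline is not None else adc_zero,
                units=units,
                desc=desc,
            )
        )
    return dict(name=name, n_sig=n_sig, fs=fs, n_samples=n_samples, signals=sigs)


def read_record(path_prefix: str | os.PathLike) -> EcgRecord:
    """Read a WFDB record (header + signal file) into physical units.

    Supports signal formats 212 and 16; all channels must share one signal
    file.  Amplitudes are converted to mV as ``(adc - baseline) / adc_gain``.
    """
    path_prefix = os.fspath(path_prefix)
    hdr = _parse_header(path_prefix + ".hea")
    n_sig, n_samples = hdr["n_sig"], hdr["n_samples"]
    if n_samples is None:
        raise FormatError("header does not declare the number of samples")
    fmts = {s["fmt"] for s in hdr["signals"]}
    if len(fmts) != 1:
        raise FormatError("mixed signal formats are not supported")
    fmt = fmts.pop()
    if fmt not in (212, 16):
        raise FormatError(f"unsupported signal format {fmt} (only 212 and 16)")
    fnames = {s["fname"] for s in hdr["signals"]}
    if len(fnames) != 1:
        raise FormatError("multiple signal files are not supported")
    dat_path = os.path.join(os.path.dirname(path_prefix) or ".", fnames.pop())
    try:
        with open(dat_path, "rb") as fh:
            data = fh.read()
    except OSError as exc:
        raise FormatError(f"cannot read signal file {dat_path}: {exc}") from exc

    total = n_samples * n_sig
    if fmt == 212:
        expected = ((total + 1) // 2) * 3
        if len(data) != expected:
            raise IntegrityError(
                f"signal file has {len(data)} bytes, header implies {expected}"
            )
        flat = _unpack_212(data, total)
    else:
        expected = total * 2
        if len(data) != expected:
            raise IntegrityError(
                f"signal file has {len(data)} bytes, header implies {expected}"
            )
        flat = np.frombuffer(data, dtype="<i2").astype(np.int64)

    adc = flat.reshape(n_samples, n_sig).T
    gain = np.array([s["gain"] for s in hdr["signals"]])
    base = np.array([s["baseline"] for s in hdr["signals"]], dtype=np.float64)
    signals = (adc - base[:, None]) / gain[:, None]
    return EcgRecord(
        record_name=hdr["name"],
        fs=hdr["fs"],
        signals=signals,
        channel_names=[s["desc"] for s in hdr["signals"]],
        adc_gain=gain,
        baseline=base,
    )


def write_record(
    rec: EcgRecord, path_prefix: str | os.PathLike, fmt: int = 212
) -> None:
    """Write a record as ``<prefix>.hea`` + ``<prefix>.dat``.

    Signals are digitized with the record's per-channel gain/baseline and
    clipped to the format's range (12-bit for 212, 16-bit for 16).
    """
    path_prefix = os.fspath(path_prefix)
    if fmt not in (212, 16):
        raise FormatError(f"unsupported signal format {fmt} (only 212 and 16)")
    name = os.path.basename(path_prefix)
    adc = np.rint(rec.signals * rec.adc_gain[:, None] + rec.baseline[:, None])
    lo, hi = (-2048, 2047) if fmt == 212 else (-32768, 32767)
    adc = np.clip(adc, lo, hi).astype(np.int64)
    flat = adc.T.reshape(-1)
    data = _pack_212(flat) if fmt == 212 else flat.astype("<i2").tobytes()

    fs_str = f"{rec.fs:g}"
    lines = [f"{name} {rec.n_channels} {fs_str} {rec.n_samples}"]
    for i in range(rec.n_channels):
        g = f"{rec.adc_gain[i]:g}"
        b = int(round(rec.baseline[i]))
        bits = 12 if fmt == 212 else 16
        lines.append(
            f"{name}.dat {fmt} {g}({b})/mV {bits} {b} 0 0 0 {rec.channel_names[i]}"
        )
    try:
        with open(path_prefix + ".hea", "w") as fh:
            fh.write("\n".join(lines) + "\n")
        with open(path_prefix + ".dat", "wb") as fh:
            fh.write(data)
    except OSError as exc:
        raise IOError(f"cannot write record {path_prefix}: {exc}") from exc


# ---------------------------------------------------------------------------
# MIT annotation files
# ---------------------------------------------------------------------------

def read_annotations(path_prefix: str | os.PathLike, extension: str = "atr") -> AnnotationSet:
    """Read a MIT annotation file (``<prefix>.<extension>``).

    Decodes the 16-bit little-endian word stream: 6-bit annotation code plus
    10-bit time delta, with SKIP (long intervals), NUM/SUB/CHN (ignored) and
    AUX (rhythm strings) pseudo-annotations handled per the WFDB convention.
    """
    path = f"{os.fspath(path_prefix)}.{extension}"
    try:
        with open(path, "rb") as fh:
            data = fh.read()
    except OSError as exc:
        raise FormatError(f"cannot read annotation file {path}: {exc}") from exc
    return decode_annotation_bytes(data)


def decode_annotation_bytes(data: bytes) -> AnnotationSet:
    """Decode a raw MIT annotation byte stream into an :class:`AnnotationSet`."""
    if len(data) % 2:
        raise IntegrityError("annotation stream has an odd byte count")
    words = np.frombuffer(data, dtype="<u2")
    idxs: list[int] = []
    syms: list[str] = []
    auxs: list[str | None] = []
    t = 0
    i = 0
    saw_eof = len(words) == 0  # an empty body is a valid empty set
    while i < len(words):
        w = int(words[i])
        i += 1
        code, delta = w >> 10, w & 0x3FF
        if w == 0:
            saw_eof = True
            break
        if code == _SKIP and delta == 0:
            if i + 2 > len(words):
                raise IntegrityError("truncated SKIP interval")
            t += (int(words[i]) << 16) | int(words[i + 1])
            i += 2
        elif code in (_NUM, _SUB, _CHN):
            continue  # field modifiers; not represented in AnnotationSet
        elif code == _AUX:
            nbytes = delta + (delta % 2)
            byte_pos = 2 * i
            if byte_pos + nbytes > len(data):
                raise IntegrityError("truncated AUX string")
            raw = data[byte_pos : byte_pos + delta]
            aux = raw.rstrip(b"\x00").decode("latin-1")
            if auxs:
                auxs[-1] = aux
            i += nbytes // 2
        else:
            sym = _CODE_TO_SYMBOL.get(code)
            if sym is None:
                raise FormatError(f"unknown annotation code {code}")
            t += delta
            idxs.append(t)
            syms.append(sym)
            auxs.append(None)
    if not saw_eof:
        raise IntegrityError("annotation stream ended without EOF word")
    return AnnotationSet(np.array(idxs, dtype=np.int64), syms, auxs)


def encode_annotation_bytes(ann: AnnotationSet) -> bytes:
    """Encode an :class:`AnnotationSet` as a MIT annotation byte stream."""
    out = bytearray()

    def put(word: int) -> None:
        out.extend(int(word).to_bytes(2, "little"))

    t_prev = 0
    for idx, sym, aux in zip(ann.sample_indices, ann.symbols, ann.aux_labels):
        code = _SYMBOL_TO_CODE[sym]
        delta = int(idx) - t_prev
        if delta > 1023:
            put(_SKIP << 10)
            put((delta >> 16) & 0xFFFF)
            put(delta & 0xFFFF)
            delta = 0
        put((code << 10) | delta)
        t_prev = int(idx)
        if aux:
            raw = aux.encode("latin-1")
            if len(raw) > 1023:
                raise ConfigError("aux string longer than 1023 bytes")
            put((_AUX << 10) | len(raw))
            out += raw
            if len(raw) % 2:
                out += b"\x00"
    put(0)  # EOF
    return bytes(out)


def write_annotations(
    ann: AnnotationSet, path_prefix: str | os.PathLike, extension: str = "atr"
) -> str:
    """Write annotations so that :func:`read_annotations` round-trips exactly."""
    path = f"{os.fspath(path_prefix)}.{extension}"
    try:
        with open(path, "wb") as fh:
            fh.write(encode_annotation_bytes(ann))
    except OSError as exc:
        raise IOError(f"cannot write annotation file {path}: {exc}") from exc
    return path


def count_beats(
    ann: AnnotationSet, beat_symbols: frozenset[str] | set[str] = BEAT_SYMBOLS
) -> int:
    """Count annotations whose symbol is a beat class (rhythm/artifact codes excluded)."""
    return sum(1 for s in ann.symbols if s in beat_symbols)
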