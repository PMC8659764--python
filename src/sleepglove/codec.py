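"""Lossless block codec for the smart-glove recording format.

The device stores one red-light PPG channel at 100 Hz, SpO2 at 1 Hz and a
per-minute movement count in 4 KB flash blocks. Each block holds 25 rows of
157 bytes; row 1 carries a 4-byte running PPG sample counter (LSB-first),
every row carries a 2-byte useful-bit count (LSB-first) followed by a
prefix-coded payload. Payload tokens use an empirical Huffman prefix table:

    ======  ==========  =============================
    prefix  payload     meaning
    ======  ==========  =============================
    0       8 b signed  DD: PPG delta vs previous
    10      --          GB: garbage / artifact sample
    110     18 b        AV: absolute PPG value
    1110    3 b + 8 b   SF: scale code + DD quotient
    11110   6 b         SpO2 (percent minus 37)
    111110  16 b        movement count
    ======  ==========  =============================

The first data token of every block is AV, so each block decodes
independently and blocks may be stored (and transmitted) out of order.
A delta too wide for 8 bits is factored as ``scale * quotient`` over the
scale set {2,4,8,16,32,64,128,256}; when no exact factoring exists the
sample is re-sent as AV, which keeps the stream bit-exact. Samples outside
the 18-bit converter range are the only sanctioned loss: they are coded GB
(value dropped, counter still incremented) and the encoder re-syncs with AV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TokenKind",
    "Token",
    "EncodedRow",
    "EncodedBlock",
    "TransportFrame",
    "SampleStream",
    "CodecError",
    "SCALES",
    "PPG_MAX",
    "SPO2_OFFSET",
    "encode_delta",
    "encode_spo2",
    "decode_spo2",
    "encode_recording",
    "decode_file",
    "xor_checksum",
    "write_bin",
    "read_bin",
    "stream_to_csv",
    "stream_from_csv",
]

# --- format constants -------------------------------------------------------
N_ROWS = 25
ROW_BYTES = 157
ROW1_PAYLOAD_BYTES = 151          # 157 - 4 (counter) - 2 (useful bits)
ROW_PAYLOAD_BYTES = 155           # 157 - 2 (useful bits)
BLOCK_RAW_BYTES = N_ROWS * ROW_BYTES          # 3925
BLOCK_PADDED_BYTES = 4096                     # flash block size
SCALES = (2, 4, 8, 16, 32, 64, 128, 256)
PPG_BITS = 18
PPG_MAX = (1 << PPG_BITS) - 1
SPO2_OFFSET = 37
SPO2_MAX_CODE = 63
MOVE_MAX = (1 << 16) - 1

# channel cadence relative to the 100 Hz PPG clock
PPG_FS = 100
SPO2_STRIDE = 100                 # one SpO2 reading per 100 PPG samples (1 Hz)
MOVE_STRIDE = 6000                # one movement count per minute

# token bit widths including descriptor
_W_DD = 1 + 8
_W_GB = 2
_W_AV = 3 + PPG_BITS
_W_SF = 4 + 3 + 8                 # SF prefix+code, then the bare DD quotient
_W_SPO2 = 5 + 6
_W_MOVE = 6 + 16


class CodecError(ValueError):
    """Raised on malformed input to the encoder or a corrupt block."""


class TokenKind(Enum):
    DD = "DD"
    GB = "GB"
    AV = "AV"
    SF = "SF"
    SPO2 = "SPO2"
    MOVE = "MOVE"


@dataclass(frozen=True)
class Token:
    kind: TokenKind
    value: int | None = None

    def __post_init__(self) -> None:
        k, v = self.kind, self.value
        if k is TokenKind.GB:
            if v is not None:
                raise CodecError("GB carries no payload")
            return
        if v is None:
            raise CodecError(f"{k.value} requires a payload")
        limits = {
            TokenKind.DD: (-128, 127),
            TokenKind.AV: (0, PPG_MAX),
            TokenKind.SF: (0, 7),
            TokenKind.SPO2: (0, SPO2_MAX_CODE),
            TokenKind.MOVE: (0, MOVE_MAX),
        }
        lo, hi = limits[k]
        if not lo <= v <= hi:
            raise CodecError(f"{k.value} payload {v} outside [{lo}, {hi}]")


@dataclass
class EncodedRow:
    useful_bits: int
    payload: bytes

    def __post_init__(self) -> None:
        if self.useful_bits > 8 * len(self.payload):
            raise CodecError("useful_bits exceeds row capacity")


@dataclass
class EncodedBlock:
    """One 4 KB flash block: sample counter plus 25 prefix-coded rows."""

    sample_counter: int
    rows: list[EncodedRow]

    def to_bytes(self) -> bytes:
        if len(self.rows) != N_ROWS:
            raise CodecError(f"block must have {N_ROWS} rows")
        out = bytearray()
        for i, row in enumerate(self.rows):
            if i == 0:
                out += int(self.sample_counter).to_bytes(4, "little")
            out += int(row.useful_bits).to_bytes(2, "little")
            out += row.payload
        if len(out) != BLOCK_RAW_BYTES:
            raise CodecError("serialized block has wrong size")
        out += bytes(BLOCK_PADDED_BYTES - BLOCK_RAW_BYTES)
        return bytes(out)

    @classmethod
    def from_bytes(cls, raw: bytes) -> "EncodedBlock":
        if len(raw) < BLOCK_RAW_BYTES:
            raise CodecError("block too short")
        counter = int.from_bytes(raw[:4], "little")
        rows: list[EncodedRow] = []
        pos = 4
        for i in range(N_ROWS):
            n_payload = ROW1_PAYLOAD_BYTES if i == 0 else ROW_PAYLOAD_BYTES
            useful = int.from_bytes(raw[pos : pos + 2], "little")
            pos += 2
            payload = raw[pos : pos + n_payload]
            pos += n_payload
            if useful > 8 * n_payload:
                raise CodecError("corrupt row: useful_bits exceeds capacity")
            rows.append(EncodedRow(useful, payload))
        return cls(counter, rows)


@dataclass
class TransportFrame:
    """A block plus the JSON header sent over the radio link."""

    device_id: str
    checksum: int
    block_bytes: bytes

    @property
    def header(self) -> dict:
        return {"device_id": self.device_id, "checksum": self.checksum}

    def verify(self) -> bool:
        return xor_checksum(self.block_bytes) == self.checksum


@dataclass
class SampleStream:
    """Time-aligned decoded channels.

    ``ppg`` runs at 100 Hz; ``spo2`` at 1 Hz (value k stamped at PPG sample
    100k); ``movements`` one count per minute (stamped at PPG sample 6000m).
    Validity masks mark samples lost to GB artifacts or corrupt blocks;
    ``gaps`` lists half-open invalid PPG index ranges.
    """

    ppg: np.ndarray
    spo2: np.ndarray
    movements: np.ndarray
    ppg_valid: np.ndarray | None = None
    spo2_valid: np.ndarray | None = None
    movements_valid: np.ndarray | None = None
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=np.int64)
        self.spo2 = np.asarray(self.spo2, dtype=np.int64)
        self.movements = np.asarray(self.movements, dtype=np.int64)
        if self.ppg_valid is None:
            self.ppg_valid = np.ones(len(self.ppg), dtype=bool)
        if self.spo2_valid is None:
            self.spo2_valid = np.ones(len(self.spo2), dtype=bool)
        if self.movements_valid is None:
            self.movements_valid = np.ones(len(self.movements), dtype=bool)

    @property
    def duration_s(self) -> float:
        return len(self.ppg) / PPG_FS

    @property
    def spo2_artifact(self) -> np.ndarray:
        """SpO2 readings at the offset floor are artifact-coded."""
        return self.spo2 <= SPO2_OFFSET

    def equals(self, other: "SampleStream") -> bool:
        for a, b, m in (
            (self.ppg, other.ppg, self.ppg_valid & other.ppg_valid),
            (self.spo2, other.spo2, self.spo2_valid & other.spo2_valid),
            (self.movements, other.movements,
             self.movements_valid & other.movements_valid),
        ):
            if len(a) != len(b) or not np.array_equal(a[m], b[m]):
                return False
        return (
            np.array_equal(self.ppg_valid, other.ppg_valid)
            and np.array_equal(self.spo2_valid, other.spo2_valid)
            and np.array_equal(self.movements_valid, other.movements_valid)
        )


# --- scalar token operations ------------------------------------------------

def xor_checksum(data: Iterable[int]) -> int:
    """Fold XOR over a byte sequence, reduced to 8 bits (0 for empty)."""
    acc = 0
    for b in bytes(data):
        acc ^= b
    return acc & 0xFF


def encode_spo2(spo2_percent: int) -> Token:
    """Offset-encode an SpO2 percent reading into the 6-bit field.

    The stored code is ``spo2 - 37`` clamped to [0, 63]; code 0 is the
    artifact sentinel (readings below 37% are physiologically implausible
    for this sensor and flagged rather than stored).
    """
    code = int(spo2_percent) - SPO2_OFFSET
    if code < 0:
        code = 0
    if code > SPO2_MAX_CODE:
        logger.warning("SpO2 reading %s above representable range; clamped",
                       spo2_percent)
        code = SPO2_MAX_CODE
    return Token(TokenKind.SPO2, code)


def decode_spo2(code: int) -> int:
    return int(code) + SPO2_OFFSET


def encode_delta(prev_ppg: int, cur_ppg: int) -> list[Token]:
    """Encode one PPG sample relative to the previous one.

    Returns ``[DD(d)]`` when the delta fits signed 8 bits, ``[SF(s), DD(q)]``
    when the delta factors exactly as ``scale(s) * q`` (smallest admissible
    scale), else ``[AV(cur)]``. Decoding always reproduces ``cur_ppg``.
    """
    if not 0 <= cur_ppg <= PPG_MAX:
        raise CodecError(f"PPG value {cur_ppg} outside 18-bit range")
    d = int(cur_ppg) - int(prev_ppg)
    if -128 <= d <= 127:
        return [Token(TokenKind.DD, d)]
    for code, scale in enumerate(SCALES):
        if d % scale == 0 and -128 <= d // scale <= 127:
            return [Token(TokenKind.SF, code), Token(TokenKind.DD, d // scale)]
    return [Token(TokenKind.AV, int(cur_ppg))]


# --- block building ---------------------------------------------------------

class _BlockBuilder:
    """Packs prefix-coded bits into rows; tokens never straddle a row."""

    __slots__ = ("sample_counter", "rows", "acc", "nbits", "cap", "n_ppg")

    def __init__(self, sample_counter: int):
        self.sample_counter = sample_counter
        self.rows: list[tuple[int, int, int]] = []   # (useful, acc, cap)
        self.acc = 0
        self.nbits = 0
        self.cap = ROW1_PAYLOAD_BYTES * 8
        self.n_ppg = 0

    def _close_row(self) -> None:
        self.rows.append((self.nbits, self.acc, self.cap))
        self.acc = 0
        self.nbits = 0
        self.cap = ROW_PAYLOAD_BYTES * 8

    def try_append_group(self, parts: list[tuple[int, int]]) -> bool:
        """Append a group of (bits, width) atomically; False if the block
        cannot hold it (caller then closes the block and re-syncs)."""
        # fast path: all fit in the current row
        total = 0
        for _, w in parts:
            total += w
        if self.nbits + total <= self.cap:
            for bits, w in parts:
                self.acc = (self.acc << w) | bits
                self.nbits += w
            return True
        # slow path: may need row closes; simulate against block capacity
        saved = (list(self.rows), self.acc, self.nbits, self.cap)
        for bits, w in parts:
            if self.nbits + w > self.cap:
                self._close_row()
                if len(self.rows) == N_ROWS:
                    self.rows, self.acc, self.nbits, self.cap = saved
                    return False
            self.acc = (self.acc << w) | bits
            self.nbits += w
        return True

    def finish(self) -> EncodedBlock:
        self._close_row()
        while len(self.rows) < N_ROWS:
            self._close_row()
        rows = []
        for i, (useful, acc, cap) in enumerate(self.rows):
            n_payload = cap // 8
            payload = (acc << (cap - useful)).to_bytes(n_payload, "big")
            rows.append(EncodedRow(useful, payload))
        return EncodedBlock(self.sample_counter, rows)


def _ppg_parts(prev: int | None, cur: int) -> tuple[int, int, bool]:
    """(bits, width, resync) for one PPG sample; resync means AV was forced."""
    if prev is None:
        return (0b110 << PPG_BITS) | cur, _W_AV, True
    d = cur - prev
    if -128 <= d <= 127:
        return (0b0 << 8) | (d & 0xFF), _W_DD, False
    for code, scale in enumerate(SCALES):
        if d % scale == 0 and -128 <= d // scale <= 127:
            q = d // scale
            bits = (((0b1110 << 3) | code) << 8) | (q & 0xFF)
            return bits, _W_SF, False
    return (0b110 << PPG_BITS) | cur, _W_AV, True


def encode_recording(stream: SampleStream, device_id: str = "UPNEA-0") -> list[TransportFrame]:
    """Encode a full recording into transport frames.

    Every block starts with the 4-byte running sample counter and an AV
    token; SpO2/movement tokens are interleaved immediately after the PPG
    sample they are stamped on. Out-of-range or invalid PPG samples are
    coded GB (value lost, counter preserved) with an AV re-sync after.
    """
    ppg = np.asarray(stream.ppg, dtype=np.int64)
    if len(ppg) == 0:
        raise CodecError("empty PPG channel")
    spo2 = np.asarray(stream.spo2, dtype=np.int64)
    moves = np.asarray(stream.movements, dtype=np.int64)
    valid = np.asarray(stream.ppg_valid, dtype=bool)
    artifact = (~valid) | (ppg < 0) | (ppg > PPG_MAX)

    spo2_codes = [encode_spo2(int(v)).value for v in spo2]
    frames: list[TransportFrame] = []
    n = len(ppg)
    i = 0
    while i < n:
        builder = _BlockBuilder(sample_counter=i)
        prev: int | None = None
        while i < n:
            parts: list[tuple[int, int]] = []
            if artifact[i]:
                parts.append((0b10, _W_GB))
                nxt = None
            else:
                cur = int(ppg[i])
                bits, w, resync = _ppg_parts(prev, cur)
                parts.append((bits, w))
                nxt = cur
            if i % SPO2_STRIDE == 0 and i // SPO2_STRIDE < len(spo2_codes):
                parts.append(((0b11110 << 6) | spo2_codes[i // SPO2_STRIDE], _W_SPO2))
            if i % MOVE_STRIDE == 0 and i // MOVE_STRIDE < len(moves):
                mv = int(moves[i // MOVE_STRIDE])
                parts.append(((0b111110 << 16) | max(0, min(MOVE_MAX, mv)), _W_MOVE))
            if not builder.try_append_group(parts):
                break
            prev = nxt
            builder.n_ppg += 1
            i += 1
        block_bytes = builder.finish().to_bytes()
        frames.append(TransportFrame(device_id, xor_checksum(block_bytes), block_bytes))
    return frames


# --- decoding ---------------------------------------------------------------

class _RowReader:
    __slots__ = ("val", "cap", "pos", "useful")

    def __init__(self, row: EncodedRow):
        self.val = int.from_bytes(row.payload, "big")
        self.cap = 8 * len(row.payload)
        self.pos = 0
        self.useful = row.useful_bits

    def read(self, width: int) -> int:
        if self.pos + width > self.useful:
            raise CodecError("token overruns useful bits")
        out = (self.val >> (self.cap - self.pos - width)) & ((1 << width) - 1)
        self.pos += width
        return out


def _decode_block_events(block: EncodedBlock) -> list[tuple[str, int, int]]:
    """Yield (kind, a, b) events: PPG value ops, GB, SPO2 and MOVE codes."""
    events: list[tuple[str, int, int]] = []
    for row in block.rows:
        r = _RowReader(row)
        while r.pos < r.useful:
            ones = 0
            while r.read(1) == 1:
                ones += 1
                if ones > 5:
                    raise CodecError("invalid descriptor prefix")
            if ones == 0:       # DD
                b = r.read(8)
                events.append(("DD", b - 256 if b >= 128 else b, 0))
            elif ones == 1:     # GB
                events.append(("GB", 0, 0))
            elif ones == 2:     # AV
                events.append(("AV", r.read(PPG_BITS), 0))
            elif ones == 3:     # SF + bare quotient
                code = r.read(3)
                q = r.read(8)
                events.append(("SF", SCALES[code], q - 256 if q >= 128 else q))
            elif ones == 4:
                events.append(("SPO2", r.read(6), 0))
            else:
                events.append(("MOVE", r.read(16), 0))
    return events


def decode_file(frames: Sequence[TransportFrame]) -> SampleStream:
    """Reassemble a recording from frames in arbitrary order.

    Checksum-failing or unparseable blocks are dropped and their sample
    range recorded as a gap; duplicate sample counters keep the first
    occurrence. GB samples stay invalid (the enclosing segment is excluded
    downstream).
    """
    decoded: dict[int, list[tuple[str, int, int]]] = {}
    n_dropped = 0
    for frame in frames:
        if not frame.verify():
            n_dropped += 1
            continue
        try:
            block = EncodedBlock.from_bytes(frame.block_bytes)
            events = _decode_block_events(block)
        except CodecError:
            n_dropped += 1
            continue
        if block.sample_counter in decoded:
            logger.warning("duplicate block at counter %d; keeping first",
                           block.sample_counter)
            continue
        decoded[block.sample_counter] = events
    if n_dropped:
        logger.warning("%d corrupt block(s) dropped", n_dropped)
    if not decoded:
        raise CodecError("no decodable blocks")

    counters = sorted(decoded)
    # per-block PPG sample counts fix the global span and expose gaps
    block_n_ppg = {
        c: sum(1 for k, _, _ in decoded[c] if k in ("DD", "AV", "SF", "GB"))
        for c in counters
    }
    n_total = counters[-1] + block_n_ppg[counters[-1]]
    ppg = np.zeros(n_total, dtype=np.int64)
    ppg_valid = np.zeros(n_total, dtype=bool)
    n_spo2 = (n_total - 1) // SPO2_STRIDE + 1
    n_move = (n_total - 1) // MOVE_STRIDE + 1
    spo2 = np.full(n_spo2, SPO2_OFFSET, dtype=np.int64)   # artifact sentinel
    spo2_valid = np.zeros(n_spo2, dtype=bool)
    moves = np.zeros(n_move, dtype=np.int64)
    moves_valid = np.zeros(n_move, dtype=bool)

    gaps: list[tuple[int, int]] = []
    expected = 0
    for c in counters:
        if c > expected:
            gaps.append((expected, c))
        expected = max(expected, c + block_n_ppg[c])
        idx = c - 1                      # index of last decoded PPG sample
        prev: int | None = None
        for kind, a, b in decoded[c]:
            if kind == "AV":
                idx += 1
                prev = a
                ppg[idx] = a
                ppg_valid[idx] = True
            elif kind == "DD":
                idx += 1
                if prev is None:
                    raise CodecError("DD before any AV in block")
                prev += a
                ppg[idx] = prev
                ppg_valid[idx] = True
            elif kind == "SF":
                idx += 1
                if prev is None:
                    raise CodecError("SF before any AV in block")
                prev += a * b
                ppg[idx] = prev
                ppg_valid[idx] = True
            elif kind == "GB":
                idx += 1
                prev = None
                gaps.append((idx, idx + 1))
            elif kind == "SPO2":
                k = idx // SPO2_STRIDE   # stamped at last PPG sample
                spo2[k] = decode_spo2(a)
                spo2_valid[k] = True
            elif kind == "MOVE":
                moves[idx // MOVE_STRIDE] = a
                moves_valid[idx // MOVE_STRIDE] = True
    gaps.sort()
    return SampleStream(ppg, spo2, moves, ppg_valid, spo2_valid, moves_valid, gaps)


# --- container / file I/O ---------------------------------------------------

def write_bin(frames: Sequence[TransportFrame], path, *, rng: np.random.Generator | None = None) -> None:
    """Write frames as length-prefixed JSON header + 4 KB block records.

    When ``rng`` is given frames are shuffled on disk, emulating the
    non-chronological flash layout the decoder must tolerate.
    """
    order = np.arange(len(frames))
    if rng is not None:
        rng.shuffle(order)
    with open(path, "wb") as fh:
        for k in order:
            frame = frames[int(k)]
            hdr = json.dumps(frame.header, separators=(",", ":")).encode()
            fh.write(len(hdr).to_bytes(4, "little"))
            fh.write(hdr)
            fh.write(frame.block_bytes)


def read_bin(path) -> list[TransportFrame]:
    frames: list[TransportFrame] = []
    with open(path, "rb") as fh:
        while True:
            raw_len = fh.read(4)
            if not raw_len:
                break
            hdr_len = int.from_bytes(raw_len, "little")
            hdr = json.loads(fh.read(hdr_len))
            block = fh.read(BLOCK_PADDED_BYTES)
            frames.append(TransportFrame(hdr["device_id"], hdr["checksum"], block))
    return frames


def stream_to_csv(stream: SampleStream, path) -> None:
    """Unpacked-signal CSV: time_s, ppg, spo2, movements (sparse cells)."""
    n = len(stream.ppg)
    time_s = np.arange(n) / PPG_FS
    ppg = stream.ppg.astype(float)
    ppg[~stream.ppg_valid] = np.nan
    spo2 = np.full(n, np.nan)
    k = np.arange(len(stream.spo2)) * SPO2_STRIDE
    k = k[k < n]
    spo2[k] = np.where(stream.spo2_valid[: len(k)], stream.spo2[: len(k)], np.nan)
    moves = np.full(n, np.nan)
    m = np.arange(len(stream.movements)) * MOVE_STRIDE
    m = m[m < n]
    moves[m] = np.where(stream.movements_valid[: len(m)],
                        stream.movements[: len(m)], np.nan)
    pd.DataFrame({"time_s": time_s, "ppg": ppg, "spo2": spo2,
                  "movements": moves}).to_csv(path, index=False)


def stream_from_csv(path) -> SampleStream:
    df = pd.read_csv(path)
    ppg = df["ppg"].to_numpy()
    ppg_valid = np.isfinite(ppg)
    spo2_rows = df["spo2"].dropna()
    moves_rows = df["movements"].dropna()
    return SampleStream(
        ppg=np.nan_to_num(ppg).astype(np.int64),
        spo2=spo2_rows.to_numpy().astype(np.int64),
        movements=moves_rows.to_numpy().astype(np.int64),
        ppg_valid=ppg_valid,
    )
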