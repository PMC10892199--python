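"""Bit-exact codec for the acquisition board's 26-byte serial packets.

Each packet carries one simultaneous sample of all eight channels: a
header byte, 8 x 3 bytes of signed 24-bit ADC codes (big-endian two's
complement, channel order 1..8), and a tail byte.  At 250 SPS with 8-N-1
serial framing this is 26 * 250 * 10 = 65,000 bps, comfortably inside a
115,200 bps link — the analytic real-time-transmission check.

Header/tail values and byte order on the real device are not published;
the defaults (0xAA/0x55, big-endian) are common sync bytes and the ADC
family's standard data format, and both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PACKET_LEN",
    "DEFAULT_HEADER",
    "DEFAULT_TAIL",
    "CODE_MIN",
    "CODE_MAX",
    "PacketFrame",
    "AdcConfig",
    "StreamDiagnostics",
    "encode_packet",
    "decode_packet",
    "encode_stream",
    "decode_stream",
    "code_to_microvolts",
    "microvolts_to_code",
    "serial_throughput_bps",
]

PACKET_LEN = 26
N_CHANNELS = 8
DEFAULT_HEADER = 0xAA
DEFAULT_TAIL = 0x55
CODE_MIN = -(2**23)
CODE_MAX = 2**23 - 1

_VALID_GAINS = (1, 2, 4, 6, 8, 12, 24)
_VALID_RATES = (250, 500, 1000, 2000, 4000)


@dataclass(frozen=True)
class PacketFrame:
    """One decoded 26-byte packet: header, 8 ADC codes, tail."""

    samples: tuple[int, ...]
    header: int = DEFAULT_HEADER
    tail: int = DEFAULT_TAIL

    def __post_init__(self) -> None:
        samples = tuple(int(s) for s in self.samples)
        if len(samples) != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} samples per frame")
        for s in samples:
            if not CODE_MIN <= s <= CODE_MAX:
                raise ValueError(f"sample {s} outside signed 24-bit range")
        for b in (self.header, self.tail):
            if not 0 <= b <= 0xFF:
                raise ValueError("header/tail must be single bytes")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class AdcConfig:
    """Front-end configuration needed to convert ADC codes to volts."""

    vref: float = 4.5
    pga_gain: int = 12
    fs: int = 250

    def __post_init__(self) -> None:
        if self.vref <= 0:
            raise ValueError("vref must be > 0")
        if self.pga_gain not in _VALID_GAINS:
            raise ValueError(f"pga_gain must be one of {_VALID_GAINS}")
        if self.fs not in _VALID_RATES:
            raise ValueError(f"fs must be one of {_VALID_RATES}")

    @property
    def lsb_microvolts(self) -> float:
        """Input-referred size of one ADC code, in microvolts."""
        return (2.0 * self.vref / self.pga_gain) / 2**24 * 1e6


def encode_packet(frame: PacketFrame, byteorder: str = "big") -> bytes:
    """Serialize a frame to its 26-byte wire form."""
    body = b"".join(
        s.to_bytes(3, byteorder, signed=True) for s in frame.samples  # type: ignore[arg-type]
    )
    return bytes([frame.header]) + body + bytes([frame.tail])


def decode_packet(
    buf: bytes,
    header: int = DEFAULT_HEADER,
    tail: int = DEFAULT_TAIL,
    byteorder: str = "big",
) -> PacketFrame:
    """Parse exactly one 26-byte packet; raises on framing mismatch."""
    if len(buf) != PACKET_LEN:
        raise ValueError(f"packet must be exactly {PACKET_LEN} bytes")
    if buf[0] != header or buf[-1] != tail:
        raise ValueError("header/tail framing mismatch")
    samples = tuple(
        int.from_bytes(buf[1 + 3 * i : 4 + 3 * i], byteorder, signed=True)  # type: ignore[arg-type]
        for i in range(N_CHANNELS)
    )
    return PacketFrame(samples, header=buf[0], tail=buf[-1])


def encode_stream(frames: Iterable[PacketFrame], byteorder: str = "big") -> bytes:
    return b"".join(encode_packet(f, byteorder) for f in frames)


@dataclass
class StreamDiagnostics:
    n_frames: int = 0
    resyncs: int = 0
    dropped_bytes: int = 0
    trailing_bytes: int = 0


def decode_stream(
    data: bytes,
    header: int = DEFAULT_HEADER,
    tail: int = DEFAULT_TAIL,
    byteorder: str = "big",
) -> tuple[list[PacketFrame], StreamDiagnostics]:
    """Scan a byte stream for framed packets, resynchronizing on garbage.

    On a framing violation the scanner advances one byte and retries;
    each contiguous run of skipped bytes counts as one resync.  Decoding
    is prefix-stable: appending bytes never changes frames already
    emitted.  An incomplete packet at the end is reported as
    ``trailing_bytes`` (it may complete when more bytes arrive).
    """
    frames: list[PacketFrame] = []
    diag = StreamDiagnostics()
    i = 0
    in_garbage = False
    n = len(data)
    while i < n:
        if n - i < PACKET_LEN:
            if data[i] == header:
                break  # plausible packet start, awaiting more bytes
            diag.dropped_bytes += 1
            if not in_garbage:
                diag.resyncs += 1
                in_garbage = True
            i += 1
            continue
        if data[i] == header and data[i + PACKET_LEN - 1] == tail:
            frames.append(decode_packet(data[i : i + PACKET_LEN], header, tail, byteorder))
            diag.n_frames += 1
            i += PACKET_LEN
            in_garbage = False
        else:
            diag.dropped_bytes += 1
            if not in_garbage:
                diag.resyncs += 1
                in_garbage = True
            i += 1
    diag.trailing_bytes = n - i
    return frames, diag


def code_to_microvolts(code: int, cfg: AdcConfig | None = None) -> float:
    """Convert a signed 24-bit ADC code to input-referred microvolts."""
    cfg = AdcConfig() if cfg is None else cfg
    if not CODE_MIN <= code <= CODE_MAX:
        raise ValueError("code outside signed 24-bit range")
    return code * cfg.lsb_microvolts


def microvolts_to_code(uv: float, cfg: AdcConfig | None = None) -> int:
    """Quantize an input-referred voltage (uV) to the nearest ADC code."""
    cfg = AdcConfig() if cfg is None else cfg
    code = int(round(uv / cfg.lsb_microvolts))
    if not CODE_MIN <= code <= CODE_MAX:
        raise ValueError("voltage exceeds the ADC input range")
    return code


def frames_to_matrix(frames: Sequence[PacketFrame], cfg: AdcConfig | None = None) -> np.ndarray:
    """Stack decoded frames into an (8, n_frames) microvolt matrix."""
    cfg = AdcConfig() if cfg is None else cfg
    if not frames:
        return np.empty((N_CHANNELS, 0))
    codes = np.array([f.samples for f in frames], dtype=float).T
    return codes * cfg.lsb_microvolts


def serial_throughput_bps(
    fs: int = 250, packet_bytes: int = PACKET_LEN, bits_per_byte: int = 10
) -> int:
    """Serial link load: packets/s x bytes/packet x bits/byte (8-N-1)."""
    return fs * packet_bytes * bits_per_byte
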