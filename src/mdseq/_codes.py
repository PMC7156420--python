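"""Fast 2-bit base coding shared by the simulator and bulk callers."""

from __future__ import annotations

import numpy as np

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase

_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)

#: complement in code space (A<->T, C<->G)
COMP = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    codes = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"non-ACGT base {seq[bad]!r} at position {bad + 1}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode()


def decode_rows(matrix: np.ndarray) -> list[str]:
    """Decode each row of an (n, L) code matrix to a string."""
    raw = _DEC[matrix].tobytes()
    L = matrix.shape[1]
    return [raw[i : i + L].decode() for i in range(0, len(raw), L)]
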