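"""Genome container and low-level sequence encoding helpers.

Sequences are kept as plain uppercase strings; hot loops convert to 2-bit
numpy codes (A=0, C=1, G=2, T=3, anything else 4) on demand.  All coordinates
throughout the package are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """2-bit encode a sequence (non-ACGT -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


@dataclass
class Genome:
    """Ordered collection of named chromosome sequences."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def fetch(self, name: str, start: int, end: int) -> str:
        """Subsequence on chromosome `name` ([start, end), clipped to bounds)."""
        seq = self.sequences[name]
        return seq[max(0, start) : min(len(seq), end)]
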