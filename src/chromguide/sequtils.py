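"""Small sequence helpers shared across modules."""

from __future__ import annotations

from typing import Dict

import numpy as np
from Bio import SeqIO

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
_BASE2CODE = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; any other base becomes 4 (never matches)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE2CODE.items():
        out[arr == ord(base)] = code
    return out


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
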