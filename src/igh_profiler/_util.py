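"""Small shared helpers: sequence ops, FASTA/FASTQ I/O, atomic writes."""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Dict, Iterable, Tuple

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA file into an ordered {name: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[Tuple[str, str]], path, width: int = 80) -> None:
    with atomic_open(path) as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class atomic_open:
    """Write to a temp file in the target directory, rename on success."""

    def __init__(self, path, mode: str = "w"):
        self.path = Path(path)
        self.mode = mode

    def __enter__(self):
        fd, self._tmp = tempfile.mkstemp(
            dir=self.path.parent, prefix=self.path.name + ".", suffix=".tmp"
        )
        self._fh = os.fdopen(fd, self.mode)
        return self._fh

    def __exit__(self, exc_type, exc, tb):
        self._fh.close()
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            os.unlink(self._tmp)
        return False
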