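"""Adapters around external command-line tools.

Raw-sequence inputs (FASTA/FASTQ reads, contigs) are aligned with
minimap2 invoked as a subprocess; the adapter validates the output and
surfaces the tool's stderr on failure.  Command templates are
configurable so an alternative long-read aligner can be dropped in.
"""

from __future__ import annotations

import shutil
import subprocess
from pathlib import Path
from typing import Optional, Sequence


class AdapterError(RuntimeError):
    """External command failed; carries the captured stderr."""


DEFAULT_MINIMAP2_TEMPLATE = (
    "minimap2 -a -x {preset} --secondary=no -t 1 {reference} {query}"
)


def minimap2_available() -> bool:
    return shutil.which("minimap2") is not None


def minimap2_align(
    reference: Path,
    query: Path,
    out_sam: Path,
    preset: str = "map-hifi",
    template: str = DEFAULT_MINIMAP2_TEMPLATE,
    extra_args: Sequence[str] = (),
) -> Path:
    """Align query sequences against a reference FASTA, writing SAM."""
    cmd = template.format(
        preset=preset, reference=str(reference), query=str(query)
    ).split()
    cmd[1:1] = list(extra_args)
    try:
        with open(out_sam, "w") as out:
            proc = subprocess.run(
                cmd, stdout=out, stderr=subprocess.PIPE, text=True
            )
    except FileNotFoundError as exc:
        raise AdapterError(f"aligner not found: {cmd[0]}") from exc
    if proc.returncode != 0:
        raise AdapterError(
            f"{cmd[0]} exited {proc.returncode}:\n{proc.stderr}"
        )
    if not Path(out_sam).stat().st_size:
        raise AdapterError(f"{cmd[0]} produced an empty SAM")
    return Path(out_sam)
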