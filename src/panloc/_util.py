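"""Small shared helpers: sequence utilities and plain-text FASTA/FASTQ output."""

from __future__ import annotations

from pathlib import Path
from typing import IO, Iterable

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _as_handle(dest, mode: str = "w"):
    if hasattr(dest, "write"):
        return dest, False
    return open(Path(dest), mode), True


def write_fasta(records: Iterable[tuple[str, str]], dest, width: int = 80) -> None:
    """Write ``(header, sequence)`` pairs as FASTA to a path or open handle."""
    handle, owned = _as_handle(dest)
    try:
        for header, seq in records:
            handle.write(f">{header}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if owned:
            handle.close()


def write_fastq(records: Iterable[tuple[str, str, str]], dest) -> None:
    """Write ``(name, sequence, quality)`` triples as FASTQ."""
    handle, owned = _as_handle(dest)
    try:
        for name, seq, qual in records:
            handle.write(f"@{name}\n{seq}\n+\n{qual}\n")
    finally:
        if owned:
            handle.close()


def read_fasta(source) -> dict[str, str]:
    """Read a (small) FASTA file or handle into an ordered name -> sequence dict."""
    handle, owned = _as_handle(source, "r")
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    try:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            out[name] = "".join(chunks)
    finally:
        if owned:
            handle.close()
    return out
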