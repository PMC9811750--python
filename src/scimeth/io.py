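"""Plain-text I/O and sequence-encoding helpers shared across the pipeline.

Sequences are held internally as ``numpy.uint8`` code arrays
(A=0, C=1, G=2, T=3, N=4); strings appear only at file boundaries.
All genomic intervals are 0-based half-open (BED convention); CGmap
positions are 1-based, per that format's standard.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

# --- sequence codes ---------------------------------------------------------

A, C, G, T, N = 0, 1, 2, 3, 4

_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement lookup in code space (N -> N)
_COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string as a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an uppercase DNA string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return codes_to_seq(revcomp_codes(seq_to_codes(seq)))


# --- FASTA ------------------------------------------------------------------

def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    contigs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    contigs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
        if name is not None:
            contigs[name] = "".join(chunks)
    return contigs


def write_fasta(path, contigs: dict[str, str], width: int = 80) -> None:
    with _open(path, "wt") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- FASTQ ------------------------------------------------------------------

def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a 4-line FASTQ file (gz ok)."""
    with _open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip()
            fh.readline()  # '+'
            qual = fh.readline().rstrip()
            yield header.rstrip()[1:].split()[0], seq, qual


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with _open(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# --- BED --------------------------------------------------------------------

BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (3-6 columns, 0-based half-open) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in df:
            df[col] = default
    return df[BED_COLUMNS]


def write_bed(path, df: pd.DataFrame) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# --- CGmap ------------------------------------------------------------------

CGMAP_COLUMNS = [
    "contig",
    "nucleotide",
    "position",
    "context",
    "dinucleotide",
    "level",
    "methylated",
    "coverage",
]


def write_cgmap(path, calls: pd.DataFrame) -> None:
    """Write per-cytosine calls in the 8-column CGmap dialect.

    Columns: contig, nucleotide on the Watson strand (C for plus-strand
    cytosines, G for minus-strand ones), 1-based position, context
    (CG/CHG/CHH), cytosine dinucleotide, methylation level, methylated
    count, coverage.
    """
    calls[CGMAP_COLUMNS].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def read_cgmap(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=CGMAP_COLUMNS)
    return df
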