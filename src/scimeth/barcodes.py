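"""Combinatorial-index demultiplexing.

Each read pair carries three indexes: i7 (read I1) and Tn5 + i5
(concatenated in read I2).  A pair is assigned to the cell ``Tn5:i5:i7``
iff *every* index matches a whitelist entry uniquely within a Hamming
distance strictly below ``max_hamming`` (default 3, i.e. up to two
substitutions are corrected).  Ties at the minimum distance are rejected
as ambiguous so that no read can be routed to the wrong cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import seq_to_codes


class FormatError(ValueError):
    """Desynchronized or malformed input streams."""


@dataclass
class IndexDesign:
    """Index-read layout: lengths of each barcode and the matching threshold.

    I2 is the concatenation Tn5 then i5; `i5_length` is 10 for the NovaSeq
    dialect and 9 for NextSeq.  `max_hamming` is an exclusive threshold: a
    barcode matches when its distance is < max_hamming.
    """

    tn5_length: int = 11
    i5_length: int = 10
    i7_length: int = 10
    max_hamming: int = 3

    def __post_init__(self):
        if min(self.tn5_length, self.i5_length, self.i7_length) <= 0:
            raise ValueError("index lengths must be positive")
        if self.max_hamming < 1:
            raise ValueError("max_hamming must be >= 1")

    @property
    def i2_length(self) -> int:
        return self.tn5_length + self.i5_length

    def split_i2(self, i2: str) -> tuple[str, str]:
        return i2[: self.tn5_length], i2[self.tn5_length : self.i2_length]


def hamming(a: str, b: str) -> int:
    """Hamming distance; any base (including N) differs from any other base.

    N equals N (identical characters never count as a difference).
    """
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b))


def match_index(
    observed: str, whitelist: Sequence[str], max_hamming: int = 3
) -> tuple[int | None, int, bool]:
    """Match one observed index against a whitelist.

    Returns (whitelist index or None, best distance, tie flag).  The match
    is accepted only when the minimum distance is < max_hamming and is
    attained by exactly one entry.
    """
    if len(whitelist) == 0:
        raise ValueError("empty whitelist")
    best_i, best_d, tie = None, len(observed) + 1, False
    for i, entry in enumerate(whitelist):
        d = hamming(observed, entry)
        if d < best_d:
            best_i, best_d, tie = i, d, False
        elif d == best_d:
            tie = True
    if best_d >= max_hamming or tie:
        return None, best_d, tie
    return best_i, best_d, False


def _encode_whitelist(whitelist: Sequence[str]) -> np.ndarray:
    return np.stack([seq_to_codes(w) for w in whitelist])


def _match_block(
    observed: np.ndarray, wl: np.ndarray, max_hamming: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized matching: (best index, best distance, ok flag) per row.

    ok is False for no-match (distance >= max_hamming) and for ties.
    """
    n = observed.shape[0]
    best_idx = np.zeros(n, dtype=np.int32)
    best_d = np.zeros(n, dtype=np.int32)
    ok = np.zeros(n, dtype=bool)
    chunk = max(1, 8_000_000 // max(1, wl.size))
    for lo in range(0, n, chunk):
        obs = observed[lo : lo + chunk]
        dmat = (obs[:, None, :] != wl[None, :, :]).sum(axis=2)
        bi = dmat.argmin(axis=1)
        bd = dmat[np.arange(len(obs)), bi]
        tie = (dmat == bd[:, None]).sum(axis=1) > 1
        best_idx[lo : lo + chunk] = bi
        best_d[lo : lo + chunk] = bd
        ok[lo : lo + chunk] = (bd < max_hamming) & ~tie
    return best_idx, best_d, ok


@dataclass
class DemuxResult:
    """Assignment table, per-cell read indices and summary counts."""

    assignments: pd.DataFrame  # read_id, status, cell_id, d_tn5, d_i5, d_i7
    cells: dict[str, np.ndarray]  # cell name -> row indices into the input streams
    summary: dict


def demultiplex(
    r1: Sequence[tuple[str, str, str]],
    r2: Sequence[tuple[str, str, str]],
    i1: Sequence[tuple[str, str, str]],
    i2: Sequence[tuple[str, str, str]],
    design: IndexDesign,
    whitelists: dict[str, Sequence[str]],
    outdir=None,
) -> DemuxResult:
    """Assign read pairs to cells from their three index reads.

    `whitelists` maps 'tn5', 'i5', 'i7' to barcode lists.  The four streams
    must be record-synchronized; a read-id mismatch raises FormatError naming
    the offending record.  Status per read pair:

    - ``unmatched`` — some index has no whitelist entry within the threshold;
    - ``ambiguous`` — every index is within threshold but at least one has a
      tie at its minimum distance;
    - ``assigned``  — all three match uniquely; routed to cell ``Tn5:i5:i7``.

    When `outdir` is given, per-cell FASTQ files ``<Tn5>_<i5>_<i7>.R{1,2}.fastq``
    are written alongside the assignment TSV and a JSON summary.
    """
    nrec = len(r1)
    if not (len(r2) == len(i1) == len(i2) == nrec):
        raise FormatError("input streams differ in record count")
    ids = [rec[0] for rec in r1]
    for k, streams in (("R2", r2), ("I1", i1), ("I2", i2)):
        for j in range(nrec):
            if streams[j][0] != ids[j]:
                raise FormatError(f"{k} desynchronized at record {j + 1}")

    tn5_obs = np.zeros((nrec, design.tn5_length), dtype=np.uint8)
    i5_obs = np.zeros((nrec, design.i5_length), dtype=np.uint8)
    i7_obs = np.zeros((nrec, design.i7_length), dtype=np.uint8)
    for j in range(nrec):
        i2_seq = i2[j][1]
        if len(i2_seq) < design.i2_length:
            raise FormatError(f"I2 record {j + 1} shorter than Tn5+i5 layout")
        tn5_obs[j] = seq_to_codes(i2_seq[: design.tn5_length])
        i5_obs[j] = seq_to_codes(i2_seq[design.tn5_length : design.i2_length])
        i7_obs[j] = seq_to_codes(i1[j][1][: design.i7_length])

    results = {}
    for key, obs in (("tn5", tn5_obs), ("i5", i5_obs), ("i7", i7_obs)):
        wl = whitelists[key]
        if len(wl) == 0:
            raise ValueError(f"empty whitelist for {key}")
        results[key] = _match_block(obs, _encode_whitelist(wl), design.max_hamming)

    ok = results["tn5"][2] & results["i5"][2] & results["i7"][2]
    within = (
        (results["tn5"][1] < design.max_hamming)
        & (results["i5"][1] < design.max_hamming)
        & (results["i7"][1] < design.max_hamming)
    )
    status = np.where(ok, "assigned", np.where(within, "ambiguous", "unmatched"))

    tn5_names = np.asarray(whitelists["tn5"], dtype=object)
    i5_names = np.asarray(whitelists["i5"], dtype=object)
    i7_names = np.asarray(whitelists["i7"], dtype=object)
    cell_ids = np.where(
        ok,
        np.char.add(
            np.char.add(
                np.char.add(tn5_names[results["tn5"][0]].astype(str), ":"),
                np.char.add(i5_names[results["i5"][0]].astype(str), ":"),
            ),
            i7_names[results["i7"][0]].astype(str),
        ),
        "",
    )
    assignments = pd.DataFrame(
        {
            "read_id": ids,
            "status": status,
            "cell_id": cell_ids,
            "d_tn5": results["tn5"][1],
            "d_i5": results["i5"][1],
            "d_i7": results["i7"][1],
        }
    )
    cells: dict[str, np.ndarray] = {}
    if ok.any():
        order = np.argsort(cell_ids[ok], kind="stable")
        rows = np.flatnonzero(ok)[order]
        sorted_ids = cell_ids[rows]
        bounds = np.flatnonzero(np.r_[True, sorted_ids[1:] != sorted_ids[:-1], True])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            cells[str(sorted_ids[b0])] = rows[b0:b1]
    summary = {
        "total": int(nrec),
        "assigned": int((status == "assigned").sum()),
        "ambiguous": int((status == "ambiguous").sum()),
        "unmatched": int((status == "unmatched").sum()),
        "n_cells": len(cells),
    }
    result = DemuxResult(assignments, cells, summary)
    if outdir is not None:
        _write_demux(result, r1, r2, outdir)
    return result


def _write_demux(result: DemuxResult, r1, r2, outdir) -> None:
    import json
    import os

    from .io import write_fastq

    os.makedirs(outdir, exist_ok=True)
    for cell, rows in result.cells.items():
        stem = cell.replace(":", "_")
        write_fastq(os.path.join(outdir, f"{stem}.R1.fastq"), (r1[j] for j in rows))
        write_fastq(os.path.join(outdir, f"{stem}.R2.fastq"), (r2[j] for j in rows))
    result.assignments.to_csv(os.path.join(outdir, "assignments.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2)
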