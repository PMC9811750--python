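"""Two-pass adapter/contaminant trimming and read-2 truncation.

Pass 1 removes a 3′-anchored Illumina adapter (longest read suffix matching
an adapter prefix, mismatch fraction <= error_rate, overlap >= 3).  Pass 2
removes read-through contaminants found *anywhere* in the read — because
these arise from sequencing past the fragment end, the match and everything
3′ of it are clipped.  Read 2 is finally hard-truncated (poly-G tails from
low-signal cycles concentrate beyond ~60 bp).  Reads shorter than the
minimum length after trimming are dropped, and dropping one mate drops the
pair to keep the streams synchronized.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .simdata import ADAPTER_P7, LINEAR_PRIMER

# i7/P7 read-through followed by poly-A then poly-G, as seen on two-colour
# instruments when the template runs out
_POLYG_CONTAMINANT = "ATCTCGTATGCCGTCTTCTGCTTG" + "A" * 10 + "G" * 28

ILLUMINA_ADAPTER = "AGATCGGAAGAGC"


@dataclass
class TrimConfig:
    pass1_adapter: str = ILLUMINA_ADAPTER
    pass1_min_overlap: int = 3
    pass2_contaminants: tuple[str, ...] = (ADAPTER_P7, LINEAR_PRIMER, _POLYG_CONTAMINANT)
    pass2_times: int = 2
    min_length: int = 20
    error_rate: float = 0.1
    read2_max_len: int = 60

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


def trim_three_prime(
    read: str, adapter: str, min_overlap: int = 3, error_rate: float = 0.1
) -> str:
    """Remove the longest 3′-anchored adapter occurrence.

    Scans overlap lengths from the longest possible down to `min_overlap`;
    the first overlap whose mismatch count is <= floor(error_rate * overlap)
    is clipped.  Returns the read unchanged when nothing matches.
    """
    max_ov = min(len(read), len(adapter))
    for ov in range(max_ov, min_overlap - 1, -1):
        budget = int(error_rate * ov)
        mism = 0
        tail = read[len(read) - ov :]
        for x, y in zip(tail, adapter):
            if x != y:
                mism += 1
                if mism > budget:
                    break
        else:
            return read[: len(read) - ov]
    return read


def _suffix_prefix_overlap(
    read: str, query: str, error_rate: float, min_overlap: int = 3
) -> tuple[int, int] | None:
    """Longest read-suffix / query-prefix overlap within the error budget.

    Returns (start in read, mismatches) or None.
    """
    for ov in range(min(len(read), len(query)), min_overlap - 1, -1):
        budget = int(error_rate * ov)
        mism = 0
        tail = read[len(read) - ov :]
        for x, y in zip(tail, query):
            if x != y:
                mism += 1
                if mism > budget:
                    break
        else:
            return len(read) - ov, mism
    return None


def _find_contaminant(read: str, contaminant: str, error_rate: float) -> tuple[int, int] | None:
    """Best occurrence of `contaminant` anywhere in `read`.

    Full occurrences may sit anywhere (exact substring search as the fast
    path, infix edit-distance alignment for approximate ones); a partial
    occurrence — a prefix of the contaminant running off the read's 3′ end,
    the signature of read-through — is matched by suffix/prefix overlap.
    Returns (start, distance) of the best (lowest-distance, then leftmost)
    occurrence within the error budget, or None.
    """
    best: tuple[int, int] | None = None  # (distance, start)
    pos = read.find(contaminant)
    if pos >= 0:
        best = (0, pos)
    else:
        k = int(error_rate * len(contaminant))
        if k > 0:
            res = edlib.align(contaminant, read, mode="HW", task="locations", k=k)
            if res["editDistance"] >= 0:
                start = min(loc[0] for loc in res["locations"])
                best = (res["editDistance"], start)
    partial = _suffix_prefix_overlap(read, contaminant, error_rate)
    if partial is not None:
        cand = (partial[1], partial[0])
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return best[1], best[0]


def trim_anywhere(
    read: str,
    contaminants,
    times: int = 2,
    error_rate: float = 0.1,
    min_length: int = 20,
) -> str | None:
    """Up to `times` rounds of anywhere-contaminant removal.

    Each round clips the best contaminant occurrence and everything 3′ of
    it.  Returns the trimmed read, or None when it falls below `min_length`
    (the drop signal).
    """
    for _ in range(times):
        best = None
        for c in contaminants:
            hit = _find_contaminant(read, c, error_rate)
            if hit is not None and (best is None or (hit[1], hit[0]) < (best[1], best[0])):
                best = hit
        if best is None:
            break
        read = read[: best[0]]
    if len(read) < min_length:
        return None
    return read


def truncate_read2(read2: str, max_len: int = 60) -> str:
    """Hard-clip read 2 to its first `max_len` bases."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    return read2[:max_len]


@dataclass
class TrimReport:
    pairs_in: int = 0
    pairs_out: int = 0
    pairs_dropped: int = 0
    bases_removed: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def trim_pair(
    r1: str, r2: str, config: TrimConfig | None = None
) -> tuple[str, str] | None:
    """Full trimming of one read pair; None means the pair is dropped."""
    config = config or TrimConfig()
    t1 = trim_three_prime(r1, config.pass1_adapter, config.pass1_min_overlap, config.error_rate)
    t2 = trim_three_prime(r2, config.pass1_adapter, config.pass1_min_overlap, config.error_rate)
    t1 = trim_anywhere(t1, config.pass2_contaminants, config.pass2_times,
                       config.error_rate, config.min_length)
    if t1 is None:
        return None
    t2 = trim_anywhere(t2, config.pass2_contaminants, config.pass2_times,
                       config.error_rate, config.min_length)
    if t2 is None:
        return None
    t2 = truncate_read2(t2, config.read2_max_len)
    return t1, t2


def trim_pairs(
    pairs, config: TrimConfig | None = None
) -> tuple[list, TrimReport]:
    """Trim an iterable of (read_id, r1_seq, r2_seq); returns surviving
    triples and a report."""
    config = config or TrimConfig()
    report = TrimReport()
    out = []
    for rid, r1, r2 in pairs:
        report.pairs_in += 1
        trimmed = trim_pair(r1, r2, config)
        if trimmed is None:
            report.pairs_dropped += 1
            continue
        t1, t2 = trimmed
        report.bases_removed += (len(r1) - len(t1)) + (len(r2) - len(t2))
        report.pairs_out += 1
        out.append((rid, t1, t2))
    return out, report
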