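"""Three-letter alignment of converted reads and per-cytosine methylation calls.

Converted reads are seeded against reduced-alphabet images of the reference
(C→T for original-top-strand molecules, G→A for original-bottom) and then
verified against the *raw* reference under the asymmetric mismatch rule: a
read T over a reference C is not a mismatch on OT (it is an unmethylated,
converted cytosine), while a read C over a reference T is; symmetrically
G/A on OB.  Both the read and its reverse complement are tried under both
rules, so mates of either strand place correctly.

Methylation is extracted from deduplicated alignments: on OT, a read C over
a reference C is a methylated observation and a read T an unmethylated one;
on OB the informative bases are G/A at reference-G positions, reported on
the minus strand.  Context (CG/CHG/CHH, H ∈ {A,C,T}) comes from the
strand-local reference trinucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import A, C, G, N, T, revcomp_codes, seq_to_codes

CONTEXT_NAMES = np.array(["CG", "CHG", "CHH"])
DINUC_NAMES = np.array(["CA", "CC", "CG", "CT"])
# dinucleotide code: index of the base following the cytosine (A,C,G,T)
_DINUC_OF_BASE = np.array([0, 1, 2, 3, 0], dtype=np.uint8)


class OrderingError(ValueError):
    pass


# --------------------------------------------------------------------------
# reference and converted index
# --------------------------------------------------------------------------

class ConvertedIndex:
    """Reference genome with C→T / G→A images, k-mer seed tables and
    per-cytosine site annotation (strand, context, dinucleotide).

    Contigs are concatenated into one global coordinate space separated by
    runs of N so that no seed or alignment can span a contig boundary.
    """

    def __init__(self, contigs: dict[str, str], seed_k: int = 12,
                 mappability_mask: dict[str, np.ndarray] | None = None):
        if seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        self.seed_k = int(seed_k)
        self.names = list(contigs)
        gap = np.full(self.seed_k + 2, N, dtype=np.uint8)
        parts, offsets, pos = [], [], 0
        for name in self.names:
            codes = seq_to_codes(contigs[name])
            if np.any(codes > N):  # seq_to_codes maps unknown to N already
                raise ValueError(f"contig {name} contains non-ACGTN symbols")
            offsets.append(pos)
            parts.append(codes)
            parts.append(gap)
            pos += len(codes) + len(gap)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = np.asarray([len(contigs[n]) for n in self.names], dtype=np.int64)
        self.codes = np.concatenate(parts) if parts else np.empty(0, np.uint8)

        self.ct_image = self.codes.copy()
        self.ct_image[self.ct_image == C] = T
        self.ga_image = self.codes.copy()
        self.ga_image[self.ga_image == G] = A
        self._ct_index = _build_kmer_table(self.ct_image, self.seed_k)
        self._ga_index = _build_kmer_table(self.ga_image, self.seed_k)
        self._pow4 = 4 ** np.arange(self.seed_k - 1, -1, -1, dtype=np.int64)
        for name in self.names:
            if len(contigs[name]) < self.seed_k:
                import warnings

                warnings.warn(f"contig {name} shorter than seed_k; no seeds stored")

        self.mask = np.ones(len(self.codes), dtype=bool)
        self.mask[self.codes == N] = False
        if mappability_mask is not None:
            for name, m in mappability_mask.items():
                o = self.offsets[self.names.index(name)]
                if len(m) != self.length_of(name):
                    raise ValueError("mappability mask length mismatch")
                self.mask[o : o + len(m)] &= np.asarray(m, bool)

        self._build_sites()

    # -- coordinates --------------------------------------------------------

    def length_of(self, name: str) -> int:
        return int(self.lengths[self.names.index(name)])

    def contig_of(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right") - 1)
        return self.names[i], int(gpos - self.offsets[i])

    def global_pos(self, name: str, pos: int) -> int:
        return int(self.offsets[self.names.index(name)] + pos)

    def contig_roles_sites(self, names: Sequence[str]) -> np.ndarray:
        """Boolean mask over the site table selecting sites on `names`."""
        sel = np.zeros(self.n_sites, dtype=bool)
        for name in names:
            i = self.names.index(name)
            lo, hi = self.offsets[i], self.offsets[i] + self.lengths[i]
            sel |= (self.site_gpos >= lo) & (self.site_gpos < hi)
        return sel

    # -- site table ---------------------------------------------------------

    def _build_sites(self):
        g = self.codes
        L = len(g)
        nxt1 = np.full(L, N, np.uint8)
        nxt2 = np.full(L, N, np.uint8)
        nxt1[:-1] = g[1:]
        nxt2[:-2] = g[2:]
        prv1 = np.full(L, N, np.uint8)
        prv2 = np.full(L, N, np.uint8)
        prv1[1:] = g[:-1]
        prv2[2:] = g[:-2]
        comp = np.array([T, G, C, A, N], dtype=np.uint8)

        def _classify(is_cyt, b1, b2):
            ok = is_cyt & (b1 < N) & (b2 < N)
            ctx = np.full(L, 255, np.uint8)
            ctx[ok & (b1 == G)] = 0  # CG
            ctx[ok & (b1 != G) & (b2 == G)] = 1  # CHG
            ctx[ok & (b1 != G) & (b2 != G)] = 2  # CHH
            return ok, ctx

        ok_p, ctx_p = _classify(g == C, nxt1, nxt2)
        ok_m, ctx_m = _classify(g == G, comp[prv1], comp[prv2])
        pos_p = np.flatnonzero(ok_p)
        pos_m = np.flatnonzero(ok_m)
        self.site_gpos = np.concatenate([pos_p, pos_m])
        self.site_strand = np.concatenate(
            [np.zeros(len(pos_p), np.uint8), np.ones(len(pos_m), np.uint8)]
        )
        self.site_context = np.concatenate([ctx_p[pos_p], ctx_m[pos_m]])
        self.site_dinuc = np.concatenate(
            [_DINUC_OF_BASE[nxt1[pos_p]], _DINUC_OF_BASE[comp[prv1[pos_m]]]]
        )
        order = np.argsort(self.site_gpos * 2 + self.site_strand, kind="stable")
        for attr in ("site_gpos", "site_strand", "site_context", "site_dinuc"):
            setattr(self, attr, getattr(self, attr)[order])
        self.n_sites = len(self.site_gpos)
        self._lookup_plus = np.full(L, -1, np.int64)
        self._lookup_minus = np.full(L, -1, np.int64)
        plus = self.site_strand == 0
        self._lookup_plus[self.site_gpos[plus]] = np.flatnonzero(plus)
        self._lookup_minus[self.site_gpos[~plus]] = np.flatnonzero(~plus)

    def sites_frame(self) -> pd.DataFrame:
        contig_idx = np.searchsorted(self.offsets, self.site_gpos, side="right") - 1
        return pd.DataFrame(
            {
                "contig": np.asarray(self.names, object)[contig_idx],
                "position": self.site_gpos - self.offsets[contig_idx] + 1,
                "strand": np.where(self.site_strand == 0, "+", "-"),
                "context": CONTEXT_NAMES[self.site_context],
                "dinucleotide": DINUC_NAMES[self.site_dinuc],
            }
        )


def _build_kmer_table(image: np.ndarray, k: int):
    L = len(image)
    if L < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    n = L - k + 1
    kmers = np.zeros(n, dtype=np.int64)
    for j in range(k):
        kmers = kmers * 4 + image[j : j + n]
    bad = (image >= N).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0
    pos = np.flatnonzero(valid).astype(np.int64)
    km = kmers[pos]
    order = np.argsort(km, kind="stable")
    return km[order], pos[order]


def build_index(contigs: dict[str, str], seed_k: int = 12, **kw) -> ConvertedIndex:
    """Build a ConvertedIndex from a {name: sequence} dict (see class doc)."""
    return ConvertedIndex(contigs, seed_k=seed_k, **kw)


def _lookup(table, kmer: int) -> np.ndarray:
    km, pos = table
    lo = np.searchsorted(km, kmer, side="left")
    hi = np.searchsorted(km, kmer, side="right")
    return pos[lo:hi]


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

@dataclass(slots=True)
class Alignment:
    read_id: str
    contig: str
    start: int          # 0-based, aligned window
    end: int            # half-open
    strand_conv: str    # "OT" | "OB"
    orient: str         # "+" read as given; "-" reverse complement aligned
    mode: str           # "end-to-end" | "local"
    clip5: int
    clip3: int
    nm: int
    score: int
    unique: bool
    read_len: int
    seq: np.ndarray     # full read codes in genome orientation
    g0: int             # global coord of full-read placement start
    paired: bool = False
    insert: int | None = None

    @property
    def clipped(self) -> int:
        return self.clip5 + self.clip3

    def read_positions(self, window_offsets: np.ndarray) -> np.ndarray:
        """Map offsets within the aligned window to 0-based positions in the
        original (as-sequenced) read."""
        idx = self.clip5 + window_offsets
        if self.orient == "+":
            return idx
        return self.read_len - 1 - idx


def _kadane(match: np.ndarray) -> tuple[int, int, int]:
    """Best-scoring contiguous window under +1 match / -2 mismatch.

    Vectorized maximum-subarray: with prefix sums s, the best window ending
    at j scores s[j] − min(s[:j]); the start is the argmin of the prefix.
    """
    vals = np.where(match, 1, -2)
    s = np.concatenate([[0], np.cumsum(vals)])
    prefix_min = np.minimum.accumulate(s[:-1])
    gains = s[1:] - prefix_min
    j = int(np.argmax(gains))
    score = int(gains[j])
    if score <= 0:
        return 0, 0, 0
    i = int(np.argmax(s[: j + 1] == prefix_min[j]))
    return i, j + 1, score


MIN_LOCAL_WINDOW = 25


def align_read(
    read: str | np.ndarray,
    index: ConvertedIndex,
    max_mismatch_frac: float = 0.1,
    read_id: str = "",
) -> Alignment | None:
    """Seed-and-verify alignment of one converted read.

    End-to-end placement is attempted first; when the full read exceeds the
    mismatch budget the best soft-clipped (local, indel-free) window is
    scored instead.  The alignment is flagged unique iff its score strictly
    beats every other candidate across all four strand/orientation attempts.
    Returns None when nothing acceptable is found.
    """
    codes = seq_to_codes(read) if isinstance(read, str) else read
    L = len(codes)
    k = index.seed_k
    if L < k:
        return None
    rc = revcomp_codes(codes)
    seed_offsets = sorted({0, (L - k) // 2, L - k})
    pow4 = index._pow4

    # Collect candidate placements with a vote per supporting seed.  Seeds
    # hitting more than `max_seed_hits` loci are repetitive and skipped.
    # Loci supported by >= 2 seeds are verified first; only when no locus
    # reaches 2 votes (e.g. adapter chimeras leave a single anchored seed)
    # are single-vote candidates verified.
    max_seed_hits = 200
    votes: dict[tuple[int, str, str], int] = {}
    seqs = {"+": codes, "-": rc}
    for orient, s in seqs.items():
        ct_s = s.copy()
        ct_s[ct_s == C] = T
        ga_s = s.copy()
        ga_s[ga_s == G] = A
        for rule, img_s, table in (
            ("OT", ct_s, index._ct_index),
            ("OB", ga_s, index._ga_index),
        ):
            km, pos = table
            for off in seed_offsets:
                window = img_s[off : off + k]
                if window.max() >= N:
                    continue
                kmer = int(window.astype(np.int64) @ pow4)
                lo = km.searchsorted(kmer, side="left")
                hi = km.searchsorted(kmer, side="right")
                if hi - lo > max_seed_hits:
                    continue
                for p in pos[lo:hi]:
                    g0 = int(p) - off
                    if 0 <= g0 <= len(index.codes) - L:
                        key = (g0, rule, orient)
                        votes[key] = votes.get(key, 0) + 1
    if not votes:
        return None
    strong = [k_ for k_, v in votes.items() if v >= 2]
    chosen = strong if strong else list(votes)
    candidates = [(g0, rule, orient, seqs[orient]) for g0, rule, orient in chosen]

    best: Alignment | None = None
    best_score = None
    second_score = None
    budget = int(max_mismatch_frac * L)
    for g0, rule, orient, s in candidates:
        g = index.codes[g0 : g0 + L]
        match = (s == g) & (g < N)
        if rule == "OT":
            match |= (g == C) & (s == T)
        else:
            match |= (g == G) & (s == A)
        nmatch = int(match.sum())
        mism = L - nmatch
        # end-to-end if within budget, but a soft-clipped window that scores
        # strictly higher (e.g. an untrimmed adapter tail absorbed as
        # mismatches) wins over it
        e2e_score = nmatch - 2 * mism if mism <= budget else None
        w0_l, w1_l, local_score = _kadane(match)
        wlen = w1_l - w0_l
        local_ok = (
            wlen >= max(k, MIN_LOCAL_WINDOW)
            and (w0_l, w1_l) != (0, L)
            and int((~match[w0_l:w1_l]).sum()) <= int(max_mismatch_frac * wlen)
        )
        if e2e_score is not None and (not local_ok or e2e_score >= local_score):
            w0, w1, mode, score, nm_w = 0, L, "end-to-end", e2e_score, mism
        elif local_ok:
            w0, w1, mode, score = w0_l, w1_l, "local", local_score
            nm_w = int((~match[w0:w1]).sum())
        else:
            continue
        if best_score is None or score > best_score:
            second_score = best_score
            best_score = score
            contig, cstart = index.contig_of(g0 + w0)
            best = Alignment(
                read_id=read_id, contig=contig, start=cstart, end=cstart + (w1 - w0),
                strand_conv=rule, orient=orient, mode=mode, clip5=w0, clip3=L - w1,
                nm=nm_w, score=score, unique=True, read_len=L, seq=s, g0=g0,
            )
        elif second_score is None or score > second_score:
            second_score = score
    if best is None:
        return None
    best.unique = second_score is None or best_score > second_score
    return best


def pair_reads(a1: Alignment | None, a2: Alignment | None) -> int | None:
    """Mate pairing: same contig, same conversion strand, opposite
    orientation, insert within [30, 2000].  On success both alignments are
    marked paired and the insert size (max end − min start) is returned;
    otherwise mates stay single and None is returned."""
    if a1 is None or a2 is None:
        return None
    if (
        a1.contig != a2.contig
        or a1.strand_conv != a2.strand_conv
        or a1.orient == a2.orient
    ):
        return None
    insert = max(a1.end, a2.end) - min(a1.start, a2.start)
    if not 30 <= insert <= 2000:
        return None
    a1.paired = a2.paired = True
    a1.insert = a2.insert = insert
    return insert


@dataclass(slots=True)
class ReadUnit:
    """One sequenced molecule after alignment: a pair or a single mate."""

    read_id: str
    a1: Alignment | None
    a2: Alignment | None

    @property
    def alignments(self) -> list[Alignment]:
        return [a for a in (self.a1, self.a2) if a is not None]

    @property
    def contig(self) -> str:
        return self.alignments[0].contig

    @property
    def start(self) -> int:
        return min(a.start for a in self.alignments)

    @property
    def strand_conv(self) -> str:
        return self.alignments[0].strand_conv


def deduplicate(units: Sequence[ReadUnit], cell_id: str = "") -> tuple[list[ReadUnit], int]:
    """Collapse PCR duplicates among a cell's aligned molecules.

    Molecules sharing (contig, leftmost start, conversion strand) are
    duplicates; the one with the fewest mismatches survives (ties broken by
    read-id order).  Input must be sorted by (contig, start).  Returns the
    survivors and the number of duplicates removed.
    """
    keys = [(u.contig, u.start) for u in units]
    if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
        raise OrderingError("alignments not sorted by (contig, start)")
    survivors: dict[tuple, ReadUnit] = {}
    for u in units:
        key = (u.contig, u.start, u.strand_conv)
        prev = survivors.get(key)
        if prev is None:
            survivors[key] = u
        else:
            nm_new = sum(a.nm for a in u.alignments)
            nm_old = sum(a.nm for a in prev.alignments)
            if nm_new < nm_old or (nm_new == nm_old and u.read_id < prev.read_id):
                survivors[key] = u
    kept = sorted(survivors.values(), key=lambda u: (u.contig, u.start))
    return kept, len(units) - len(kept)


def sort_units(units: Iterable[ReadUnit]) -> list[ReadUnit]:
    return sorted(units, key=lambda u: (u.contig, u.start))


# --------------------------------------------------------------------------
# methylation extraction
# --------------------------------------------------------------------------

@dataclass
class CellCalls:
    """Sparse per-cell methylation calls indexed into a ConvertedIndex site
    table: parallel arrays of site index, methylated count and coverage."""

    site_idx: np.ndarray
    meth: np.ndarray
    cov: np.ndarray

    def to_frame(self, index: ConvertedIndex) -> pd.DataFrame:
        base = index.sites_frame().iloc[self.site_idx].reset_index(drop=True)
        base["nucleotide"] = np.where(base["strand"] == "+", "C", "G")
        base["methylated"] = self.meth
        base["coverage"] = self.cov
        base["level"] = self.meth / self.cov
        return base[
            ["contig", "nucleotide", "position", "context", "dinucleotide",
             "level", "methylated", "coverage", "strand"]
        ]


def _accumulate(aln: Alignment, index, meth_p, cov_p, meth_m, cov_m,
                exclude: tuple[int, int] | None = None) -> None:
    w0, wlen = aln.clip5, aln.end - aln.start
    gw = aln.g0 + w0
    g = index.codes[gw : gw + wlen]
    s = aln.seq[w0 : w0 + wlen]
    if aln.strand_conv == "OT":
        cyt, meth_base, unmeth_base = C, C, T
        meth_arr, cov_arr = meth_p, cov_p
    else:
        cyt, meth_base, unmeth_base = G, G, A
        meth_arr, cov_arr = meth_m, cov_m
    is_cyt = g == cyt
    if exclude is not None:
        offs = np.arange(wlen) + gw
        is_cyt = is_cyt & ~((offs >= exclude[0]) & (offs < exclude[1]))
    m_idx = np.flatnonzero(is_cyt & (s == meth_base)) + gw
    u_idx = np.flatnonzero(is_cyt & (s == unmeth_base)) + gw
    meth_arr[m_idx] += 1
    cov_arr[m_idx] += 1
    cov_arr[u_idx] += 1


def extract_methylation(units: Sequence[ReadUnit], index: ConvertedIndex) -> CellCalls:
    """Per-cytosine methylation calls from deduplicated alignments.

    Overlapping mate segments are counted once (the first mate wins); sites
    outside the mappability mask or without a defined trinucleotide context
    are skipped; zero-coverage sites are omitted.
    """
    L = len(index.codes)
    meth_p = np.zeros(L, np.int32)
    cov_p = np.zeros(L, np.int32)
    meth_m = np.zeros(L, np.int32)
    cov_m = np.zeros(L, np.int32)
    for u in units:
        a1, a2 = u.a1, u.a2
        if a1 is not None:
            if a1.end > index.length_of(a1.contig):
                raise ValueError(f"alignment beyond contig bounds: {a1.read_id}")
            _accumulate(a1, index, meth_p, cov_p, meth_m, cov_m)
        if a2 is not None:
            if a2.end > index.length_of(a2.contig):
                raise ValueError(f"alignment beyond contig bounds: {a2.read_id}")
            excl = None
            if a1 is not None and a1.contig == a2.contig:
                lo = max(a1.g0 + a1.clip5, a2.g0 + a2.clip5)
                hi = min(a1.g0 + a1.clip5 + (a1.end - a1.start),
                         a2.g0 + a2.clip5 + (a2.end - a2.start))
                if lo < hi:
                    excl = (lo, hi)
            _accumulate(a2, index, meth_p, cov_p, meth_m, cov_m, exclude=excl)

    parts = []
    for cov, meth, lookup in (
        (cov_p, meth_p, index._lookup_plus),
        (cov_m, meth_m, index._lookup_minus),
    ):
        gpos = np.flatnonzero(cov)
        sidx = lookup[gpos]
        keep = (sidx >= 0) & index.mask[gpos]
        parts.append((sidx[keep], meth[gpos[keep]], cov[gpos[keep]]))
    site_idx = np.concatenate([p[0] for p in parts])
    meth = np.concatenate([p[1] for p in parts])
    cov = np.concatenate([p[2] for p in parts])
    order = np.argsort(site_idx, kind="stable")
    return CellCalls(site_idx[order].astype(np.int64), meth[order], cov[order])


def merge_calls(calls_list: Sequence[CellCalls]) -> CellCalls:
    """Sum methylated and coverage counts of several call sets site-wise."""
    if not calls_list:
        return CellCalls(np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64))
    site = np.concatenate([c.site_idx for c in calls_list])
    meth = np.concatenate([c.meth for c in calls_list])
    cov = np.concatenate([c.cov for c in calls_list])
    order = np.argsort(site, kind="stable")
    site, meth, cov = site[order], meth[order], cov[order]
    uniq, inv = np.unique(site, return_inverse=True)
    m = np.zeros(len(uniq), np.int64)
    v = np.zeros(len(uniq), np.int64)
    np.add.at(m, inv, meth)
    np.add.at(v, inv, cov)
    return CellCalls(uniq, m, v)


def mappable_dinucleotide_counts(
    contigs: dict[str, str] | ConvertedIndex, mask: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Counts of CA/CC/CG/CT cytosine dinucleotides per strand, restricted to
    cytosines whose position falls inside the (optional) mappability mask."""
    index = contigs if isinstance(contigs, ConvertedIndex) else ConvertedIndex(
        contigs, seed_k=8, mappability_mask=mask
    )
    rows = []
    for strand_code, strand in ((0, "+"), (1, "-")):
        sel = (index.site_strand == strand_code) & index.mask[index.site_gpos]
        counts = np.bincount(index.site_dinuc[sel], minlength=4)
        for d, c in zip(DINUC_NAMES, counts):
            rows.append((strand, d, int(c)))
    return pd.DataFrame(rows, columns=["strand", "dinucleotide", "count"])
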