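"""Synthetic single-cell combinatorial-indexing methylation runs.

Generates everything a real sequencing run would provide — a reference
genome with unmethylated-lambda and CpG-methylated-pUC19 spike-in contigs,
cell-type methylomes with differentially methylated regions (DMRs),
tagmentation-style fragments, C→T conversion chemistry (enzymatic or
bisulfite, the latter with optional 5′→3′ positional bias and
methylation-dependent fragment survival), combinatorial index reads and
adapter/poly-G contamination — together with a per-read ground-truth table.

All randomness flows from a single master seed through
``numpy.random.SeedSequence.spawn``, so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import A, C, G, T, codes_to_seq, revcomp_codes, seq_to_codes, write_fasta, write_fastq

# Illumina P7 read-through adapter (also the first trimming-pass target) and
# the linear-amplification primer fragment seen as a read-through contaminant.
ADAPTER_P7 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
LINEAR_PRIMER = "GAAGAGCACACGTCTGAACTC"

ROLE_SAMPLE = "sample"
ROLE_LAMBDA = "lambda_unmethylated"
ROLE_PUC19 = "puc19_methylated"

LAMBDA_LENGTH = 48502
PUC19_LENGTH = 2686


class LayoutError(ValueError):
    """Requested DMR layout does not fit in the sample genome."""


def _rng(seed) -> np.random.Generator:
    """Accept an int, SeedSequence or Generator as a randomness source."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])


# --------------------------------------------------------------------------
# genome
# --------------------------------------------------------------------------

@dataclass
class SimGenome:
    """A small synthetic genome: sample contigs plus two spike-in contigs.

    Spike-ins are random sequences with realistic lambda/pUC19 lengths; only
    their *role* (fully unmethylated vs CpG-methylated control) matters to
    the pipeline.
    """

    contigs: dict[str, str]
    roles: dict[str, str]
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if len(seq) < 1000:
                raise ValueError(f"contig {name} shorter than 1 kb")
        if ROLE_SAMPLE not in self.roles.values():
            raise ValueError("genome needs at least one sample contig")
        if ROLE_LAMBDA not in self.roles.values():
            raise ValueError("genome needs a lambda spike-in contig")

    def codes(self, name: str) -> np.ndarray:
        if name not in self._codes:
            self._codes[name] = seq_to_codes(self.contigs[name])
        return self._codes[name]

    @property
    def sample_contigs(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == ROLE_SAMPLE]

    def contigs_with_role(self, role: str) -> list[str]:
        return [n for n, r in self.roles.items() if r == role]

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def to_fasta(self, path) -> None:
        write_fasta(path, self.contigs)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return codes_to_seq(rng.choice(4, size=length, p=p).astype(np.uint8))


def simulate_genome(
    n_contigs: int,
    contig_length: int,
    gc_fraction: float,
    seed: int,
    lambda_length: int = LAMBDA_LENGTH,
    puc19_length: int = PUC19_LENGTH,
) -> SimGenome:
    """Draw a random genome with `n_contigs` sample contigs plus spike-ins.

    Sample contigs are i.i.d. bases at the requested GC fraction; spike-in
    contigs are drawn at GC 0.5.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    if contig_length < 1000:
        raise ValueError("contig_length must be at least 1000 bp")
    if n_contigs < 1:
        raise ValueError("need at least one sample contig")
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_contigs + 2)]
    contigs: dict[str, str] = {}
    roles: dict[str, str] = {}
    for i in range(n_contigs):
        name = f"chr{i + 1}"
        contigs[name] = _random_seq(rngs[i], contig_length, gc_fraction)
        roles[name] = ROLE_SAMPLE
    contigs["lambda"] = _random_seq(rngs[-2], lambda_length, 0.5)
    roles["lambda"] = ROLE_LAMBDA
    contigs["pUC19"] = _random_seq(rngs[-1], puc19_length, 0.5)
    roles["pUC19"] = ROLE_PUC19
    return SimGenome(contigs, roles)


# --------------------------------------------------------------------------
# methylomes
# --------------------------------------------------------------------------

@dataclass
class CellTypeMethylome:
    """Per-position methylation probabilities for one cell type.

    ``p_plus[contig][i]`` is the probability that the plus-strand cytosine at
    position *i* is methylated (meaningful only where the reference base is
    C); ``p_minus`` likewise for minus-strand cytosines (reference base G).
    """

    name: str
    p_plus: dict[str, np.ndarray]
    p_minus: dict[str, np.ndarray]


def _context_masks(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(plus-strand CpG C positions, minus-strand CpG G positions) masks."""
    is_c = codes == C
    is_g = codes == G
    cpg_plus = is_c.copy()
    cpg_plus[:-1] &= is_g[1:]
    cpg_plus[-1] = False
    cpg_minus = is_g.copy()
    cpg_minus[1:] &= is_c[:-1]
    cpg_minus[0] = False
    return cpg_plus, cpg_minus


def simulate_methylomes(
    genome: SimGenome,
    n_celltypes: int,
    n_dmrs: int,
    dmr_length: int,
    cph_rate: float | Sequence[float] = 0.01,
    baseline_cpg: float = 0.8,
    seed: int = 0,
    dmr_low: float = 0.1,
    dmr_high: float = 0.9,
) -> tuple[list[CellTypeMethylome], pd.DataFrame]:
    """Build cell-type methylomes sharing a baseline but differing at DMRs.

    Each DMR is assigned (round-robin) one cell type that is hypomethylated
    there (CpG level `dmr_low`); all other cell types sit at `dmr_high`.
    Outside DMRs every cell type has CpG level `baseline_cpg`.  `cph_rate`
    sets the global CpH level — a scalar gives every type the same rate,
    while a per-type sequence emulates the genuine CpH differences between
    brain cell types (neurons carry several-fold more CpH methylation than
    glia), which is what genomic-bin CpH summaries discriminate on.  The
    lambda spike-in is fully unmethylated; pUC19 is fully CpG-methylated
    (and unmethylated elsewhere).

    Returns the methylomes and a DMR table (contig, start, end, celltype).
    """
    if n_celltypes < 1:
        raise ValueError("n_celltypes must be >= 1")
    cph_rates = (
        [float(cph_rate)] * n_celltypes
        if np.isscalar(cph_rate)
        else [float(v) for v in cph_rate]
    )
    if len(cph_rates) != n_celltypes:
        raise ValueError("cph_rate sequence length must equal n_celltypes")
    for v, nm in (*((r, "cph_rate") for r in cph_rates), (baseline_cpg, "baseline_cpg")):
        if not 0 <= v <= 1:
            raise ValueError(f"{nm} outside [0,1]")
    rng = _rng(seed)
    samples = genome.sample_contigs
    total = sum(genome.length(c) for c in samples)
    if n_dmrs * dmr_length > 0.6 * total:
        raise LayoutError("DMRs do not fit in the sample genome without overlap")

    # place non-overlapping DMRs, contig chosen proportional to length
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in samples}
    weights = np.array([genome.length(c) for c in samples], float)
    weights /= weights.sum()
    rows = []
    for i in range(n_dmrs):
        for _attempt in range(1000):
            contig = samples[rng.choice(len(samples), p=weights)]
            limit = genome.length(contig) - dmr_length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + dmr_length
            if all(end <= s or start >= e for s, e in placed[contig]):
                placed[contig].append((start, end))
                rows.append((contig, start, end, i % n_celltypes, f"dmr{i}"))
                break
        else:
            raise LayoutError("could not place non-overlapping DMRs")
    dmr_table = pd.DataFrame(rows, columns=["contig", "start", "end", "celltype_idx", "name"])

    celltype_names = [f"type{i}" for i in range(n_celltypes)]
    dmr_table["celltype"] = [celltype_names[i] for i in dmr_table["celltype_idx"]]

    methylomes = []

    def _base_arrays(cph: float):
        plus: dict[str, np.ndarray] = {}
        minus: dict[str, np.ndarray] = {}
        for contig in genome.contigs:
            codes = genome.codes(contig)
            cpg_p, cpg_m = _context_masks(codes)
            role = genome.roles[contig]
            pp = np.zeros(len(codes), dtype=np.float32)
            pm = np.zeros(len(codes), dtype=np.float32)
            if role == ROLE_SAMPLE:
                pp[codes == C] = cph
                pm[codes == G] = cph
                pp[cpg_p] = baseline_cpg
                pm[cpg_m] = baseline_cpg
            elif role == ROLE_PUC19:
                pp[cpg_p] = 1.0
                pm[cpg_m] = 1.0
            # lambda: all zero
            plus[contig] = pp
            minus[contig] = pm
        return plus, minus

    for ci, name in enumerate(celltype_names):
        pp, pm = _base_arrays(cph_rates[ci])
        for _, r in dmr_table.iterrows():
            codes = genome.codes(r.contig)
            cpg_p, cpg_m = _context_masks(codes)
            level = dmr_low if r.celltype_idx == ci else dmr_high
            sl = slice(r.start, r.end)
            pp[r.contig][sl][cpg_p[sl]] = level
            pm[r.contig][sl][cpg_m[sl]] = level
        methylomes.append(CellTypeMethylome(name, pp, pm))
    return methylomes, dmr_table[["contig", "start", "end", "celltype", "name"]]


# --------------------------------------------------------------------------
# chemistry
# --------------------------------------------------------------------------

@dataclass
class ChemistryModel:
    """Conversion chemistry parameters.

    conversion_rate
        Probability an unmethylated cytosine is read as T.
    overconversion_rate
        Probability a methylated cytosine is (erroneously) read as T.
    positional_bias_slope
        Bisulfite-only: per-fragment-fraction increase of the *non*-conversion
        probability from 5′ to 3′, producing apparent methylation rising along
        the fragment.
    survival_gamma
        Bisulfite-only: fragments survive conversion with probability
        proportional to exp(survival_gamma * methylated_fraction), modelling
        over-representation of methylated fragments.
    """

    mode: str = "enzymatic"
    conversion_rate: float = 0.999
    overconversion_rate: float = 0.001
    positional_bias_slope: float = 0.0
    survival_gamma: float = 0.0

    def __post_init__(self):
        if self.mode not in ("enzymatic", "bisulfite"):
            raise ValueError("mode must be 'enzymatic' or 'bisulfite'")
        for v, nm in (
            (self.conversion_rate, "conversion_rate"),
            (self.overconversion_rate, "overconversion_rate"),
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"{nm} outside [0,1]")
        if self.mode == "enzymatic" and (
            self.positional_bias_slope != 0 or self.survival_gamma != 0
        ):
            raise ValueError(
                "enzymatic mode has no positional bias or survival bias; "
                "use mode='bisulfite' to enable them"
            )


# --------------------------------------------------------------------------
# fragments
# --------------------------------------------------------------------------

@dataclass
class Fragment:
    """A tagmented fragment with its (molecule-level) methylation states."""

    __slots__ = ("contig", "start", "end", "meth_plus", "meth_minus")
    contig: str
    start: int
    end: int
    meth_plus: np.ndarray  # bool, len = end-start; True where plus-strand C methylated
    meth_minus: np.ndarray  # bool; True where minus-strand C (reference G) methylated

    @property
    def length(self) -> int:
        return self.end - self.start

    def methylated_fraction(self, codes: np.ndarray) -> float:
        sl = codes[self.start : self.end]
        nc = int((sl == C).sum() + (sl == G).sum())
        if nc == 0:
            return 0.0
        nm = int(self.meth_plus[sl == C].sum() + self.meth_minus[sl == G].sum())
        return nm / nc


def _draw_fragment(
    genome: SimGenome,
    methylome: CellTypeMethylome,
    contig: str,
    insert_mean: float,
    insert_sd: float,
    rng: np.random.Generator,
) -> Fragment:
    clen = genome.length(contig)
    length = max(30, int(round(rng.normal(insert_mean, insert_sd))))
    length = min(length, clen)
    start = int(rng.integers(0, clen - length + 1))
    end = start + length
    codes = genome.codes(contig)[start:end]
    u = rng.random(length)
    meth_plus = (u < methylome.p_plus[contig][start:end]) & (codes == C)
    meth_minus = (rng.random(length) < methylome.p_minus[contig][start:end]) & (codes == G)
    return Fragment(contig, start, end, meth_plus, meth_minus)


def simulate_fragments(
    genome: SimGenome,
    methylome: CellTypeMethylome,
    n_fragments: int,
    insert_mean: float = 250.0,
    insert_sd: float = 80.0,
    chemistry: ChemistryModel | None = None,
    seed: int = 0,
) -> list[Fragment]:
    """Draw tagmented fragments uniformly over contigs (weighted by length).

    Insert sizes are truncated-normal with a 30 bp floor.  Methylation states
    are sampled once per fragment (molecule level).  In bisulfite mode with
    ``survival_gamma > 0`` candidate fragments are retained by rejection with
    probability exp(gamma * (m - 1)) where m is the fragment's methylated
    cytosine fraction, i.e. retention proportional to exp(gamma * m); sampling
    continues until exactly `n_fragments` survive.
    """
    chemistry = chemistry or ChemistryModel()
    rng = _rng(seed)
    names = list(genome.contigs)
    weights = np.array([genome.length(c) for c in names], float)
    weights /= weights.sum()
    gamma = chemistry.survival_gamma
    out: list[Fragment] = []
    while len(out) < n_fragments:
        contig = names[rng.choice(len(names), p=weights)]
        frag = _draw_fragment(genome, methylome, contig, insert_mean, insert_sd, rng)
        if gamma > 0:
            m = frag.methylated_fraction(genome.codes(contig))
            if rng.random() >= np.exp(gamma * (m - 1.0)):
                continue
        out.append(frag)
    return out


# --------------------------------------------------------------------------
# conversion
# --------------------------------------------------------------------------

def convert_fragment(
    fragment: Fragment,
    genome: SimGenome,
    chemistry: ChemistryModel,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply C→T conversion chemistry to one fragment.

    Returns (top-strand template, bottom-strand template) as code arrays,
    each written 5′→3′ of its own strand.  Unmethylated cytosines are read
    as T with probability `conversion_rate`, modulated by the positional
    bias term: effective non-conversion probability at fractional position
    f is clip((1 - conversion_rate) + slope * f, 0, 1), with f measured from
    the 5′ end of the strand being converted.  Methylated cytosines are read
    as T with probability `overconversion_rate`.
    """
    rng = _rng(rng)
    gslice = genome.codes(fragment.contig)[fragment.start : fragment.end]
    L = len(gslice)
    slope = chemistry.positional_bias_slope
    conv = chemistry.conversion_rate
    over = chemistry.overconversion_rate

    def _convert(codes: np.ndarray, cyt_base: int, meth: np.ndarray, frac_pos: np.ndarray):
        outb = codes.copy()
        idx = np.where(codes == cyt_base)[0]
        if len(idx) == 0:
            return outb
        is_meth = meth[idx]
        stay = np.clip((1.0 - conv) + slope * frac_pos[idx], 0.0, 1.0)
        u = rng.random(len(idx))
        converted = np.where(is_meth, u < over, u >= stay)
        to_base = T if cyt_base == C else A  # G on the template strand -> A
        outb[idx[converted]] = to_base
        return outb

    frac_top = np.arange(L) / L
    top = _convert(gslice, C, fragment.meth_plus, frac_top)
    # bottom strand: its cytosines sit at reference-G positions; its 5' end is
    # the 3' end of the top strand
    frac_bottom = (L - 1 - np.arange(L)) / L
    bottom_src = _convert(gslice, G, fragment.meth_minus, frac_bottom)
    bottom = revcomp_codes(bottom_src)
    return top, bottom


# --------------------------------------------------------------------------
# barcodes / run design
# --------------------------------------------------------------------------

def generate_whitelist(
    n: int, length: int, min_dist: int, rng: np.random.Generator
) -> list[str]:
    """Random barcode whitelist with pairwise Hamming distance >= min_dist."""
    kept: list[np.ndarray] = []
    attempts = 0
    while len(kept) < n:
        attempts += 1
        if attempts > 500 * n:
            raise RuntimeError("whitelist generation failed; relax parameters")
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        if all(int((cand != k).sum()) >= min_dist for k in kept):
            kept.append(cand)
    return [codes_to_seq(k) for k in kept]


@dataclass
class BarcodeDesign:
    """Three whitelists plus the cell-id → index-triplet assignment."""

    tn5: list[str]
    i5: list[str]
    i7: list[str]
    assignment: dict[str, tuple[int, int, int]]

    @property
    def tn5_length(self) -> int:
        return len(self.tn5[0])

    @property
    def i5_length(self) -> int:
        return len(self.i5[0])

    @property
    def i7_length(self) -> int:
        return len(self.i7[0])

    def triplet(self, cell_id: str) -> tuple[str, str, str]:
        t, f, s = self.assignment[cell_id]
        return self.tn5[t], self.i5[f], self.i7[s]

    def cell_name(self, cell_id: str) -> str:
        t, f, s = self.triplet(cell_id)
        return f"{t}:{f}:{s}"


def design_barcodes(
    cell_ids: Sequence[str],
    seed: int,
    n_tn5: int = 96,
    n_i5: int = 96,
    n_i7: int = 96,
    tn5_length: int = 11,
    i5_length: int = 10,
    i7_length: int = 10,
    min_dist: int = 5,
) -> BarcodeDesign:
    """Whitelists (pairwise Hamming >= min_dist, so <3 correction is
    unambiguous) and a distinct index triplet for every cell."""
    if len(cell_ids) > n_tn5 * n_i5 * n_i7:
        raise ValueError("more cells than available index triplets")
    ss = np.random.SeedSequence(seed).spawn(3)
    tn5 = generate_whitelist(n_tn5, tn5_length, min_dist, np.random.default_rng(ss[0]))
    i5 = generate_whitelist(n_i5, i5_length, min_dist, np.random.default_rng(ss[1]))
    i7 = generate_whitelist(n_i7, i7_length, min_dist, np.random.default_rng(ss[2]))
    assignment = {}
    for k, cid in enumerate(cell_ids):
        assignment[cid] = (k % n_tn5, (k // n_tn5) % n_i5, (k // (n_tn5 * n_i5)) % n_i7)
    return BarcodeDesign(tn5, i5, i7, assignment)


# --------------------------------------------------------------------------
# read-count mixture (for cell-QC experiments)
# --------------------------------------------------------------------------

def simulate_readcount_mixture(
    n: tuple[int, int, int] = (600, 300, 700),
    mu_log10: tuple[float, float, float] = (2.0, 2.9, 3.8),
    sigma_log10: tuple[float, float, float] = (0.22, 0.22, 0.22),
    seed: int = 0,
) -> pd.DataFrame:
    """Three log-normal barcode populations: debris, low-count and real nuclei.

    Returns a DataFrame with cell_id, population and unique_reads, emulating
    the trimodal unique-read-count distribution a combinatorial-indexing run
    shows across its barcode space.  Population centres are chosen so that
    all three modes survive the minimum-unique-read filter (about half of
    the debris barcodes fall below 100 reads), since the k = 3 clustering
    step models exactly this trimodal structure.
    """
    rng = _rng(seed)
    rows = []
    for pop, npop, mu, sd in zip(("debris", "low", "real"), n, mu_log10, sigma_log10):
        counts = np.round(10 ** rng.normal(mu, sd, size=npop)).astype(int)
        counts = np.maximum(counts, 1)
        for c in counts:
            rows.append((f"{pop}{len(rows)}", pop, int(c)))
    return pd.DataFrame(rows, columns=["cell_id", "population", "unique_reads"])


# --------------------------------------------------------------------------
# run emission
# --------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "read_id",
    "cell_id",
    "celltype",
    "fragment_id",
    "contig",
    "start",
    "end",
    "conv_strand",
    "duplicate",
    "adapter_start_r1",
    "adapter_start_r2",
    "polyg_start",
]


@dataclass
class SimRun:
    """An emitted run: four synchronized FASTQ record lists plus ground truth."""

    r1: list[tuple[str, str, str]]
    r2: list[tuple[str, str, str]]
    i1: list[tuple[str, str, str]]
    i2: list[tuple[str, str, str]]
    truth: pd.DataFrame
    design: BarcodeDesign
    chemistry: ChemistryModel

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for name, recs in (("R1", self.r1), ("R2", self.r2), ("I1", self.i1), ("I2", self.i2)):
            write_fastq(os.path.join(outdir, f"{name}.fastq"), recs)
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
        for nm, wl in (("tn5", self.design.tn5), ("i5", self.design.i5), ("i7", self.design.i7)):
            with open(os.path.join(outdir, f"whitelist_{nm}.txt"), "w") as fh:
                fh.write("\n".join(wl) + "\n")


def _fill_read(template: np.ndarray, read_length: int) -> tuple[str, int]:
    """Take a read from a template 5′ end; read-through fills with adapter
    then linear primer then A.  Returns (sequence, adapter onset or -1)."""
    if len(template) >= read_length:
        return codes_to_seq(template[:read_length]), -1
    fill = ADAPTER_P7 + LINEAR_PRIMER
    seq = codes_to_seq(template) + fill
    if len(seq) < read_length:
        seq += "A" * (read_length - len(seq))
    return seq[:read_length], len(template)


def _apply_index_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    codes = seq_to_codes(seq)
    hit = rng.random(len(codes)) < rate
    if hit.any():
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=int(hit.sum()))
        codes[hit] = (codes[hit] + shift) % 4
    return codes_to_seq(codes)


def emit_run(
    cells: Sequence[tuple[str, str, int]],
    genome: SimGenome,
    methylomes: dict[str, CellTypeMethylome] | Iterable[CellTypeMethylome],
    design: BarcodeDesign,
    chemistry: ChemistryModel,
    read_length: int = 142,
    insert_mean: float = 250.0,
    insert_sd: float = 80.0,
    adapter_contamination_rate: float = 0.0,
    polyg_rate: float = 0.0,
    index_error_rate: float = 0.0,
    duplication_rate: float = 0.0,
    seed: int = 0,
) -> SimRun:
    """Emit a full synthetic run for `cells` = [(cell_id, celltype, n_fragments)].

    Per fragment one converted molecule is built (top- or bottom-strand
    template, equiprobable); R1 reads its 5′ end and R2 the reverse
    complement of its 3′ end.  With probability `adapter_contamination_rate`
    a fragment's insert is shortened below the read length so both reads run
    through into adapter sequence.  With probability `polyg_rate` read 2 is
    overwritten with G from a random position > 60.  I1 carries i7; I2 is
    the concatenation Tn5 + i5 (NovaSeq dialect when i5 is 10 bp, NextSeq
    when 9 bp).  With probability `duplication_rate` a molecule is emitted
    twice (PCR duplicate: identical sequences, same fragment id).
    """
    if isinstance(methylomes, dict):
        meth_by_type = methylomes
    else:
        meth_by_type = {m.name: m for m in methylomes}
    for cid, ctype, _n in cells:
        if cid not in design.assignment:
            raise KeyError(f"cell id {cid!r} has no index triplet in the barcode design")
        if ctype not in meth_by_type:
            raise KeyError(f"unknown cell type {ctype!r}")

    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(len(cells) + 1)
    rng = np.random.default_rng(cell_seeds[-1])

    r1s, r2s, i1s, i2s, rows = [], [], [], [], []
    qual = "I" * read_length
    serial = 0
    frag_serial = 0
    for (cid, ctype, nfrag), cseed in zip(cells, cell_seeds[:-1]):
        child = cseed.spawn(2)
        frags = simulate_fragments(
            genome, meth_by_type[ctype], nfrag, insert_mean, insert_sd, chemistry,
            seed=child[0],
        )
        crng = np.random.default_rng(child[1])
        tn5, i5, i7 = design.triplet(cid)
        i2_clean = tn5 + i5
        for frag in frags:
            if adapter_contamination_rate > 0 and crng.random() < adapter_contamination_rate:
                newlen = int(crng.integers(30, read_length))
                if frag.length > newlen:
                    frag = Fragment(
                        frag.contig, frag.start, frag.start + newlen,
                        frag.meth_plus[:newlen], frag.meth_minus[:newlen],
                    )
            top, bottom = convert_fragment(frag, genome, chemistry, crng)
            if crng.random() < 0.5:
                strand, template = "OT", top
            else:
                strand, template = "OB", bottom
            seq1, ad1 = _fill_read(template, read_length)
            seq2, ad2 = _fill_read(revcomp_codes(template), read_length)
            pg = -1
            if polyg_rate > 0 and crng.random() < polyg_rate and read_length > 61:
                pg = int(crng.integers(61, read_length))
                seq2 = seq2[:pg] + "G" * (read_length - pg)
            copies = 2 if (duplication_rate > 0 and crng.random() < duplication_rate) else 1
            for copy in range(copies):
                rid = f"r{serial:09d}"
                serial += 1
                r1s.append((rid, seq1, qual))
                r2s.append((rid, seq2, qual))
                i1s.append((rid, _apply_index_errors(i7, index_error_rate, crng), "I" * len(i7)))
                i2s.append(
                    (rid, _apply_index_errors(i2_clean, index_error_rate, crng), "I" * len(i2_clean))
                )
                rows.append(
                    (rid, cid, ctype, frag_serial, frag.contig, frag.start, frag.end,
                     strand, copy > 0, ad1, ad2, pg)
                )
            frag_serial += 1
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return SimRun(r1s, r2s, i1s, i2s, truth, design, chemistry)
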