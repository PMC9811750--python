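"""Per-cell quality control.

Covers per-barcode processing metrics (mapping efficiency, paired fraction,
insert sizes, local-alignment fraction), high-quality-cell selection by
k-means on log10 unique-read counts with a fitted-normal confidence bound,
spike-in conversion/overconversion efficiency, cytosine-dinucleotide
coverage per mapped base, and the M-bias profile (methylation level by
read position) with its first-half vs second-half t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import A, C, G, T
from .methalign import (
    Alignment,
    CellCalls,
    ConvertedIndex,
    DINUC_NAMES,
    ReadUnit,
)


class DegenerateInputError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


# --------------------------------------------------------------------------
# per-cell metrics
# --------------------------------------------------------------------------

METRIC_COLUMNS = [
    "cell_id",
    "assigned",
    "aligned",
    "unique",
    "mapping_efficiency",
    "paired_fraction",
    "mean_insert",
    "local_fraction",
    "mapped_bases",
    "lambda_meth",
    "lambda_cov",
    "puc19_meth",
    "puc19_cov",
]


def cell_stats_from_units(
    units: Sequence[ReadUnit],
    dedup_units: Sequence[ReadUnit],
    calls: CellCalls | None,
    index: ConvertedIndex,
    lambda_contigs: Sequence[str] = (),
    puc19_contigs: Sequence[str] = (),
) -> dict:
    """Raw per-cell numbers from aligned (pre-dedup) and deduplicated units."""
    alns = [a for u in units for a in u.alignments]
    inserts = [u.a1.insert for u in units if u.a1 is not None and u.a1.paired]
    stats_d = {
        "aligned": len(units),
        "unique": len(dedup_units),
        "paired": sum(1 for u in units if u.a1 is not None and u.a2 is not None),
        "local": sum(1 for a in alns if a.mode == "local"),
        "n_alignments": len(alns),
        "mean_insert": float(np.mean(inserts)) if inserts else np.nan,
        "mapped_bases": int(sum(a.end - a.start for u in dedup_units for a in u.alignments)),
        "lambda_meth": 0,
        "lambda_cov": 0,
        "puc19_meth": 0,
        "puc19_cov": 0,
    }
    if calls is not None and len(calls.site_idx):
        for prefix, contigs, cg_only in (
            ("lambda", lambda_contigs, False),
            ("puc19", puc19_contigs, True),
        ):
            if not contigs:
                continue
            sel = index.contig_roles_sites(contigs)[calls.site_idx]
            if cg_only:
                sel &= index.site_context[calls.site_idx] == 0
            stats_d[f"{prefix}_meth"] = int(calls.meth[sel].sum())
            stats_d[f"{prefix}_cov"] = int(calls.cov[sel].sum())
    return stats_d


def compute_cell_metrics(
    assigned: Mapping[str, int], stats: Mapping[str, dict]
) -> pd.DataFrame:
    """Assemble the per-cell metrics table.

    `assigned` maps cell id to the number of read pairs demultiplexed to it;
    `stats` holds the per-cell numbers from ``cell_stats_from_units``.  A
    cell present in `stats` but absent from `assigned` is an inconsistency;
    cells with zero assigned reads are reported with zeros.
    """
    for cell in stats:
        if cell not in assigned:
            raise ConsistencyError(f"cell {cell!r} has alignments but no assignment record")
    rows = []
    for cell, n_assigned in assigned.items():
        s = stats.get(cell, {})
        aligned = s.get("aligned", 0)
        rows.append(
            {
                "cell_id": cell,
                "assigned": int(n_assigned),
                "aligned": aligned,
                "unique": s.get("unique", 0),
                "mapping_efficiency": aligned / n_assigned if n_assigned else 0.0,
                "paired_fraction": s.get("paired", 0) / aligned if aligned else 0.0,
                "mean_insert": s.get("mean_insert", np.nan),
                "local_fraction": (
                    s.get("local", 0) / s["n_alignments"] if s.get("n_alignments") else 0.0
                ),
                "mapped_bases": s.get("mapped_bases", 0),
                "lambda_meth": s.get("lambda_meth", 0),
                "lambda_cov": s.get("lambda_cov", 0),
                "puc19_meth": s.get("puc19_meth", 0),
                "puc19_cov": s.get("puc19_cov", 0),
            }
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


# --------------------------------------------------------------------------
# cell selection
# --------------------------------------------------------------------------

@dataclass
class QCThresholds:
    min_unique_reads: int = 100
    kmeans_k: int = 3
    ci_level: float = 0.95
    # interpretation knobs (the selection rule in the field's pipelines is
    # under-specified): which cluster is the "real cells" cluster, and
    # whether the confidence bound is one- or two-sided
    cluster_select: str = "highest-mean"
    tail: str = "two-sided"

    def __post_init__(self):
        if self.min_unique_reads < 0:
            raise ValueError("min_unique_reads must be >= 0")
        if self.kmeans_k < 2:
            raise ValueError("kmeans_k must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0,1)")


def select_cells(
    unique_counts: Mapping[str, int] | pd.Series,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
) -> tuple[list[str], dict]:
    """High-quality-cell selection from unique-read counts.

    Barcodes below `min_unique_reads` are removed first.  The remaining
    log10 counts are k-means clustered (k = 3 by default, seeded
    deterministic init); a normal distribution is fitted to each cluster and
    cells whose log10 count reaches the lower bound of the highest-mean
    cluster's central `ci_level` interval (mean − z·sd) are retained.
    """
    thresholds = thresholds or QCThresholds()
    counts = pd.Series(unique_counts, dtype=float)
    counts = counts[counts >= thresholds.min_unique_reads]
    k = thresholds.kmeans_k
    if len(counts) < k:
        raise DegenerateInputError(
            f"only {len(counts)} barcodes pass the minimum-read filter; "
            f"need at least kmeans_k={k} to cluster"
        )
    x = np.log10(counts.to_numpy())
    if thresholds.tail == "two-sided":
        z = stats.norm.ppf(1 - (1 - thresholds.ci_level) / 2)
    else:
        z = stats.norm.ppf(thresholds.ci_level)

    if len(np.unique(x)) < k:
        # degenerate: counts do not support k clusters; fit one normal
        labels = np.zeros(len(x), dtype=int)
        k_eff = 1
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(x.reshape(-1, 1))
        k_eff = k
    means = np.array([x[labels == i].mean() for i in range(k_eff)])
    sds = np.array([x[labels == i].std(ddof=0) for i in range(k_eff)])
    top = int(np.argmax(means))
    boundary = means[top] - z * sds[top]
    retained = counts.index[x >= boundary].tolist()
    report = {
        "n_input": int(len(counts)),
        "cluster_means_log10": means.tolist(),
        "cluster_sds_log10": sds.tolist(),
        "cluster_sizes": [int((labels == i).sum()) for i in range(k_eff)],
        "top_cluster": top,
        "z": float(z),
        "boundary_log10": float(boundary),
        "n_retained": len(retained),
    }
    return retained, report


# --------------------------------------------------------------------------
# spike-in efficiencies
# --------------------------------------------------------------------------

def conversion_efficiency(
    calls: CellCalls, index: ConvertedIndex, lambda_contigs: Sequence[str]
) -> float | None:
    """Conversion efficiency (%) = 100 × (1 − pooled 5mC level) over every
    call on the unmethylated lambda spike-in, all contexts.  None when the
    spike-in has no coverage (distinct from 100%)."""
    sel = index.contig_roles_sites(lambda_contigs)[calls.site_idx]
    cov = int(calls.cov[sel].sum())
    if cov == 0:
        return None
    meth = int(calls.meth[sel].sum())
    return 100.0 * (1.0 - meth / cov)


def overconversion_rate(
    calls: CellCalls, index: ConvertedIndex, puc19_contigs: Sequence[str]
) -> float | None:
    """Overconversion (%) = 100 × (1 − pooled 5mC level) over CpG-context
    calls on the fully CpG-methylated pUC19 spike-in."""
    sel = index.contig_roles_sites(puc19_contigs)[calls.site_idx]
    sel &= index.site_context[calls.site_idx] == 0
    cov = int(calls.cov[sel].sum())
    if cov == 0:
        return None
    meth = int(calls.meth[sel].sum())
    return 100.0 * (1.0 - meth / cov)


def dinucleotide_coverage(
    calls: CellCalls, index: ConvertedIndex, mapped_bases: int
) -> pd.DataFrame:
    """Distinct covered cytosine-dinucleotide sites as % of mapped bases."""
    if mapped_bases <= 0:
        raise ValueError("mapped_bases must be positive")
    counts = np.bincount(index.site_dinuc[calls.site_idx], minlength=4)
    return pd.DataFrame(
        {
            "dinucleotide": DINUC_NAMES,
            "covered_sites": counts.astype(int),
            "pct_of_mapped_bases": 100.0 * counts / mapped_bases,
        }
    )


def global_context_levels(
    calls: CellCalls, index: ConvertedIndex, contigs: Sequence[str] | None = None
) -> dict[str, float]:
    """Pooled methylation level per context (CG/CHG/CHH), optionally
    restricted to a contig subset (e.g. sample contigs only)."""
    sel = np.ones(len(calls.site_idx), dtype=bool)
    if contigs is not None:
        sel = index.contig_roles_sites(contigs)[calls.site_idx]
    out = {}
    ctx = index.site_context[calls.site_idx]
    for code, name in enumerate(("CG", "CHG", "CHH")):
        pick = sel & (ctx == code)
        cov = int(calls.cov[pick].sum())
        out[name] = float(calls.meth[pick].sum() / cov) if cov else np.nan
    return out


# --------------------------------------------------------------------------
# M-bias
# --------------------------------------------------------------------------

@dataclass
class MbiasProfile:
    """Methylation by read position with the first-half/second-half test."""

    table: pd.DataFrame  # position (1-based), context, methylated, coverage, level
    tests: dict  # context -> {statistic, pvalue, mean_first, mean_second}

    def pooled_level(self, context: str | None = None) -> float:
        t = self.table if context is None else self.table[self.table.context == context]
        return float(t.methylated.sum() / t.coverage.sum())


class MbiasAccumulator:
    """Streaming accumulator of per-read-position methylation counts."""

    def __init__(self, index: ConvertedIndex, max_len: int = 200):
        self.index = index
        self.meth = np.zeros((max_len, 3), np.int64)
        self.cov = np.zeros((max_len, 3), np.int64)

    def add_alignment(self, aln: Alignment) -> None:
        idx = self.index
        w0, wlen = aln.clip5, aln.end - aln.start
        gw = aln.g0 + w0
        g = idx.codes[gw : gw + wlen]
        s = aln.seq[w0 : w0 + wlen]
        if aln.strand_conv == "OT":
            cyt, mb, ub, lookup = C, C, T, idx._lookup_plus
        else:
            cyt, mb, ub, lookup = G, G, A, idx._lookup_minus
        offs = np.flatnonzero((g == cyt) & ((s == mb) | (s == ub)))
        if len(offs) == 0:
            return
        sidx = lookup[gw + offs]
        keep = sidx >= 0
        offs, sidx = offs[keep], sidx[keep]
        ctx = idx.site_context[sidx]
        rpos = aln.read_positions(offs)
        keep = rpos < self.meth.shape[0]
        offs, ctx, rpos = offs[keep], ctx[keep], rpos[keep]
        meth_flag = s[offs] == mb
        np.add.at(self.cov, (rpos, ctx), 1)
        if meth_flag.any():
            np.add.at(self.meth, (rpos[meth_flag], ctx[meth_flag]), 1)

    def add_units(self, units: Sequence[ReadUnit]) -> None:
        for u in units:
            for a in u.alignments:
                self.add_alignment(a)

    def profile(self) -> MbiasProfile:
        used = np.flatnonzero(self.cov.sum(axis=1))
        L = int(used.max()) + 1 if len(used) else 0
        rows = []
        for p in range(L):
            for c, cname in enumerate(("CG", "CHG", "CHH")):
                rows.append((p + 1, cname, int(self.meth[p, c]), int(self.cov[p, c])))
        table = pd.DataFrame(rows, columns=["position", "context", "methylated", "coverage"])
        with np.errstate(invalid="ignore", divide="ignore"):
            table["level"] = table.methylated / table.coverage
        tests = {}
        half = L // 2
        for cname in ("CG", "CHG", "CHH"):
            sub = table[(table.context == cname) & (table.coverage > 0)]
            first = sub[sub.position <= half].level.to_numpy()
            second = sub[sub.position > half].level.to_numpy()
            if len(first) < 2 or len(second) < 2:
                tests[cname] = None
                continue
            t, p = stats.ttest_ind(first, second, equal_var=True)
            tests[cname] = {
                "statistic": float(t),
                "pvalue": float(p),
                "mean_first": float(first.mean()),
                "mean_second": float(second.mean()),
            }
        return MbiasProfile(table, tests)


def mbias(
    units: Sequence[ReadUnit], index: ConvertedIndex, max_len: int = 200
) -> MbiasProfile:
    """M-bias profile of a set of aligned molecules (see MbiasAccumulator)."""
    acc = MbiasAccumulator(index, max_len=max_len)
    acc.add_units(units)
    return acc.profile()
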