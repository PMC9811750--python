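"""Cells × features methylation matrices.

Three summaries of per-cell calls, all pooled-ratio (Σmethylated/Σcoverage,
never a mean of per-site levels):

- metagene profiles: each (flanked) region is split into fractional-width
  bins (3% windows → 34 bins) and pooled across regions, bin 1 always 5′;
- per-region means over an interval set (DMRs, DEG promoters, regulatory
  build);
- fixed-size genomic bins (100 kb by default), typically for CpH.

Zero-coverage entries are missing (NaN + mask), and ``filter_and_impute``
turns a sparse matrix into the dense non-negative input factorization needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methalign import CellCalls, ConvertedIndex


class DegenerateInputError(ValueError):
    pass


CONTEXT_CODES = {"CG": (0,), "CHG": (1,), "CHH": (2,), "CpH": (1, 2), None: (0, 1, 2)}


@dataclass
class FeatureMatrix:
    """Methylation-level matrix with an observation mask.

    values[i, j] is the pooled level of cell i in feature j (NaN when the
    cell has no coverage there); coverage[i, j] is the pooled read coverage.
    """

    cells: list[str]
    features: list[str]
    values: np.ndarray
    coverage: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.features)

    def to_tsv(self, path, mask_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t")
        if mask_path is not None:
            pd.DataFrame(self.mask, index=self.cells, columns=self.features).to_csv(
                mask_path, sep="\t"
            )


def _region_frame(regions) -> pd.DataFrame:
    df = pd.DataFrame(regions).copy()
    if "strand" not in df:
        df["strand"] = "+"
    if "name" not in df:
        df["name"] = [f"region{i}" for i in range(len(df))]
    if (df.start >= df.end).any():
        raise ValueError("regions must satisfy start < end")
    return df


def _cell_sites_in(calls: CellCalls, lo: int, hi: int) -> slice:
    """Index range of a cell's (site-sorted) calls within site rows [lo, hi)."""
    a = int(np.searchsorted(calls.site_idx, lo, side="left"))
    b = int(np.searchsorted(calls.site_idx, hi, side="left"))
    return slice(a, b)


def metagene_profile(
    calls_by_cell: Mapping[str, CellCalls],
    index: ConvertedIndex,
    regions,
    flank: int = 5000,
    window_frac: float = 0.03,
    context: str = "CG",
) -> FeatureMatrix:
    """Fractional-window metagene profile pooled over a region set.

    Each region is extended by `flank` on both sides (clipped at the contig
    ends), divided into ceil(1/window_frac) bins whose widths differ by at
    most 1 bp and partition the flanked interval exactly, and bin-reversed
    for minus-strand regions so bin 1 is always the 5′ flank.  Per cell and
    bin, methylated and coverage counts of the requested context are pooled
    over all regions.
    """
    if not 2 <= 1 / window_frac <= 1000:
        raise ValueError("window_frac out of range")
    regions = _region_frame(regions)
    if len(regions) == 0:
        raise ValueError("empty region set")
    nbins = math.ceil(1 / window_frac)
    ctx_codes = CONTEXT_CODES[context]
    cells = list(calls_by_cell)
    meth = np.zeros((len(cells), nbins))
    cov = np.zeros((len(cells), nbins))
    for _, reg in regions.iterrows():
        clen = index.length_of(reg.contig)
        lo_c = max(0, int(reg.start) - flank)
        hi_c = min(clen, int(reg.end) + flank)
        g_lo = index.global_pos(reg.contig, lo_c)
        g_hi = g_lo + (hi_c - lo_c)
        length = hi_c - lo_c
        edges = (np.arange(nbins + 1) * length) // nbins
        s_lo = int(np.searchsorted(index.site_gpos, g_lo, side="left"))
        s_hi = int(np.searchsorted(index.site_gpos, g_hi, side="left"))
        ctx_ok = np.isin(index.site_context[s_lo:s_hi], ctx_codes)
        for ci, cell in enumerate(cells):
            calls = calls_by_cell[cell]
            sl = _cell_sites_in(calls, s_lo, s_hi)
            if sl.start == sl.stop:
                continue
            sidx = calls.site_idx[sl]
            keep = ctx_ok[sidx - s_lo]
            if not keep.any():
                continue
            sidx = sidx[keep]
            offs = index.site_gpos[sidx] - g_lo
            bins = np.searchsorted(edges, offs, side="right") - 1
            if reg.strand == "-":
                bins = nbins - 1 - bins
            np.add.at(meth[ci], bins, calls.meth[sl][keep])
            np.add.at(cov[ci], bins, calls.cov[sl][keep])
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
    features = [f"bin{i + 1:02d}" for i in range(nbins)]
    return FeatureMatrix(cells, features, values, cov.astype(int))


def region_methylation(
    calls_by_cell: Mapping[str, CellCalls],
    index: ConvertedIndex,
    regions,
    context: str = "CG",
) -> FeatureMatrix:
    """Pooled methylation level per region (regions as features).

    Overlapping regions are allowed; calls falling in several regions count
    in each.  Regions without coverage in a cell are missing for that cell.
    """
    regions = _region_frame(regions)
    ctx_codes = CONTEXT_CODES[context]
    cells = list(calls_by_cell)
    nreg = len(regions)
    meth = np.zeros((len(cells), nreg))
    cov = np.zeros((len(cells), nreg))
    for ri, (_, reg) in enumerate(regions.iterrows()):
        g_lo = index.global_pos(reg.contig, int(reg.start))
        g_hi = index.global_pos(reg.contig, 0) + int(reg.end)
        s_lo = int(np.searchsorted(index.site_gpos, g_lo, side="left"))
        s_hi = int(np.searchsorted(index.site_gpos, g_hi, side="left"))
        ctx_ok = np.isin(index.site_context[s_lo:s_hi], ctx_codes)
        for ci, cell in enumerate(cells):
            calls = calls_by_cell[cell]
            sl = _cell_sites_in(calls, s_lo, s_hi)
            if sl.start == sl.stop:
                continue
            keep = ctx_ok[calls.site_idx[sl] - s_lo]
            meth[ci, ri] = calls.meth[sl][keep].sum()
            cov[ci, ri] = calls.cov[sl][keep].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
    return FeatureMatrix(cells, list(regions.name), values, cov.astype(int))


def genomic_bins(
    calls_by_cell: Mapping[str, CellCalls],
    index: ConvertedIndex,
    bin_size: int = 100_000,
    context: str = "CpH",
    contigs: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Pooled methylation over fixed genomic windows tiled from position 0.

    Default context CpH pools CHG and CHH calls, the summary used to
    separate neuronal methylomes.
    """
    if bin_size < 1000:
        raise ValueError("bin_size must be >= 1000")
    names = list(contigs) if contigs is not None else list(index.names)
    ctx_codes = CONTEXT_CODES[context]
    features = []
    offsets = {}
    for name in names:
        nb = math.ceil(index.length_of(name) / bin_size)
        offsets[name] = len(features)
        features += [f"{name}:{i * bin_size}" for i in range(nb)]
    cells = list(calls_by_cell)
    meth = np.zeros((len(cells), len(features)))
    cov = np.zeros((len(cells), len(features)))
    for name in names:
        ci_idx = index.names.index(name)
        g0 = int(index.offsets[ci_idx])
        g1 = g0 + int(index.lengths[ci_idx])
        s_lo = int(np.searchsorted(index.site_gpos, g0, side="left"))
        s_hi = int(np.searchsorted(index.site_gpos, g1, side="left"))
        ctx_ok = np.isin(index.site_context[s_lo:s_hi], ctx_codes)
        for ci, cell in enumerate(cells):
            calls = calls_by_cell[cell]
            sl = _cell_sites_in(calls, s_lo, s_hi)
            if sl.start == sl.stop:
                continue
            sidx = calls.site_idx[sl]
            keep = ctx_ok[sidx - s_lo]
            if not keep.any():
                continue
            sidx = sidx[keep]
            bins = (index.site_gpos[sidx] - g0) // bin_size + offsets[name]
            np.add.at(meth[ci], bins, calls.meth[sl][keep])
            np.add.at(cov[ci], bins, calls.cov[sl][keep])
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
    return FeatureMatrix(cells, features, values, cov.astype(int))


def filter_and_impute(
    matrix: FeatureMatrix, min_cell_fraction: float = 0.2
) -> tuple[np.ndarray, list[str]]:
    """Drop features observed in < `min_cell_fraction` of cells and fill the
    remaining missing entries with the feature's observed mean.

    Returns the dense array (all values in [0, 1]) and the kept feature ids.
    """
    mask = matrix.mask
    frac = mask.mean(axis=0)
    keep = frac >= min_cell_fraction
    if not keep.any():
        raise DegenerateInputError("no feature passes the observation filter")
    vals = matrix.values[:, keep].copy()
    col_mean = np.nanmean(vals, axis=0)
    missing = np.isnan(vals)
    vals[missing] = np.broadcast_to(col_mean, vals.shape)[missing]
    return vals, [f for f, k in zip(matrix.features, keep) if k]


def promoters_from_genes(regions, upstream: int = 1500) -> pd.DataFrame:
    """Promoter intervals (`upstream` bp 5′ of the TSS) from stranded gene
    annotations; coordinates clipped at 0."""
    regions = _region_frame(regions)
    rows = []
    for _, r in regions.iterrows():
        if r.strand == "-":
            start, end = int(r.end), int(r.end) + upstream
        else:
            start, end = max(0, int(r.start) - upstream), int(r.start)
        if start < end:
            rows.append((r.contig, start, end, f"{r['name']}_promoter", 0, r.strand))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score", "strand"])
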