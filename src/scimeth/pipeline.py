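"""End-to-end orchestration: simulate → demultiplex → trim → align →
deduplicate → call methylation → QC → feature matrices → NMF/t-SNE/DBSCAN →
pseudobulk annotation, with ground-truth evaluation when the input is a
simulated run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import barcodes, cellqc, celltyping, methalign, methfeatures, readprep, simdata


@dataclass
class PipelineConfig:
    """Study design for a simulated end-to-end run.

    Defaults describe the reference simulation: four cell types of 50 cells,
    ~3,000 fragments per cell on a 2 Mb genome with 30 DMRs, enzymatic
    chemistry at realistic conversion rates, NovaSeq-style 142 bp paired
    reads with three-level combinatorial indexes.
    """

    n_contigs: int = 1
    contig_length: int = 2_000_000
    gc_fraction: float = 0.42
    n_celltypes: int = 4
    cells_per_type: int = 50
    fragments_per_cell: int = 3000
    n_dmrs: int = 30
    dmr_length: int = 2000
    n_extra_regions: int = 30
    baseline_cpg: float = 0.8
    # None: per-type CpH rates spread over the neuron/glia range
    # (0.5% .. 3%), the structure the CpH genomic-bin summary clusters on
    cph_rate: float | None = None
    chemistry: simdata.ChemistryModel = field(
        default_factory=lambda: simdata.ChemistryModel(
            mode="enzymatic", conversion_rate=0.999, overconversion_rate=0.002
        )
    )
    read_length: int = 142
    insert_mean: float = 250.0
    insert_sd: float = 80.0
    adapter_contamination_rate: float = 0.05
    polyg_rate: float = 0.01
    index_error_rate: float = 0.002
    duplication_rate: float = 0.1
    seed_k: int = 12
    embedding: celltyping.EmbeddingConfig = field(default_factory=celltyping.EmbeddingConfig)
    min_cell_fraction: float = 0.2
    bin_size: int = 100_000
    # "min-reads" keeps every barcode with >= 100 unique reads (the generator
    # emits no debris barcodes, so the trimodal k-means selection has nothing
    # to reject); "kmeans" runs the full selection
    selection: str = "min-reads"


@dataclass
class SimulatedInputs:
    genome: simdata.SimGenome
    methylomes: list[simdata.CellTypeMethylome]
    dmr_table: pd.DataFrame
    regulatory_regions: pd.DataFrame
    design: simdata.BarcodeDesign
    run: simdata.SimRun
    cells: list[tuple[str, str, int]]


def simulate_inputs(config: PipelineConfig, seed: int) -> SimulatedInputs:
    """Build genome, methylomes, barcode design and the emitted run."""
    ss = np.random.SeedSequence(seed).spawn(5)

    def _seed(s):
        return int(s.generate_state(1)[0] % (2**31))

    genome = simdata.simulate_genome(
        config.n_contigs, config.contig_length, config.gc_fraction, _seed(ss[0])
    )
    cph = config.cph_rate
    if cph is None:
        cph = np.linspace(0.005, 0.03, config.n_celltypes).tolist()
    methylomes, dmr_table = simdata.simulate_methylomes(
        genome,
        config.n_celltypes,
        config.n_dmrs,
        config.dmr_length,
        cph_rate=cph,
        baseline_cpg=config.baseline_cpg,
        seed=_seed(ss[1]),
    )
    regulatory = _regulatory_regions(genome, dmr_table, config, _seed(ss[2]))
    cells = [
        (f"cell{t}_{i}", f"type{t}", config.fragments_per_cell)
        for t in range(config.n_celltypes)
        for i in range(config.cells_per_type)
    ]
    design = simdata.design_barcodes([c[0] for c in cells], _seed(ss[3]))
    run = simdata.emit_run(
        cells,
        genome,
        methylomes,
        design,
        config.chemistry,
        read_length=config.read_length,
        insert_mean=config.insert_mean,
        insert_sd=config.insert_sd,
        adapter_contamination_rate=config.adapter_contamination_rate,
        polyg_rate=config.polyg_rate,
        index_error_rate=config.index_error_rate,
        duplication_rate=config.duplication_rate,
        seed=_seed(ss[4]),
    )
    return SimulatedInputs(genome, methylomes, dmr_table, regulatory, design, run, cells)


def _regulatory_regions(genome, dmr_table, config, seed) -> pd.DataFrame:
    """Synthetic regulatory build: the DMRs plus extra non-DMR regions."""
    rng = np.random.default_rng(seed)
    rows = [
        (r.contig, int(r.start), int(r.end), r['name'])
        for _, r in dmr_table.iterrows()
    ]
    samples = genome.sample_contigs
    for i in range(config.n_extra_regions):
        contig = samples[int(rng.integers(0, len(samples)))]
        length = config.dmr_length
        start = int(rng.integers(0, genome.length(contig) - length))
        rows.append((contig, start, start + length, f"reg{i}"))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "name"])
    df["strand"] = "+"
    return df


@dataclass
class ProcessedRun:
    """Per-cell products of demux → trim → align → dedup → extraction."""

    index: methalign.ConvertedIndex
    demux: barcodes.DemuxResult
    trim_report: readprep.TrimReport
    calls_by_cell: dict[str, methalign.CellCalls]
    metrics: pd.DataFrame
    mbias: cellqc.MbiasProfile
    duplicates_removed: int


def process_run(
    run: simdata.SimRun,
    genome: simdata.SimGenome,
    design: simdata.BarcodeDesign | None = None,
    seed_k: int = 12,
    trim_config: readprep.TrimConfig | None = None,
    max_mismatch_frac: float = 0.1,
) -> ProcessedRun:
    """Run the read-level pipeline on an emitted run."""
    design = design or run.design
    index = methalign.build_index(genome.contigs, seed_k=seed_k)
    idx_design = barcodes.IndexDesign(
        tn5_length=design.tn5_length,
        i5_length=design.i5_length,
        i7_length=design.i7_length,
    )
    demux = barcodes.demultiplex(
        run.r1, run.r2, run.i1, run.i2, idx_design,
        {"tn5": design.tn5, "i5": design.i5, "i7": design.i7},
    )
    trim_cfg = trim_config or readprep.TrimConfig()
    lambda_contigs = genome.contigs_with_role(simdata.ROLE_LAMBDA)
    puc_contigs = genome.contigs_with_role(simdata.ROLE_PUC19)

    calls_by_cell: dict[str, methalign.CellCalls] = {}
    stats_by_cell: dict[str, dict] = {}
    agg_trim = readprep.TrimReport()
    mbias_acc = cellqc.MbiasAccumulator(index, max_len=run.r1[0][1].__len__() if run.r1 else 200)
    total_dups = 0
    for cell_name, rows in demux.cells.items():
        pairs = ((run.r1[j][0], run.r1[j][1], run.r2[j][1]) for j in rows)
        trimmed, rep = readprep.trim_pairs(pairs, trim_cfg)
        for k in ("pairs_in", "pairs_out", "pairs_dropped", "bases_removed"):
            setattr(agg_trim, k, getattr(agg_trim, k) + getattr(rep, k))
        units = []
        for rid, t1, t2 in trimmed:
            a1 = methalign.align_read(t1, index, max_mismatch_frac, read_id=rid)
            a2 = methalign.align_read(t2, index, max_mismatch_frac, read_id=rid)
            if a1 is not None and not a1.unique:
                a1 = None
            if a2 is not None and not a2.unique:
                a2 = None
            methalign.pair_reads(a1, a2)
            if a1 is not None or a2 is not None:
                units.append(methalign.ReadUnit(rid, a1, a2))
        units = methalign.sort_units(units)
        dedup, ndup = methalign.deduplicate(units)
        total_dups += ndup
        calls = methalign.extract_methylation(dedup, index)
        calls_by_cell[cell_name] = calls
        stats_by_cell[cell_name] = cellqc.cell_stats_from_units(
            units, dedup, calls, index, lambda_contigs, puc_contigs
        )
        mbias_acc.add_units(dedup)

    assigned = demux.assignments
    assigned_counts = (
        assigned[assigned.status == "assigned"].cell_id.value_counts().to_dict()
    )
    metrics = cellqc.compute_cell_metrics(assigned_counts, stats_by_cell)
    return ProcessedRun(
        index, demux, agg_trim, calls_by_cell, metrics, mbias_acc.profile(), total_dups
    )


@dataclass
class ClusteringResult:
    retained: list[str]
    qc_report: dict
    fm_cpg: methfeatures.FeatureMatrix
    fm_cph: methfeatures.FeatureMatrix
    merged: np.ndarray
    coords: np.ndarray
    clusters: pd.Series  # cell -> cluster id (-1 noise)
    pseudobulk: dict[int, methalign.CellCalls]
    annotation: celltyping.ClusterAnnotation | None


def cluster_cells(
    processed: ProcessedRun,
    regulatory_regions: pd.DataFrame,
    dmr_table: pd.DataFrame | None,
    genome: simdata.SimGenome,
    config: PipelineConfig,
    seed: int = 0,
) -> ClusteringResult:
    """QC selection, feature matrices, NMF–tSNE–DBSCAN and annotation."""
    emb = config.embedding
    counts = processed.metrics.set_index("cell_id")["unique"]
    if config.selection == "kmeans":
        retained, qc_report = cellqc.select_cells(counts, seed=seed)
    else:
        thr = cellqc.QCThresholds()
        retained = counts.index[counts >= thr.min_unique_reads].tolist()
        qc_report = {"n_retained": len(retained), "rule": "min-reads"}
    calls = {c: processed.calls_by_cell[c] for c in retained}
    index = processed.index

    fm_cpg = methfeatures.region_methylation(calls, index, regulatory_regions, context="CG")
    fm_cph = methfeatures.genomic_bins(
        calls, index, bin_size=config.bin_size, context="CpH",
        contigs=genome.sample_contigs,
    )
    x_cpg, _ = methfeatures.filter_and_impute(fm_cpg, config.min_cell_fraction)
    x_cph, _ = methfeatures.filter_and_impute(fm_cph, config.min_cell_fraction)
    w_cpg = celltyping.nmf_embed(x_cpg, emb.nmf_k, emb.nmf_seed)
    k_cph = min(emb.nmf_k, x_cph.shape[1] - 1)
    w_cph = celltyping.nmf_embed(x_cph, k_cph, emb.nmf_seed)
    merged = celltyping.merge_embeddings(w_cpg, w_cph, (emb.cpg_weight, emb.cph_weight))
    coords = celltyping.tsne_project(merged, emb.tsne_perplexity, emb.tsne_seed)
    labels = celltyping.dbscan_cluster(coords, emb.dbscan_eps, emb.dbscan_min_samples)
    clusters = pd.Series(labels, index=retained)
    pseudo = celltyping.pseudobulk(calls, clusters.to_dict())

    annotation = None
    if dmr_table is not None and len(pseudo) > 1:
        levels = annotation_set_levels(pseudo, index, dmr_table)
        annotation = celltyping.annotate_clusters(levels, method="lowest-z")
    return ClusteringResult(
        retained, qc_report, fm_cpg, fm_cph, merged, coords, clusters, pseudo, annotation
    )


def annotation_set_levels(
    pseudo: Mapping[int, methalign.CellCalls],
    index: methalign.ConvertedIndex,
    dmr_table: pd.DataFrame,
    context: str = "CG",
) -> pd.DataFrame:
    """Annotation-set × cluster pooled CpG levels.

    Each cell type's hypomethylated-DMR set is one annotation row; levels
    pool methylated/coverage over the set's regions in each cluster's
    pseudobulk methylome.
    """
    pseudo_calls = {f"cluster{cl}": c for cl, c in pseudo.items()}
    fm = methfeatures.region_methylation(pseudo_calls, index, dmr_table, context=context)
    sets = sorted(dmr_table.celltype.unique())
    out = pd.DataFrame(index=sets, columns=list(pseudo_calls.keys()), dtype=float)
    region_sets = dmr_table.groupby("celltype")["name"].apply(list)
    fidx = {f: j for j, f in enumerate(fm.features)}
    for s in sets:
        cols = [fidx[n] for n in region_sets[s]]
        meth = np.nansum(fm.values[:, cols] * fm.coverage[:, cols], axis=1)
        cov = fm.coverage[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out.loc[s] = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
    return out


@dataclass
class EndToEndResult:
    inputs: SimulatedInputs
    processed: ProcessedRun
    clustering: ClusteringResult
    evaluation: dict


def run_end_to_end(config: PipelineConfig | None = None, seed: int = 0) -> EndToEndResult:
    """Simulate a run, process it and evaluate clustering against the truth."""
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(seed).spawn(3)

    def _seed(s):
        return int(s.generate_state(1)[0] % (2**31))

    inputs = simulate_inputs(config, _seed(ss[0]))
    processed = process_run(inputs.run, inputs.genome, inputs.design, seed_k=config.seed_k)
    clustering = cluster_cells(
        processed, inputs.regulatory_regions, inputs.dmr_table, inputs.genome,
        config, seed=_seed(ss[1]),
    )
    evaluation = evaluate_clustering(inputs, clustering)
    return EndToEndResult(inputs, processed, clustering, evaluation)


def evaluate_clustering(inputs: SimulatedInputs, clustering: ClusteringResult) -> dict:
    """Adjusted Rand index over DBSCAN-assigned cells plus annotation accuracy."""
    from sklearn.metrics import adjusted_rand_score

    name_to_type = {
        inputs.design.cell_name(cid): ctype for cid, ctype, _ in inputs.cells
    }
    clusters = clustering.clusters
    assigned = clusters[clusters >= 0]
    truth = [name_to_type[c] for c in assigned.index]
    ari = adjusted_rand_score(truth, assigned.to_numpy()) if len(assigned) else 0.0
    n_clusters = int(assigned.nunique())
    label_acc = None
    if clustering.annotation is not None:
        correct = 0
        total = 0
        for cl in sorted(set(assigned)):
            members = assigned.index[assigned == cl]
            majority = pd.Series([name_to_type[c] for c in members]).mode()[0]
            predicted = clustering.annotation.labels.get(f"cluster{cl}")
            total += 1
            if predicted == majority:
                correct += 1
        label_acc = correct / total if total else None
    return {
        "ari": float(ari),
        "n_clusters": n_clusters,
        "noise_cells": int((clusters < 0).sum()),
        "n_cells": int(len(clusters)),
        "label_accuracy": label_acc,
    }
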