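"""Generator correctness: genome composition, methylome structure,
conversion chemistry and run emission, each against an independent oracle
where the spec of the quantity admits one (binomial sampling bounds,
importance-sampling expectations, brute-force decoding)."""

import numpy as np
import pandas as pd
import pytest

from scimeth import simdata
from scimeth.io import seq_to_codes


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        g1 = simdata.simulate_genome(1, 10_000, 0.4, seed=7)
        g2 = simdata.simulate_genome(1, 10_000, 0.4, seed=7)
        assert g1.contigs == g2.contigs
        g3 = simdata.simulate_genome(1, 10_000, 0.4, seed=8)
        assert g3.contigs["chr1"] != g1.contigs["chr1"]

    def test_gc_fraction_binomial_bound(self):
        # observed G+C of an i.i.d. sequence is Binomial(n, gc)
        n = 1_000_000
        g = simdata.simulate_genome(1, n, 0.5, seed=1)
        codes = g.codes("chr1")
        gc = ((codes == 1) | (codes == 2)).mean()
        sd = np.sqrt(0.25 / n)
        assert abs(gc - 0.5) < 3 * sd

    def test_gc_zero_degenerate(self):
        g = simdata.simulate_genome(1, 2_000, 0.0, seed=2)
        assert not set("GC") & set(g.contigs["chr1"])

    def test_roles_and_spikein_lengths(self):
        g = simdata.simulate_genome(2, 5_000, 0.4, seed=3)
        assert g.roles["lambda"] == simdata.ROLE_LAMBDA
        assert g.roles["pUC19"] == simdata.ROLE_PUC19
        assert len(g.contigs["lambda"]) == simdata.LAMBDA_LENGTH
        assert len(g.contigs["pUC19"]) == simdata.PUC19_LENGTH

    @pytest.mark.parametrize("kwargs", [
        dict(n_contigs=0, contig_length=5000, gc_fraction=0.5),
        dict(n_contigs=1, contig_length=500, gc_fraction=0.5),
        dict(n_contigs=1, contig_length=5000, gc_fraction=1.5),
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            simdata.simulate_genome(seed=0, **kwargs)


class TestSimulateMethylomes:
    def test_spikein_probabilities(self, small_genome, small_methylomes):
        methylomes, _ = small_methylomes
        for m in methylomes:
            assert m.p_plus["lambda"].max() == 0.0
            assert m.p_minus["lambda"].max() == 0.0
            codes = small_genome.codes("pUC19")
            cpg_p, cpg_m = simdata._context_masks(codes)
            assert (m.p_plus["pUC19"][cpg_p] == 1.0).all()
            assert (m.p_minus["pUC19"][cpg_m] == 1.0).all()
            assert m.p_plus["pUC19"][(codes == 1) & ~cpg_p].max() == 0.0

    def test_no_dmrs_all_types_identical(self, small_genome):
        ms, dmr = simdata.simulate_methylomes(small_genome, 3, 0, 1000, seed=5)
        assert dmr.empty
        for m in ms[1:]:
            for contig in small_genome.contigs:
                np.testing.assert_array_equal(m.p_plus[contig], ms[0].p_plus[contig])

    def test_dmr_levels_and_assignment(self, small_genome, small_methylomes):
        methylomes, dmr = small_methylomes
        by_name = {m.name: m for m in methylomes}
        for _, r in dmr.iterrows():
            codes = small_genome.codes(r.contig)[r.start : r.end]
            cpg = (codes[:-1] == 1) & (codes[1:] == 2)
            hypo = by_name[r.celltype].p_plus[r.contig][r.start : r.end - 1][cpg]
            assert (hypo == 0.1).all()
            other = next(m for m in methylomes if m.name != r.celltype)
            assert (other.p_plus[r.contig][r.start : r.end - 1][cpg] == 0.9).all()

    def test_layout_error(self, small_genome):
        with pytest.raises(simdata.LayoutError):
            simdata.simulate_methylomes(small_genome, 2, 100, 1000, seed=0)


class TestFragments:
    def test_zero_fragments(self, small_genome, small_methylomes):
        ms, _ = small_methylomes
        assert simdata.simulate_fragments(small_genome, ms[0], 0, seed=1) == []

    def test_insert_floor_and_bounds(self, small_genome, small_methylomes):
        ms, _ = small_methylomes
        frags = simdata.simulate_fragments(
            small_genome, ms[0], 300, insert_mean=40, insert_sd=50, seed=2
        )
        for f in frags:
            assert f.length >= 30
            assert 0 <= f.start < f.end <= small_genome.length(f.contig)

    def test_survival_bias_importance_sampling_oracle(self, small_genome, small_methylomes):
        """Mean methylated fraction of surviving fragments matches
        E[m·w]/E[w] with w = exp(gamma·m) estimated from an unbiased
        candidate sample."""
        ms, _ = small_methylomes
        gamma = 4.0
        chem0 = simdata.ChemistryModel()
        chem = simdata.ChemistryModel(mode="bisulfite", survival_gamma=gamma)
        base = simdata.simulate_fragments(small_genome, ms[0], 8000, seed=3, chemistry=chem0)
        m_base = np.array([f.methylated_fraction(small_genome.codes(f.contig)) for f in base])
        w = np.exp(gamma * m_base)
        expected = float((m_base * w).sum() / w.sum())
        sel = simdata.simulate_fragments(small_genome, ms[0], 6000, seed=4, chemistry=chem)
        m_sel = np.array([f.methylated_fraction(small_genome.codes(f.contig)) for f in sel])
        assert m_sel.mean() > m_base.mean()
        assert abs(m_sel.mean() - expected) < 4 * m_sel.std() / np.sqrt(len(m_sel))

    def test_survival_monotone_in_gamma(self, small_genome, small_methylomes):
        ms, _ = small_methylomes
        means = []
        for gamma in (0.0, 2.0, 5.0):
            chem = (
                simdata.ChemistryModel()
                if gamma == 0
                else simdata.ChemistryModel(mode="bisulfite", survival_gamma=gamma)
            )
            frags = simdata.simulate_fragments(
                small_genome, ms[0], 4000, seed=9, chemistry=chem
            )
            means.append(
                np.mean([f.methylated_fraction(small_genome.codes(f.contig)) for f in frags])
            )
        assert means[0] < means[1] < means[2]


class TestChemistry:
    def test_enzymatic_forbids_bias_terms(self):
        with pytest.raises(ValueError):
            simdata.ChemistryModel(mode="enzymatic", positional_bias_slope=0.1)
        with pytest.raises(ValueError):
            simdata.ChemistryModel(mode="enzymatic", survival_gamma=1.0)

    def test_full_conversion_leaves_no_c(self, small_genome, small_methylomes):
        ms, _ = small_methylomes
        # lambda fragments are fully unmethylated
        frag = simdata.Fragment(
            "lambda", 0, 2000, np.zeros(2000, bool), np.zeros(2000, bool)
        )
        chem = simdata.ChemistryModel(conversion_rate=1.0, overconversion_rate=0.0)
        top, bottom = simdata.convert_fragment(frag, small_genome, chem, 1)
        assert (top != 1).all()  # no C on top template
        assert (bottom != 1).all()

    def test_zero_conversion_is_identity(self, small_genome):
        frag = simdata.Fragment(
            "lambda", 100, 400, np.zeros(300, bool), np.zeros(300, bool)
        )
        chem = simdata.ChemistryModel(conversion_rate=0.0, overconversion_rate=0.0)
        top, _ = simdata.convert_fragment(frag, small_genome, chem, 2)
        np.testing.assert_array_equal(top, small_genome.codes("lambda")[100:400])

    def test_retained_c_binomial_oracle(self, small_genome):
        """At conversion 0.9994 the retained-C count over n lambda cytosines
        is Binomial(n, 0.0006)."""
        chem = simdata.ChemistryModel(conversion_rate=0.9994, overconversion_rate=0.0)
        L = small_genome.length("lambda")
        frag = simdata.Fragment("lambda", 0, L, np.zeros(L, bool), np.zeros(L, bool))
        codes = small_genome.codes("lambda")
        n_c = int((codes == 1).sum())
        rng = np.random.default_rng(12)
        total, kept = 0, 0
        while total < 1_000_000:
            top, _ = simdata.convert_fragment(frag, small_genome, chem, rng)
            kept += int((top == 1).sum())
            total += n_c
        p = 0.0006
        sd = np.sqrt(total * p * (1 - p))
        assert abs(kept - total * p) < 3 * sd

    def test_positional_bias_raises_3prime_retention(self, small_genome):
        chem = simdata.ChemistryModel(
            mode="bisulfite", conversion_rate=1.0, positional_bias_slope=0.3
        )
        L = small_genome.length("lambda")
        frag = simdata.Fragment("lambda", 0, L, np.zeros(L, bool), np.zeros(L, bool))
        rng = np.random.default_rng(5)
        top, _ = simdata.convert_fragment(frag, small_genome, chem, rng)
        codes = small_genome.codes("lambda")
        c_pos = np.flatnonzero(codes == 1)
        retained = top[c_pos] == 1
        first, second = retained[: len(c_pos) // 2], retained[len(c_pos) // 2 :]
        assert second.mean() > first.mean()


class TestEmitRun:
    def test_record_conservation(self, small_run):
        n = len(small_run.truth)
        assert len(small_run.r1) == len(small_run.r2) == n
        assert len(small_run.i1) == len(small_run.i2) == n
        assert n == 300
        assert small_run.truth.read_id.is_unique

    def test_error_free_indexes_match_whitelist(self, small_run):
        design = small_run.design
        for (rid, i1_seq, _), (_, i2_seq, _), cid in zip(
            small_run.i1, small_run.i2, small_run.truth.cell_id
        ):
            tn5, i5, i7 = design.triplet(cid)
            assert i1_seq == i7
            assert i2_seq == tn5 + i5

    def test_short_fragment_reads_through_into_adapter(
        self, small_genome, small_methylomes, clean_chemistry
    ):
        ms, _ = small_methylomes
        design = simdata.design_barcodes(["c0"], seed=1)
        run = simdata.emit_run(
            [("c0", "type0", 120)], small_genome, ms, design, clean_chemistry,
            read_length=100, insert_mean=60, insert_sd=10, seed=4,
        )
        short = run.truth[run.truth.adapter_start_r1 >= 0]
        assert len(short) > 0
        for _, row in short.iterrows():
            seq = run.r1[int(row.name)][1]
            onset = int(row.adapter_start_r1)
            expected = simdata.ADAPTER_P7[: 100 - onset]
            assert seq[onset : onset + len(expected)] == expected

    def test_polyg_overwrites_read2_tail(self, small_genome, small_methylomes, clean_chemistry):
        ms, _ = small_methylomes
        design = simdata.design_barcodes(["c0"], seed=1)
        run = simdata.emit_run(
            [("c0", "type0", 200)], small_genome, ms, design, clean_chemistry,
            read_length=100, polyg_rate=0.5, seed=6,
        )
        hit = run.truth[run.truth.polyg_start >= 0]
        assert len(hit) > 0
        for _, row in hit.iterrows():
            seq = run.r2[int(row.name)][1]
            assert row.polyg_start > 60
            assert set(seq[int(row.polyg_start) :]) == {"G"}

    def test_unknown_cell_id_rejected(self, small_genome, small_methylomes, clean_chemistry):
        ms, _ = small_methylomes
        design = simdata.design_barcodes(["c0"], seed=1)
        with pytest.raises(KeyError):
            simdata.emit_run(
                [("ghost", "type0", 10)], small_genome, ms, design, clean_chemistry
            )

    def test_clean_reads_decode_to_fragment_coordinates(
        self, small_genome, small_methylomes
    ):
        """With all error rates 0, conversion 1 and a fully unmethylated
        methylome, brute-force substring search of read 1 against the
        converted genome recovers the exact fragment coordinates."""
        methylomes, _ = simdata.simulate_methylomes(
            small_genome, 1, 0, 1000, cph_rate=0.0, baseline_cpg=0.0, seed=2
        )
        methylome = methylomes[0]
        chem = simdata.ChemistryModel(conversion_rate=1.0, overconversion_rate=0.0)
        design = simdata.design_barcodes(["c0"], seed=1)
        run = simdata.emit_run(
            [("c0", "type0", 40)], small_genome, [methylome], design, chem,
            read_length=80, insert_mean=300, insert_sd=40, seed=8,
        )
        converted = {
            name: seq.replace("C", "T") for name, seq in small_genome.contigs.items()
        }
        rc = {name: _revcomp(seq).replace("C", "T") for name, seq in small_genome.contigs.items()}
        for (rid, seq, _), row in zip(run.r1, run.truth.itertuples()):
            if row.end - row.start < 80 or row.contig == "pUC19":
                continue  # pUC19 keeps its methylated CpGs as C
            if row.conv_strand == "OT":
                assert converted[row.contig].find(seq) == row.start
            else:
                pos = rc[row.contig].find(seq)
                assert pos >= 0
                assert small_genome.length(row.contig) - pos - (row.end - row.start) == row.start


def _revcomp(seq):
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


class TestWhitelists:
    def test_pairwise_distance_floor(self):
        rng = np.random.default_rng(0)
        wl = simdata.generate_whitelist(48, 10, 5, rng)
        arr = np.stack([seq_to_codes(w) for w in wl])
        for i in range(len(wl)):
            d = (arr[i] != arr).sum(axis=1)
            d[i] = 99
            assert d.min() >= 5

    def test_design_assigns_distinct_triplets(self):
        design = simdata.design_barcodes([f"c{i}" for i in range(200)], seed=3)
        triplets = {design.triplet(f"c{i}") for i in range(200)}
        assert len(triplets) == 200


class TestReadcountMixture:
    def test_population_sizes_and_reproducibility(self):
        df1 = simdata.simulate_readcount_mixture(seed=1)
        df2 = simdata.simulate_readcount_mixture(seed=1)
        pd.testing.assert_frame_equal(df1, df2)
        assert df1.population.value_counts().to_dict() == {
            "real": 700, "debris": 600, "low": 300
        }
        assert (df1.unique_reads >= 1).all()
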