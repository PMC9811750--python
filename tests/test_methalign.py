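"""Aligner and methylation extraction: converted images, the asymmetric
mismatch rule, exhaustive-alignment oracles, mate pairing, deduplication
against the truth table, and per-cytosine call recovery."""

import numpy as np
import pandas as pd
import pytest

from scimeth import methalign, simdata
from scimeth.io import codes_to_seq, revcomp, seq_to_codes


class TestBuildIndex:
    def test_toy_images(self):
        idx = methalign.build_index({"toy": "ACGT"}, seed_k=8)
        lo = idx.global_pos("toy", 0)
        assert codes_to_seq(idx.ct_image[lo : lo + 4]) == "ATGT"
        assert codes_to_seq(idx.ga_image[lo : lo + 4]) == "ACAT"

    def test_stored_kmer_lookup_roundtrip(self, small_index):
        km, pos = small_index._ct_index
        rng = np.random.default_rng(4)
        for i in rng.integers(0, len(km), 50):
            p = pos[i]
            window = small_index.ct_image[p : p + small_index.seed_k]
            val = int(window.astype(np.int64) @ small_index._pow4)
            assert val == km[i]

    def test_seed_k_floor(self):
        with pytest.raises(ValueError):
            methalign.build_index({"toy": "ACGT" * 100}, seed_k=4)

    def test_short_contig_warns(self):
        with pytest.warns(UserWarning):
            methalign.build_index({"tiny": "ACGTACG"}, seed_k=8)


def _converted_read(genome, contig, start, length, rule="OT"):
    seq = genome.contigs[contig][start : start + length]
    if rule == "OT":
        return seq.replace("C", "T")
    return seq.replace("G", "A")


class TestAlignRead:
    def test_clean_converted_read_end_to_end(self, small_genome, small_index):
        read = _converted_read(small_genome, "chr1", 12345, 80)
        a = methalign.align_read(read, small_index)
        assert a is not None
        assert (a.contig, a.start, a.end) == ("chr1", 12345, 12425)
        assert a.mode == "end-to-end" and a.nm == 0 and a.strand_conv == "OT"

    def test_reverse_complement_read_maps_to_same_locus(self, small_genome, small_index):
        read = revcomp(_converted_read(small_genome, "chr1", 9000, 80))
        a = methalign.align_read(read, small_index)
        assert a is not None
        assert (a.contig, a.start, a.orient) == ("chr1", 9000, "-")

    def test_adapter_tail_triggers_local_mode(self, small_genome, small_index):
        read = _converted_read(small_genome, "chr1", 5000, 60) + simdata.ADAPTER_P7
        a = methalign.align_read(read, small_index)
        assert a is not None
        assert a.mode == "local"
        assert a.start == 5000 and a.end <= 5000 + 66
        assert a.clipped >= 25

    def test_random_read_unmapped(self, small_index):
        rng = np.random.default_rng(9)
        read = "".join(rng.choice(list("ACGT"), 80))
        a = methalign.align_read(read, small_index, max_mismatch_frac=0.05)
        if a is not None:  # a seed may hit; the placement must then be poor
            assert a.mode == "local"

    def test_asymmetric_mismatch_rule(self, small_genome, small_index):
        """C→T differences from the reference are free on OT; the reverse
        substitution pattern (T→C) is penalized."""
        seg = small_genome.contigs["chr1"][20000:20080]
        ct = seg.replace("C", "T")
        a = methalign.align_read(ct, small_index)
        assert a.nm == 0 and a.strand_conv == "OT" and a.start == 20000
        tc = seg.replace("T", "C")
        b = methalign.align_read(tc, small_index)
        assert b is None or b.nm > 0 or b.contig != "chr1" or b.start != 20000

    def test_exhaustive_alignment_oracle(self, small_genome, small_index):
        """Indexed alignment coordinates equal brute-force scanning of every
        offset under both conversion rules and orientations."""
        rng = np.random.default_rng(13)
        gcodes = {c: small_genome.codes(c) for c in small_genome.contigs}
        n_checked = 0
        for _ in range(60):
            contig = "chr1"
            start = int(rng.integers(0, 49_000))
            L = 70
            rule = ("OT", "OB")[int(rng.integers(2))]
            orient = ("+", "-")[int(rng.integers(2))]
            read = _converted_read(small_genome, contig, start, L, rule)
            if orient == "-":
                read = revcomp(read)
            a = methalign.align_read(read, small_index)
            exp_contig, exp_start = _exhaustive_best(gcodes, seq_to_codes(read), L)
            assert a is not None
            assert (a.contig, a.start) == (exp_contig, exp_start) == (contig, start)
            n_checked += 1
        assert n_checked == 60


def _exhaustive_best(gcodes, read, L):
    """Brute-force best end-to-end placement over all contigs, offsets,
    orientations and conversion rules."""
    from scimeth.io import revcomp_codes

    C, G, T, A = 1, 2, 3, 0
    best = (None, None, -1)
    for contig, g in gcodes.items():
        if len(g) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(g, L)
        for s in (read, revcomp_codes(read)):
            for rule in ("OT", "OB"):
                match = win == s
                if rule == "OT":
                    match |= (win == C) & (s == T)
                else:
                    match |= (win == G) & (s == A)
                scores = match.sum(axis=1)
                j = int(scores.argmax())
                sc = int(scores[j])
                if sc > best[2]:
                    best = (contig, j, sc)
    return best[0], best[1]


class TestPairing:
    def _aln(self, contig, start, end, rule, orient):
        return methalign.Alignment(
            read_id="r", contig=contig, start=start, end=end, strand_conv=rule,
            orient=orient, mode="end-to-end", clip5=0, clip3=0, nm=0, score=0,
            unique=True, read_len=end - start, seq=np.zeros(end - start, np.uint8), g0=0,
        )

    def test_proper_pair_insert(self):
        a1 = self._aln("chr1", 1000, 1080, "OT", "+")
        a2 = self._aln("chr1", 1220, 1300, "OT", "-")
        assert methalign.pair_reads(a1, a2) == 300
        assert a1.paired and a1.insert == 300

    def test_cross_contig_kept_single(self):
        a1 = self._aln("chr1", 1000, 1080, "OT", "+")
        a2 = self._aln("chr2", 1220, 1300, "OT", "-")
        assert methalign.pair_reads(a1, a2) is None
        assert not a1.paired

    def test_out_of_range_insert_kept_single(self):
        a1 = self._aln("chr1", 1000, 1080, "OT", "+")
        a2 = self._aln("chr1", 5920, 6000, "OT", "-")
        assert methalign.pair_reads(a1, a2) is None


class TestDeduplicate:
    def _unit(self, rid, contig, start, rule="OT", nm=0):
        a = methalign.Alignment(
            read_id=rid, contig=contig, start=start, end=start + 50, strand_conv=rule,
            orient="+", mode="end-to-end", clip5=0, clip3=0, nm=nm, score=50,
            unique=True, read_len=50, seq=np.zeros(50, np.uint8), g0=0,
        )
        return methalign.ReadUnit(rid, a, None)

    def test_pcr_copies_collapse_to_best(self):
        units = [self._unit("r2", "chr1", 100, nm=1), self._unit("r1", "chr1", 100, nm=0)]
        kept, ndup = methalign.deduplicate(methalign.sort_units(units))
        assert ndup == 1 and kept[0].read_id == "r1"

    def test_different_strand_not_collapsed(self):
        units = [self._unit("r1", "chr1", 100, "OT"), self._unit("r2", "chr1", 100, "OB")]
        kept, ndup = methalign.deduplicate(units)
        assert ndup == 0 and len(kept) == 2

    def test_unsorted_input_rejected(self):
        units = [self._unit("r1", "chr1", 200), self._unit("r2", "chr1", 100)]
        with pytest.raises(methalign.OrderingError):
            methalign.deduplicate(units)

    def test_simulated_duplicates_recover_distinct_fragments(
        self, small_genome, small_methylomes, small_index
    ):
        """With duplication_rate 0.3 and clean chemistry, the survivor count
        equals the number of distinct (contig, start, strand) molecules in
        the truth table."""
        methylomes, _ = small_methylomes
        design = simdata.design_barcodes(["c0"], seed=1)
        run = simdata.emit_run(
            [("c0", "type0", 300)], small_genome, methylomes, design,
            simdata.ChemistryModel(conversion_rate=1.0, overconversion_rate=0.0),
            read_length=100, insert_mean=300, insert_sd=40,
            duplication_rate=0.3, seed=33,
        )
        units = []
        for (rid, seq, _), (_, seq2, _) in zip(run.r1, run.r2):
            a1 = methalign.align_read(seq, small_index, read_id=rid)
            a2 = methalign.align_read(seq2, small_index, read_id=rid)
            methalign.pair_reads(a1, a2)
            if a1 is not None or a2 is not None:
                units.append(methalign.ReadUnit(rid, a1, a2))
        kept, ndup = methalign.deduplicate(methalign.sort_units(units))
        truth_distinct = run.truth.groupby(
            ["contig", "start", "conv_strand"]
        ).ngroups
        assert len(kept) == truth_distinct
        assert ndup == len(units) - truth_distinct


class TestExtraction:
    def _units_from_run(self, run, index):
        units = []
        for (rid, seq, _), (_, seq2, _) in zip(run.r1, run.r2):
            a1 = methalign.align_read(seq, index, read_id=rid)
            a2 = methalign.align_read(seq2, index, read_id=rid)
            # multi-mappers are excluded from methylation extraction
            if a1 is not None and not a1.unique:
                a1 = None
            if a2 is not None and not a2.unique:
                a2 = None
            methalign.pair_reads(a1, a2)
            if a1 is not None or a2 is not None:
                units.append(methalign.ReadUnit(rid, a1, a2))
        kept, _ = methalign.deduplicate(methalign.sort_units(units))
        return kept

    def test_fully_methylated_and_unmethylated_levels(self, small_genome, small_index):
        """pUC19 CpGs (methylation 1, overconversion 0) read back at level
        1.0; lambda (conversion 1) at level 0.0."""
        methylomes, _ = simdata.simulate_methylomes(small_genome, 1, 0, 500, seed=2)
        design = simdata.design_barcodes(["c0"], seed=1)
        run = simdata.emit_run(
            [("c0", "type0", 500)], small_genome, methylomes, design,
            simdata.ChemistryModel(conversion_rate=1.0, overconversion_rate=0.0),
            read_length=100, seed=12,
        )
        kept = self._units_from_run(run, small_index)
        calls = methalign.extract_methylation(kept, small_index)
        frame = calls.to_frame(small_index)
        puc_cg = frame[(frame.contig == "pUC19") & (frame.context == "CG")]
        assert len(puc_cg) > 0 and (puc_cg.level == 1.0).all()
        lam = frame[frame.contig == "lambda"]
        assert len(lam) > 0 and (lam.level == 0.0).all()

    def test_overlapping_mates_counted_once(self, small_genome, small_methylomes, small_index):
        """A short-insert pair whose mates overlap contributes coverage 1 at
        every site."""
        methylomes, _ = small_methylomes
        design = simdata.design_barcodes(["c0"], seed=1)
        run = simdata.emit_run(
            [("c0", "type0", 80)], small_genome, methylomes, design,
            simdata.ChemistryModel(conversion_rate=1.0, overconversion_rate=0.0),
            read_length=100, insert_mean=120, insert_sd=10, seed=14,
        )
        kept = self._units_from_run(run, small_index)
        overlapping = [
            u for u in kept
            if u.a1 is not None and u.a2 is not None
            and max(u.a1.start, u.a2.start) < min(u.a1.end, u.a2.end)
        ]
        assert overlapping
        for u in overlapping[:10]:
            calls = methalign.extract_methylation([u], small_index)
            assert calls.cov.max() == 1

    def test_lambda_level_binomial_oracle(self, small_genome, small_index):
        """Conversion 0.999 on lambda: the pooled retained-C fraction over n
        covered cytosines is Binomial(n, 0.001)."""
        methylomes, _ = simdata.simulate_methylomes(small_genome, 1, 0, 500, seed=2)
        design = simdata.design_barcodes(["c0"], seed=1)
        run = simdata.emit_run(
            [("c0", "type0", 2500)], small_genome, methylomes, design,
            simdata.ChemistryModel(conversion_rate=0.999, overconversion_rate=0.0),
            read_length=120, seed=15,
        )
        kept = self._units_from_run(run, small_index)
        calls = methalign.extract_methylation(kept, small_index)
        sel = small_index.contig_roles_sites(["lambda"])[calls.site_idx]
        cov = calls.cov[sel].sum()
        meth = calls.meth[sel].sum()
        assert cov > 50_000
        sd = np.sqrt(cov * 0.001 * 0.999)
        assert abs(meth - 0.001 * cov) < 3.5 * sd


class TestSiteTable:
    def test_strand_complementarity_of_cpg(self, small_index):
        """A plus-strand CG at position p implies a minus-strand CG call
        site at p+1."""
        plus_cg = small_index.site_gpos[
            (small_index.site_strand == 0) & (small_index.site_context == 0)
        ]
        minus_cg = set(
            small_index.site_gpos[
                (small_index.site_strand == 1) & (small_index.site_context == 0)
            ].tolist()
        )
        missing = [p for p in plus_cg[:-1] if p + 1 not in minus_cg]
        assert not missing

    def test_context_partition(self, small_genome, small_index):
        """CG + CHG + CHH counts equal the number of cytosines with a
        defined (non-edge, N-free) trinucleotide context."""
        total_sites = small_index.n_sites
        expected = 0
        for contig in small_genome.contigs:
            codes = small_genome.codes(contig)
            expected += int((codes[:-2] == 1).sum())  # plus-strand C, 2 bases room
            expected += int((codes[2:] == 2).sum())  # minus-strand C (ref G)
        assert total_sites == expected

    def test_cg_context_iff_cg_dinucleotide(self, small_index):
        cg_ctx = small_index.site_context == 0
        cg_dinuc = small_index.site_dinuc == 2
        assert (cg_ctx == cg_dinuc).all()


class TestDinucleotideCounts:
    def test_toy_enumeration(self):
        df = methalign.mappable_dinucleotide_counts({"toy": "CCGG"})
        plus = df[df.strand == "+"].set_index("dinucleotide")["count"]
        minus = df[df.strand == "-"].set_index("dinucleotide")["count"]
        assert plus["CC"] == 1 and plus["CG"] == 1 and plus["CA"] == 0
        assert minus["CC"] == 1 and minus["CG"] == 1

    def test_all_false_mask_zeroes(self):
        seq = "ACGTACGTCC" * 20
        df = methalign.mappable_dinucleotide_counts(
            {"toy": seq}, mask={"toy": np.zeros(len(seq), bool)}
        )
        assert (df["count"] == 0).all()

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        df = methalign.mappable_dinucleotide_counts({"g": seq})
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        for strand, s in (("+", seq), ("-", rc)):
            # brute force: count cytosine dinucleotides with a defined
            # trinucleotide context (2 downstream bases available)
            counts = {"CA": 0, "CC": 0, "CG": 0, "CT": 0}
            for i in range(len(s) - 2):
                if s[i] == "C":
                    counts["C" + s[i + 1]] += 1
            got = df[df.strand == strand].set_index("dinucleotide")["count"].to_dict()
            assert got == counts


class TestMergeCalls:
    def test_sitewise_sum(self):
        a = methalign.CellCalls(
            np.array([1, 5, 9]), np.array([1, 0, 2]), np.array([2, 1, 2])
        )
        b = methalign.CellCalls(np.array([5, 9]), np.array([1, 0]), np.array([1, 3]))
        m = methalign.merge_calls([a, b])
        assert m.site_idx.tolist() == [1, 5, 9]
        assert m.meth.tolist() == [1, 1, 2]
        assert m.cov.tolist() == [2, 2, 5]
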