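"""Window iteration, filters, pi/d_XY and the scan table."""

import numpy as np
import pandas as pd
import pytest

from fdscan import io as fio
from fdscan import windows as W
from fdscan.windows import ScanConfig, UnsortedInputError

GROUPS8 = ["P1", "P1", "P2", "P2", "P3", "P3", "O", "O"]


def matrix_source(scaffolds, n_hap=8, names=None):
    names = names or [f"h{i}" for i in range(n_hap)]
    return fio.MatrixSource(scaffolds, names)


def full_call_scaffold(name, length, rng, n_hap=8):
    positions = np.arange(length)
    matrix = rng.integers(0, 2, size=(n_hap, length)).astype(np.int8) * 3  # A/T
    return (name, length, positions, matrix)


def small_config(**kw):
    defaults = dict(
        group_map={f"h{i}": g for i, g in enumerate(GROUPS8)},
        window_size=5000,
        min_genotyped_sites=0,
    )
    defaults.update(kw)
    return ScanConfig(**defaults)


class TestIterateWindows:
    def test_scaffold_tiling_with_partial_tail(self, rng):
        src = matrix_source([full_call_scaffold("s1", 12000, rng)])
        wins = list(W.iterate_windows(src, small_config()))
        assert [(w.start, w.end, w.partial) for w in wins] == [
            (0, 5000, False),
            (5000, 10000, False),
            (10000, 12000, True),
        ]

    def test_windows_never_span_scaffolds(self, rng):
        src = matrix_source(
            [full_call_scaffold("s1", 5000, rng), full_call_scaffold("s2", 5000, rng)]
        )
        wins = list(W.iterate_windows(src, small_config()))
        assert [(w.scaffold, w.start, w.end) for w in wins] == [
            ("s1", 0, 5000),
            ("s2", 0, 5000),
        ]

    def test_empty_scaffold_yields_nothing(self):
        src = matrix_source([])
        assert list(W.iterate_windows(src, small_config())) == []

    def test_unsorted_positions_rejected(self, rng):
        name, L, pos, mat = full_call_scaffold("s1", 100, rng)
        pos = pos.copy()
        pos[50], pos[51] = pos[51], pos[50]
        src = matrix_source([(name, L, pos, mat)])
        with pytest.raises(UnsortedInputError, match="s1"):
            list(W.iterate_windows(src, small_config(window_size=100)))

    def test_revisited_scaffold_rejected(self, rng):
        a = full_call_scaffold("s1", 10, rng)
        b = full_call_scaffold("s2", 10, rng)
        src = matrix_source([a, b, ("s1", 10, np.arange(10), a[3])])
        with pytest.raises(UnsortedInputError, match="s1"):
            list(W.iterate_windows(src, small_config(window_size=100)))

    def test_overlapping_step(self, rng):
        src = matrix_source([full_call_scaffold("s1", 10000, rng)])
        wins = list(W.iterate_windows(src, small_config(step=2500)))
        assert [w.start for w in wins] == [0, 2500, 5000, 7500]


class TestWindowFilter:
    @pytest.mark.parametrize("n_good,kept", [(3000, True), (2999, False)])
    def test_min_sites_threshold_is_inclusive(self, rng, n_good, kept):
        # 8 haploid individuals; a site qualifies when >= 4 are called
        mat = np.zeros((8, 5000), dtype=np.int8)
        mat[0:5, n_good:] = -1  # only 3 of 8 called beyond n_good
        win = W.GenotypeWindow(
            "s1", 0, 5000, np.arange(5000), mat,
            [f"h{i}" for i in range(8)], np.arange(8),
        )
        cfg = small_config(min_genotyped_sites=3000)
        assert W.window_filter(win, cfg) is kept

    def test_zero_threshold_keeps_everything(self, rng):
        mat = np.full((8, 10), -1, dtype=np.int8)
        win = W.GenotypeWindow(
            "s1", 0, 5000, np.arange(10), mat, [f"h{i}" for i in range(8)], np.arange(8)
        )
        assert W.window_filter(win, small_config()) is True

    def test_half_of_odd_individual_count_rounds_up(self):
        # 5 individuals: "at least half" means >= 3
        mat = np.zeros((5, 4), dtype=np.int8)
        mat[3:, 0] = -1  # site 0: 3 called -> qualifies
        mat[2:, 1] = -1  # site 1: 2 called -> fails
        win = W.GenotypeWindow(
            "s1", 0, 4, np.arange(4), mat, [f"h{i}" for i in range(5)], np.arange(5)
        )
        assert win.sites_with_individual_calls(0.5) == 3  # sites 0, 2, 3


class TestPiAndDxy:
    def test_identical_haplotypes(self):
        h = np.zeros((2, 100), dtype=np.int8)
        assert W.nucleotide_diversity(h) == 0.0

    def test_single_difference(self):
        h = np.zeros((2, 100), dtype=np.int8)
        h[1, 0] = 3
        assert W.nucleotide_diversity(h) == pytest.approx(0.01, abs=1e-15)

    def test_pairwise_missing_exclusion_example(self):
        h = np.array([fio_encode("ACGT"), fio_encode("ACGA"), fio_encode("ACG?")])
        # pair diffs: (1/4, 0/3, 0/3) -> mean = 1/12
        assert W.nucleotide_diversity(h) == pytest.approx(1 / 12, abs=1e-12)

    def test_fewer_than_two_haplotypes_missing(self):
        assert W.nucleotide_diversity(np.zeros((1, 10), dtype=np.int8)) is None

    def test_within_individual_pairs_excluded_by_default(self):
        h = np.array([fio_encode("AAAA"), fio_encode("TTTT"), fio_encode("AAAA")])
        individuals = np.array([0, 0, 1])
        # eligible pairs: (0,2) identical and (1,2) all-diff -> mean 0.5
        assert W.nucleotide_diversity(h, individuals=individuals) == pytest.approx(0.5)
        # including within-individual pairs adds the (0,1) all-diff pair
        assert W.nucleotide_diversity(
            h, individuals=individuals, within_individuals=True
        ) == pytest.approx(2 / 3)

    def test_dxy_examples(self):
        assert W.dxy([fio_encode("AAAA")], [fio_encode("AAAT")]) == pytest.approx(0.25)
        assert W.dxy([fio_encode("ACGT")], [fio_encode("ACGT")]) == 0.0
        assert W.dxy([fio_encode("AC?T")], [fio_encode("ACGA")]) == pytest.approx(
            1 / 3, abs=1e-12
        )

    def test_no_jointly_called_sites_missing(self):
        assert W.dxy([fio_encode("??")], [fio_encode("AA")]) is None

    def test_invariant_to_haplotype_order(self, rng):
        h = rng.integers(-1, 4, size=(6, 50)).astype(np.int8)
        perm = rng.permutation(6)
        a = W.nucleotide_diversity(h)
        b = W.nucleotide_diversity(h[perm], individuals=perm)
        assert a == pytest.approx(b, rel=1e-12)
        x = rng.integers(0, 4, size=(4, 50)).astype(np.int8)
        y = rng.integers(0, 4, size=(3, 50)).astype(np.int8)
        assert W.dxy(x, y) == pytest.approx(W.dxy(x[rng.permutation(4)], y), rel=1e-12)

    def test_fast_and_general_paths_agree(self, rng):
        h = rng.integers(0, 4, size=(8, 200)).astype(np.int8)
        fast = W.nucleotide_diversity(h)
        general = W._mean_pairwise(
            ((h[i], h[j]) for i in range(8) for j in range(i + 1, 8)), 0
        )
        assert fast == pytest.approx(general, rel=1e-12)
        x, y = h[:4], h[4:]
        assert W.dxy(x, y) == pytest.approx(
            W._mean_pairwise(((a, b) for a in x for b in y), 0), rel=1e-12
        )


def fio_encode(s):
    from fdscan.core import encode_nucleotides

    return encode_nucleotides(np.array(list(s)))


class TestScan:
    def test_full_call_fixture_two_rows(self, rng):
        src = matrix_source([full_call_scaffold("s1", 10000, rng)])
        cfg = small_config(min_genotyped_sites=3000)
        table = W.scan(src, cfg)
        assert len(table) == 2
        assert list(table.columns) == W.TABLE_COLUMNS
        assert table["sites"].tolist() == [5000, 5000]
        assert table[["D", "fhom", "fd", "pi_P1", "dxy_P2P3"]].notna().all().all()

    def test_p2_matching_p1_gives_zero_d(self, rng):
        name, L, pos, mat = full_call_scaffold("s1", 5000, rng)
        mat[2:4] = mat[0:2]  # P2 haplotypes copy P1 -> p2 == p1 at every site
        table = W.scan(matrix_source([(name, L, pos, mat)]), small_config())
        assert table["D"].dropna().abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_fixed_abba_tract_maximal_statistics(self):
        # P2 and P3 fixed derived in a tract, everyone else ancestral
        mat = np.zeros((8, 1000), dtype=np.int8)
        mat[2:6, 100:200] = 3
        src = matrix_source([("s1", 1000, np.arange(1000), mat)])
        table = W.scan(src, small_config(window_size=1000))
        assert table.loc[0, "D"] == 1.0
        assert table.loc[0, "fd"] == 1.0

    def test_unassigned_group_raises_before_work(self, rng):
        cfg = small_config(group_map={"h0": "P1", "h1": "P2", "h2": "P3"})
        with pytest.raises(ValueError, match="no assigned samples"):
            W.scan(matrix_source([full_call_scaffold("s1", 100, rng)]), cfg)

    def test_scan_deterministic(self, rng):
        scaf = full_call_scaffold("s1", 6000, rng)
        cfg = small_config()
        t1 = W.scan(matrix_source([scaf]), cfg)
        t2 = W.scan(matrix_source([scaf]), cfg)
        pd.testing.assert_frame_equal(t1, t2)


class TestChromosomeSummary:
    def make_table(self, d_by_scaffold):
        rows = []
        for scaf, ds in d_by_scaffold.items():
            for i, d in enumerate(ds):
                rows.append(
                    {
                        "scaffold": scaf,
                        "start": i * 5000,
                        "end": (i + 1) * 5000,
                        "D": d,
                        "fd": abs(d) / 2,
                        "pi_P1": 0.01,
                        "pi_P2": 0.01,
                        "pi_P3": 0.01,
                    }
                )
        return pd.DataFrame(rows)

    def test_sample_variance(self):
        table = self.make_table({"s1": [0.0, 0.5]})
        summary, _ = W.summarize_chromosomes(table, {"s1": "chr1"})
        assert summary.loc[0, "var_D"] == pytest.approx(0.125)

    def test_identical_windows_zero_variance(self):
        table = self.make_table({"s1": [0.3, 0.3, 0.3]})
        summary, _ = W.summarize_chromosomes(table, {"s1": "chr1"})
        assert summary.loc[0, "var_D"] == 0.0

    def test_single_window_chromosome_missing_variance(self):
        table = self.make_table({"s1": [0.3]})
        summary, _ = W.summarize_chromosomes(table, {"s1": "chr1"})
        assert summary.loc[0, "var_D"] is None

    def test_degenerate_correlation_is_missing(self):
        table = self.make_table({"s1": [0.0, 0.5], "s2": [0.0, 0.5]})
        _, corr = W.summarize_chromosomes(table, {"s1": "chr1", "s2": "chr2"})
        assert corr["var_D_vs_mean_pi"]["r"] is None


class TestWindowTableOutput:
    def test_one_based_start_and_na(self, rng, tmp_path):
        table = pd.DataFrame(
            [{"scaffold": "s1", "start": 0, "end": 5000, "D": None, "fd": 0.5}]
        )
        out = tmp_path / "t.tsv"
        W.write_window_table(table, out, comments={"seed": 7})
        text = out.read_text()
        assert "# seed=7" in text
        assert "s1\t1\t5000\tNA\t0.5" in text


class TestVcfAndFasta:
    def write_vcf(self, path, records, samples):
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=s1,length=40>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        path.write_text(header + "".join(records))

    def test_vcf_scan_matches_direct_computation(self, tmp_path):
        samples = [f"i{k}" for k in range(4)]  # one diploid individual per group
        recs = []
        # 40-bp scaffold, all sites called; derived T at sites 10-14 in P2,P3
        for pos in range(40):
            if 10 <= pos < 15:
                gts = ["0|0", "1|1", "1|1", "0|0"]
                alt = "T"
            elif pos == 20:
                gts = ["0|1", "0|0", "0|0", "0|0"]
                alt = "T"
            else:
                gts = ["0|0", "0|0", "0|0", "0|0"]
                alt = "."
            recs.append(
                f"s1\t{pos + 1}\t.\tA\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
        vcf = tmp_path / "x.vcf"
        self.write_vcf(vcf, recs, samples)
        src = fio.VcfSource(vcf)
        group_of = {"i0": "P1", "i1": "P2", "i2": "P3", "i3": "O"}
        cfg = ScanConfig(
            group_map={f"{s}_{k}": group_of[s] for s in samples for k in (1, 2)},
            window_size=40,
            min_genotyped_sites=40,
        )
        table = W.scan(src, cfg)
        assert len(table) == 1
        assert table.loc[0, "D"] == 1.0  # only fixed-ABBA and BABA-free sites
        # dxy P2P3 = 0; dxy P1P2 counts 5 fixed + the het at site 20
        assert table.loc[0, "dxy_P2P3"] == 0.0
        assert table.loc[0, "dxy_P1P2"] == pytest.approx((5 + 0.5) / 40)

    def test_vcf_missing_genotypes_drop_qualifying_sites(self, tmp_path):
        samples = ["i0", "i1", "i2", "i3"]
        recs = [
            "s1\t1\t.\tA\tT\t.\tPASS\t.\tGT\t0|0\t1|1\t1|1\t0|0\n",
            "s1\t2\t.\tA\tT\t.\tPASS\t.\tGT\t./.\t./.\t./.\t0|0\n",
        ]
        self.write_vcf(tmp_path / "y.vcf", recs, samples)
        src = fio.VcfSource(tmp_path / "y.vcf")
        wins = list(
            W.iterate_windows(
                src,
                ScanConfig(group_map={"any": "P1"}, window_size=40, min_genotyped_sites=0),
            )
        )
        assert wins[0].sites_with_individual_calls(0.5) == 1

    def test_fasta_source_roundtrip(self, tmp_path, rng):
        from fdscan.core import MISSING

        names = [f"{g}_{i}" for g in ("P1", "P2", "P3", "O") for i in (1, 2)]
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in names]
        fa = tmp_path / "aln.fa"
        fa.write_text("".join(f">{n}\n{s}\n" for n, s in zip(names, seqs)))
        src = fio.FastaSource(fa)
        assert src.haplotype_names == names
        assert src.scaffold_lengths == {"aln": 30}
        cols = list(src)
        assert len(cols) == 30 and cols[0][0] == "aln"

    def test_population_map_reader(self, tmp_path):
        f = tmp_path / "pops.txt"
        f.write_text("# comment\na P1\nb P2\nc P3\nd O\n")
        assert fio.read_population_map(f) == {"a": "P1", "b": "P2", "c": "P3", "d": "O"}
        f.write_text("a P5\n")
        with pytest.raises(ValueError, match="unknown population"):
            fio.read_population_map(f)
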