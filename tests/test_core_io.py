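"""Round-trips, VCF decoding and allele-frequency estimation."""

import numpy as np
import pytest

from aimkit.core_io import (
    FormatError,
    GenotypeMatrix,
    Panel,
    PanelSnp,
    UndefinedFrequencyError,
    canonical_call,
    estimate_frequencies,
    read_frequency_table,
    read_snipper_grid,
    read_vcf,
    write_frequency_table,
    write_snipper_grid,
    write_structure_input,
)
from aimkit.synthetic_data import SyntheticConfig, build_reference_dataset

from conftest import make_panel, random_matrix

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""

# Hand-decoded five-record fixture: biallelic hom/het, missing, tri-allelic
# 1/2 call, half-call, and an off-panel allele that must flag the locus.
VCF_BODY = (
    "1\t100\trsA\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n"
    "1\t200\trsB\tC\tT\t.\t.\t.\tGT\t./.\t1/1\n"
    "1\t300\trsC\tC\tT,G\t.\t.\t.\tGT\t1/2\t0/0\n"
    "1\t400\trsD\tA\tC\t.\t.\t.\tGT\t./1\t0/0\n"
    "1\t500\trsE\tA\tT\t.\t.\t.\tGT\t0/1\t0/0\n"
)


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "calls.vcf"
    p.write_text(VCF_HEADER + VCF_BODY)
    return p


def test_vcf_decoding_matches_hand_decoded_records(vcf_path):
    panel = Panel(
        [
            PanelSnp("rsA", "1", 100, ("A", "G")),
            PanelSnp("rsB", "1", 200, ("C", "T")),
            PanelSnp("rsC", "1", 300, ("C", "G", "T")),
            PanelSnp("rsD", "1", 400, ("A", "C")),
            PanelSnp("rsE", "1", 500, ("A", "C")),  # VCF carries T: off-panel
            PanelSnp("rsF", "1", 600, ("A", "G")),  # absent from the VCF
        ]
    )
    with pytest.warns(UserWarning, match="rsE"):
        gm = read_vcf(vcf_path, panel)
    assert gm.sample_ids == ["S1", "S2"]
    s1 = {panel[j].snp_id: gm.calls[0, j] for j in range(len(panel))}
    s2 = {panel[j].snp_id: gm.calls[1, j] for j in range(len(panel))}
    assert s1["rsA"] == "AA" and s2["rsA"] == "AG"
    assert s1["rsB"] is None and s2["rsB"] == "TT"
    assert s1["rsC"] == "GT" and s2["rsC"] == "CC"  # 1/2 decodes to {T,G}
    assert s1["rsD"] is None  # half-call treated as missing
    assert s1["rsE"] is None and s2["rsE"] is None  # flagged locus
    assert s1["rsF"] is None and s2["rsF"] is None  # unmatched locus


def test_canonical_call_unordered_and_missing():
    assert canonical_call("GA") == "AG" == canonical_call(("G", "A"))
    assert canonical_call("NN") is None and canonical_call(None) is None


class TestSnipperGrid:
    def test_round_trip_preserves_calls_labels_flags(self, tmp_path, rng):
        gm = random_matrix(40, 12, rng)
        path = tmp_path / "grid.csv"
        write_snipper_grid(gm, path)
        back = read_snipper_grid(path)
        assert back.sample_ids == gm.sample_ids
        assert back.population_labels == gm.population_labels
        assert back.training_flags == gm.training_flags
        assert [s.snp_id for s in back.loci] == [s.snp_id for s in gm.loci]
        assert (back.calls == gm.calls).all()

    def test_round_trip_full_synthetic_reference(self, tmp_path):
        _, gm = build_reference_dataset(SyntheticConfig(seed=5))
        path = tmp_path / "ref.csv"
        write_snipper_grid(gm, path)
        back = read_snipper_grid(path)
        assert (back.calls == gm.calls).all()
        assert back.population_labels == gm.population_labels
        assert back.training_flags == gm.training_flags

    def test_header_counts_written_from_content(self, tmp_path, rng):
        gm = random_matrix(7, 3, rng, n_pops=2)
        path = tmp_path / "grid.csv"
        write_snipper_grid(gm, path)
        first = path.read_text().splitlines()[0].split(",")
        n_pops = len({p for p, f in zip(gm.population_labels, gm.training_flags) if f})
        assert [int(x) for x in first[:3]] == [7, 3, n_pops]

    def test_row_count_mismatch_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "5,1,1\nsample,rs1,population,flag\n"
            "a,AA,POP1,1\nb,AG,POP1,1\nc,GG,POP1,1\nd,AA,POP1,0\n"
        )
        with pytest.raises(FormatError, match="5 profiles"):
            read_snipper_grid(path)

    def test_empty_matrix_writes_zero_header(self, tmp_path):
        gm = GenotypeMatrix([], [], [], [], np.empty((0, 0), dtype=object))
        path = tmp_path / "empty.csv"
        write_snipper_grid(gm, path)
        assert path.read_text().splitlines()[0].split(",")[:3] == ["0", "0", "0"]

    def test_query_only_profile_has_zero_population_count(self, tmp_path):
        gm = GenotypeMatrix(
            ["q1"], [None], [0], make_panel(2), np.array([["AG", "AA"]], dtype=object)
        )
        path = tmp_path / "query.csv"
        write_snipper_grid(gm, path)
        assert path.read_text().splitlines()[0].split(",")[2] == "0"
        back = read_snipper_grid(path)
        assert back.population_labels == [None] and back.training_flags == [0]


class TestStructureExport:
    def _reparse(self, path):
        """Independent test reader for the two-row STRUCTURE format."""
        lines = open(path).read().splitlines()
        markers = lines[0].split()
        rows = [l.split() for l in lines[1:]]
        out = {}
        for first, second in zip(rows[::2], rows[1::2]):
            assert first[0] == second[0]
            out[first[0]] = (
                int(first[1]),
                int(first[2]),
                list(zip([int(x) for x in first[3:]], [int(x) for x in second[3:]])),
            )
        return markers, out

    def test_two_rows_recode_and_missing(self, tmp_path):
        loci = [PanelSnp("rs1", "1", 1, ("A", "G"))]
        gm = GenotypeMatrix(
            ["s1", "s2"], ["POP1", None], [1, 0], loci,
            np.array([["AG"], [None]], dtype=object),
        )
        path = tmp_path / "structure.txt"
        write_structure_input(gm, path)
        _, rows = self._reparse(path)
        assert rows["s1"][2] == [(1, 2)]  # A->1, G->2
        assert rows["s2"][2] == [(-9, -9)]
        assert rows["s1"][1] == 1 and rows["s2"][1] == 0  # POPFLAG column

    def test_full_matrix_round_trip_via_test_reader(self, tmp_path, rng):
        gm = random_matrix(25, 8, rng)
        path = tmp_path / "structure.txt"
        write_structure_input(gm, path)
        markers, rows = self._reparse(path)
        assert markers == [s.snp_id for s in gm.loci]
        import json

        legend = json.load(open(str(path) + ".legend.json"))
        for i, sid in enumerate(gm.sample_ids):
            for j, snp in enumerate(gm.loci):
                a, b = rows[sid][2][j]
                call = gm.calls[i, j]
                if call is None:
                    assert (a, b) == (-9, -9)
                else:
                    code = legend["alleles"][snp.snp_id]
                    assert sorted((a, b)) == sorted((code[call[0]], code[call[1]]))


class TestEstimateFrequencies:
    def _matrix(self, calls, pop="POP1"):
        loci = make_panel(1)
        n = len(calls)
        return GenotypeMatrix(
            [f"s{i}" for i in range(n)], [pop] * n, [1] * n, loci,
            np.array([[c] for c in calls], dtype=object),
        )

    def test_plain_mle(self):
        ft = estimate_frequencies(self._matrix(["AA", "AG"]), smoothing=0)
        assert ft.freq_of(0, "POP1", "A") == pytest.approx(0.75)

    def test_pseudocount_for_unobserved_allele(self):
        ft = estimate_frequencies(self._matrix(["AA"] * 50), smoothing=1)
        assert ft.freq_of(0, "POP1", "G") == pytest.approx(1 / 102)

    def test_zero_observations_unsmoothed_raises(self):
        gm = self._matrix([None, None])
        with pytest.raises(UndefinedFrequencyError, match="POP1"):
            estimate_frequencies(gm, smoothing=0)
        ft = estimate_frequencies(gm, smoothing=1)  # smoothed: uniform
        assert ft.freq_of(0, "POP1", "A") == pytest.approx(0.5)

    def test_smoothed_and_mle_converge_at_large_n(self, rng):
        calls = []
        for _ in range(500):
            a = "A" if rng.random() < 0.5 else "G"
            b = "A" if rng.random() < 0.5 else "G"
            calls.append("".join(sorted(a + b)))
        gm = self._matrix(calls)
        f0 = estimate_frequencies(gm, smoothing=0).freq_of(0, "POP1", "A")
        f1 = estimate_frequencies(gm, smoothing=1).freq_of(0, "POP1", "A")
        assert abs(f0 - f1) < 0.01

    def test_smoothing_keeps_frequencies_off_boundary(self, rng):
        gm = random_matrix(30, 10, rng, missing_rate=0.3)
        ft = estimate_frequencies(gm, smoothing=1)
        for f in ft.freqs:
            assert (f > 0).all() and (f < 1).all()
        ft.validate()


def test_frequency_table_tsv_round_trip(tmp_path, rng):
    gm = random_matrix(30, 6, rng)
    ft = estimate_frequencies(gm, smoothing=1)
    path = tmp_path / "freqs.tsv"
    write_frequency_table(ft, path)
    back = read_frequency_table(path)
    assert back.populations == ft.populations
    for a, b in zip(back.freqs, ft.freqs):
        np.testing.assert_allclose(a, b, atol=1e-12)
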