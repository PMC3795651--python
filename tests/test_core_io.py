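import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatpop import (GenotypeMatrix, LocusSpec, allele_freqs, read_genepop,
                     write_genepop)
from msatpop.core_io import (GenepopDialectError, GenepopEncodingError,
                             GenepopParseError)

from conftest import make_gm


class TestLocusSpec:
    def test_defaults_define_11_state_dinucleotide_lattice(self):
        l = LocusSpec("L1")
        assert l.n_states == 11
        assert l.size_to_repeat(24) == 2
        assert l.repeat_to_size(10) == 40

    @pytest.mark.parametrize("kw", [
        dict(motif_bp=0),
        dict(min_len=40, max_len=40),
        dict(min_len=20, max_len=41),          # span not multiple of motif
        dict(mu=1.5),
        dict(p_gsm=1.0),
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            LocusSpec("bad", **dict(dict(motif_bp=2, min_len=20, max_len=40),
                                    **kw))


class TestGenotypeMatrix:
    def test_requires_individuals_and_loci(self):
        with pytest.raises(ValueError):
            GenotypeMatrix([], [LocusSpec("L1")],
                           np.zeros((0, 1, 2), dtype=np.int32))

    def test_allele_off_lattice_rejected(self):
        with pytest.raises(ValueError, match="lattice"):
            make_gm([(21, 22)], locus=LocusSpec("L1"))

    def test_allele_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_gm([(18, 22)], locus=LocusSpec("L1"))


class TestGenepopRoundTrip:
    def test_small_file_round_trips(self, tmp_path):
        gm = make_gm([[(120, 122), (95, 95)], [(122, 122), (95, 97)]],
                     locus=LocusSpec("x", motif_bp=1, min_len=90,
                                     max_len=130, mu=0.0, p_gsm=0.0))
        p = tmp_path / "two.gen"
        write_genepop(gm, p)
        back = read_genepop(p, loci=gm.loci)
        assert back.equals(gm)

    def test_missing_calls_become_zero_codes(self, tmp_path):
        gm = make_gm([[(0, 0)], [(120, 122)]],
                     locus=LocusSpec("x", motif_bp=1, min_len=100,
                                     max_len=130, mu=0.0, p_gsm=0.0))
        p = tmp_path / "m.gen"
        write_genepop(gm, p)
        assert "000000" in p.read_text()
        assert read_genepop(p).calls[0, 0].tolist() == [0, 0]

    def test_simulated_matrix_round_trips(self, tmp_path, ti_fixture):
        p = tmp_path / "ti.gen"
        write_genepop(ti_fixture, p)
        back = read_genepop(p, loci=ti_fixture.loci)
        assert back.equals(ti_fixture)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_matrices_round_trip(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(2, 40)), int(rng.integers(1, 6))
        locus = LocusSpec("r", motif_bp=2, min_len=20, max_len=40,
                          mu=0.0, p_gsm=0.0)
        sizes = 20 + 2 * rng.integers(0, 11, size=(n, L, 2))
        sizes[rng.random((n, L)) < 0.1] = 0    # sprinkle missing pairs
        gm = GenotypeMatrix([f"i{k}" for k in range(n)],
                            [LocusSpec(f"r{j}", motif_bp=2, min_len=20,
                                       max_len=40, mu=0.0, p_gsm=0.0)
                             for j in range(L)],
                            sizes)
        p = tmp_path / "r.gen"
        write_genepop(gm, p)
        assert read_genepop(p, loci=gm.loci).equals(gm)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_round_trip_is_identity(self, tmp_path_factory, data):
        n = data.draw(st.integers(1, 25))
        L = data.draw(st.integers(1, 5))
        repeats = data.draw(st.lists(
            st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10)),
                     min_size=L, max_size=L),
            min_size=n, max_size=n))
        calls = 20 + 2 * np.array(repeats, dtype=np.int32)
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(n)],
            [LocusSpec(f"h{j}") for j in range(L)], calls)
        p = tmp_path_factory.mktemp("hyp") / "x.gen"
        write_genepop(gm, p)
        assert read_genepop(p, loci=gm.loci).equals(gm)

    def test_two_digit_coding_round_trips(self, tmp_path):
        gm = make_gm([(20, 22), (40, 40)],
                     locus=LocusSpec("s", motif_bp=2, min_len=20, max_len=40,
                                     mu=0.0, p_gsm=0.0))
        p = tmp_path / "w2.gen"
        write_genepop(gm, p, width=2)
        assert "2022" in p.read_text().replace(" ", "")
        assert read_genepop(p, loci=gm.loci).equals(gm)

    def test_allele_too_large_for_coding(self, tmp_path):
        gm = make_gm([(1000, 1000)],
                     locus=LocusSpec("x", motif_bp=1, min_len=900,
                                     max_len=1100, mu=0.0, p_gsm=0.0))
        with pytest.raises(GenepopEncodingError):
            write_genepop(gm, tmp_path / "big.gen")


class TestGenepopDialect:
    def test_inconsistent_coding_width_rejected(self, tmp_path):
        p = tmp_path / "bad.gen"
        p.write_text("t\nL1\nL2\nPOP\nind1 , 0910 090110\n")
        with pytest.raises(GenepopDialectError, match="width"):
            read_genepop(p)

    def test_wrong_genotype_count_names_line(self, tmp_path):
        p = tmp_path / "bad.gen"
        p.write_text("t\nL1\nL2\nPOP\nind1 , 020020\n")
        with pytest.raises(GenepopParseError, match="line 5"):
            read_genepop(p)

    def test_multiple_pop_blocks_retain_labels(self, tmp_path):
        p = tmp_path / "two_pops.gen"
        p.write_text("t\nL1\nPOP\na , 020022\nPOP\nb , 022022\n")
        gm = read_genepop(p)
        assert gm.populations == ["pop1", "pop2"]
        assert gm.individuals == ["a", "b"]


class TestAlleleFreqs:
    def test_all_homozygous_single_allele(self):
        gm = make_gm([(120, 120), (120, 120)],
                     locus=LocusSpec("x", motif_bp=1, min_len=100,
                                     max_len=130, mu=0.0, p_gsm=0.0))
        t = allele_freqs(gm)
        assert t.counts[0] == {120: 4}
        assert t.freqs(0) == {120: 1.0}

    def test_direct_counts(self):
        gm = make_gm([(120, 122), (122, 122)],
                     locus=LocusSpec("x", motif_bp=1, min_len=100,
                                     max_len=130, mu=0.0, p_gsm=0.0))
        t = allele_freqs(gm)
        assert t.counts[0] == {120: 1, 122: 3}
        assert t.freqs(0) == {120: 0.25, 122: 0.75}

    def test_all_missing_locus_flagged(self):
        gm = make_gm([[(0, 0), (120, 120)], [(0, 0), (120, 122)]],
                     locus=LocusSpec("x", motif_bp=1, min_len=100,
                                     max_len=130, mu=0.0, p_gsm=0.0))
        t = allele_freqs(gm)
        assert t.all_missing[0] and not t.all_missing[1]
        assert t.freqs(0) == {}

    def test_gene_copy_conservation(self, ti_fixture):
        t = allele_freqs(ti_fixture)
        for j in range(ti_fixture.n_loci):
            pairs = ti_fixture.calls[:, j, :]
            typed = int(np.sum(np.all(pairs != 0, axis=1)))
            assert sum(t.counts[j].values()) == t.n_copies[j]
            assert t.n_copies[j] == 2 * typed

    def test_fixture_shape(self, ti_fixture):
        assert ti_fixture.calls.shape == (63, 12, 2)
        assert np.all(ti_fixture.calls > 0)
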