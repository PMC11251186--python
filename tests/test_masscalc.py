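"""Mass arithmetic: glycan/chain/complex masses and stoichiometry assignment."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass

from c4bpkit.masscalc import (
    MECHANISTIC_CHAIN_MASSES_KDA,
    ChainSpec,
    GlycanComposition,
    assign_stoichiometry,
    chain_mass,
    complex_mass,
    glycan_mass,
)

compositions = st.builds(
    GlycanComposition,
    st.integers(0, 8),
    st.integers(0, 10),
    st.integers(0, 3),
    st.integers(0, 4),
)


def _oracle_glycan_mass(comp, average=False):
    """Independent oracle: sum elemental-formula masses residue by residue."""
    formulas = {"HexNAc": "C8H13NO5", "Hex": "C6H10O5", "dHex": "C6H10O4", "NeuAc": "C11H17NO8"}
    return sum(
        n * pmass.calculate_mass(formula=formulas[k], average=average)
        for k, n in comp.as_dict().items()
    )


class TestGlycanMass:
    def test_empty_composition_is_zero(self):
        assert glycan_mass(GlycanComposition()) == 0.0

    def test_biantennary_disialyl_monoisotopic(self):
        comp = GlycanComposition.parse("HexNAc4Hex5NeuAc2")
        assert glycan_mass(comp, "monoisotopic") == pytest.approx(2204.772, abs=5e-3)
        assert glycan_mass(comp, "monoisotopic") == pytest.approx(
            _oracle_glycan_mass(comp), abs=1e-9
        )

    @given(compositions, compositions)
    @settings(max_examples=50, deadline=None)
    def test_additivity(self, c1, c2):
        for mode in ("monoisotopic", "average"):
            assert glycan_mass(c1, mode) + glycan_mass(c2, mode) == pytest.approx(
                glycan_mass(c1 + c2, mode), rel=1e-12
            )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            GlycanComposition(n_Hex=-1)


class TestCompositionParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("HexNAc4Hex5NeuAc2", GlycanComposition(4, 5, 0, 2)),
            ("N4H5S2", GlycanComposition(4, 5, 0, 2)),
            ("N4H5F1S1", GlycanComposition(4, 5, 1, 1)),
            ("HexNAc5Hex6dHex1NeuAc3", GlycanComposition(5, 6, 1, 3)),
            ("", GlycanComposition()),
        ],
    )
    def test_long_and_short_notation(self, text, expected):
        assert GlycanComposition.parse(text) == expected

    def test_key_round_trip(self):
        c = GlycanComposition(4, 5, 1, 2)
        assert GlycanComposition.parse(c.key) == c

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            GlycanComposition.parse("Xyz3")


class TestChainMass:
    def test_fixed_mass_passthrough(self):
        assert chain_mass(ChainSpec("C4BPa", fixed_mass_kda=72.9)) == 72.9

    def test_single_glycine_average(self):
        # residue 57.052 + one water 18.015 Da
        assert chain_mass(ChainSpec("x", sequence="G")) == pytest.approx(0.07505, abs=1e-4)

    def test_fixed_mass_plus_glycan(self):
        comp = GlycanComposition(4, 5, 0, 2)
        spec = ChainSpec("x", fixed_mass_kda=70.7, glycoforms={1: comp})
        assert chain_mass(spec) == pytest.approx(70.7 + glycan_mass(comp) / 1000.0, rel=1e-12)
        assert chain_mass(spec) == pytest.approx(72.905, abs=2e-3)

    def test_exactly_one_of_sequence_or_mass(self):
        with pytest.raises(ValueError):
            ChainSpec("x")
        with pytest.raises(ValueError):
            ChainSpec("x", sequence="GG", fixed_mass_kda=1.0)

    def test_glycosite_outside_sequence(self):
        with pytest.raises(ValueError):
            ChainSpec("x", sequence="GG", glycoforms={5: GlycanComposition(1)})


class TestComplexMass:
    def test_printed_peak_masses(self):
        assert complex_mass((7, 1, 1)).mass_kda == pytest.approx(630.8)
        assert complex_mass((6, 1, 0)).mass_kda == pytest.approx(478.1)
        assert complex_mass((7, 1, 0)).mass_kda == pytest.approx(551.0)
        assert complex_mass((6, 1, 1)).mass_kda == pytest.approx(557.9)

    def test_single_chain_identity(self):
        assert complex_mass((1, 0, 0)).mass_kda == pytest.approx(72.9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            complex_mass((0, 0, 0))

    @given(st.integers(0, 8), st.integers(0, 2), st.integers(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_alpha(self, na, nb, np_):
        if na + 1 == 0 and nb == 0 and np_ == 0:
            return
        base = MECHANISTIC_CHAIN_MASSES_KDA
        if (na, nb, np_) == (0, 0, 0):
            na = 1
        m1 = complex_mass((na, nb, np_), base).mass_kda
        m2 = complex_mass((na + 1, nb, np_), base).mass_kda
        assert m2 - m1 == pytest.approx(base["C4BPa"], rel=1e-12)


def test_fasta_chain_round_trip(tmp_path):
    from c4bpkit.masscalc import read_fasta_chains

    fasta = tmp_path / "chains.fasta"
    fasta.write_text(">C4BPb\nGGAG\n>ProS\nWKR\n")
    chains = read_fasta_chains(fasta)
    assert set(chains) == {"C4BPb", "ProS"}
    assert chains["C4BPb"].sequence == "GGAG"
    assert chain_mass(chains["C4BPb"]) > 0


def _brute_force(observed, sd, chain_masses, bounds, k_sigma):
    out = []
    for na, nb, np_ in itertools.product(*(range(b + 1) for b in bounds)):
        if na == nb == np_ == 0:
            continue
        m = (
            na * chain_masses["C4BPa"]
            + nb * chain_masses["C4BPb"]
            + np_ * chain_masses["ProS"]
        )
        if abs(m - observed) <= k_sigma * sd:
            out.append(((na, nb, np_), m - observed))
    return sorted(out, key=lambda t: abs(t[1]))


class TestAssignStoichiometry:
    def test_middle_peak_ambiguity(self):
        """The 553 kDa native population admits both α7β1 and α6β1+ProS."""
        a = assign_stoichiometry(553.0, 20.0)
        assert a.ambiguous
        top2 = [(sp.n_alpha, sp.n_beta, sp.n_pros) for sp, _ in a.candidates[:2]]
        assert top2 == [(7, 1, 0), (6, 1, 1)]
        assert a.candidates[0][1] == pytest.approx(-2.0, abs=1e-9)
        assert a.candidates[1][1] == pytest.approx(4.9, abs=1e-9)

    def test_free_pros_best_assignment(self):
        a = assign_stoichiometry(79.8, 6.0)
        assert a.best is not None
        assert (a.best.n_alpha, a.best.n_beta, a.best.n_pros) == (0, 0, 1)
        assert a.candidates[0][1] == pytest.approx(0.0, abs=1e-9)

    def test_below_smallest_species_empty(self):
        a = assign_stoichiometry(10.0, 1.0)
        assert a.candidates == [] and not a.ambiguous

    @pytest.mark.parametrize(
        "observed,sd,expected",
        [
            (633.0, 22.0, (7, 1, 1)),
            (553.0, 20.0, (7, 1, 0)),
            (481.0, 20.0, (6, 1, 0)),
            (551.0, 22.0, (7, 1, 0)),
            (478.0, 23.0, (6, 1, 0)),
        ],
    )
    def test_printed_peaks_get_reported_assignment(self, observed, sd, expected):
        a = assign_stoichiometry(observed, sd)
        assert (a.best.n_alpha, a.best.n_beta, a.best.n_pros) == expected

    @given(
        st.floats(50, 800),
        st.floats(1, 40),
        st.floats(30, 120),
        st.floats(20, 80),
        st.floats(40, 120),
        st.integers(1, 9),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, observed, sd, ma, mb, mp_, max_a):
        masses = {"C4BPa": ma, "C4BPb": mb, "ProS": mp_}
        bounds = (max_a, 1, 1)
        ours = assign_stoichiometry(observed, sd, masses, bounds=bounds)
        oracle = _brute_force(observed, sd, masses, bounds, 2.0)
        got = sorted(
            ((sp.n_alpha, sp.n_beta, sp.n_pros) for sp, _ in ours.candidates)
        )
        assert got == sorted(s for s, _ in oracle)
        if ours.candidates:
            assert abs(ours.candidates[0][1]) == pytest.approx(abs(oracle[0][1]), rel=1e-12)
        assert ours.ambiguous == (len(oracle) >= 2)
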