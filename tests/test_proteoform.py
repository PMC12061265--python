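"""Mass calculus, naming grammar and ID-table round trips.

The mass oracle here is coded independently of the implementation: residue
elemental formulas and element masses are literal values, and the summation
is its own arithmetic, so agreement is a genuine cross-check rather than a
tautology.
"""
import math
import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

from htpi.proteoform import (
    EN_DASH,
    MOD_REGISTRY,
    ModificationSpec,
    ProteoformError,
    ProteoformParseError,
    ProteoformRecord,
    ResidueRangeError,
    SequenceError,
    UnknownGeneError,
    UnknownModificationError,
    compute_masses,
    format_proteoform_name,
    mono_to_avg_estimate,
    parse_proteoform_name,
    read_id_table,
    write_id_table,
)

UBIQUITIN = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

# ---------------------------------------------------------------------------
# independent oracle: residue formulas + literal element masses, own summation

_EL_MONO = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
            "O": 15.9949146221, "S": 31.97207069}
_EL_AVG = {"C": 12.010736, "H": 1.007941, "N": 14.006703,
           "O": 15.999405, "S": 32.064787}
_FORMULAS = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}


def oracle_masses(sequence, mod_deltas=(0.0, 0.0)):
    """Brute-force residue-formula summation, independent of the package."""
    mono = 2 * _EL_MONO["H"] + _EL_MONO["O"]
    avg = 2 * _EL_AVG["H"] + _EL_AVG["O"]
    for aa in sequence:
        for sym, n in re.findall(r"([A-Z])(\d*)", _FORMULAS[aa]):
            k = int(n) if n else 1
            mono += _EL_MONO[sym] * k
            avg += _EL_AVG[sym] * k
    return mono + mod_deltas[0], avg + mod_deltas[1]


AA = "".join(_FORMULAS)
seqs = st.text(alphabet=AA, min_size=1, max_size=80)


# ---------------------------------------------------------------------------
class TestComputeMasses:
    def test_glycine(self):
        mono, avg = compute_masses("G")
        assert mono == pytest.approx(75.032, abs=0.001)
        assert avg == pytest.approx(75.067, abs=0.001)

    def test_ubiquitin_matches_oracle(self):
        mono, avg = compute_masses(UBIQUITIN)
        o_mono, o_avg = oracle_masses(UBIQUITIN)
        assert avg == pytest.approx(o_avg, abs=0.1)
        assert mono == pytest.approx(o_mono, abs=0.01)

    def test_modification_additivity_is_exact(self):
        ac = ModificationSpec("Ac", *MOD_REGISTRY["Ac"])
        base = compute_masses(UBIQUITIN)
        modded = compute_masses(UBIQUITIN, [ac])
        assert modded[0] - base[0] == pytest.approx(MOD_REGISTRY["Ac"][0], abs=1e-9)
        assert modded[1] - base[1] == pytest.approx(MOD_REGISTRY["Ac"][1], abs=1e-9)

    def test_mod_count_scales_delta(self):
        me2 = ModificationSpec("Me", *MOD_REGISTRY["Me"], count=2)
        base = compute_masses("ACDEF")
        assert compute_masses("ACDEF", [me2])[1] - base[1] == pytest.approx(
            2 * MOD_REGISTRY["Me"][1], abs=1e-9
        )

    def test_noncanonical_residue_names_position(self):
        with pytest.raises(SequenceError, match=r"'B' at position 3"):
            compute_masses("AABAA")

    @given(seqs)
    def test_matches_independent_oracle(self, seq):
        mono, avg = compute_masses(seq)
        o_mono, o_avg = oracle_masses(seq)
        assert abs(mono - o_mono) < 0.01
        assert abs(avg - o_avg) < 0.01
        assert avg > mono > 0

    @given(seqs, st.sampled_from(AA))
    def test_appending_residue_increases_mass(self, seq, aa):
        m0 = compute_masses(seq)
        m1 = compute_masses(seq + aa)
        assert m1[0] > m0[0] and m1[1] > m0[1]

    def test_relative_mono_avg_gap_in_averagine_band(self):
        rng = np.random.default_rng(11)
        freqs = np.array([_FORMULAS[a].count("C") for a in AA], float)
        for _ in range(30):
            n = rng.integers(20, 201)
            seq = "".join(rng.choice(list(AA), size=n))
            mono, avg = compute_masses(seq)
            rel = (avg - mono) / mono
            assert 4e-4 <= rel <= 8e-4


class TestMonoToAvg:
    def test_senko_ratio_at_10kda(self):
        assert mono_to_avg_estimate(10000.0) == pytest.approx(10006.4, abs=0.1)

    @pytest.mark.parametrize("bad", [0.0, 999.9, 25000.1, -5.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ProteoformError):
            mono_to_avg_estimate(bad)

    def test_ubiquitin_estimate_close_to_sequence_exact(self):
        mono, avg = compute_masses(UBIQUITIN)
        assert mono_to_avg_estimate(mono) == pytest.approx(avg, abs=0.5)


# ---------------------------------------------------------------------------
LOOKUP = {"Ubb": UBIQUITIN, "X": "G", "Pcp4": "M" + "ACDEFGHIKLMNPQRSTVWY" * 4}


class TestNameGrammar:
    def test_plain_truncation(self):
        rec = parse_proteoform_name("Ubb(1–76)", LOOKUP)
        assert (rec.start, rec.end, rec.mods) == (1, 76, ())
        assert rec.sequence == UBIQUITIN

    def test_hyphen_accepted_endash_emitted(self):
        rec = parse_proteoform_name("Ubb(1-74)", LOOKUP)
        assert rec.display_name == f"Ubb(1{EN_DASH}74)"

    def test_mods_collected_as_multiset(self):
        rec = parse_proteoform_name("Pcp4(2–62)@Ac@Phospho", LOOKUP)
        assert {(m.code, m.count) for m in rec.mods} == {("Ac", 1), ("Phospho", 1)}

    def test_repeated_mod_becomes_count(self):
        rec = parse_proteoform_name("Pcp4(2–62)@Me@Me", LOOKUP)
        assert {(m.code, m.count) for m in rec.mods} == {("Me", 2)}
        assert rec.display_name == f"Pcp4(2{EN_DASH}62)@Me@Me"

    def test_single_residue_glycine_masses(self):
        rec = parse_proteoform_name("X(1–1)", LOOKUP)
        o_mono, o_avg = oracle_masses("G")
        assert rec.avg_mass == pytest.approx(o_avg, abs=0.01)

    @pytest.mark.parametrize(
        "name,exc",
        [
            ("Ubb[1-76]", ProteoformParseError),
            ("Ubb(76–1)", ResidueRangeError),
            ("Ubb(1–99)", ResidueRangeError),
            ("Nope(1–5)", UnknownGeneError),
            ("Ubb(1–76)@Wild", UnknownModificationError),
        ],
    )
    def test_errors(self, name, exc):
        with pytest.raises(exc):
            parse_proteoform_name(name, LOOKUP)

    def test_unknown_mod_error_lists_registry(self):
        with pytest.raises(UnknownModificationError, match="Phospho"):
            parse_proteoform_name("Ubb(1–76)@Wild", LOOKUP)

    @given(
        st.sampled_from(sorted(LOOKUP)),
        st.data(),
        st.lists(st.sampled_from(sorted(MOD_REGISTRY)), max_size=3),
    )
    def test_round_trip(self, gene, data, mods):
        n = len(LOOKUP[gene])
        start = data.draw(st.integers(1, n))
        end = data.draw(st.integers(start, n))
        name = f"{gene}({start}{EN_DASH}{end})" + "".join(f"@{m}" for m in sorted(mods))
        rec = parse_proteoform_name(name, LOOKUP)
        assert format_proteoform_name(rec) == name


# ---------------------------------------------------------------------------
class TestIdTables:
    def test_round_trip(self, tmp_path):
        recs = [
            parse_proteoform_name("Ubb(1–76)", LOOKUP, source_region="SUB"),
            parse_proteoform_name("Pcp4(2–62)@Ac@Phospho", LOOKUP, source_region="CTX"),
            parse_proteoform_name("Pcp4(2–62)@Me@Me", LOOKUP, source_region="CTX"),
        ]
        p = tmp_path / "ids.tsv"
        write_id_table(recs, p)
        back = read_id_table(p)
        assert [r.display_name for r in back] == [r.display_name for r in recs]
        assert all(
            a.avg_mass == pytest.approx(b.avg_mass, abs=1e-6)
            for a, b in zip(back, recs)
        )
        assert back[0].source_region == "SUB"

    def test_missing_mono_mass_computed_on_load(self, tmp_path):
        p = tmp_path / "ids.tsv"
        header = "display_name\tgene\tfull_sequence\tstart\tend\tmods\tmono_mass\tsource_region"
        line = f"Ubb(1{EN_DASH}76)\tUbb\t{UBIQUITIN}\t1\t76\t\t\tSUB"
        p.write_text(header + "\n" + line + "\n", encoding="utf-8")
        (rec,) = read_id_table(p)
        mono, avg = compute_masses(UBIQUITIN)
        assert rec.mono_mass == pytest.approx(mono, abs=0.01)
        assert rec.avg_mass == pytest.approx(avg, abs=0.01)

    def test_mass_only_record_uses_averagine(self, tmp_path):
        p = tmp_path / "ids.tsv"
        header = "display_name\tgene\tfull_sequence\tstart\tend\tmods\tmono_mass\tsource_region"
        line = "Unk1(1–80)\tUnk1\t\t1\t80\t\t9000.0\tCTX"
        p.write_text(header + "\n" + line + "\n", encoding="utf-8")
        (rec,) = read_id_table(p)
        assert not rec.sequence_exact
        assert rec.avg_mass == pytest.approx(mono_to_avg_estimate(9000.0), abs=1e-9)
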