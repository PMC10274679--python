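"""Modification universe, offset adjustment, and search-space combinatorics."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from fpopseek.mod_model import (
    CARBAMIDOMETHYL,
    ModelError,
    Modification,
    ModificationSpace,
    OXIDATION_MASS,
    PHOSPHO_MASS,
    ZERO_OFFSET,
    adjust_offsets_for_fixed_mods,
    count_configurations,
    enumerate_peptidoforms,
    load_fpop_table,
    peptidoform_mass,
)

# The printed FPOP offset table (mass at 4 decimals, residue string).
PRINTED_TABLE = {
    "Oxidation": (15.9949, "MFHILVWYADEKNPQR"),
    "Dioxidation": (31.9898, "CFMWY"),
    "Trioxidation": (47.9847, "CFWY"),
    "Carbonylation": (13.9793, "EIKLPQRV"),
    "Arg deguanidation": (-43.0534, "R"),
    "H to D": (-22.0320, "H"),
    "H to N": (-23.0160, "H"),
    "H -10": (-10.0320, "H"),
    "H + 5": (4.9735, "H"),
    "Decarboxylation": (-30.0106, "DE"),
    "CO loss": (-27.9949, "DE"),
    "CO2 loss": (-43.9898, "DE"),
    "C dioxidation assuming fixed carbamidomethylation": (-25.0316, "C"),
    "C trioxidation assuming fixed carbamidomethylation": (-9.0367, "C"),
}


class TestFpopTable:
    def test_has_14_offset_rows(self):
        assert len(load_fpop_table()) == 14

    def test_masses_and_residues_round_trip_to_printed_values(self):
        table = {m.name: m for m in load_fpop_table()}
        assert set(table) == set(PRINTED_TABLE)
        for name, (mass4, residues) in PRINTED_TABLE.items():
            m = table[name]
            assert round(m.mass_delta, 4) == pytest.approx(mass4, abs=0)
            assert m.residues == frozenset(residues)
            assert m.mod_class == "offset"


class TestAdjustOffsets:
    @pytest.mark.parametrize(
        "n_ox, expected",
        [(2, -25.0316), (3, -9.0367)],
        ids=["cys-dioxidation", "cys-trioxidation"],
    )
    def test_cys_oxidation_relative_to_carbamidomethyl(self, n_ox, expected):
        """Oxidized Cys displaces the fixed alkyl adduct, so the observable
        delta is n*15.994915 - 57.021464, matching the printed values."""
        off = Modification(
            f"C {n_ox}x-ox", n_ox * 15.994915, frozenset("C"), mod_class="offset"
        )
        (adjusted,) = adjust_offsets_for_fixed_mods([off], [CARBAMIDOMETHYL])
        assert round(adjusted.mass_delta, 4) == expected

    def test_empty_fixed_list_is_identity(self):
        offs = load_fpop_table()
        assert adjust_offsets_for_fixed_mods(offs, []) == offs

    def test_partially_fixed_residue_sets_unchanged(self):
        # dioxidation targets CFMWY; only C carries the fixed mod, so the
        # multi-residue offset keeps its chemical delta
        off = Modification("Dioxidation", 31.98983, frozenset("CFMWY"), mod_class="offset")
        (adjusted,) = adjust_offsets_for_fixed_mods([off], [CARBAMIDOMETHYL])
        assert adjusted.mass_delta == off.mass_delta

    def test_collision_between_adjusted_offsets_is_flagged(self):
        a = Modification("a", 57.0216, frozenset("C"), mod_class="offset")
        b = Modification("b", 114.043, frozenset("C"), mod_class="offset")
        # after subtracting carbamidomethyl both land near each other
        with pytest.raises(ModelError, match="collision"):
            adjust_offsets_for_fixed_mods(
                [a, Modification("c", 0.0002 + 57.0216, frozenset("C"), mod_class="offset")],
                [CARBAMIDOMETHYL],
            )
        adjust_offsets_for_fixed_mods([a, b], [CARBAMIDOMETHYL])  # distinct: fine


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def brute_force_peptidoforms(sequence, space):
    """Independent exhaustive oracle for the hybrid peptidoform space.

    Enumerates every per-site assignment (each site takes one variable mod
    or none) by direct product, applies the global cap, then attaches each
    applicable offset to each assignment.  Returns a set of canonical keys.
    """
    site_choices = []
    for i, aa in enumerate(sequence):
        choices = [None]
        for vm in space.variable:
            if vm.terminus == "none" and aa in vm.residues:
                choices.append(vm)
        site_choices.append(choices)
    out = set()
    for assignment in itertools.product(*site_choices):
        sites = tuple(
            (i, vm.name) for i, vm in enumerate(assignment) if vm is not None
        )
        if len(sites) > space.max_var_mods:
            continue
        free = {aa for i, aa in enumerate(sequence) if assignment[i] is None}
        for off in space.offsets:
            if not off.is_zero and not (off.residues & free):
                continue
            out.add((sites, off.name))
    return out


class TestEnumerate:
    def test_no_mods_yields_single_unmodified_form(self):
        space = ModificationSpace(variable=(), offsets=(ZERO_OFFSET,))
        forms = enumerate_peptidoforms("PEPTIDE", space)
        assert len(forms) == 1
        assert forms[0].var_mod_sites == () and forms[0].offset.is_zero

    def test_single_met_with_metox_gives_two_forms(self, metox):
        space = ModificationSpace(variable=(metox,), offsets=(ZERO_OFFSET,))
        assert len(enumerate_peptidoforms("MKSSSR", space)) == 2

    def test_unknown_residue_rejected_with_offending_character(self, metox):
        space = ModificationSpace(variable=(metox,), offsets=(ZERO_OFFSET,))
        with pytest.raises(ModelError, match="'B'"):
            enumerate_peptidoforms("PEPTIBE", space)

    def test_total_mass_matches_component_sum(self, hybrid_space):
        for pf in enumerate_peptidoforms("MWCMK", hybrid_space):
            expected = peptidoform_mass(
                pf.sequence, pf.var_mod_sites, pf.offset, hybrid_space.fixed
            )
            assert pf.total_mass == pytest.approx(expected, abs=1e-4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="MWCFKSARL", min_size=1, max_size=12),
        cap=st.integers(min_value=0, max_value=3),
    )
    def test_matches_exhaustive_site_assignment_oracle(self, seq, cap, metox, dioxidation_offset):
        space = ModificationSpace(
            variable=(metox, Modification("Trp-ox", 15.994915, frozenset("W"))),
            offsets=(ZERO_OFFSET, dioxidation_offset),
            max_var_mods=cap,
        )
        forms = enumerate_peptidoforms(seq, space)
        keys = {
            (
                tuple((p, m.name) for p, m in pf.var_mod_sites),
                pf.offset.name,
            )
            for pf in forms
        }
        assert len(keys) == len(forms), "duplicate peptidoforms emitted"
        assert keys == brute_force_peptidoforms(seq, space)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

class TestCountConfigurations:
    """The worked search-space examples: a 20-mer with 1 Met and 3 Ser."""

    SPEC_20MER = {"M": 1, "S": 3, "G": 16}

    def test_metox_only_gives_two_configurations(self, metox):
        assert count_configurations(self.SPEC_20MER, [metox], "variable_only") == 2

    def test_metox_plus_phospho_gives_sixteen(self, metox):
        serp = Modification("Ser-phos", PHOSPHO_MASS, frozenset("S"))
        assert (
            count_configurations(self.SPEC_20MER, [metox, serp], "variable_only") == 16
        )

    def test_two_mods_per_residue_on_20mer_is_3_pow_20(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        mods = [
            Modification(f"{aa}-{i}", float(i), frozenset(aa))
            for aa in seq
            for i in (1, 2)
        ]
        assert count_configurations(seq, mods, "variable_only") == 3_486_784_401

    def test_negative_residue_count_rejected(self, metox):
        with pytest.raises(ModelError):
            count_configurations({"M": -1}, [metox], "variable_only")

    def test_capped_count_via_polynomial_dp(self, metox):
        # 4 Met, cap 2: 1 + 4 + C(4,2) = 11
        assert (
            count_configurations({"M": 4}, [metox], "variable_only", max_var_mods=2)
            == 11
        )

    def test_offset_only_counts_one_per_applicable_offset(self, dioxidation_offset):
        other = Modification("H to D", -22.032, frozenset("H"), mod_class="offset")
        assert count_configurations("MWK", [dioxidation_offset, other], "offset_only") == 2
        assert count_configurations("GGK", [dioxidation_offset, other], "offset_only") == 1

    def test_enumeration_length_equals_hybrid_count(self, hybrid_space, metox, dioxidation_offset):
        for seq in ("MWFMK", "WWW", "MMMMW", "GGKR"):
            forms = enumerate_peptidoforms(seq, hybrid_space)
            count = count_configurations(
                seq, [metox, dioxidation_offset], "hybrid",
                hybrid_space.max_var_mods,
            )
            assert len(forms) == count, seq

    def test_hybrid_never_exceeds_all_variable_unlimited(self, metox, dioxidation_offset):
        as_variable = Modification("Diox-var", 2 * OXIDATION_MASS, frozenset("CFMWY"))
        for seq in ("MWFMK", "MCW", "MMMWWF"):
            hybrid = count_configurations(
                seq, [metox, dioxidation_offset], "hybrid", 3
            )
            full = count_configurations(seq, [metox, as_variable], "variable_only")
            assert hybrid <= full

    def test_promoting_offset_to_variable_does_not_decrease_count(self, metox):
        """With an unbinding cap, moving a modification from the offsets
        list (at most one instance) to the variable list (combinatorial)
        can only grow the hybrid search space."""
        diox_off = Modification(
            "Diox", 2 * OXIDATION_MASS, frozenset("WF"), mod_class="offset"
        )
        diox_var = Modification("Diox", 2 * OXIDATION_MASS, frozenset("WF"))
        for seq in ("MWFK", "WFWF", "MMWK"):
            before = count_configurations(seq, [metox, diox_off], "hybrid", None)
            after = count_configurations(seq, [metox, diox_var], "hybrid", None)
            assert after >= before


class TestSpaceInvariants:
    def test_offsets_list_requires_exactly_one_zero_entry(self, dioxidation_offset):
        with pytest.raises(ModelError, match="zero-mass"):
            ModificationSpace(offsets=(dioxidation_offset,))

    def test_residue_mass_pair_cannot_be_variable_and_offset(self, metox):
        clash = Modification(
            "Ox-off", OXIDATION_MASS, frozenset("MW"), mod_class="offset"
        )
        with pytest.raises(ModelError, match="both"):
            ModificationSpace(variable=(metox,), offsets=(ZERO_OFFSET, clash))

    def test_negative_cap_rejected(self):
        with pytest.raises(ModelError):
            ModificationSpace(max_var_mods=-1)

    def test_zero_mass_modification_rejected_outside_sentinel(self):
        with pytest.raises(ModelError):
            Modification("bad", 0.0, frozenset("M"))
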