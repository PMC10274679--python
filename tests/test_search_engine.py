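"""Fragment index, hyperscore, localization, and dual-route search."""

import numpy as np
import pandas as pd
import pytest

from fpopseek.mod_model import (
    Modification,
    ModificationSpace,
    OXIDATION_MASS,
    Peptidoform,
    ZERO_OFFSET,
    enumerate_peptidoforms,
    peptidoform_mass,
)
from fpopseek.proteome import Peptide, peptide_mass
from fpopseek.search_engine import (
    SearchError,
    SearchParams,
    build_fragment_index,
    build_peptidoform_table,
    hyperscore,
    localize_delta_mass,
    match_precursor,
    score_psm,
    search_dataset,
)
from fpopseek.spectra import Spectrum, fragment_mz_arrays
from fpopseek.synthetic_data import (
    NoiseModel,
    generate_benchmark,
    render_spectra,
)


def _pf(sequence, var_sites=(), offset=ZERO_OFFSET, site="unlocalized"):
    return Peptidoform(
        sequence=sequence,
        var_mod_sites=tuple(var_sites),
        offset=offset,
        offset_site=site,
        total_mass=peptidoform_mass(sequence, var_sites, offset),
    )


def _peptide(seq, nterm=False, decoy=False):
    return Peptide(
        sequence=seq,
        parent_accessions=("P",),
        missed_cleavages=0,
        is_nterm_of_protein=nterm,
        mass=peptide_mass(seq),
        is_decoy=decoy,
    )


def perfect_spectrum(pf, scan="s", charge=2, intensity=1e4):
    """Noise-free charge-1 b/y rendering of a peptidoform."""
    mz, _, _ = fragment_mz_arrays(pf, max_fragment_charge=1)
    from fpopseek.mod_model import MASS_PROTON

    return Spectrum(
        scan,
        (pf.total_mass + charge * MASS_PROTON) / charge,
        charge,
        mz,
        np.full(mz.size, intensity),
    )


DIOX_W = Modification(
    "Dioxidation", 2 * OXIDATION_MASS, frozenset("W"), mod_class="offset"
)


class TestFragmentIndex:
    def test_octapeptide_charge1_gives_14_entries(self):
        idx = build_fragment_index([_pf("PEPTIDEK")], max_fragment_charge=1)
        assert idx.n_fragments == 14

    def test_every_fragment_retrievable_by_self_lookup(self):
        forms = enumerate_peptidoforms(
            "MWPETK",
            ModificationSpace(
                variable=(Modification("Met-ox", OXIDATION_MASS, frozenset("M")),),
                offsets=(ZERO_OFFSET,),
            ),
        )
        idx = build_fragment_index(forms, bin_width=0.02)
        for i, mz in enumerate(idx.frag_mz):
            hits = idx.query(float(mz), 1e-6)
            assert i in hits

    def test_doubling_bin_width_never_increases_bin_count(self):
        forms = [_pf("PEPTIDEK"), _pf("MWGGCKR")]
        widths = [0.01, 0.02, 0.04, 0.08]
        counts = [
            len(build_fragment_index(forms, bin_width=w).bins) for w in widths
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_each_fragment_in_exactly_one_bin(self):
        idx = build_fragment_index([_pf("MWGGCKR")], bin_width=0.02)
        covered = sorted(
            i for (s, e) in idx.bins.values() for i in range(s, e)
        )
        assert covered == list(range(idx.n_fragments))

    def test_empty_input_rejected(self):
        with pytest.raises(SearchError):
            build_fragment_index([])


class TestMatchPrecursor:
    def _table(self, seqs):
        space = ModificationSpace(offsets=(ZERO_OFFSET, DIOX_W))
        return build_peptidoform_table([_peptide(s) for s in seqs], space), space

    def _spectrum_with_mass(self, neutral, charge=2):
        from fpopseek.mod_model import MASS_PROTON

        return Spectrum(
            "q", (neutral + charge * MASS_PROTON) / charge, charge,
            np.array([200.0]), np.array([1.0]),
        )

    def test_exact_mass_matches_with_zero_offset(self):
        table, space = self._table(["PEPTIDEK"])
        sp = self._spectrum_with_mass(peptide_mass("PEPTIDEK"))
        cands = match_precursor(sp, table, space)
        assert any(off.is_zero for _, off in cands)

    def test_dioxidation_delta_requires_eligible_tryptophan(self):
        table, space = self._table(["GWPETIDEK", "GAPETIDEK"])
        for seq, expect in (("GWPETIDEK", True), ("GAPETIDEK", False)):
            sp = self._spectrum_with_mass(peptide_mass(seq) + 2 * OXIDATION_MASS)
            cands = match_precursor(sp, table, space)
            found = any(
                off.name == "Dioxidation"
                and table.form(i).sequence == seq
                for i, off in cands
            )
            assert found == expect, seq


class TestScoring:
    def test_zero_matches_scores_zero(self):
        sp = Spectrum("s", 500.0, 2, np.array([1500.0]), np.array([10.0]))
        score, matched = score_psm(sp, _pf("PEPTIDEK"))
        assert score == 0.0 and matched == 0

    def test_hyperscore_formula_components(self):
        import math

        assert hyperscore(0, 0, 0, 0) == 0.0
        assert hyperscore(2, 3, 10.0, 100.0) == pytest.approx(
            math.log(2) + math.log(6) + math.log(10.0) + math.log(100.0), abs=1e-6
        )
        # factorial cap: counts beyond 20 add only intensity
        assert hyperscore(25, 0, 1.0, 1.0) == hyperscore(20, 0, 1.0, 1.0)

    def test_score_invariant_to_peak_order(self):
        pf = _pf("MWPETKR")
        sp = perfect_spectrum(pf)
        rng = np.random.default_rng(0)
        perm = rng.permutation(sp.n_peaks)
        shuffled = Spectrum(
            "s", sp.precursor_mz, sp.precursor_charge, sp.mz[perm], sp.intensity[perm]
        )
        assert score_psm(sp, pf) == score_psm(shuffled, pf)

    def test_true_peptidoform_outscores_equal_length_decoys(self):
        pf = _pf("MWPETIDKR")
        sp = perfect_spectrum(pf)
        true_score, _ = score_psm(sp, pf)
        rng = np.random.default_rng(42)
        letters = list("MWPETIDKR")
        for _ in range(20):
            rng.shuffle(letters)
            decoy = "".join(letters)
            if decoy == pf.sequence:
                continue
            decoy_score, _ = score_psm(sp, _pf(decoy))
            assert true_score > decoy_score


class TestLocalization:
    def test_planted_site_recovered_on_unique_tryptophan(self):
        truth = _pf("GAWPETIDEKR", offset=DIOX_W, site=2)
        sp = perfect_spectrum(truth)
        query = _pf("GAWPETIDEKR", offset=DIOX_W)
        site, scores = localize_delta_mass(sp, query)
        assert site == 2

    def test_single_eligible_site_returned_directly(self):
        query = _pf("GAWPETIDEKR", offset=DIOX_W)
        sp = Spectrum("s", 600.0, 2, np.array([300.0]), np.array([5.0]))
        site, scores = localize_delta_mass(sp, query)
        assert site == 2 and list(scores) == [2]

    def test_symmetric_unmatchable_sites_tie_to_unlocalized(self):
        # no informative peaks: every placement scores identically
        query = _pf("GWGWGKR", offset=DIOX_W)
        sp = Spectrum("s", 600.0, 2, np.array([1900.0]), np.array([5.0]))
        site, scores = localize_delta_mass(sp, query)
        assert site == "unlocalized"
        assert len(scores) == 2

    def test_zero_offset_rejected(self):
        with pytest.raises(SearchError):
            localize_delta_mass(perfect_spectrum(_pf("PEPTIDEK")), _pf("PEPTIDEK"))

    def test_no_eligible_site_rejected(self):
        query = _pf("PEPTIDEK", offset=DIOX_W)
        with pytest.raises(SearchError):
            localize_delta_mass(perfect_spectrum(_pf("PEPTIDEK")), query)


class TestHybridCoverage:
    """The designed trade-off: one rare offset findable, two are not."""

    def test_common_mods_plus_one_rare_offset_is_in_space(self, hybrid_space):
        forms = enumerate_peptidoforms("MMMWK", hybrid_space)
        keys = {
            (tuple(p for p, _ in pf.var_mod_sites), pf.offset.name) for pf in forms
        }
        assert ((0, 1, 2), "Dioxidation") in keys  # 3 common + 1 rare

    def test_two_rare_offsets_not_representable(self, hybrid_space):
        forms = enumerate_peptidoforms("WWPETKR", hybrid_space)
        assert all(
            sum(1 for o in [pf.offset] if not o.is_zero) <= 1 for pf in forms
        )
        # no form mass accounts for two dioxidations
        double = peptide_mass("WWPETKR") + 4 * OXIDATION_MASS
        assert not any(
            abs(pf.total_mass - double) < 0.01 for pf in forms
        )


class TestSearchDataset:
    def test_empty_spectra_gives_empty_table(self):
        out = search_dataset([], [_peptide("PEPTIDEK")], ModificationSpace())
        assert len(out) == 0

    def test_noise_free_spectra_recover_their_peptidoforms_at_rank1(
        self, hybrid_space
    ):
        peptides = [_peptide(s) for s in ("MWPETKR", "GIDPMTWR", "LLGNDKPETIR")]
        spectra = [
            perfect_spectrum(_pf(p.sequence), scan=f"scan={i}")
            for i, p in enumerate(peptides)
        ]
        out = search_dataset(spectra, peptides, hybrid_space)
        assert len(out) == 3
        for i, p in enumerate(peptides):
            row = out[out["scan"] == f"scan={i}"].iloc[0]
            assert row["peptide"] == p.sequence
            assert row["offset_label"] == "none"

    def test_index_and_naive_routes_agree_exactly(self):
        """Oracle equivalence on a small instance (<500 peptidoforms)."""
        bench = generate_benchmark(
            n_proteins=2, mean_length=120, n_spectra=50, seed=13
        )
        from fpopseek.mod_model import load_fpop_table

        space = ModificationSpace(
            variable=(Modification("Met-ox", OXIDATION_MASS, frozenset("M")),),
            offsets=tuple([ZERO_OFFSET] + [
                m for m in load_fpop_table()
                if m.name in ("Dioxidation", "Carbonylation", "H to D")
            ]),
            max_var_mods=3,
        )
        table = build_peptidoform_table(bench.peptides, space)
        assert len(table) <= 500
        params = SearchParams()
        a = search_dataset(bench.spectra, bench.peptides, space, params, method="index")
        b = search_dataset(bench.spectra, bench.peptides, space, params, method="naive")
        pd.testing.assert_frame_equal(a, b)

    def test_search_is_deterministic(self, hybrid_space):
        bench = generate_benchmark(n_proteins=3, mean_length=150, n_spectra=30, seed=5)
        a = search_dataset(bench.spectra, bench.peptides, hybrid_space)
        b = search_dataset(bench.spectra, bench.peptides, hybrid_space)
        pd.testing.assert_frame_equal(a, b)
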