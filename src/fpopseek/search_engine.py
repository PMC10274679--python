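"""Fragment-indexed peptide-spectrum matching with delta-mass localization.

The search follows the hybrid scheme: the peptidoform table stores every
variable-modification-resolved form (no offsets), sorted by neutral mass,
and mass offsets are applied at query time as precursor-level shifted
lookups.  For each spectrum every (peptidoform, offset) pair whose shifted
mass falls within the precursor tolerance — and whose offset specificity is
satisfiable by a residue left free of variable modifications — is scored
with an X!Tandem-style hyperscore; non-zero offsets are localized by
rescoring with the offset placed at each eligible site and taking the
argmax.

Two search routes are provided and must agree exactly:

* ``method="index"`` — binary-search candidate lookup on the mass-sorted
  peptidoform table; zero-offset candidates are scored through the binned
  fragment-ion index (peak-centric accumulation) when the index fits the
  configured fragment budget, and otherwise by the per-candidate kernel,
  which performs the mathematically identical reduction fragment-wise;
* ``method="naive"`` — an exhaustive linear scan over all peptidoforms with
  per-candidate scoring, kept as the transparent reference path.

Hyperscores are rounded to 6 decimals so the two accumulation orders cannot
produce spuriously different rankings; remaining exact ties are broken
deterministically (higher matched peak count, lexicographic peptide, target
before decoy, lower peptidoform id).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mod_model import (
    MASS_PROTON,
    ModificationSpace,
    Modification,
    Peptidoform,
    ZERO_OFFSET,
    _variable_site_options,
)
from .proteome import Peptide
from .spectra import Spectrum, fragment_mz_arrays, preprocess

_LOG_FACT = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, 21)))))

_SCORE_DECIMALS = 6
_LOCALIZE_TIE_TOL = 1e-6


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class SearchParams:
    """Tolerances and engine defaults for Orbitrap-class data.

    ``max_indexed_fragments`` bounds the size of the materialized fragment
    index; larger search spaces score candidates fragment-wise instead
    (identical scores, see module docstring).
    """

    precursor_tol_ppm: float = 20.0
    fragment_tol_da: float = 0.02
    bin_width: float = 0.02
    max_fragment_charge: int = 2
    top_n_peaks: int = 150
    min_peak_mz: float = 100.0
    min_matched_fragments: int = 4
    max_indexed_fragments: int = 5_000_000


@dataclass
class PSM:
    """A scored spectrum-peptidoform match."""

    scan_id: str
    peptidoform: Peptidoform
    score: float
    matched_peaks: int
    precursor_delta: float
    offset_applied: Modification
    offset_position: int | str
    is_decoy: bool
    rank: int
    charge: int
    peptidoform_id: int


# ---------------------------------------------------------------------------
# Peptidoform table
# ---------------------------------------------------------------------------

def _residue_mask(sequence: str, occupied: Iterable[int]) -> int:
    occ = set(occupied)
    mask = 0
    for i, aa in enumerate(sequence):
        if i not in occ:
            mask |= 1 << (ord(aa) - 65)
    return mask


def _mod_mask(residues: Iterable[str]) -> int:
    mask = 0
    for aa in residues:
        mask |= 1 << (ord(aa) - 65)
    return mask


@dataclass
class PeptidoformTable:
    """Variable-mod-resolved peptidoforms sorted ascending by neutral mass.

    Forms are stored compactly as (peptide index, variable-mod site tuple)
    pairs; :meth:`form` materializes a :class:`Peptidoform` on demand.
    """

    peptides: list[Peptide]
    pep_index: np.ndarray
    var_sites: list[tuple[tuple[int, Modification], ...]]
    mass: np.ndarray
    free_mask: np.ndarray
    is_decoy: np.ndarray

    def __len__(self) -> int:
        return int(self.mass.size)

    def form(self, i: int, offset: Modification = ZERO_OFFSET) -> Peptidoform:
        pep = self.peptides[int(self.pep_index[i])]
        return Peptidoform(
            sequence=pep.sequence,
            var_mod_sites=self.var_sites[i],
            offset=offset,
            offset_site="unlocalized",
            total_mass=float(self.mass[i]) + offset.mass_delta,
            is_protein_nterm=pep.is_nterm_of_protein,
        )


def _enumerate_var_combos(
    sequence: str,
    space: ModificationSpace,
    is_protein_nterm: bool,
) -> list[tuple[tuple[int, Modification], ...]]:
    """All variable-mod site assignments of one peptide (offsets excluded).

    Mirrors :func:`fpopseek.mod_model.enumerate_peptidoforms` exactly
    (distinct sites, per-mod caps, global cap, unmodified form included).
    """
    options = _variable_site_options(sequence, space, is_protein_nterm)
    caps = {vm.name: vm.max_count for vm in space.variable}
    combos: list[tuple[tuple[int, Modification], ...]] = []
    for k in range(min(space.max_var_mods, len(options)) + 1):
        for combo in itertools.combinations(options, k):
            if len({p for p, _ in combo}) != k:
                continue
            counts: dict[str, int] = {}
            ok = True
            for _, vm in combo:
                counts[vm.name] = counts.get(vm.name, 0) + 1
                cap = caps.get(vm.name)
                if cap is not None and counts[vm.name] > cap:
                    ok = False
                    break
            if ok:
                combos.append(tuple(sorted(combo)))
    return combos


def build_peptidoform_table(
    peptides: Sequence[Peptide], space: ModificationSpace
) -> PeptidoformTable:
    """Enumerate variable-mod forms of all peptides (offsets applied later)."""
    peptides = list(peptides)
    pep_idx: list[int] = []
    var_sites: list[tuple[tuple[int, Modification], ...]] = []
    masses: list[float] = []
    free_masks: list[int] = []
    for j, pep in enumerate(peptides):
        seq = pep.sequence
        base_mask = _residue_mask(seq, ())
        letter_counts: dict[str, int] = {}
        for aa in seq:
            letter_counts[aa] = letter_counts.get(aa, 0) + 1
        for combo in _enumerate_var_combos(seq, space, pep.is_nterm_of_protein):
            pep_idx.append(j)
            var_sites.append(combo)
            masses.append(pep.mass + sum(vm.mass_delta for _, vm in combo))
            if combo:
                consumed: dict[str, int] = {}
                for pos, _ in combo:
                    if pos >= 0:
                        aa = seq[pos]
                        consumed[aa] = consumed.get(aa, 0) + 1
                mask = base_mask
                for aa, c in consumed.items():
                    if c == letter_counts[aa]:
                        mask &= ~(1 << (ord(aa) - 65))
                free_masks.append(mask)
            else:
                free_masks.append(base_mask)
    if not masses:
        raise SearchError("no peptidoforms to index")
    mass = np.array(masses)
    order = np.argsort(mass, kind="stable")
    decoy = np.array([peptides[j].is_decoy for j in pep_idx], dtype=bool)
    return PeptidoformTable(
        peptides=peptides,
        pep_index=np.array(pep_idx, dtype=np.int64)[order],
        var_sites=[var_sites[i] for i in order],
        mass=mass[order],
        free_mask=np.array(free_masks, dtype=np.int64)[order],
        is_decoy=decoy[order],
    )


# ---------------------------------------------------------------------------
# Fragment index
# ---------------------------------------------------------------------------

@dataclass
class FragmentIndex:
    """Binned m/z index over every unshifted fragment of every peptidoform.

    ``bins`` maps a bin id (``floor(mz / bin_width)``) to a contiguous slice
    of the mz-sorted fragment arrays; offset shifts are applied at query
    time (shifted precursor lookup), not stored per offset.
    """

    table: PeptidoformTable
    bin_width: float
    frag_mz: np.ndarray
    frag_form: np.ndarray
    frag_series: np.ndarray  # 0 = b, 1 = y
    bins: dict[int, tuple[int, int]]
    max_fragment_charge: int

    @property
    def n_fragments(self) -> int:
        return int(self.frag_mz.size)

    def query(self, mz: float, tol: float) -> np.ndarray:
        """Indices (into the sorted fragment arrays) of fragments within tol."""
        lo_bin = int(math.floor((mz - tol) / self.bin_width))
        hi_bin = int(math.floor((mz + tol) / self.bin_width))
        parts = []
        for b in range(lo_bin, hi_bin + 1):
            sl = self.bins.get(b)
            if sl is not None:
                parts.append(np.arange(sl[0], sl[1]))
        if not parts:
            return np.empty(0, dtype=np.int64)
        idx = np.concatenate(parts)
        return idx[np.abs(self.frag_mz[idx] - mz) <= tol]


def build_fragment_index(
    table: PeptidoformTable | Sequence[Peptidoform],
    bin_width: float = 0.02,
    max_fragment_charge: int = 2,
) -> FragmentIndex:
    """Build the binned fragment-ion index over a peptidoform table."""
    if bin_width <= 0:
        raise SearchError("bin_width must be > 0")
    if not isinstance(table, PeptidoformTable):
        table = _table_from_forms(list(table))
    mzs, form_ids, series = [], [], []
    for i in range(len(table)):
        mz, ser, _ = fragment_mz_arrays(table.form(i), max_fragment_charge)
        mzs.append(mz)
        form_ids.append(np.full(mz.size, i, dtype=np.int64))
        series.append(ser)
    frag_mz = np.concatenate(mzs)
    frag_form = np.concatenate(form_ids)
    frag_series = np.concatenate(series)
    order = np.argsort(frag_mz, kind="stable")
    frag_mz, frag_form, frag_series = frag_mz[order], frag_form[order], frag_series[order]
    bin_ids = np.floor(frag_mz / bin_width).astype(np.int64)
    bins: dict[int, tuple[int, int]] = {}
    if bin_ids.size:
        boundaries = np.flatnonzero(np.diff(bin_ids)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [bin_ids.size]))
        for s, e in zip(starts, ends):
            bins[int(bin_ids[s])] = (int(s), int(e))
    return FragmentIndex(
        table=table,
        bin_width=bin_width,
        frag_mz=frag_mz,
        frag_form=frag_form,
        frag_series=frag_series,
        bins=bins,
        max_fragment_charge=max_fragment_charge,
    )


def _table_from_forms(forms: list[Peptidoform]) -> PeptidoformTable:
    if not forms:
        raise SearchError("empty peptidoform list")
    peptides = [
        Peptide(
            sequence=pf.sequence,
            parent_accessions=(),
            missed_cleavages=0,
            is_nterm_of_protein=pf.is_protein_nterm,
            mass=pf.total_mass - pf.offset.mass_delta
            - sum(vm.mass_delta for _, vm in pf.var_mod_sites),
        )
        for pf in forms
    ]
    mass = np.array([pf.total_mass for pf in forms])
    order = np.argsort(mass, kind="stable")
    return PeptidoformTable(
        peptides=[peptides[i] for i in order],
        pep_index=np.arange(order.size, dtype=np.int64),
        var_sites=[forms[i].var_mod_sites for i in order],
        mass=mass[order],
        free_mask=np.array(
            [_residue_mask(forms[i].sequence, forms[i].var_positions) for i in order],
            dtype=np.int64,
        ),
        is_decoy=np.zeros(order.size, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def hyperscore(nb: int, ny: int, ib: float, iy: float) -> float:
    """X!Tandem-style hyperscore: ln(Nb! Ny! max(1,ΣIb) max(1,ΣIy)).

    Factorials are capped at 20!; the result is rounded to 6 decimals so
    that mathematically equal scores computed in different accumulation
    orders compare equal.
    """
    s = (
        _LOG_FACT[min(nb, 20)]
        + _LOG_FACT[min(ny, 20)]
        + math.log(max(1.0, ib))
        + math.log(max(1.0, iy))
    )
    return round(float(s), _SCORE_DECIMALS)


def _match_arrays(
    spectrum: Spectrum, frag_mz: np.ndarray, frag_series: np.ndarray, tol: float
) -> tuple[int, int, float, float]:
    """Fragment-centric matching: per theoretical fragment, all peaks in tol.

    Returns (Nb, Ny, ΣIb, ΣIy) where N counts distinct matched fragments and
    ΣI sums the intensities of every peak within tol of a matched fragment.
    """
    peaks = spectrum.mz
    if peaks.size == 0 or frag_mz.size == 0:
        return 0, 0, 0.0, 0.0
    csum = np.concatenate(([0.0], np.cumsum(spectrum.intensity)))
    lo = np.searchsorted(peaks, frag_mz - tol, side="left")
    hi = np.searchsorted(peaks, frag_mz + tol, side="right")
    matched = hi > lo
    isum = csum[hi] - csum[lo]
    b = frag_series == 0
    nb = int(np.count_nonzero(matched & b))
    ny = int(np.count_nonzero(matched & ~b))
    return nb, ny, float(isum[b].sum()), float(isum[~b].sum())


def score_psm(
    spectrum: Spectrum,
    peptidoform: Peptidoform,
    fragment_tol_da: float = 0.02,
    max_fragment_charge: int = 2,
) -> tuple[float, int]:
    """Hyperscore a (preprocessed) spectrum against one concrete peptidoform.

    A localized offset shifts the fragments containing its site; an
    unlocalized offset contributes unshifted fragments only.  Returns
    ``(score, matched_peaks)`` with ``matched_peaks`` the number of distinct
    matched theoretical fragments.
    """
    frag_mz, frag_series, _ = fragment_mz_arrays(peptidoform, max_fragment_charge)
    nb, ny, ib, iy = _match_arrays(spectrum, frag_mz, frag_series, fragment_tol_da)
    return hyperscore(nb, ny, ib, iy), nb + ny


def _localize_all_sites(
    spectrum: Spectrum,
    peptidoform: Peptidoform,
    fragment_tol_da: float,
    max_fragment_charge: int,
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Vectorized per-site rescoring of an unlocalized offset.

    Places the offset at every eligible site (as a +delta shift of the
    fragments containing the site) and scores each placement in one batched
    search.  Returns (sites, scores, matched counts).
    """
    sites = peptidoform.offset_candidate_sites()
    if not sites:
        raise SearchError(
            f"no eligible site for offset {peptidoform.offset.name!r} "
            f"on {peptidoform.sequence!r}"
        )
    base_mz, series, _ = fragment_mz_arrays(peptidoform, max_fragment_charge)
    n = len(peptidoform.sequence)
    delta = peptidoform.offset.mass_delta
    nf = base_mz.size
    per_block = n - 1
    # per-column shift magnitude (delta / z) and per-site containment masks
    shift_amount = np.empty(nf)
    b_ion = np.arange(1, n)          # b_i contains sites < i
    y_pos = np.arange(per_block)     # y block col i covers sites >= i … no:
    # y block col i corresponds to ion y_(n-1-i), containing site s iff i < s+1
    # (derived: s >= i), see fragment_mz_arrays.
    masks = np.zeros((len(sites), nf), dtype=bool)
    col = 0
    for z in range(1, max_fragment_charge + 1):
        shift_amount[col : col + per_block] = delta / z
        for k, s in enumerate(sites):
            masks[k, col : col + per_block] = b_ion > s
        col += per_block
        shift_amount[col : col + per_block] = delta / z
        for k, s in enumerate(sites):
            masks[k, col : col + per_block] = y_pos < s
        col += per_block
    all_mz = base_mz[None, :] + masks * shift_amount[None, :]

    peaks = spectrum.mz
    csum = np.concatenate(([0.0], np.cumsum(spectrum.intensity)))
    flat = all_mz.ravel()
    lo = np.searchsorted(peaks, flat - fragment_tol_da, side="left")
    hi = np.searchsorted(peaks, flat + fragment_tol_da, side="right")
    matched = (hi > lo).reshape(len(sites), nf)
    isum = (csum[hi] - csum[lo]).reshape(len(sites), nf)
    b = series == 0
    nb = matched[:, b].sum(axis=1)
    ny = matched[:, ~b].sum(axis=1)
    ib = isum[:, b].sum(axis=1)
    iy = isum[:, ~b].sum(axis=1)
    scores = (
        _LOG_FACT[np.minimum(nb, 20)]
        + _LOG_FACT[np.minimum(ny, 20)]
        + np.log(np.maximum(1.0, ib))
        + np.log(np.maximum(1.0, iy))
    )
    return sites, np.round(scores, _SCORE_DECIMALS), (nb + ny).astype(int)


def localize_delta_mass(
    spectrum: Spectrum,
    peptidoform: Peptidoform,
    fragment_tol_da: float = 0.02,
    max_fragment_charge: int = 2,
) -> tuple[int | str, dict[int, float]]:
    """Localize a non-zero offset by rescoring with the delta at each site.

    Candidate sites are the residues matching the offset's specificity that
    do not carry a variable modification.  Returns the argmax site, or
    ``"unlocalized"`` when >= 2 sites tie within 1e-6, together with the
    per-site scores.
    """
    if peptidoform.offset.is_zero:
        raise SearchError("localize_delta_mass requires a non-zero offset")
    sites, scores, _matched = _localize_all_sites(
        spectrum, peptidoform, fragment_tol_da, max_fragment_charge
    )
    site_scores = {s: float(sc) for s, sc in zip(sites, scores)}
    best = max(site_scores.values())
    tied = [s for s, sc in site_scores.items() if best - sc <= _LOCALIZE_TIE_TOL]
    if len(tied) > 1:
        return "unlocalized", site_scores
    return tied[0], site_scores


def _score_offset_candidate(
    spectrum: Spectrum,
    pf: Peptidoform,
    fragment_tol_da: float,
    max_fragment_charge: int,
) -> tuple[float, int, int | str]:
    """Final (score, matched, reported site) of a non-zero-offset candidate.

    The PSM takes the best site's score; the reported position degrades to
    ``"unlocalized"`` when two or more placements tie within 1e-6.
    """
    sites, scores, matched = _localize_all_sites(
        spectrum, pf, fragment_tol_da, max_fragment_charge
    )
    best = float(scores.max())
    exact_best = [s for s, sc in zip(sites, scores) if sc == best]
    psm_site = min(exact_best)
    n_tied = int(np.sum(best - scores <= _LOCALIZE_TIE_TOL))
    reported: int | str = psm_site if n_tied == 1 else "unlocalized"
    return best, int(matched[sites.index(psm_site)]), reported


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

def match_precursor(
    spectrum: Spectrum,
    index: "FragmentIndex | PeptidoformTable",
    space: ModificationSpace,
    precursor_tol_ppm: float = 20.0,
) -> list[tuple[int, Modification]]:
    """All (peptidoform id, offset) pairs explaining the precursor mass.

    A pair qualifies when |observed - (form mass + delta)| <= tol and the
    offset's residue specificity is satisfiable by a residue of the form not
    occupied by a variable modification.  The zero offset is always tried.
    """
    table = index.table if isinstance(index, FragmentIndex) else index
    obs = spectrum.precursor_neutral_mass
    tol = obs * precursor_tol_ppm * 1e-6
    out: list[tuple[int, Modification]] = []
    for off in sorted(space.offsets, key=lambda o: (o.mass_delta, o.name)):
        target = obs - off.mass_delta
        lo = int(np.searchsorted(table.mass, target - tol, side="left"))
        hi = int(np.searchsorted(table.mass, target + tol, side="right"))
        if lo == hi:
            continue
        if off.is_zero:
            out.extend((i, off) for i in range(lo, hi))
        else:
            omask = _mod_mask(off.residues)
            for i in range(lo, hi):
                if table.free_mask[i] & omask:
                    out.append((i, off))
    return out


def _naive_candidates(
    spectrum: Spectrum,
    table: PeptidoformTable,
    space: ModificationSpace,
    precursor_tol_ppm: float,
) -> list[tuple[int, Modification]]:
    """Linear-scan reference implementation of :func:`match_precursor`."""
    obs = spectrum.precursor_neutral_mass
    tol = obs * precursor_tol_ppm * 1e-6
    out = []
    for off in sorted(space.offsets, key=lambda o: (o.mass_delta, o.name)):
        for i in range(len(table)):
            pf = table.form(i)
            if abs(obs - (pf.total_mass + off.mass_delta)) > tol:
                continue
            if not off.is_zero and not (off.residues & pf.free_residues()):
                continue
            out.append((i, off))
    return out


# ---------------------------------------------------------------------------
# Dataset search
# ---------------------------------------------------------------------------

def _index_zero_offset_scores(
    spectrum: Spectrum,
    index: FragmentIndex,
    candidate_ids: np.ndarray,
    fragment_tol_da: float,
) -> dict[int, tuple[float, int]]:
    """Peak-centric hyperscores for zero-offset candidates via the bins.

    For every spectrum peak the binned index yields the fragments within
    tolerance; (fragment, peak) pairs are then reduced per candidate form to
    distinct-fragment counts and matched-intensity sums — by construction
    the same reduction :func:`score_psm` performs fragment-wise.
    """
    result = {int(i): (hyperscore(0, 0, 0.0, 0.0), 0) for i in candidate_ids}
    if candidate_ids.size == 0:
        return result
    pair_frag: list[np.ndarray] = []
    pair_int: list[np.ndarray] = []
    for pmz, pint in zip(spectrum.mz, spectrum.intensity):
        idx = index.query(float(pmz), fragment_tol_da)
        if idx.size:
            pair_frag.append(idx)
            pair_int.append(np.full(idx.size, pint))
    if not pair_frag:
        return result
    frag = np.concatenate(pair_frag)
    pint = np.concatenate(pair_int)
    local = np.full(len(index.table), -1, dtype=np.int64)
    local[candidate_ids] = np.arange(candidate_ids.size)
    loc = local[index.frag_form[frag]]
    keep = loc >= 0
    if not np.any(keep):
        return result
    frag, pint, loc = frag[keep], pint[keep], loc[keep]
    ser = index.frag_series[frag].astype(np.int64)
    isums = np.bincount(loc * 2 + ser, weights=pint, minlength=candidate_ids.size * 2)
    uniq = np.unique(frag)
    uloc = local[index.frag_form[uniq]]
    user = index.frag_series[uniq].astype(np.int64)
    counts = np.bincount(uloc * 2 + user, minlength=candidate_ids.size * 2)
    for j, form_id in enumerate(candidate_ids):
        nb, ny = int(counts[2 * j]), int(counts[2 * j + 1])
        ib, iy = float(isums[2 * j]), float(isums[2 * j + 1])
        result[int(form_id)] = (hyperscore(nb, ny, ib, iy), nb + ny)
    return result


def _rank_key(
    score: float, matched: int, pf: Peptidoform, is_decoy: bool, form_id: int,
    offset: Modification,
) -> tuple:
    return (-score, -matched, pf.sequence, bool(is_decoy), form_id, offset.name)


def estimated_fragment_count(table: PeptidoformTable, max_fragment_charge: int) -> int:
    lengths = np.array([len(table.peptides[j].sequence) for j in table.pep_index])
    return int(2 * max_fragment_charge * np.sum(lengths - 1))


def search_dataset(
    spectra: Sequence[Spectrum],
    proteome_peptides: Sequence[Peptide],
    space: ModificationSpace,
    params: SearchParams = SearchParams(),
    method: str = "index",
) -> pd.DataFrame:
    """Search spectra against the hybrid peptidoform space; rank-1 per scan.

    ``method="index"`` uses the mass-sorted table with the binned fragment
    index (falling back to the identical per-candidate kernel above the
    fragment budget); ``method="naive"`` is the exhaustive reference path.
    Both return identical results.  Spectra whose precursor matches no
    (form, offset) pair are absent from the output — the unexplained-delta
    set.
    """
    if method not in ("index", "naive"):
        raise SearchError(f"unknown search method {method!r}")
    if not spectra:
        return _psm_frame([])
    table = build_peptidoform_table(proteome_peptides, space)
    index = None
    if method == "index" and (
        estimated_fragment_count(table, params.max_fragment_charge)
        <= params.max_indexed_fragments
    ):
        index = build_fragment_index(table, params.bin_width, params.max_fragment_charge)

    best_per_scan: dict[str, tuple[tuple, PSM]] = {}
    for sp in spectra:
        psp = preprocess(sp, params.top_n_peaks, params.min_peak_mz)
        if method == "index":
            cands = match_precursor(psp, table, space, params.precursor_tol_ppm)
        else:
            cands = _naive_candidates(psp, table, space, params.precursor_tol_ppm)
        if not cands:
            continue
        zero_ids = np.array(
            sorted({i for i, off in cands if off.is_zero}), dtype=np.int64
        )
        if index is not None:
            zero_scores = _index_zero_offset_scores(
                psp, index, zero_ids, params.fragment_tol_da
            )
        else:
            zero_scores = {
                int(i): score_psm(
                    psp, table.form(i), params.fragment_tol_da,
                    params.max_fragment_charge,
                )
                for i in zero_ids
            }
        for form_id, off in cands:
            if off.is_zero:
                score, matched = zero_scores[form_id]
                pf = table.form(form_id)
                site: int | str = "unlocalized"
            else:
                pf = table.form(form_id, off)
                score, matched, site = _score_offset_candidate(
                    psp, pf, params.fragment_tol_da, params.max_fragment_charge
                )
                pf = pf.with_offset_site(site)
            if matched < params.min_matched_fragments:
                # no reportable fragment evidence; scans whose candidates all
                # fail this floor end up in the unexplained-delta set
                continue
            key = _rank_key(score, matched, pf, table.is_decoy[form_id], form_id, off)
            prev = best_per_scan.get(sp.scan_id)
            if prev is not None and key >= prev[0]:
                continue
            psm = PSM(
                scan_id=sp.scan_id,
                peptidoform=pf,
                score=score,
                matched_peaks=matched,
                precursor_delta=psp.precursor_neutral_mass - float(table.mass[form_id]),
                offset_applied=off,
                offset_position=site,
                is_decoy=bool(table.is_decoy[form_id]),
                rank=1,
                charge=sp.precursor_charge,
                peptidoform_id=form_id,
            )
            best_per_scan[sp.scan_id] = (key, psm)
    return _psm_frame([psm for _, psm in best_per_scan.values()])


def _format_mods(pf: Peptidoform) -> str:
    parts = []
    for pos, vm in sorted(pf.var_mod_sites):
        if pos < 0:
            parts.append(f"N-term/{vm.mass_delta:.4f}")
        else:
            parts.append(f"{pos + 1}{pf.sequence[pos]}/{vm.mass_delta:.4f}")
    return ";".join(parts)


def _psm_frame(psms: Sequence[PSM]) -> pd.DataFrame:
    rows = []
    for p in sorted(psms, key=lambda x: x.scan_id):
        pf = p.peptidoform
        rows.append(
            {
                "scan": p.scan_id,
                "charge": p.charge,
                "peptide": pf.sequence,
                "assigned_modifications": _format_mods(pf),
                "mods": tuple(pf.modification_list()),
                "offset_label": p.offset_applied.name,
                "offset_mass": p.offset_applied.mass_delta,
                "offset_position": (
                    p.offset_position if isinstance(p.offset_position, int) else -1
                ),
                "precursor_delta": p.precursor_delta,
                "score": p.score,
                "matched_peaks": p.matched_peaks,
                "is_decoy": p.is_decoy,
                "peptidoform_id": p.peptidoform_id,
                "n_var_mods": pf.n_var_mods,
            }
        )
    columns = [
        "scan", "charge", "peptide", "assigned_modifications", "mods",
        "offset_label", "offset_mass", "offset_position", "precursor_delta",
        "score", "matched_peaks", "is_decoy", "peptidoform_id", "n_var_mods",
    ]
    return pd.DataFrame(rows, columns=columns)
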