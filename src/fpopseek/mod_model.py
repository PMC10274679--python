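"""Modification universe and hybrid search-space construction.

FPOP (fast photochemical oxidation of proteins) exposes proteins to hydroxyl
radicals that irreversibly oxidize solvent-accessible side chains of 19 of
the 20 amino acids, each potentially in several chemical forms.  A
conventional database search that enumerates every combination of these
modifications ("variable modifications") faces a search space that grows
exponentially with peptide length.  The hybrid scheme implemented here
splits the modification universe in two:

* **variable modifications** — common modifications (e.g. Met oxidation)
  enumerated combinatorially over all eligible sites, up to a per-peptide
  cap (default 3);
* **mass offsets** — rare modifications searched as a single precursor-level
  mass shift, at most one per peptide, localized afterwards via shifted
  fragment ions.

The hybrid space therefore contains every peptidoform carrying up to
``max_var_mods`` common modifications plus at most one rare modification,
and deliberately excludes peptides bearing two or more rare modifications
at once — the documented trade-off that keeps proteome-wide FPOP searches
tractable.

This module defines the :class:`Modification`, :class:`ModificationSpace`
and :class:`Peptidoform` types, the built-in FPOP offset table, and exact
integer counting / explicit enumeration of the search space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

# ---------------------------------------------------------------------------
# Physical constants (monoisotopic).  The FPOP offset table is printed to
# 4 decimals; reproducing the carbamidomethyl-adjusted Cys offsets requires
# carrying the arithmetic at full elemental precision first.
# ---------------------------------------------------------------------------

MASS_H = 1.0078250319
MASS_C = 12.0
MASS_N = 14.0030740052
MASS_O = 15.9949146221
MASS_PROTON = 1.00727646688
MASS_WATER = 2 * MASS_H + MASS_O  # 18.0105647

#: Monoisotopic residue masses (internal residues, no termini).
AA_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

VALID_RESIDUES = frozenset(AA_MASS)

#: Carbamidomethylation of Cys (iodoacetamide alkylation, +C2H3NO), the
#: fixed modification applied during standard bottom-up sample prep.
CARBAMIDOMETHYL_MASS = 2 * MASS_C + 3 * MASS_H + MASS_N + MASS_O  # 57.0214637

ACETYL_MASS = 2 * MASS_C + 2 * MASS_H + MASS_O  # 42.0105646
OXIDATION_MASS = MASS_O  # 15.9949146
PHOSPHO_MASS = 79.96633  # HPO3, used only in worked combinatorics examples


class ModelError(ValueError):
    """Raised for invalid modifications, sequences or spaces."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Modification:
    """A named monoisotopic mass delta with residue/terminus specificity.

    Parameters
    ----------
    name:
        Short label, e.g. ``"Oxidation"``.
    mass_delta:
        Signed monoisotopic delta in Da, carried at >= 5-decimal precision.
    residues:
        Single-letter amino acids the modification may occupy.  May be empty
        only for terminus-specific modifications.
    terminus:
        ``"none"`` for residue mods, ``"peptide-N"`` or ``"protein-N"`` for
        N-terminal mods (protein-N restricts to protein N-terminal peptides).
    mod_class:
        ``"fixed"``, ``"variable"`` or ``"offset"``.
    max_count:
        Per-peptide cap for this modification alone (the space-wide
        ``max_var_mods`` cap also applies).  ``None`` means uncapped.
    """

    name: str
    mass_delta: float
    residues: frozenset[str] = frozenset()
    terminus: str = "none"
    mod_class: str = "variable"
    max_count: int | None = None

    def __post_init__(self) -> None:
        if self.terminus not in ("none", "peptide-N", "protein-N"):
            raise ModelError(f"unknown terminus {self.terminus!r}")
        if self.mod_class not in ("fixed", "variable", "offset"):
            raise ModelError(f"unknown mod_class {self.mod_class!r}")
        if not math.isfinite(self.mass_delta):
            raise ModelError(f"{self.name}: mass_delta must be finite")
        # A zero mass is only meaningful for the sentinel "no offset" entry.
        if self.mass_delta == 0.0 and self.name != ZERO_OFFSET_NAME:
            raise ModelError(f"{self.name}: zero mass_delta")
        if not self.residues and self.terminus == "none" and self.name != ZERO_OFFSET_NAME:
            raise ModelError(f"{self.name}: residues empty for non-terminal mod")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ModelError(f"{self.name}: unknown residues {sorted(bad)}")
        object.__setattr__(self, "residues", frozenset(self.residues))

    @property
    def is_zero(self) -> bool:
        return self.mass_delta == 0.0

    def __str__(self) -> str:  # Table-1-style "residues/mass"
        res = "".join(sorted(self.residues)) or "N-term"
        return f"{res}/{self.mass_delta:.6f}"


ZERO_OFFSET_NAME = "none"

#: The sentinel "no offset" entry: every offsets list contains exactly one,
#: so unmodified and variable-only peptidoforms are always part of the space.
ZERO_OFFSET = Modification(
    name=ZERO_OFFSET_NAME, mass_delta=0.0, residues=frozenset(), mod_class="offset"
)

CARBAMIDOMETHYL = Modification(
    "Carbamidomethyl", CARBAMIDOMETHYL_MASS, frozenset("C"), mod_class="fixed"
)


def _mod_key(mod: Modification) -> tuple[str, float]:
    res = "".join(sorted(mod.residues)) if mod.residues else mod.terminus
    return (res, round(mod.mass_delta, 4))


@dataclass(frozen=True)
class ModificationSpace:
    """The hybrid search space: fixed + variable mods + single-offset list.

    Invariants enforced at construction: ``max_var_mods >= 0``; the offsets
    list contains exactly one zero-mass entry; no (residue, mass) pair occurs
    in both the variable and the offsets list.
    """

    fixed: tuple[Modification, ...] = (CARBAMIDOMETHYL,)
    variable: tuple[Modification, ...] = ()
    offsets: tuple[Modification, ...] = (ZERO_OFFSET,)
    max_var_mods: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "variable", tuple(self.variable))
        object.__setattr__(self, "offsets", tuple(self.offsets))
        if self.max_var_mods < 0:
            raise ModelError("max_var_mods must be >= 0")
        n_zero = sum(1 for o in self.offsets if o.is_zero)
        if n_zero != 1:
            raise ModelError(
                f"offsets list must contain exactly one zero-mass entry, found {n_zero}"
            )
        var_keys = set()
        for m in self.variable:
            if m.mod_class != "variable":
                raise ModelError(f"{m.name} in variable list has class {m.mod_class}")
            for r in m.residues:
                var_keys.add((r, round(m.mass_delta, 4)))
        for o in self.offsets:
            if o.is_zero:
                continue
            for r in o.residues:
                if (r, round(o.mass_delta, 4)) in var_keys:
                    raise ModelError(
                        f"({r}, {o.mass_delta:.4f}) appears in both variable and offsets"
                    )

    @property
    def nonzero_offsets(self) -> tuple[Modification, ...]:
        return tuple(o for o in self.offsets if not o.is_zero)


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with a concrete modification assignment.

    ``var_mod_sites`` holds ``(position, Modification)`` pairs with 0-based
    positions; position ``-1`` denotes the peptide N-terminus (used for
    N-terminal acetylation).  ``offset`` is the single applied mass offset
    (possibly the zero entry); ``offset_site`` is a 0-based position once
    localized, or ``"unlocalized"``.
    """

    sequence: str
    var_mod_sites: tuple[tuple[int, Modification], ...] = ()
    offset: Modification = ZERO_OFFSET
    offset_site: int | str = "unlocalized"
    total_mass: float = field(default=0.0, compare=False)
    is_protein_nterm: bool = field(default=False, compare=False)

    def with_offset_site(self, site: int | str) -> "Peptidoform":
        return replace(self, offset_site=site)

    @property
    def n_var_mods(self) -> int:
        return len(self.var_mod_sites)

    @property
    def var_positions(self) -> frozenset[int]:
        return frozenset(p for p, _ in self.var_mod_sites)

    def free_residues(self) -> set[str]:
        """Residue letters present at positions not carrying a variable mod."""
        occupied = self.var_positions
        return {aa for i, aa in enumerate(self.sequence) if i not in occupied}

    def offset_candidate_sites(self) -> list[int]:
        """Positions eligible to carry this form's (non-zero) offset."""
        if self.offset.is_zero:
            return []
        occupied = self.var_positions
        return [
            i
            for i, aa in enumerate(self.sequence)
            if aa in self.offset.residues and i not in occupied
        ]

    def modification_list(self) -> list[tuple[str, float, str]]:
        """All non-fixed modifications as (site key, mass, label) triples.

        The site key is the residue letter, or ``"n"`` for N-terminal mods;
        an unlocalized offset is keyed by its residue set's sorted letters.
        Fixed modifications are deliberately excluded (they are part of every
        peptide and carry no identification information).
        """
        out = []
        for pos, m in sorted(self.var_mod_sites):
            key = "n" if pos < 0 else self.sequence[pos]
            out.append((key, m.mass_delta, m.name))
        if not self.offset.is_zero:
            if isinstance(self.offset_site, int):
                key = self.sequence[self.offset_site]
            else:
                key = "".join(sorted(self.offset.residues))
            out.append((key, self.offset.mass_delta, self.offset.name))
        return out


# ---------------------------------------------------------------------------
# The FPOP offset table
# ---------------------------------------------------------------------------

# Mass deltas carried at elemental precision where the chemistry is known;
# the two His rows without a published composition keep printed precision.
_DEGUANIDATION = -(MASS_C + 5 * MASS_H + 3 * MASS_N) + MASS_O       # -43.05343
_H_TO_D = AA_MASS["D"] - AA_MASS["H"]                                # -22.03197
_H_TO_N = AA_MASS["N"] - AA_MASS["H"]                                # -23.01598
_DECARBOXYLATION = -(MASS_C + 2 * MASS_H + MASS_O)                   # -30.01056
_CO_LOSS = -(MASS_C + MASS_O)                                        # -27.99491
_CO2_LOSS = -(MASS_C + 2 * MASS_O)                                   # -43.98983

_FPOP_ROWS: list[tuple[str, float, str]] = [
    ("Oxidation", OXIDATION_MASS, "MFHILVWYADEKNPQR"),
    ("Dioxidation", 2 * MASS_O, "CFMWY"),
    ("Trioxidation", 3 * MASS_O, "CFWY"),
    ("Carbonylation", MASS_O - 2 * MASS_H, "EIKLPQRV"),
    ("Arg deguanidation", _DEGUANIDATION, "R"),
    ("H to D", _H_TO_D, "H"),
    ("H to N", _H_TO_N, "H"),
    ("H -10", -10.0320, "H"),
    ("H + 5", 4.9735, "H"),
    ("Decarboxylation", _DECARBOXYLATION, "DE"),
    ("CO loss", _CO_LOSS, "DE"),
    ("CO2 loss", _CO2_LOSS, "DE"),
    ("C dioxidation assuming fixed carbamidomethylation",
     2 * MASS_O - CARBAMIDOMETHYL_MASS, "C"),
    ("C trioxidation assuming fixed carbamidomethylation",
     3 * MASS_O - CARBAMIDOMETHYL_MASS, "C"),
]


def load_fpop_table() -> list[Modification]:
    """Return the 14 built-in FPOP mass offsets as offset-class modifications.

    The table covers the hydroxyl-radical modification universe used for
    in-vivo FPOP searches: oxidation states, carbonylation, side-chain
    losses, His conversion products, and Cys oxidation expressed relative to
    fixed carbamidomethylation (oxidized Cys cannot be alkylated, so the
    observed delta is the oxidation mass minus the carbamidomethyl mass).
    """
    return [
        Modification(name, delta, frozenset(res), mod_class="offset")
        for name, delta, res in _FPOP_ROWS
    ]


def adjust_offsets_for_fixed_mods(
    offsets: Sequence[Modification],
    fixed: Sequence[Modification],
    collision_tol: float = 0.0005,
) -> list[Modification]:
    """Express chemical offset deltas relative to fixed modifications.

    An offset whose target residues *all* carry some fixed modification
    chemically replaces that fixed group (e.g. Cys oxidation products
    displace the carbamidomethyl adduct), so its observable precursor delta
    is ``chemical delta - fixed delta``.  Offsets with any fixed-mod-free
    target residue are returned unchanged.

    Raises :class:`ModelError` if an adjusted offset collides (within
    ``collision_tol`` Da) with another offset sharing its residue set.
    """
    adjusted: list[Modification] = []
    for off in offsets:
        if off.is_zero or not off.residues:
            adjusted.append(off)
            continue
        delta = off.mass_delta
        for fm in fixed:
            if off.residues and off.residues <= fm.residues:
                delta = delta - fm.mass_delta
        adjusted.append(replace(off, mass_delta=delta) if delta != off.mass_delta else off)
    for a, b in itertools.combinations(adjusted, 2):
        if a.is_zero or b.is_zero:
            continue
        if a.residues == b.residues and abs(a.mass_delta - b.mass_delta) < collision_tol:
            raise ModelError(
                f"offset collision on {''.join(sorted(a.residues))}: "
                f"{a.name} ({a.mass_delta:.4f}) vs {b.name} ({b.mass_delta:.4f})"
            )
    return adjusted


# ---------------------------------------------------------------------------
# Peptidoform mass and enumeration
# ---------------------------------------------------------------------------

def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ModelError("empty peptide sequence")
    for ch in sequence:
        if ch not in VALID_RESIDUES:
            raise ModelError(f"unknown amino acid {ch!r} in {sequence!r}")


def peptidoform_mass(
    sequence: str,
    var_mod_sites: Iterable[tuple[int, Modification]] = (),
    offset: Modification = ZERO_OFFSET,
    fixed: Iterable[Modification] = (CARBAMIDOMETHYL,),
) -> float:
    """Neutral monoisotopic mass of a peptidoform, fixed mods included."""
    _check_sequence(sequence)
    m = MASS_WATER + sum(AA_MASS[aa] for aa in sequence)
    for fm in fixed:
        m += fm.mass_delta * sum(1 for aa in sequence if aa in fm.residues)
    for _, vm in var_mod_sites:
        m += vm.mass_delta
    return m + offset.mass_delta


def _variable_site_options(
    sequence: str, space: ModificationSpace, is_protein_nterm: bool
) -> list[tuple[int, Modification]]:
    """All legal (position, variable mod) placements for a sequence."""
    options: list[tuple[int, Modification]] = []
    for vm in space.variable:
        if vm.terminus in ("peptide-N", "protein-N"):
            if vm.terminus == "protein-N" and not is_protein_nterm:
                continue
            options.append((-1, vm))
        else:
            for i, aa in enumerate(sequence):
                if aa in vm.residues:
                    options.append((i, vm))
    return options


def enumerate_peptidoforms(
    sequence: str,
    space: ModificationSpace,
    is_protein_nterm: bool = False,
) -> list[Peptidoform]:
    """Enumerate the hybrid peptidoform space of one peptide.

    Every returned form carries at most ``space.max_var_mods`` variable
    modifications (one per site) and at most one non-zero mass offset, which
    is applicable only if the sequence retains >= 1 residue from the
    offset's specificity set not occupied by a variable modification.  The
    fully unmodified form is always included; offsets are left unlocalized.
    """
    _check_sequence(sequence)
    options = _variable_site_options(sequence, space, is_protein_nterm)
    forms: list[Peptidoform] = []
    per_mod_cap: dict[str, int | None] = {vm.name: vm.max_count for vm in space.variable}

    for k in range(min(space.max_var_mods, len(options)) + 1):
        for combo in itertools.combinations(options, k):
            positions = [p for p, _ in combo]
            if len(set(positions)) != k:  # one site, one delta
                continue
            counts: dict[str, int] = {}
            ok = True
            for _, vm in combo:
                counts[vm.name] = counts.get(vm.name, 0) + 1
                cap = per_mod_cap.get(vm.name)
                if cap is not None and counts[vm.name] > cap:
                    ok = False
                    break
            if not ok:
                continue
            occupied = set(positions)
            free = {aa for i, aa in enumerate(sequence) if i not in occupied}
            for off in space.offsets:
                if not off.is_zero and not (off.residues & free):
                    continue
                forms.append(
                    Peptidoform(
                        sequence=sequence,
                        var_mod_sites=tuple(sorted(combo)),
                        offset=off,
                        offset_site="unlocalized",
                        total_mass=peptidoform_mass(
                            sequence, combo, off, space.fixed
                        ),
                        is_protein_nterm=is_protein_nterm,
                    )
                )
    return forms


# ---------------------------------------------------------------------------
# Exact search-space counting
# ---------------------------------------------------------------------------

def _residue_counts(sequence_spec: Mapping[str, int] | str) -> dict[str, int]:
    if isinstance(sequence_spec, str):
        _check_sequence(sequence_spec)
        counts: dict[str, int] = {}
        for aa in sequence_spec:
            counts[aa] = counts.get(aa, 0) + 1
        return counts
    counts = dict(sequence_spec)
    for aa, c in counts.items():
        if c < 0:
            raise ModelError(f"negative residue count for {aa!r}")
    return counts


def count_configurations(
    sequence_spec: Mapping[str, int] | str,
    mods: Sequence[Modification],
    scheme: str = "variable_only",
    max_var_mods: int | None = None,
) -> int:
    """Exact number of distinct modification configurations of a peptide.

    ``sequence_spec`` is either a concrete sequence or a mapping of residue
    letter to count (letters absent from every modification's specificity may
    be pooled under any unused letter, e.g. ``{"M": 1, "S": 3, "G": 16}``).

    Schemes
    -------
    ``variable_only``
        All ``mods`` act as variable modifications.  With ``max_var_mods``
        ``None`` (unlimited) the count is the product over residue instances
        of ``1 + (number of mods applicable)``; with a cap it is the number
        of site assignments using at most that many modifications.
    ``offset_only``
        All ``mods`` act as mass offsets: ``1 +`` the number of offsets with
        >= 1 eligible residue present (a single unlocalized shift each).
    ``hybrid``
        Mods with ``mod_class == "offset"`` act as offsets, the rest as
        variable modifications; each variable configuration may combine with
        at most one applicable offset (an offset requires an eligible residue
        left free by the variable assignment).

    The unmodified form is always counted.  All arithmetic is exact integer.
    """
    counts = _residue_counts(sequence_spec)
    if scheme not in ("variable_only", "offset_only", "hybrid"):
        raise ModelError(f"unknown scheme {scheme!r}")

    if scheme == "offset_only":
        n = 1
        for m in mods:
            if any(counts.get(r, 0) > 0 for r in m.residues):
                n += 1
        return n

    if scheme == "variable_only":
        var_mods, offsets = list(mods), []
    else:
        offsets = [m for m in mods if m.mod_class == "offset" and not m.is_zero]
        var_mods = [m for m in mods if m.mod_class != "offset"]

    # Per residue letter: how many variable mods may occupy an instance.
    letters = sorted(set(counts) | {r for m in var_mods + offsets for r in m.residues})
    applicable = {
        aa: sum(1 for m in var_mods if aa in m.residues) for aa in letters
    }

    if scheme == "variable_only" and max_var_mods is None:
        total = 1
        for aa in letters:
            total *= (1 + applicable[aa]) ** counts.get(aa, 0)
        return total

    # DP over residue letters.  State: (variable mods used, frozenset of
    # letters retaining >= 1 unmodified instance — only letters that some
    # offset targets need tracking).  Exact integer weights throughout.
    offset_letters = {r for m in offsets for r in m.residues}
    cap = max_var_mods if max_var_mods is not None else sum(counts.values())
    states: dict[tuple[int, frozenset[str]], int] = {(0, frozenset()): 1}
    for aa in letters:
        c = counts.get(aa, 0)
        m_aa = applicable[aa]
        if c == 0:
            continue
        new_states: dict[tuple[int, frozenset[str]], int] = {}
        for (used, free), weight in states.items():
            for k in range(0, min(c, cap - used) + 1 if m_aa else 1):
                ways = math.comb(c, k) * (m_aa**k)
                nf = free | {aa} if (k < c and aa in offset_letters) else free
                key = (used + k, nf)
                new_states[key] = new_states.get(key, 0) + weight * ways
        states = new_states

    total = 0
    for (used, free), weight in states.items():
        n_off = sum(1 for m in offsets if m.residues & free)
        total += weight * (1 + n_off)
    return total
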