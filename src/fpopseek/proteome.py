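"""Protein database handling: FASTA I/O, reversed decoys, tryptic digestion.

Digestion follows the "stricttrypsin" rule — cleavage C-terminal to K or R
with *no* proline exception — with up to 2 missed cleavages, peptide lengths
7–50, and N-terminal Met clipping (peptides are additionally generated from
the Met-clipped protein form, and protein N-terminal peptides are flagged as
eligible for N-terminal acetylation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import fasta as _pfasta

from .mod_model import (
    AA_MASS,
    CARBAMIDOMETHYL,
    MASS_WATER,
    ModelError,
    Modification,
    VALID_RESIDUES,
)

DEFAULT_DECOY_PREFIX = "rev_"


class ProteomeError(ValueError):
    """Raised for malformed databases or digestion parameters."""


@dataclass(frozen=True)
class ProteinEntry:
    accession: str
    description: str
    sequence: str
    is_decoy: bool = False
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ProteomeError(f"{self.accession}: empty sequence")


@dataclass
class Peptide:
    """A digested peptide with provenance and fixed-modification mass."""

    sequence: str
    parent_accessions: tuple[str, ...]
    missed_cleavages: int
    is_nterm_of_protein: bool
    mass: float
    is_decoy: bool = False


@dataclass(frozen=True)
class DigestionParams:
    """Enzyme rules.  Only stricttrypsin is supported (K/R, no P exception)."""

    enzyme: str = "stricttrypsin"
    max_missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 50
    clip_nterm_met: bool = True

    def __post_init__(self) -> None:
        if self.enzyme != "stricttrypsin":
            raise ProteomeError(f"unsupported enzyme {self.enzyme!r}")
        if self.max_missed_cleavages < 0 or self.min_length < 1:
            raise ProteomeError("invalid digestion bounds")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, contaminant_prefix: str = "CON_") -> list[ProteinEntry]:
    """Read a protein FASTA into :class:`ProteinEntry` records.

    The accession is the header token before the first whitespace; sequences
    are uppercased and ``'*'`` stop characters stripped.
    """
    path = Path(path)
    if not path.exists():
        raise ProteomeError(f"no such file: {path}")
    entries: list[ProteinEntry] = []
    with path.open() as fh:
        for header, seq in _pfasta.read(fh):
            header = header.strip()
            if not header:
                raise ProteomeError(f"{path}: record with empty header")
            accession, _, rest = header.partition(" ")
            seq = seq.upper().replace("*", "")
            if not seq:
                raise ProteomeError(f"{path}: record {accession!r} has no sequence")
            entries.append(
                ProteinEntry(
                    accession=accession,
                    description=rest,
                    sequence=seq,
                    is_contaminant=accession.startswith(contaminant_prefix),
                )
            )
    if not entries:
        raise ProteomeError(f"{path}: no FASTA records found")
    return entries


def write_fasta(entries: Sequence[ProteinEntry], path: str | Path, width: int = 60) -> None:
    """Write entries as FASTA with fixed line wrapping (byte-deterministic)."""
    with Path(path).open("w") as fh:
        for e in entries:
            header = e.accession if not e.description else f"{e.accession} {e.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i : i + width] + "\n")


def append_decoys(
    proteins: Sequence[ProteinEntry], prefix: str = DEFAULT_DECOY_PREFIX
) -> list[ProteinEntry]:
    """Append one full-sequence-reversed decoy per target protein.

    The output interleaves nothing: targets first, then decoys in the same
    order (stable pairing, output length exactly 2x input).
    """
    for p in proteins:
        if p.accession.startswith(prefix):
            raise ProteomeError(
                f"accession {p.accession!r} already carries decoy prefix {prefix!r}"
            )
    decoys = [
        ProteinEntry(
            accession=prefix + p.accession,
            description=p.description,
            sequence=p.sequence[::-1],
            is_decoy=True,
            is_contaminant=p.is_contaminant,
        )
        for p in proteins
    ]
    return list(proteins) + decoys


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def peptide_mass(
    sequence: str, fixed_mods: Iterable[Modification] = (CARBAMIDOMETHYL,)
) -> float:
    """Neutral monoisotopic peptide mass with fixed modifications applied."""
    m = MASS_WATER
    for aa in sequence:
        try:
            m += AA_MASS[aa]
        except KeyError:
            raise ModelError(f"unknown amino acid {aa!r} in {sequence!r}") from None
    for fm in fixed_mods:
        m += fm.mass_delta * sum(1 for aa in sequence if aa in fm.residues)
    return m


def _cleave(sequence: str, params: DigestionParams) -> list[tuple[str, int, int]]:
    """Fully tryptic peptides as (sequence, missed_cleavages, start)."""
    cuts = [0] + [i + 1 for i, aa in enumerate(sequence) if aa in "KR"]
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    out = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + params.max_missed_cleavages, len(cuts))):
            pep = sequence[cuts[a] : cuts[b]]
            if params.min_length <= len(pep) <= params.max_length:
                out.append((pep, b - a - 1, cuts[a]))
    return out


def digest(
    protein: ProteinEntry,
    params: DigestionParams = DigestionParams(),
    fixed_mods: Iterable[Modification] = (CARBAMIDOMETHYL,),
) -> list[Peptide]:
    """Digest one protein into search-ready peptides.

    When the protein starts with Met and clipping is enabled, peptides are
    additionally generated from the Met-clipped form; peptides that begin at
    the protein N-terminus (clipped or not) are flagged
    ``is_nterm_of_protein`` and thereby eligible for N-terminal acetylation.
    Duplicates by (sequence, missed cleavages) are collapsed.
    """
    seq = protein.sequence
    produced: dict[tuple[str, int], Peptide] = {}

    def _add(pep: str, mc: int, start: int) -> None:
        if any(aa not in VALID_RESIDUES for aa in pep):
            return
        key = (pep, mc)
        nterm = start == 0
        if key in produced:
            if nterm:
                produced[key].is_nterm_of_protein = True
            return
        produced[key] = Peptide(
            sequence=pep,
            parent_accessions=(protein.accession,),
            missed_cleavages=mc,
            is_nterm_of_protein=nterm,
            mass=peptide_mass(pep, fixed_mods),
            is_decoy=protein.is_decoy,
        )

    for pep, mc, start in _cleave(seq, params):
        _add(pep, mc, start)
    if params.clip_nterm_met and seq.startswith("M") and len(seq) > 1:
        for pep, mc, start in _cleave(seq[1:], params):
            _add(pep, mc, start)
    return list(produced.values())


def digest_database(
    proteins: Sequence[ProteinEntry],
    params: DigestionParams = DigestionParams(),
    fixed_mods: Iterable[Modification] = (CARBAMIDOMETHYL,),
) -> list[Peptide]:
    """Digest a whole (target+decoy) database, merging shared peptides.

    A peptide mapping to both target and decoy parents is kept as a target
    (standard competition convention); parent accessions are merged.
    """
    merged: dict[tuple[str, int], Peptide] = {}
    for prot in proteins:
        for pep in digest(prot, params, fixed_mods):
            key = (pep.sequence, pep.missed_cleavages)
            if key in merged:
                old = merged[key]
                old.parent_accessions = tuple(
                    dict.fromkeys(old.parent_accessions + pep.parent_accessions)
                )
                old.is_nterm_of_protein = old.is_nterm_of_protein or pep.is_nterm_of_protein
                old.is_decoy = old.is_decoy and pep.is_decoy
            else:
                merged[key] = pep
    return list(merged.values())
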