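"""Ground-truthed synthetic FPOP datasets: proteome, spectra, truth table.

The generator emulates the statistical structure of an in-vivo FPOP
experiment as it matters to the search problem, without modeling the
instrument: modified spectra are a minority of all spectra (default 20%),
Met oxidation is far more abundant than every other FPOP modification
(default 50x per modification type, inside the 26-90x band observed in
worm FPOP data), rare modifications are drawn from the built-in FPOP offset
table, and a small fraction of modified peptides (default 2%) carries two
rare modifications at once — the hybrid search's designed blind spot.

Spectra are rendered as charge-1 b/y ladders with Gaussian m/z jitter, peak
dropout, log-normal intensities and uniform noise peaks; precursors are
mass-accurate (the search assumes calibrated data).  Chromatography,
isotope envelopes and instrument-specific noise are out of scope.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give byte-identical FASTA/MGF
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mod_model import (
    AA_MASS,
    ACETYL_MASS,
    CARBAMIDOMETHYL,
    MASS_PROTON,
    MASS_WATER,
    Modification,
    load_fpop_table,
)
from .proteome import (
    DigestionParams,
    Peptide,
    ProteinEntry,
    append_decoys,
    digest_database,
    write_fasta,
)
from .spectra import Spectrum, write_mgf

#: Swiss-Prot-like amino-acid frequencies; K+R ~11% keeps tryptic peptides
#: of length 7-50 abundant.
AA_FREQUENCIES: dict[str, float] = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.054, "W": 0.011, "Y": 0.029, "V": 0.069,
}


class SyntheticDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------

def generate_proteome(
    n_proteins: int,
    mean_length: int = 300,
    seed: int = 0,
    fasta_path: str | Path | None = None,
) -> list[ProteinEntry]:
    """Random protein entries with realistic residue frequencies.

    Every protein starts with Met (so N-terminal Met clipping is exercised);
    lengths are normal around ``mean_length`` (sd = mean/5, floor 60).
    Deterministic per seed; optionally written as FASTA.
    """
    if n_proteins < 1:
        raise SyntheticDataError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_FREQUENCIES))
    probs = np.array(list(AA_FREQUENCIES.values()))
    probs = probs / probs.sum()
    entries = []
    for i in range(n_proteins):
        length = max(60, int(round(rng.normal(mean_length, mean_length / 5))))
        seq = "M" + "".join(rng.choice(letters, size=length - 1, p=probs))
        entries.append(
            ProteinEntry(
                accession=f"SYNP{i + 1:04d}",
                description=f"synthetic protein {i + 1}",
                sequence=seq,
            )
        )
    if fasta_path is not None:
        write_fasta(entries, fasta_path)
    return entries


# ---------------------------------------------------------------------------
# Modification planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerationProfile:
    """Relative abundances and structural fractions of planted modifications.

    ``metox_weight`` vs ``rare_weight`` sets the per-type draw odds of Met
    oxidation against each other FPOP modification type (default 50:1, in
    the observed 26-90x band).  ``modified_fraction`` is the fraction of
    spectra carrying any FPOP modification; ``double_rare_fraction`` (of
    modified spectra) plants two distinct rare modifications to exercise the
    hybrid method's blind spot.
    """

    modified_fraction: float = 0.2
    metox_weight: float = 50.0
    rare_weight: float = 1.0
    extra_common_prob: float = 0.4   # Met-ox spectra: chance of 2-3 ox sites
    common_with_rare_prob: float = 0.3  # rare spectra: chance of +1 Met-ox
    double_rare_fraction: float = 0.02
    acetyl_prob: float = 0.03        # protein N-term peptides only

    def __post_init__(self) -> None:
        if self.metox_weight < 0 or self.rare_weight < 0:
            raise SyntheticDataError("abundance weights must be >= 0")
        if self.metox_weight == 0 and self.rare_weight == 0:
            raise SyntheticDataError("abundance weights must not all be zero")


@dataclass
class GroundTruthRecord:
    """The true peptidoform behind one synthetic spectrum.

    ``mods`` holds (0-based site, mass delta, label) triples; site ``-1`` is
    the peptide N-terminus.  ``n_common`` counts Met-ox + acetyl instances,
    ``n_rare`` the rare FPOP modifications.
    """

    scan_id: str
    peptide: Peptide
    accession: str
    mods: tuple[tuple[int, float, str], ...]
    n_common: int
    n_rare: int
    charge: int = 0  # assigned at render time


def _rare_mod_types() -> list[Modification]:
    """The rare FPOP modification types the generator draws from.

    The oxidation row is split: oxidation on Met is the common modification;
    oxidation on the remaining residues is planted as one rare type.  The
    unadjusted di/trioxidation rows exclude Cys (generated Cys residues
    carry fixed carbamidomethylation, so oxidized Cys is represented by the
    carbamidomethyl-adjusted rows instead).
    """
    types = []
    for m in load_fpop_table():
        if m.name == "Oxidation":
            types.append(replace(m, residues=m.residues - {"M"}))
        elif m.name in ("Dioxidation", "Trioxidation"):
            types.append(replace(m, residues=m.residues - {"C"}))
        else:
            types.append(m)
    return types


METOX = Modification("Oxidation", 15.9949146221, frozenset("M"), mod_class="variable")


def plant_modifications(
    peptides: Sequence[Peptide],
    n_spectra: int,
    profile: GenerationProfile = GenerationProfile(),
    seed: int = 0,
) -> list[GroundTruthRecord]:
    """Draw true peptidoforms for ``n_spectra`` synthetic spectra.

    Rare modification types are drawn first from the profile weights and a
    peptide with an eligible free residue is then sampled, so realized type
    abundances track the configured weights.  Each modified peptide carries
    at most 3 common modifications and (unless in the double-rare fraction)
    at most one rare modification.
    """
    targets = [p for p in peptides if not p.is_decoy]
    if not targets:
        raise SyntheticDataError("no target peptides to plant on")
    rng = np.random.default_rng(seed)
    rare_types = _rare_mod_types()
    # eligibility pools
    with_m = [i for i, p in enumerate(targets) if "M" in p.sequence]
    rare_pool = {
        t.name: [
            i for i, p in enumerate(targets) if any(r in p.sequence for r in t.residues)
        ]
        for t in rare_types
    }
    usable_rare = [t for t in rare_types if rare_pool[t.name]]
    if not with_m and not usable_rare:
        raise SyntheticDataError("no peptide is modifiable under the profile")
    nterm_pool = [i for i, p in enumerate(targets) if p.is_nterm_of_protein]
    weights = np.array(
        [profile.metox_weight if with_m else 0.0]
        + [profile.rare_weight] * len(usable_rare)
    )
    if weights.sum() == 0:
        raise SyntheticDataError("profile weights exclude every plantable type")
    weights = weights / weights.sum()

    def _sites(p: Peptide, residues: frozenset[str], exclude: set[int]) -> list[int]:
        return [
            i for i, aa in enumerate(p.sequence) if aa in residues and i not in exclude
        ]

    records: list[GroundTruthRecord] = []
    for i in range(n_spectra):
        scan = f"scan={i:05d}"
        mods: list[tuple[int, float, str]] = []
        n_common = n_rare = 0
        if rng.random() < profile.modified_fraction:
            if rng.random() < profile.double_rare_fraction and len(usable_rare) >= 2:
                # two distinct rare mods on one peptide (hybrid blind spot)
                for _attempt in range(50):
                    ia, ib = rng.choice(len(usable_rare), size=2, replace=False)
                    ta, tb = usable_rare[int(ia)], usable_rare[int(ib)]
                    pool = sorted(set(rare_pool[ta.name]) & set(rare_pool[tb.name]))
                    if not pool:
                        continue
                    pep = targets[int(rng.choice(pool))]
                    sites_a = _sites(pep, ta.residues, set())
                    if not sites_a:
                        continue
                    site_a = int(rng.choice(sites_a))
                    sites_b = _sites(pep, tb.residues, {site_a})
                    if not sites_b:
                        continue
                    site_b = int(rng.choice(sites_b))
                    mods = [
                        (site_a, ta.mass_delta, ta.name),
                        (site_b, tb.mass_delta, tb.name),
                    ]
                    n_rare = 2
                    break
                else:
                    pep = targets[int(rng.choice(len(targets)))]
            else:
                k = int(rng.choice(len(weights), p=weights))
                if k == 0 and with_m:
                    pep = targets[int(rng.choice(with_m))]
                    msites = _sites(pep, frozenset("M"), set())
                    n_ox = 1
                    if len(msites) > 1 and rng.random() < profile.extra_common_prob:
                        n_ox = int(rng.integers(2, min(3, len(msites)) + 1))
                    chosen = rng.choice(msites, size=n_ox, replace=False)
                    for s in sorted(int(x) for x in np.atleast_1d(chosen)):
                        mods.append((s, METOX.mass_delta, "Oxidation"))
                    n_common = n_ox
                else:
                    t = usable_rare[k - 1 if with_m else k]
                    pep = targets[int(rng.choice(rare_pool[t.name]))]
                    site = int(rng.choice(_sites(pep, t.residues, set())))
                    mods.append((site, t.mass_delta, t.name))
                    n_rare = 1
                    free_m = _sites(pep, frozenset("M"), {site})
                    if free_m and rng.random() < profile.common_with_rare_prob:
                        s = int(rng.choice(free_m))
                        mods.append((s, METOX.mass_delta, "Oxidation"))
                        n_common = 1
        else:
            if nterm_pool and rng.random() < profile.acetyl_prob:
                pep = targets[int(rng.choice(nterm_pool))]
                mods.append((-1, ACETYL_MASS, "Acetyl"))
                n_common = 1
            else:
                pep = targets[int(rng.choice(len(targets)))]
        records.append(
            GroundTruthRecord(
                scan_id=scan,
                peptide=pep,
                accession=pep.parent_accessions[0],
                mods=tuple(sorted(mods)),
                n_common=n_common,
                n_rare=n_rare,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Spectrum rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Fragment-level noise: m/z jitter (Da, sd), peak dropout fraction,
    count of uniform noise peaks, log-normal intensity parameters."""

    mz_jitter_sd: float = 0.003
    dropout: float = 0.10
    n_noise_peaks: int = 10
    signal_log_mean: float = 9.2   # ~1e4 counts
    signal_log_sd: float = 0.5
    noise_log_mean: float = 6.9    # ~1e3 counts
    noise_log_sd: float = 0.7
    noise_mz_range: tuple[float, float] = (150.0, 1500.0)


def _true_residue_masses(rec: GroundTruthRecord) -> np.ndarray:
    seq = rec.peptide.sequence
    masses = np.array([AA_MASS[aa] for aa in seq])
    for i, aa in enumerate(seq):
        if aa in CARBAMIDOMETHYL.residues:
            masses[i] += CARBAMIDOMETHYL.mass_delta
    for site, delta, _label in rec.mods:
        masses[max(site, 0)] += delta
    return masses


def render_spectra(
    records: Sequence[GroundTruthRecord],
    noise_model: NoiseModel = NoiseModel(),
    seed: int = 0,
    mgf_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Render charge-1 b/y ladders of the true peptidoforms into spectra.

    Precursor m/z is exact for the true peptidoform mass (charge 2 below
    2400 Da, else 3); fragments get Gaussian jitter, Bernoulli dropout and
    log-normal intensities, plus uniform random noise peaks.  Writes MGF and
    a tab-separated truth table when paths are given; byte-deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    truth_rows = []
    for rec in records:
        masses = _true_residue_masses(rec)
        n = masses.size
        prefix = np.cumsum(masses)
        total = prefix[-1] + MASS_WATER
        charge = 2 if total <= 2400.0 else 3
        rec.charge = charge
        b = prefix[:-1] + MASS_PROTON
        y = total - prefix[:-1] + MASS_PROTON
        frag = np.concatenate([b, y])
        keep = rng.random(frag.size) >= noise_model.dropout
        frag = frag[keep]
        frag = frag + rng.normal(0.0, noise_model.mz_jitter_sd, frag.size)
        inten = rng.lognormal(
            noise_model.signal_log_mean, noise_model.signal_log_sd, frag.size
        )
        if noise_model.n_noise_peaks:
            lo, hi = noise_model.noise_mz_range
            nmz = rng.uniform(lo, hi, noise_model.n_noise_peaks)
            nint = rng.lognormal(
                noise_model.noise_log_mean, noise_model.noise_log_sd,
                noise_model.n_noise_peaks,
            )
            frag = np.concatenate([frag, nmz])
            inten = np.concatenate([inten, nint])
        spectra.append(
            Spectrum(
                scan_id=rec.scan_id,
                precursor_mz=(total + charge * MASS_PROTON) / charge,
                precursor_charge=charge,
                mz=frag,
                intensity=inten,
                retention_time=None,
            )
        )
        truth_rows.append(
            {
                "scan": rec.scan_id,
                "accession": rec.accession,
                "peptide": rec.peptide.sequence,
                "charge": charge,
                "mods": ";".join(
                    f"{site}:{delta:.6f}:{label}" for site, delta, label in rec.mods
                ),
                "n_common": rec.n_common,
                "n_rare": rec.n_rare,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["scan", "accession", "peptide", "charge", "mods", "n_common", "n_rare"],
    )
    if mgf_path is not None:
        write_mgf(spectra, mgf_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return spectra, truth


# ---------------------------------------------------------------------------
# End-to-end benchmark bundle
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkData:
    proteins: list[ProteinEntry]       # targets + appended decoys
    peptides: list[Peptide]            # digested target+decoy database
    records: list[GroundTruthRecord]
    spectra: list[Spectrum]
    truth: pd.DataFrame


def generate_benchmark(
    n_proteins: int = 50,
    mean_length: int = 300,
    n_spectra: int = 2000,
    seed: int = 42,
    profile: GenerationProfile = GenerationProfile(),
    noise_model: NoiseModel = NoiseModel(),
    digestion: DigestionParams = DigestionParams(),
    out_dir: str | Path | None = None,
) -> BenchmarkData:
    """The default ground-truthed benchmark: proteome + spectra + truth.

    Uses three decorrelated sub-seeds derived from ``seed`` for proteome
    generation, modification planting and rendering.  When ``out_dir`` is
    given, writes ``proteome.fasta`` (decoys appended), ``spectra.mgf`` and
    ``truth.tsv`` there.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    out_dir = Path(out_dir) if out_dir is not None else None
    proteins = generate_proteome(n_proteins, mean_length, seed=sub[0])
    with_decoys = append_decoys(proteins)
    peptides = digest_database(with_decoys, digestion)
    target_peps = [p for p in peptides if not p.is_decoy]
    records = plant_modifications(target_peps, n_spectra, profile, seed=sub[1])
    spectra, truth = render_spectra(
        records,
        noise_model,
        seed=sub[2],
        mgf_path=out_dir / "spectra.mgf" if out_dir else None,
        truth_path=out_dir / "truth.tsv" if out_dir else None,
    )
    if out_dir is not None:
        write_fasta(with_decoys, out_dir / "proteome.fasta")
    return BenchmarkData(with_decoys, peptides, records, spectra, truth)


# ---------------------------------------------------------------------------
# Recovery evaluation against ground truth
# ---------------------------------------------------------------------------

def _identified_mod_set(row: pd.Series) -> set[tuple[int, float]]:
    """(site, mass) pairs identified by a PSM row; N-terminus coded as -1."""
    out: set[tuple[int, float]] = set()
    am = row["assigned_modifications"]
    if isinstance(am, str) and am:
        for token in am.split(";"):
            sitestr, _, massstr = token.partition("/")
            if sitestr == "N-term":
                out.add((-1, round(float(massstr), 3)))
            else:
                out.add((int(sitestr[:-1]) - 1, round(float(massstr), 3)))
    if row["offset_label"] != "none":
        pos = int(row["offset_position"])
        out.add((pos, round(float(row["offset_mass"]), 3)))
    return out


def _true_mod_set(mods_str: str) -> set[tuple[int, float]]:
    out: set[tuple[int, float]] = set()
    if isinstance(mods_str, str) and mods_str:
        for token in mods_str.split(";"):
            site, delta, _label = token.split(":")
            out.add((int(site), round(float(delta), 3)))
    return out


def evaluate_recovery(psms: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join PSMs with ground truth and flag exact peptidoform recovery.

    ``correct_peptide`` requires the sequence to match; ``correct`` requires
    in addition the identified (site, mass) set to equal the planted one to
    3 decimals (an unlocalized offset therefore does not count as an exact
    recovery on a modified spectrum).
    """
    merged = psms.merge(
        truth, left_on="scan", right_on="scan", how="inner", suffixes=("", "_true")
    )
    if merged.empty:
        merged["correct_peptide"] = pd.Series(dtype=bool)
        merged["correct"] = pd.Series(dtype=bool)
        return merged
    merged["correct_peptide"] = merged["peptide"] == merged["peptide_true"]
    correct = []
    for _, row in merged.iterrows():
        if not row["correct_peptide"]:
            correct.append(False)
            continue
        correct.append(_identified_mod_set(row) == _true_mod_set(row["mods_true"]))
    merged["correct"] = correct
    return merged
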