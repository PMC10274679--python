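# Methods

## The hybrid search model

A peptidoform is a peptide sequence plus a concrete modification
assignment. `fpopseek` partitions the FPOP modification universe into
three classes:

* **fixed** — applied to every occurrence of a residue
  (carbamidomethyl-Cys, +57.021464 Da, by default);
* **variable** — enumerated combinatorially over all eligible sites, one
  modification per site, at most `max_var_mods` (default 3) per peptide,
  with optional per-modification caps (N-terminal acetylation is capped at
  1 and restricted to protein N-terminal peptides);
* **mass offsets** — a list of precursor-level mass shifts with residue
  specificities, of which **at most one** may apply to a peptide. The
  offsets list always contains a zero-mass sentinel, so unmodified and
  variable-only forms are always searched.

The searched space is therefore {variable-mod assignment} × {one offset or
none}, where a non-zero offset is admissible only if the peptide retains at
least one residue from the offset's specificity set that is not occupied by
a variable modification (one site carries one delta). Offsets are
unlocalized at candidate generation and localized after scoring. The
deliberate blind spot of this design is any peptide carrying two or more
rare (offset-class) modifications at once: such peptidoforms are not in
the space, and their spectra surface in the report's unexplained-delta
list when no admissible candidate explains the precursor.

`count_configurations` computes the exact size of these spaces with
integer arithmetic (a polynomial DP over residue classes for capped
variable counting; the hybrid scheme adds a DP over which offset-relevant
residue classes retain a free instance). `enumerate_peptidoforms`
materializes the same space explicitly, and the test suite asserts the two
agree case by case.

## The built-in FPOP offset table

The 14 built-in offsets cover the common hydroxyl-radical products:
oxidation (+15.9949, 16 target residues), di/trioxidation, carbonylation
(O − 2H), Arg deguanidation (−CH5N3 + O), His → Asp / His → Asn
conversions, His −10.0320 and +4.9735 products, decarboxylation (−CH2O),
CO and CO2 loss from Asp/Glu, and Cys di/trioxidation expressed **relative
to fixed carbamidomethylation** (an oxidized Cys cannot carry the alkyl
adduct, so the observable delta is the oxidation mass minus 57.021464,
i.e. −25.0316 and −9.0367). Masses are stored at full elemental precision
where the composition is known — required for the adjusted Cys arithmetic
to reproduce 4-decimal values — and at printed precision for the two His
products without a published composition. `adjust_offsets_for_fixed_mods`
performs the adjustment generically (an offset all of whose target
residues carry a fixed modification is re-expressed against it) and flags
adjusted offsets that collide within 0.0005 Da on the same residue set.

## Digestion and decoys

Digestion implements *stricttrypsin*: cleavage C-terminal to K/R with no
proline exception, ≤2 missed cleavages, peptide lengths 7–50. When a
protein starts with Met, peptides are additionally generated from the
Met-clipped sequence, and protein N-terminal peptides (clipped or not) are
flagged as eligible for N-terminal acetylation. Decoys are full sequence
reversals appended with a configurable `rev_` accession prefix; peptides
shared between target and decoy space are counted as targets.

## Scoring and localization

Spectra are preprocessed to the top 150 peaks above m/z 100. Theoretical
fragments are b/y ions at charges 1–2 (proton mass 1.00727646688). A
theoretical fragment is matched if at least one peak lies within the
fragment tolerance (±0.02 Da default); its matched intensity is the sum of
all peaks within tolerance. The PSM score is the hyperscore
`ln(Nb!·Ny!·max(1,ΣIb)·max(1,ΣIy))` with factorials capped at 20!,
rounded to 6 decimals so that mathematically equal scores computed in
different accumulation orders compare equal.

For a candidate with a non-zero offset, the offset is placed at each
eligible site in turn; fragments containing the site shift by the offset
mass (divided by fragment charge). The PSM takes the best placement's
score; the reported position degrades to "unlocalized" when two or more
placements tie within 1e-6 (e.g. symmetric sites with no distinguishing
fragments). Site rescoring is batched as one matrix search per candidate.

Rank-1 selection per scan is fully deterministic: ties on (score, matched
fragments) break by lexicographic peptide, then target before decoy, then
lower peptidoform id (mass-sorted order). PSMs with fewer than 4 distinct
matched fragments are not reported — a reporting floor analogous to
MSFragger's minimum matched fragments — because a zero-evidence PSM in a
sparsely populated FDR group would otherwise pass on precursor mass alone.

### Index structure and the equivalence contract

Candidate generation binary-searches the mass-sorted peptidoform table
once per allowed offset (`observed − δ ± tol`, 20 ppm default), with
offset specificity tested against a per-form bitmask of residues free of
variable modifications. Zero-offset candidates are scored through the
binned fragment-ion index (bin width 0.02 Da) by peak-centric
accumulation when the index fits `max_indexed_fragments` (default 5M
fragments); above that budget the engine scores candidates fragment-wise,
a reduction that is mathematically identical (same matched-fragment and
intensity sums) and faster at the low candidate densities a 20 ppm window
produces. The exhaustive `method="naive"` route — linear scan, per
candidate scoring — must produce identical rank-1 results, and the test
suite asserts frame-level equality on multi-seed instances of ≤500
peptidoforms.

## FDR control

Decoy-count q-values are computed per group: sort by descending score,
`FDR̂ = #decoys / max(1, #targets)` at each threshold (score ties share a
threshold), q = running minimum from the bottom. Groups are *unmodified*
(no variable mods, zero offset; fixed mods ignored), *assigned* (every
modification on the PSM matches the user's assigned list, default
`M:15.9949,n:42.0106`, 0.001 Da tolerance) and *other* (anything else,
including any unlisted offset). Group-based filtering applies the nominal
threshold (1% default) within each group independently; pooled
("regular") filtering is provided for comparison. Met oxidation defaults
to the assigned group because it also arises artifactually during sample
preparation and would otherwise inflate confidence in the rare-modification
group. Protein-level FDR and protein inference are out of scope.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure that stresses this search
problem, not the instrument:

* proteomes with Swiss-Prot-like residue frequencies (K+R ≈ 11%, so
  tryptic peptides of length 7–50 are abundant), every protein starting
  with Met; lengths normal around a mean of 300;
* modified spectra a minority — 20% by default (a declared default; the
  real modified fraction of in-vivo FPOP data is dataset-dependent);
* modification types drawn with Met oxidation weighted 50:1 against each
  other FPOP type, inside the 26–90× dominance band observed in worm
  in-vivo FPOP data; the type is drawn first and an eligible peptide
  second, so realized abundances track the weights;
* 40% of Met-ox spectra carry 2–3 oxidation sites; 30% of rare-offset
  spectra also carry one Met-ox (the configurations the hybrid scheme
  exists for); 2% of modified spectra carry two distinct rare offsets to
  exercise the blind spot. Di/trioxidation is not planted on Cys, whose
  oxidation is represented by the carbamidomethyl-adjusted offsets;
* spectra are charge-1 b/y ladders (precursor charge 2 below 2400 Da,
  else 3) with Gaussian m/z jitter (σ 0.003 Da), 10% fragment dropout,
  log-normal intensities and 10 uniform noise peaks; precursor masses are
  exact, matching the engine's assumption of calibrated data (instrument
  mass calibration is not modeled).

Not modeled: chromatography, isotope envelopes, charge-reduced or a/c/z
fragments, instrument-specific noise, co-isolation. Passing tests
therefore demonstrate the correctness and calibration of the search and
FDR machinery under a clean generative model, not performance on raw
instrument data.

All randomness derives from one integer seed (three decorrelated
sub-seeds for proteome, planting, rendering); outputs are byte-identical
per seed.

## Benchmark problem sizes

The default ground-truthed benchmark is 50 proteins (mean length 300,
~7600 target+decoy peptides, ~1.3M SS_H-II peptidoforms), 2000 spectra,
seed 42. FDR calibration pools 10 seeds of a smaller configuration (12
proteins, 400 spectra, the SS_H-I space) and checks that the wrong-peptide
fraction among passing PSMs stays within 1.5× the nominal 1% in every
group — "false" meaning a wrong peptide sequence, the quantity
target-decoy statistics estimate; site-level errors are assessed by the
localization tests instead.

## Known limitations

* Offsets are applied at most once and never co-located with a variable
  modification; genuinely multiply-rare-modified peptides are invisible by
  design.
* Isobaric placements (e.g. oxidation on two residues vs dioxidation on
  one, Leu/Ile swaps) are resolved by fragment evidence when present and
  by deterministic tie-breaking when not; no probabilistic localization
  score is attached.
* The q-value estimator is the plain decoy-count form without pi0
  correction; with very few PSMs in a group its resolution is limited
  (mitigated, not removed, by the matched-fragment reporting floor).
* Semi-enzymatic digestion, isotope-error correction and retention-time
  rescoring are not implemented.
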