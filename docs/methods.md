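# Methods

## Scope and model

`hlcur` treats variant interpretation as three composable layers:

1. **Candidate reduction** — set filters over an annotated variant
   table (gene panel, consequence class, population frequency).
2. **Categorical evidence combination** — ACMG/AMP criteria with
   per-code strength modifiers, combined by rule rather than by the
   Tavtigian point sum, because curation tables record criteria
   strings, not points.
3. **Structural mechanism triage** — geometry and stability
   measurements on protein models that justify (or withhold) the
   supporting in-silico criterion PP3 for missense variants.

The package consumes annotations (predictor scores, ΔΔG replicas,
secondary-structure and interface annotations) rather than computing
them: force-field energetics, homology-model construction and external
predictors are out of scope by design.

## Evidence combination

Codes count at their applied strength, so a single bucket tally
(VeryStrong, Strong, Moderate, Supporting per direction) drives the
tier. Two deliberate choices:

- **Hearing-loss panel addition.** `1 Moderate + ≥3 Supporting →
  Likely Pathogenic` is included alongside the generic combinations.
  Without it, criteria sets of the form (PM2, PM3_Supporting, PP3,
  PP4) — common in deafness curation, where the in-trans criterion is
  often downgraded — cannot leave VUS, contradicting expert-panel
  practice.
- **Benign evidence below the Likely Benign bar does not force VUS.**
  A lone downgraded benign code (e.g. `BS1_Sup`) coexists with a
  pathogenic classification; only a satisfied benign *combination*
  raises a conflict (→ VUS). BA1 is absolute and overrides all
  pathogenic evidence.

A code upgraded to VeryStrong (`PM3_VS`, `PP1_VS`) counts in the
VeryStrong bucket exactly like PVS1; two VeryStrong codes are
Pathogenic outright. The `_S` modifier always means Strong — on a
PVS base it is a downgrade, on a PP base an upgrade — never
Supporting (`Sup`/`Supporting` spell that strength).

Prior-assertion change semantics for the reclassification rate: a
single prior tier counts as changed iff the curated tier differs; dual
assertions ("Pathogenic/Likely pathogenic") and conflicting
interpretations count as changed whenever curation resolves them to
any single tier.

## Filtering

MAF thresholds are inclusive (≤ 0.01 recessive, ≤ 0.005 dominant,
config-exposed). A missing frequency means "not observed", which
cannot justify exclusion: such rows are kept and flagged. When a
case's inheritance model is unknown the looser recessive threshold
applies, logged. One frequency field (`af_global`) is used; the column
map can point it at any exported frequency column. All filters log
input/kept/excluded counts so row conservation is assertable.

## Structural evidence

- **Superposition** is closed-form least squares (SVD) over backbone
  atoms {N, CA, C, O} paired by author residue number; residues
  present in only one conformation are skipped, reflections are
  excluded, and collinear point sets are rejected as degenerate. The
  test suite cross-checks against an independent rotation-grid +
  simplex brute-force oracle.
- **Motile regions** are maximal runs (≥ 5 residues) of per-residue
  RMSD above a threshold; the automatic threshold is profile mean +
  2·SD. Only the resulting intervals, not a numeric cutoff, are
  conventionally reported, so the 2·SD rule is a package choice,
  config-exposed.
- **Side-chain distance** between residues is the minimum
  heavy-atom–heavy-atom distance over side-chain atoms (backbone
  excluded); glycine falls back to CA with a flag. Shell averages are
  arithmetic means of per-partner minima. The atom-level convention
  behind published shell averages is rarely stated; minimum heavy-atom
  distance is this package's convention, and comparisons to published
  averages should carry a tolerance of a few tenths of an Å.
- **Interface residues**: any heavy atom within 5 Å (default) of any
  ligand-chain heavy atom.
- **ΔΔG**: destabilizing iff the replica mean strictly exceeds
  1.6 kcal/mol (twice the force-field SD); five replicas per variant;
  sample (n−1) SD. Published mean±SD pairs are stored in summary form
  and replica-level operations degrade gracefully.
- **Burial proxy**: heavy-atom contact count within 8 Å of the
  side-chain centroid. It is a monotone core/surface separator, not a
  solvent-accessibility calculation; the surface cutoff (default 40
  contacts) is calibrated so a residue inside a compact synthetic
  globule fails the electrostatic gate while a peripheral one passes.

**Mechanism precedence** (LoF → interface → electrostatic surface →
stability → nonconclusive) encodes three judgments: contact with the
functional ligand dominates any other signal; a charge change only
perturbs the electrostatic surface if the side chain faces solvent
(a buried charge-changer with sub-threshold ΔΔG stays nonconclusive);
and proline gained or lost inside a helix is destabilizing even when
the force-field mean sits below threshold, since helix-breaking is
poorly captured by side-chain repacking energies.

PP3 is emitted at Supporting for conclusive missense mechanisms only.
LoF yields no code (truncating evidence is PVS1, supplied upstream —
no double counting), and BP4 is never emitted automatically:
withholding adverse computational evidence is a deliberate asymmetry,
since the triage heuristics are one-sided (they detect damage, they do
not certify harmlessness).

## Phenotype

PTA is the mean of thresholds at 0.5/1/2/4 kHz. Severity bins:
moderate 41–70, severe 71–95, profound > 95 dB HL; below 41 dB is
flagged below-range. The four audiogram shapes use a 15 dB
slope/flatness criterion (config-exposed) with precedence
high-frequency → low-frequency → U-shaped → flat; the clinical shape
names carry no standard numeric rule, so this is a package convention.
Whether PTA is better-ear or binaural is an input choice (`ear` field);
nothing downstream depends on it.

## Synthetic data

Generators are pure functions of (spec, seed), NumPy `default_rng`.

- **Cohort**: 32 probands by default, 62.5% carrying a spiked
  reportable variant, AR/AD split 50/50, 30 background variants per
  patient with MAF ~ Beta(0.2, 5) (mostly rare, a controlled fraction
  above threshold) and a consequence mix including synonymous and
  intronic decoys. Spikes are panel genes, kept consequences, MAF
  drawn below half the relevant threshold, with evidence whose
  combined tier is asserted at generation time. Trio pedigrees are
  consistent by default and can be made contradictory for
  negative-control cases. The generator emulates table structure and
  filter behavior, not sequencing error, linkage or annotation noise —
  passing recovery tests shows the pipeline logic is sound, not that
  real-exome performance is characterized.
- **Two-conformation helix**: ideal α-helix backbone (1.5 Å rise,
  100°/residue, CB pseudo-side-chains, 100 residues by default); the
  second conformation rigidly rotates the hinge residues (default
  20–30) about the helix axis by the hinge angle and adds Gaussian
  noise (default 0.1 Å). The motion is a clean step localized to the
  hinge, chosen analytically so that the mean+2·SD auto-threshold
  separates hinge from flank with margin at the default 30° angle.
  Real inter-conformation motion is smoother; the generator tests
  localization, not amplitude estimation.
- **ΔΔG sets**: Normal(μ, σ) replicas, five per variant.

Toy side chains are single CB pseudo-atoms, so every geometry
operation must (and does) work without full side chains; the glycine
CA fallback path is exercised by these models.

## Bundled fixtures

`fixtures/table2.tsv` (28 curated variants across 20 patients, with
criteria strings, prior assertions and post-curation tiers) and
`fixtures/table3.tsv` (20 synthetase variants with ΔΔG summaries,
expert-panel classifications and structural-effect labels) are
transcriptions of published curation tables; `lars2_domains.tsv`
carries the synthetase domain architecture with approximate residue
ranges (names and order exact); `panel183.txt` is a stand-in 183-gene
deafness panel (study genes plus filler symbols). The structural
annotation columns of the synthetase table (interface / helix /
exposed) encode statements made in the accompanying modeling analysis
rather than printed table columns. SHA-256 checksums are pinned in
`fixtures/manifest.json`; loading fails if a fixture is edited without
updating the manifest.

Two curated rows (the ACTG1 and the COL4A5 Gly1220Asp missense
variants) are printed Pathogenic but reach only Likely Pathogenic
under every standard reading of the combining rules; the engine
reports them as discordant by name rather than special-casing them.

## Numerical choices and degenerate inputs

- Altloc resolution: highest occupancy, tie → first encountered;
  first MODEL block only; insertion codes are part of residue
  addressing; no renumbering anywhere (author numbers throughout).
- Superposition requires ≥ 3 pairs and non-collinear sets.
- `ddg_classify` is strict at the threshold (1.6 is *not*
  destabilizing).
- Template screening is strict at both cutoffs (identity > 0.36,
  resolution < 2.5 Å; a 2.4 Å alternative is config-exposed).
- Percentages are stored at full precision and rounded only at render
  time (rates to one decimal, reclassification and mechanism
  percentages to integers).
- Empty evidence lists classify as VUS with a `no_evidence` flag;
  empty variant tables flow through filters and cases as empty, never
  as errors.

## Known limitations

- Mutant-side-chain geometry (rotamer rebuilding) is out of scope:
  distances involving the mutated residue's side chain cannot be
  reproduced, only wild-type shells.
- The formal-charge heuristic ignores histidine protonation and pKa
  shifts; the burial proxy is not solvent accessibility.
- Compound-heterozygous phase is an input (`phase_partner`), not
  inferred from reads.
- Segregation checking is contradiction-based; no likelihood/LOD
  support, and graded strengths for the cosegregation criterion (PP1)
  are accepted as input rather than derived from meiosis counts.
- The deposited motor-domain and synthetase models are not bundled;
  external-model measurements (e.g. shell averages on the deposited
  structures) run only if the user supplies the files.
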