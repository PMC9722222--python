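# Methods

## Scope and model

`covprep` prepares electrophilic ("covalent") ligands for docking engines
that support covalent constraints, and orchestrates the docking itself
behind a backend contract. The chemistry model is deliberately rule-based
and auditable: every decision a compound experiences (discard reasons,
applied normalizations, which warhead and reaction fired, which atom is
the link atom) is recorded, because in large-scale screening the failure
modes matter as much as the successes.

## Standardization

Stages run in a fixed order: element/species filter → null-structure
filter → largest fragment → normalization → canonical tautomer →
stereoisomer enumeration → microspecies. Consequences of that order worth
knowing:

* The element filter (allowed set H, C, O, N, S, P, B, F, Cl, Br, I; no
  isotopes; no radicals) runs **before** desalting, so salts with metal
  counterions (Na⁺, K⁺, …) are discarded outright as `nonstandard_element`.
  Salts of allowed elements (e.g. hydrochlorides) are desalted normally.
* A structure is "null" when its heavy-atom molecular weight is zero
  (atom-free SDF records are already caught by the reader).
* Largest fragment: most heavy atoms, ties broken by molecular weight,
  then by lexicographically smallest canonical SMILES. The second
  tie-break is why `C.N` keeps the ammonia fragment (N outweighs C).
* Normalization uses RDKit's published normalization transforms plus its
  uncharger; the charge-separated nitro form `[N+](=O)[O-]` is the
  canonical dialect. Wavy single-bond flags and undefined double-bond
  stereo are cleared to plain bonds.
* Tautomers: RDKit's scoring-based canonicalizer (aromatic rings scored
  above carbonyl, carbonyl above enol/hydroxyl), capped at 1000 tautomers;
  on enumeration blow-up the input passes through unchanged with a
  warning. pH does not influence tautomer choice; protonation is handled
  only at the microspecies stage.
* Stereoisomers: only **undefined tetrahedral** centers are enumerated —
  E/Z double bonds are not — in a depth-first order over centers sorted by
  canonical atom rank, clockwise tag before counter-clockwise. The cap
  (default 1000) therefore truncates deterministically: 9 undefined
  centers (512 isomers) is the largest complete case, 10 centers yield
  exactly 1000. Symmetric (meso) inputs can produce duplicate isomers;
  the count is defined over assignments, not unique structures.
* Microspecies at pH 7.4: a shipped SMARTS → (site, acid/base, nominal
  pKa) table (`data/pka_rules.tsv`). Acids with pKa < pH are deprotonated,
  bases whose conjugate acid has pKa > pH are protonated; everything else
  — thiols (8.3), phenols (10.0), anilines (4.6) — stays neutral at 7.4.
  The table covers carboxylic, sulfonic and phosphorus acids, tetrazoles,
  thiols, phenols, aliphatic amines, amidines/guanidines and aromatic
  amines; groups outside the table are untouched. This is a deterministic
  approximation, not a pKa predictor: conjugation effects, intramolecular
  interactions and polyprotic coupling are ignored (each phosphorus O–H
  match fires independently).

## Warhead knowledge base

`data/warheads.tsv` ships 68 warhead classes spanning Michael acceptors
(acrylamides and congeners, vinyl sulfones/sulfonamides/sulfonates,
nitroalkenes, maleimides, quinones, enals, fumarates), activated alkynes,
α-halo carbonyls and other SN2 electrophiles (including acyloxymethyl and
diazomethyl ketones), strained rings (epoxides, aziridines, epoxyketones,
β-lactams/lactones), reversible carbonyl electrophiles (aldehydes,
trifluoromethyl ketones, α-ketoamides/esters), activated nitriles, boron
acids/esters/benzoxaboroles, sulfur(VI) fluorides, acylating and
phosphorylating agents, SNAr heteroaryl halides and sulfur-exchange
warheads (disulfides, thiosulfonates). Each entry carries the residues it
can attack; summed over residues the library defines 98 residue-specific
reactions. Correctness lives in the data file, not the code: the loader
validates SMARTS compilation, residue vocabulary, id uniqueness and
reaction cross-references, and the test suite applies every reaction to a
representative molecule per warhead.

Two matching rules keep counts honest:

* symmetric SMARTS embeddings over the same atom set collapse to one
  occurrence (a disulfide matches once, not twice);
* `parent_id` links declare specificity: a match of a specific pattern
  (epoxyketone, enal, carbamate, …) suppresses overlapping matches of its
  generic parent (epoxide, aldehyde, aryl ester), so one functional group
  never counts as two warheads. Whether a vendor tool would instead
  discard such compounds as "multiple warheads" is unknowable from the
  outside; suppression was chosen because it keeps chemically reasonable
  single-warhead compounds.

Triage keeps a compound only when exactly one warhead matched exactly
once (`no_warhead` / `multiple_warheads` / `repeated_warhead` otherwise).
Warhead reactivity prediction is out of scope.

## Reaction and link atom

Reactions are SMIRKS transforms (editable TSV). Each grafts the residue
nucleophile carrying isotope label 13 — an arbitrary, transient marker —
onto the electrophilic carbon/boron/sulfur/phosphorus. After the
transform, fragments without the label (halide, phenol, sulfinate and
other leaving groups) are dropped; the product must contain **exactly
one** labelled atom, whose 1-based index becomes `Link_Atom` after the
label is cleared. Zero or two labels mean the reaction was ambiguous and
the record is discarded (`ambiguous_link_atom`).

Chemistry simplifications, applied uniformly: Michael additions give the
anti-Markovnikov β-adduct only; carbonyl additions give the tetrahedral
(hemiketal-type) adduct for all residues including Lys (no Schiff-base
dehydration); boron adducts are written as anionic tetrahedral boronates;
the nucleophile is written with implicit hydrogens completing valence —
the docking engine's covalent mode handles hydrogen bookkeeping when the
bond forms. New stereocenters created by the reaction are left undefined
at this 2D stage and enumerated at embedding, capped at two (2² = 4
isomers per input), matching the observation that reactions rarely create
more than one or two.

## Embedding

One conformer per stereoisomer via RDKit's ETKDGv3 distance-geometry
embedder (seeded; up to five retries with perturbed seeds). Heavy-atom
order is preserved through AddHs/RemoveHs, so `Link_Atom` stays valid in
the 3D SDF. Single input conformers suffice because pose-search engines
sample torsions internally; no force-field refinement is applied beyond
the embedder default.

## Docking orchestration

The configuration writer emits plain `key = value` files with a covalent
block (covalent flag, protein link-atom serial, ligand link-atom number),
the scoring-function keyword (GoldScore, ASP, ChemScore or PLP — exactly
four options) and the pose count. The key names live in one mapping
(`CONF_KEYS`) so users can re-dialect them for a specific engine version.
Jobs are partitioned into `n_shards` balanced shards (sizes differ by at
most one, contiguous in input order); each shard is an independent command
writing to shard-private files, suitable for any scheduler.

Backends implement `dock(conf_path, ligand_path) -> [PoseResult]`. The
external-engine backend shells out to `gold_auto` when installed. The
**mock backend** rigidly rotates the ligand (uniform random quaternion)
and places its link atom at a seeded 1.6–2.4 Å from the protein link atom;
score = −distance + N(0, 0.1) noise. The per-ligand RNG is seeded by
`crc32(ligand_id) XOR seed`, so results are reproducible and independent
of shard composition. Mock poses exercise every contract of the pipeline
(geometry, ordering, determinism, failure accounting) but are physically
meaningless; nothing about real binding can be concluded from them.

`process` merges protein (minimal TRIPOS mol2 parser: ATOM / BOND /
SUBSTRUCTURE records, serials taken verbatim) and pose, adds exactly one
single bond between the configured link atoms, and removes one explicit
hydrogen per endpoint when the new bond would exceed default valence
(e.g. the cysteine HG). Coordinates are never altered and no geometry
relaxation is attempted at the new bond. The classical-docking filter
keeps poses whose reactive-atom distance is ≤ 5 Å by default.

## Screening metrics

AUC is computed as the midrank Mann–Whitney statistic — exactly the
probability that a random active outranks a random inactive with ties
counting ½ — and is cross-checked in the tests against a brute-force
pairwise oracle (≤ 1e-12) and an independent library implementation.
EF(f) uses a top set of ⌈fN⌉ compounds with threshold ties broken by
ligand id; EF(1) ≡ 1. BEDROC/RIE and bootstrap confidence intervals are
not provided.

## Synthetic fixtures

The toy library is templated, not random: acrylamide anilides (labelled
active), chloroacetamide anilides (decoys — in covalent screening decoys
are warhead-bearing inactives, since warhead-free compounds never reach
docking), an amine hydrochloride salt whose desalted parent has no
warhead, an isotope-labelled acrylamide, a bis-electrophile
(acrylamide + chloroacetamide), a bis-acrylamide and an organosilane.
Para-substituents are drawn from a seeded RNG so fixed seeds give
byte-identical SDF output. Every record's fate is declared in a manifest
and verified end-to-end (the default 15-record library yields 10 kept
compounds and 5 discards, one per adversarial class). The toy protein is
a single capped cysteine written as mol2 with SG at the origin (serial 4)
and an explicit HG; pose fixtures place a small thioether adduct at exact
distances (4.2 Å / 6.1 Å) for the filter tests. None of this emulates
realistic binding-site geometry — passing tests demonstrate pipeline
correctness, not docking accuracy.

## Problem sizes and limitations

The shipped test and acceptance runs use the 15-record library, 10-ligand
docking campaigns with 2 poses in 4 shards, 100-instance metric checks and
≤ 1000-isomer enumerations — sizes chosen so the whole suite verifies the
full contract in seconds while remaining representative of per-compound
behaviour at scale (each compound is processed independently, so scale-out
is linear and handled by sharding).

Known limitations: no pKa prediction or tautomer energetics; tetrahedral
stereo only; single-conformer output; no warhead reactivity or
reaction-energy model; no re-implementation of any scoring function; the
hydrogen treatment at the new covalent bond is pure bookkeeping. The mock
backend validates orchestration, never docking quality.
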