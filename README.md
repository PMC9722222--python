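# covprep

Automated ligand preparation and docking orchestration for **covalent
virtual screening**.

Covalent inhibitors bind their target through a chemical bond between an
electrophilic group on the ligand (the *warhead*) and a nucleophilic
protein residue — most often a cysteine thiol. Docking such compounds with
a conventional engine requires, per ligand, knowing *which* warhead it
carries, what the post-reaction adduct looks like, and *which atom* of that
adduct (the *link atom*) bonds to the protein. Doing this by hand does not
scale to libraries of thousands of electrophiles. `covprep` automates the
whole chain:

1. **Standardization** — element/isotope/radical filtering, desalting,
   mesomer normalization (nitro written charge-separated), neutralization,
   canonical tautomer, enumeration of undefined tetrahedral stereocenters
   (up to 1000 isomers, i.e. complete through 9 undefined centers), and
   rule-based major-microspecies assignment at pH 7.4.
2. **Warhead triage** — substructure search against a shipped,
   user-editable library of **68 electrophilic warheads** annotated with
   the nucleophilic residues they attack (Cys, Lys, Ser, Tyr, Thr, Asp,
   Glu). Compounds are kept only if they carry **exactly one warhead
   exactly once**; everything else is discarded with an explicit reason.
3. **Covalent reaction** — one of **98 residue-specific SMIRKS
   transforms** converts the warhead into its adduct form, grafting on the
   residue nucleophile (S for Cys, O for Ser/Thr/Tyr/Asp/Glu, N for Lys)
   with a transient isotope label. The unique labelled atom defines the
   1-based link-atom index written to the output SDF (`Link_Atom` field).
4. **3D embedding** — distance-geometry embedding with
   experimental-torsion preferences, enumerating up to **two**
   stereocenters created by the reaction (2² = 4 isomers).
5. **Docking orchestration** — per-ligand GOLD-style covalent
   configuration files (four scoring-function options: GoldScore, ASP,
   ChemScore, PLP), balanced job shards for parallel execution, a
   deterministic **mock backend** so the full loop runs without the
   proprietary engine, and a `process` step that fuses each docked pose
   with the protein by adding the single covalent bond. A classical-docking
   shortcut filters noncovalent poses on the reactive-atom distance
   (default cutoff 5 Å).
6. **Screening metrics** — rank-based ROC AUC (ties count ½) and
   enrichment factors EF(f) = (actives in top ⌈fN⌉ / ⌈fN⌉) ÷ (actives / N).

## Worked example

```bash
covprep fixtures --out work --seed 7
covprep prepare --in work/toy_library.sdf --residue CYS \
    --out work/prepared.sdf --discards work/discards.csv
covprep embed --in work/prepared.sdf --out work/prepared3d.sdf --seed 7
covprep dock prepare --ligands work/prepared3d.sdf \
    --protein work/toy_protein.mol2 --residue A:CYS:25:SG \
    --sf PLP --shards 4 --output-dir work/dock
covprep dock run --commands work/dock/commands.txt --backend mock --seed 7 \
    --out work/poses.sdf
covprep dock process --poses work/poses.sdf --out work/complexes.sdf \
    --protein work/toy_protein.mol2 --residue A:CYS:25:SG
```

This prints:

```
15 ligand records -> work/toy_library.sdf
toy protein -> work/toy_protein.mol2 (SG atom serial 4)
10 post-reacted ligands; 5 compounds discarded
embedded 10 structures; 0 failures
10 ligand jobs in 4 shards; commands in work/dock/commands.txt
20 poses; 0 ligand failures
20 covalent complexes written to work/complexes.sdf
```

The 15-record toy library contains 10 single-warhead compounds (5 labelled
active, 5 decoys) and 5 adversarial records; the 5 discards are, by
construction, one organosilane (nonstandard element), one isotope-labelled
compound, one amine salt whose parent carries no warhead, one
bis-electrophile (two different warheads) and one bis-acrylamide (same
warhead twice). Each of the 10 survivors is converted to its cysteine
thioether adduct (link atom S), docked twice by the mock backend against
the toy protein's CYS25 SG, and fused into a covalent complex — one
complex per pose, each with exactly one new S–S bond.

Scoring a ranked library:

```bash
covprep metrics --in scores.csv --ef 0.2
# AUC = 0.7500
# EF(0.2) = 5.0000
```

## Layout

| module | role |
| --- | --- |
| `covprep.standardizer` | filters, normalization, tautomers, stereo enumeration, pH-7.4 microspecies |
| `covprep.warheads` | warhead library loading, residue-aware detection, one-warhead triage |
| `covprep.reactor` | SMIRKS transforms, link-atom labelling, annotated SDF output |
| `covprep.conformers` | 3D embedding with reaction-born stereocenter enumeration |
| `covprep.gold_bridge` | conf files, sharding, backends (mock / external engine), complex assembly, distance filter |
| `covprep.vs_metrics` | AUC and enrichment factors |
| `covprep.fixtures` | synthetic toy library, toy protein, geometric pose fixtures |

The warhead and reaction knowledge bases are plain TSV files under
`src/covprep/data/` and are meant to be extended by users; the loader
validates SMARTS/SMIRKS, residue assignments and cross-references at load
time.
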