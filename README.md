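# paedomains

Domain-architecture inference from AlphaFold2 outputs for multidomain
proteins.

AlphaFold2 produces two artefacts for a query sequence: a structural model
whose B-factor column carries the per-residue confidence score pLDDT
(0–100), and an N×N predicted aligned error (PAE) matrix, where entry
e(i, j) is the expected positional error (Å) of residue *i* when model and
truth are aligned on residue *j*. Read together they encode the domain
organisation of the protein: structured domains are high-pLDDT runs,
intrinsically disordered regions are low-pLDDT runs, rigid units appear as
dark low-error squares on the PAE diagonal, and low off-diagonal blocks
flag pairs of domains immobilised against each other by interdomain
contacts. Structural biologists usually read these plots by eye;
`paedomains` turns that reading into a reproducible, parameterised
algorithm, developed around the 17-member human PARP family, where it
captures features such as split domains (one spatial unit built from two
sequence segments separated by a long insertion, e.g. split RWD and KH
domains) and state-dependent rigidity (PARP1's beads-on-a-string collapse
on DNA-break binding).

## Method

Given one chain's model and PAE matrix:

1. **Segmentation** — pLDDT is median-smoothed (window 9) and thresholded
   at 70; structured runs < 10 residues are dropped, interior disordered
   gaps < 4 residues absorbed. Structured segments are then recursively
   bisected at the PAE cut point maximising
   `median(cross-block) − mean(intra-block medians)`, accepting cuts with
   gain ≥ 5 Å and both halves ≥ 25 residues.
2. **Rigidity** — the asymmetric PAE is symmetrised (elementwise min);
   structured segments are clustered by average-linkage on the median
   symmetrised cross-PAE, and the dendrogram is cut twice: at
   τ_domain = 5 Å for domain-level units and τ_assembly = 10 Å for larger
   rigid assemblies (the two partitions are nested by construction).
3. **Domain calls** — each domain-level unit becomes one call; calls whose
   ranges are separated by an insertion ≥ 30 residues are flagged *split*
   and labelled with quarter fractions ("¾", "¼"). Every unordered pair of
   domains gets a contact score (median symmetrised cross-PAE); pairs
   scoring ≤ τ_contact = 12 Å are called in contact.
4. **Labelling** — optional: a call is superposed on a user-supplied
   reference structure by iterative core Cα superposition (Kabsch fit,
   reject pairs deviating > 2 × RMSD, ≤ 5 cycles, core ≥ 30% of input),
   attaching a homology label with its core RMSD and core size.
5. **Mobility** — per-residue crosspeak intensities from two NMR states
   are normalised by the median over disordered-linker residues per state;
   each domain's bound/free median ratio classifies it mobile (≥ 0.5),
   immobilized (≤ 0.2) or intermediate.

A synthetic-data module generates AF2-style models, PAE matrices and
intensity tables with planted ground truth so the whole pipeline is
testable with no downloads.

## Worked example

Simulate the default benchmark chain (445 residues: domains A 1–110 and
C 346–445, split domain B 141–230 + 276–320, A and B rigidified into one
assembly), then annotate it:

```bash
paedomains simulate --spec spec.json --out-prefix demo --immobilized A,B
paedomains annotate --model demo.pdb --pae demo.pae.json --out demo.arch.json
# demo: 3 domains (1 split), 3 disordered regions, 1 contacts -> demo.arch.json
paedomains diagram --arch demo.arch.json --out demo.svg
```

The architecture JSON shows the planted layout recovered within a couple
of residues — D1 = 1–109, D2 = 142–231 + 277–319 with `"split": true` and
part fractions 0.68/0.32 (displayed ¾/¼), D3 = 347–445 — and a single
contact call between D1 and D2 (median cross-PAE ≈ 5.5 Å ≤ 12), matching
the planted assembly. Classifying mobility from the simulated two-state
intensity table (A and B immobilized on ligand binding):

```bash
paedomains mobility --free demo.intensity.tsv --arch demo.arch.json
# D1           ratio= 0.159  class=immobilized       n=99
# D2           ratio= 0.057  class=immobilized       n=123
# D3           ratio= 0.972  class=mobile            n=83
```

i.e. the domains scaled to ~10% intensity in the bound state are called
immobilized, the spared domain mobile. Superposition is exposed the same
way (`paedomains superpose --mobile a.pdb --target b.pdb --mode core`
prints `rmsd=… n_core=… n_input=…`).

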