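# Methods

## What the pipeline models

The pipeline treats an AlphaFold2 prediction as two coupled observables on
one chain of length N: a per-residue confidence profile pLDDT ∈ [0, 100]
and a PAE matrix e(i, j) ≥ 0 (Å). The working assumptions are the ones
structural biologists use when reading these plots:

- sustained high pLDDT marks folded structure, sustained low pLDDT marks
  intrinsic disorder;
- residues that are rigid relative to each other have mutually low PAE
  regardless of sequence separation, so rigid units appear as low-error
  blocks and flexibly linked units as high-error blocks;
- PAE is asymmetric (aligning on i and scoring j is not the same as the
  reverse); it must be symmetrised before use as a dissimilarity;
- a low off-diagonal block between two domains predicts an interdomain
  contact that immobilises them against each other.

The pipeline makes no claim about which ligand state a model represents:
predicted models can reflect conformations sampled only in the presence
of ligands (the PARP1 matrix, for instance, resembles the DNA-bound
state), so the output reports what the matrix says and leaves state
interpretation to the user — that question is exactly what the NMR
mobility module addresses with experimental data.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `plddt_cutoff` | 70 | conventional "low confidence" boundary of the AFDB colour scale |
| `window` | 9 residues | running-median width; removes single-residue confidence spikes without eroding ~10-residue elements |
| `min_struct` | 10 residues | shorter high-confidence islands are residual secondary-structure propensity, not domains, and are not annotated |
| `min_gap` | 4 residues | interior low-confidence dips shorter than this are absorbed (loops, not linkers) |
| `split_gain` | 5 Å | PAE bisection gain needed to cut a structured segment; keeps rigid subdomain pairs (cross ≈ intra + 3 Å, e.g. an HD–ART catalytic unit) merged while flexibly linked domains (cross ≥ intra + 9 Å) split |
| `min_subsegment` | 25 residues | smallest half a PAE cut may produce |
| `tau_domain` | 5 Å | dendrogram cut for domain-level units |
| `tau_assembly` | 10 Å | dendrogram cut for rigid assemblies |
| `tau_contact` | 12 Å | median cross-PAE at or below which a domain pair is called in contact |
| `symmetrize` | min | elementwise min of e(i,j), e(j,i); mean available |
| `min_insertion` | 30 residues | smallest sequence gap that makes a multi-range call a split domain; separates genuine long insertions from unmodelled inter-subdomain connectors |
| `max_cycles`, `kappa`, `min_core_frac` | 5, 2.0, 0.3 | core superposition: reject pairs deviating > κ·RMSD, at most 5 cycles, never below 30% of input pairs |
| mobility `hi`, `lo` | 0.5, 0.2 | bound/free ratio thresholds for mobile / immobilized; published intensity-profile analyses are qualitative, so these are conventions, CLI-exposed |

Median statistics are used throughout (segment dissimilarity, contact
score, per-domain intensity ratio) because the near-diagonal low-error
band, single flexible residues and single unassigned peaks must not move
a call. Average linkage is used rather than single linkage because single
linkage chains sequence-adjacent units together through the near-diagonal
band. Clustering ties are broken deterministically (clusters ordered by
lowest member start), and the whole pipeline is a pure function of its
inputs and parameters — identical inputs give byte-identical outputs.

The published visual analyses this pipeline mechanises threshold "dark
green" by eye and give no numeric cutoffs; the defaults above were fixed
by requiring correct recovery on the synthetic suite and are all exposed
as CLI flags, so boundary calls near the thresholds may differ from a
visual annotation by a few residues.

## Synthetic data: what it emulates and what it does not

`synthetic.SyntheticSpec` lays out domains and linkers along a chain,
declares sets of domains as mutually rigid assemblies, and plants split
domains by listing one domain in two non-adjacent elements. Generated
observables:

- **Geometry** — a Cα trace with 3.8 Å steps; each domain is a
  self-avoiding walk (3.0 Å clash distance, dead ends escaped by
  backtracking) confined to a sphere of radius 2.5·L^⅓ Å, the empirical
  size scaling of globular domains; both segments of a split domain share
  one sphere. Linkers are extended random walks; the insertion inside a
  split domain is distance-biased to return to the domain sphere, since
  an unbiased walk would strand the chain far from it.
- **pLDDT** — Normal(88, σ) in domains, Normal(40, 5σ/3) in linkers
  (disordered confidence is empirically noisier), clipped to [0, 100],
  with a 3-residue taper across boundaries. Default σ = 6: separates the
  two populations by ≈ 4 linker standard deviations, comparable to a
  well-predicted real protein, while leaving occasional sub-threshold
  residues inside domains.
- **PAE** — expected value 3 Å within a domain, 6 Å between domains of
  one assembly, 12 + 0.05·|i−j| Å otherwise; |i−j| ≤ 4 forced ≤ 4 Å
  (the near-diagonal band always present in real matrices — without it
  change-point detection would be unrealistically easy); independent
  noise for (i, j) and (j, i) (σ = 1 Å, doubled on the ramp), clipped to
  [0, 31.75], zero diagonal. Default pae σ = 1 Å puts roughly one noise
  standard deviation between the domain/assembly levels and three between
  assembly and ramp, mirroring how crisp real rigid blocks are against
  how fuzzy contact blocks are.
- **Intensities** — free state ≈ 1 everywhere; bound state scaled by
  U(0.05, 0.15) per immobilized domain and U(0.8, 1.0) otherwise;
  multiplicative log-normal noise (σ = 0.1); 10% of residues masked "NA"
  (unassigned), as in real partially assigned spectra.

All draws flow from per-call generators seeded from the spec's seed, so
identical spec + seed gives bit-identical outputs.

Deliberately **not** emulated: real secondary structure or packing,
sequence–structure consistency, pLDDT/PAE correlation with local geometry,
gradual rigidity (every pair is exactly domain-, assembly- or ramp-level),
and spectral artefacts beyond uniform masking. Passing the synthetic suite
therefore shows the algorithms recover planted block structure under
realistic noise; it does not show that the default thresholds are optimal
for any particular real protein family, which is why the experimental
anchor tests (PARP13 MZAP vs its experimental structure, PARP4 ITIHL vs
ITIH1, the PARP4 MVPID call) exist, fetching reference files at run time
when the network allows.

## Numerical choices and degenerate inputs

- Kabsch superposition uses SVD with the standard determinant correction
  (reflections forbidden); < 3 pairs or collinear inputs raise a
  degenerate-input error. The test suite checks the RMSD against an
  independent quaternion closed form (largest eigenvalue of the 4×4 key
  matrix) to 1e-6 over 1,000 random point sets.
- Core refinement stops on convergence, cycle limit, core floor, or if a
  refit fails to tighten; the reported RMSD/n_core always describe the
  final retained core.
- Residue pairing for superposition defaults to global BLOSUM62 alignment
  (gap open −11, extend −1); an explicit pairs table overrides it for
  remote homologs where sequence alignment is unreliable.
- B-factors outside [0, 100] are clipped with a warning (non-AFDB files);
  residues without Cα are skipped with a warning; author residue
  numbering is never altered.
- PAE JSON without a ceiling defaults to 31.75 Å (AFDB convention).
- An all-disordered chain yields an architecture with zero domains; a
  single structured segment yields one domain and no contacts.
- Part fractions of split domains are stored exactly; the quarter glyphs
  ("¾", "¼") are display-only rounding.

## Problem sizes

The packaged benchmarks use 445-residue chains (50 seeds) for recovery,
1,000 point sets for the superposition oracle, 100 instances per
structural-invariant sweep and 10 seeds × 5 domains × 2 states for
mobility — sizes at which every statistic is stable to well within its
acceptance margin while the whole suite runs in well under a minute.

## Known limitations

- Domain boundaries are change points in smoothed profiles; boundaries of
  domains shorter than `min_struct` or separated by linkers shorter than
  `min_gap` are invisible by construction.
- Contact calls measure predicted relative immobilisation; they cannot
  distinguish a physical interface from coordinated motion, and say
  nothing about binding energetics.
- Homology labels come only from user-supplied references and pairings;
  there is no fold search.
- The PAE ramp treats all flexible pairs alike; real matrices show richer
  intermediate structure (partial occupancy, multi-state models) that the
  clustering collapses onto one of three levels.
- Reference core-atom counts depend on the rejection rule of whichever
  tool produced them; counts from interactive viewers with undisclosed
  refinement are matched only approximately.
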