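# Methods

## Scope and model

The toolkit operates on human VH3–Vk1 Fv domains only. Its central objects
are (i) a position-labelled Fv (`NumberedFv`), (ii) two disjoint paratope
position sets (H-side = HCDR1+HCDR3+LCDR2, L-side = LCDR1+LCDR3+HCDR2,
each optionally extended by framework "enhancing" residues), and (iii) a
scaffold rule set encoding the stability and HCDR3-conformation
constraints. Everything else — merging, library design, compliance audits —
is set algebra and positional substitution over that frame.

## Numbering

Numbering is template-alignment based, not profile-HMM based: the platform
deliberately restricts itself to VH3/Vk1-like domains, so a global
alignment (BLOSUM62, affine gaps open 11 / extend 1, Biopython
`PairwiseAligner`, first traceback) against embedded consensus templates is
sufficient and fully deterministic. The templates are VH3-23-like (113
residues) and Vk1-39-like (107 residues) consensus sequences; their
residues carry the contiguous label frames H1–H113 and L1–L107. This frame
is deliberately simplified relative to historical Kabat tabulations: the
template itself has no constitutive insertion codes, and insertion codes
arise only when a query is longer than the template.

Length differences are absorbed at permitted anchors only (H35, H52, H82,
H100; L27, L95, L106 — the canonical insertion points). Each chain is cut
into seven segments (four frameworks, three CDRs); after alignment, every
query residue is assigned to a segment, with insertion runs on a segment
boundary attributed to the adjacent elastic segment. Within an elastic
segment of template length m holding n query residues:

* n = m → plain labels in order;
* n > m → labels up to the anchor, then `anchorA`, `anchorB`, …, then the
  remaining plain labels (e.g. one extra HCDR3 residue becomes `100A`);
* n < m → the d = m − n labels counting back from the anchor are skipped
  (a one-short HCDR3 lacks label 100 while 101 — the invariant Asp — stays).

A required indel in a rigid segment is an error ("insertion at a
non-permitted anchor"), as is framework identity below 55% — the numberer
refuses rather than guesses. Ties in gap placement are resolved by the
canonicalisation itself, which always places indels at the segment anchor.

CDR boundary tables (Kabat, Chothia, Contact, in the template label frame)
are shipped constants with an override hook; the `union` scheme takes, per
CDR, the union of the three ranges and is the default for paratope
resolution, since the platform diversifies every position any definition
calls CDR. An insertion-coded label belongs to the region covering its
integer anchor.

## Paratopes and rules

Enhancing extents default to H1–H7 and H71–H78 (H-side), L1–L7 and L66–L71
(L-side). The published design marks these regions only graphically, so the
ranges were chosen once to cover the engineered N-terminal positions (Vk3,
Vk5, Vk7) and the outer loops that pack against CDR1, and are
config-overridable. Disjointness of the resolved H-side and L-side sets
(with and without enhancing, under every scheme) is asserted by tests; it
holds for all shipped boundary tables.

Default rules: singletons at H35/H50/L34/L91 (identities taken from the
templates, since the exact scaffold identities are not published in
machine-readable form — the rule set is a YAML config for users who have
them), H94 ∈ {R, K}, H101 = D, H99 ∈ {Y, F}, L49 ∈ {Y, F}. A rule whose
label is absent from a frame is recorded as inapplicable and fails the
audit unless the rule set is configured lenient.

## Merging

The merge substitutes, into the scaffold, every resolved H-side position of
the H-side binder and every resolved L-side position of the L-side binder;
each side's resolved set is computed on that binder, so the H-side binder
dictates the merged HCDR3 length and the L-side binder the light-CDR
lengths. Strict mode rejects binders that deviate from the scaffold at
framework positions (outside both paratopes); deviations inside the
*opposite* paratope are ignored rather than rejected — this is what makes
the merge idempotent (merging a merge output with itself reproduces it) and
lets previous merge outputs be reused as inputs. Lenient mode downgrades
framework deviations to warnings with the scaffold winning. Provenance is
recorded per (chain, label) as scaffold / H-binder / L-binder.

Point mutations use the grammar `chain:wt+label+new` (`L:Q3Y`,
`H:G100AY` → label 100A) with wild-type verification and duplicate
detection.

## Libraries

A library spec maps diversified positions to amino-acid alphabets;
validation enforces side ownership (a position must lie in the side's
resolved set) and the scaffold rules (an alphabet at a rule position must
be a subset of the allowed set). Diversity is the exact integer product of
alphabet sizes — amino-acid combinations, not codons; degenerate-codon
design is out of scope. Sampling is uniform per position (no positional
priors are published) from numpy's PCG64 generator with an explicit integer
seed recorded in member ids; equal seeds give byte-identical FASTA.
Maturation specs freeze the opposite paratope (validated) and can revert
framework positions outside both paratopes and outside the enhancing
ranges to template identity, leaving the outer loops free to deviate.

## Structure analyses

* **SASA** — Shrake–Rupley with a golden-spiral point lattice; per atom,
  the exposed fraction of m points on the sphere of radius r_i + w times
  4π(r_i + w)². Defaults: probe w = 1.4 Å, m = 960 points, radii C 1.70 /
  N 1.55 / O 1.52 / S 1.80 Å (config-overridable); hydrogens and waters
  stripped on reading. Tests pin the implementation to the isolated-sphere
  closed form (exact), the two-sphere analytic cap formula and a dense-point
  recomputation (≤ 1%), a 960-vs-10000-point convergence bound (≤ 2%),
  rigid-motion invariance, and biotite's independent implementation (≤ 1%).
* **Footprints** — buried(A) = SASA(A alone) − SASA(A in A∪B), computed per
  residue and clamped only for numerical dust (>−10⁻⁶). Contact residues
  are those with positive ΔSASA. When an annotation and a chain map are
  supplied, antibody-side buried area is attributed per CDR/framework
  region by treating author residue numbers as frame labels. The protocol
  intended for deposited antibody–antigen structures is antibody-side
  ΔSASA over heavy atoms, waters stripped, averaged over the
  crystallographically independent copies; since the original radii/probe/
  software settings are unpublished, comparisons against reported paratope
  sizes should allow ~15%.
* **Superposition** — Kabsch via SVD with the determinant-sign reflection
  correction; exactly collinear configurations are rejected (second
  singular value < 1e-8 relative). Optimality is property-tested against a
  10⁴-random-rotation brute-force oracle on small instances.
* **Ternary co-binding models** — complex 2 is superposed onto complex 1
  via shared Fab Cα atoms (paired by residue id; ≥ 50 required by default),
  its antigen transplanted, and all inter-antigen atom pairs scanned; a
  pair closer than r_i + r_j − 0.4 Å counts as a severe clash (0.4 Å is a
  common steric allowance). Zero severe clashes means simultaneous binding
  of both antigens is geometrically feasible.
* **Crystal forms** — V_M = V/(z·n·MW) in Å³/Da and
  S = 1 − 1.66054·v̄/V_M with v̄ = 0.74 cm³/g by default, S clamped to
  [0, 1].

## Assay models

The 4PL model y = bottom + (top − bottom)/(1 + (x/IC50)^n_H) is fitted by
Levenberg–Marquardt least squares in log-dose parameterisation.
Initialisation: top/bottom from the signal extrema, IC50 from the dose
closest to half-maximal signal, n_H = 1 with its sign set by the dose-signal
trend; fits are canonicalised to positive n_H. Non-convergence is flagged,
not raised. The viscosity conversion is the exact identity
η = η₀·(r_h/r_h,0).

## Synthetic data

The fixture generators define the test conditions:

* scaffolds = template + 3 paratope mutations per side (rule positions
  untouched), so compliance and numbering hold by construction;
* binders = scaffold + n mutations drawn uniformly from the side's resolved
  mutable positions (cysteine excluded as a substitution to avoid unpaired
  thiols), with the deviation set returned as ground truth;
* toy complexes = two pseudo-atom blobs (default 40 atoms each, 6 Å blob
  radius, C/N/O/S elements) that are separated (provably zero footprint),
  contacting (dense 5000-point oracle areas attached), or separated with k
  engineered isolated clash pairs of exactly 0.6 Å overlap;
* co-binding pairs = a shared 60-Cα pseudo-Fab with antigens on opposite
  (+x/−x) faces — or the same face as a positive-clash control — with a
  random rigid motion applied to complex 2;
* dose-response curves = 11 half-log doses spanning 5 decades around a true
  IC50 of 100 pM, top 2.0, bottom 0.1, n_H 1.2, Gaussian signal noise
  σ = 0.03 where noise is requested.

These fixtures exercise every code path without downloads, and all are
byte-reproducible from a seed. What they do **not** emulate: real antibody
3D geometry, correlated CDR mutation patterns from panning, codon-level
library composition, or plate-assay artefacts — so passing tests demonstrate
algorithmic correctness of the measurements, not biological realism of the
inputs. Analyses of deposited crystal structures use the same code paths
via `read_structure`, which handles PDB/mmCIF, first model, highest-
occupancy altlocs, and author chain ids.

## Problem sizes

The shipped test and acceptance runs use: 1,000 random binder fixtures
(500 merge pairs) for provenance checks, 200 sampled library members for
compliance, 100 seeds for the noisy 4PL study, 10⁴ random rotations for
the Kabsch oracle, and 40–80-atom toy complexes with 960-point SASA
(5,000-point oracles). These sizes give stable statistics in seconds on a
single CPU.

## Known limitations

* Only kappa light chains and VH3-like heavy chains number successfully;
  IMGT/Aho/Martin frames, lambda chains and VHH single domains are out of
  scope.
* The embedded templates are consensus-derived; exact germline scaffold
  identities, Fig-level diversified position lists and the proprietary
  per-position library alphabets must be supplied as config where known.
* Interface analysis is purely geometric (areas, distances); no energetic
  scoring, and no prediction of whether a merged clone retains affinity.
* The elastic-deletion rule can only remove labels counting back from an
  anchor; loops shorter than an anchor's offset within its segment are
  rejected rather than renumbered.
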