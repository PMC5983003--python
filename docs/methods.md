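# Methods

## The model

`tessmut` scores protein structures with a four-body knowledge-based
statistical potential defined on a residue-level coarse-grained
representation: each residue is reduced to its C-alpha coordinate, and the
Delaunay tessellation of that point set partitions the convex hull into
tetrahedra whose circumspheres contain no other point. Each tetrahedron
objectively identifies a quadruplet of nearest-neighbor residues.
Tetrahedra containing any edge longer than 12 Å (configurable) are
discarded whole, leaving only physically plausible four-residue contacts.

Over a training set of tessellated structures, each retained tetrahedron
increments the count of its unordered residue quadruplet (the four letters
in ascending alphabetical order; there are C(23, 4) = 8855 types over the
20-letter alphabet). The observed relative frequency f of each quadruplet
is compared with the rate expected by chance under a multinomial reference,

    p = 4!/∏ t_n! · ∏ a_n^{t_n},

where a_n is the pooled proportion of residue type n in the training set
and t_n its multiplicity in the quadruplet. The inverted-Boltzmann score
s = −log(f/p) over all quadruplet types is the potential.

Derived quantities:

* **total potential** — sum of quadruplet scores over all retained
  tetrahedra of a structure;
* **RES** (residue environment score) — per position, the sum of the
  scores of every tetrahedron sharing its C-alpha vertex; the RES vector
  is the 3D-1D potential profile. By construction Σ RES = 4 × total
  potential (each tetrahedron contributes at four vertices);
* **residual profile / EP scores** — a substitution relabels the residue
  at its fixed C-alpha (coordinates never move) at *every* chain copy of
  the mutated position; EP is the mutant-minus-native RES difference per
  position and the residual score is the total-potential difference.
  Only tetrahedra incident to mutated vertices change, so EP support is
  the mutated site(s) plus their tessellation neighbors, Σ EP = 4 ×
  residual score, and in a single-chain tessellation EP at the mutated
  position equals the residual score exactly. The incremental rescore is
  the implementation; an exhaustive full rescore is kept as a test oracle;
* **CMP** — per position, the mean residual score over all 19
  substitutions, with conservative (C) and non-conservative (NC) submeans.
  C/NC follows the physicochemical clusters (A,S,T,G,P), (D,E,N,Q),
  (R,K,H), (F,Y,W), (V,L,I,M), (C); cysteine is a singleton, so every
  substitution involving C is NC and native cysteines have an undefined
  (NaN) C-CMP.

## Feature vectors and models

A variant's 27-attribute vector comprises: position number, native and
replacement residues, EP at the mutated position, and — for the six
nearest neighbors by C-alpha distance among retained-edge neighbors
(ties broken by lower flat index) — signed sequence separation, residue
identity and EP; then mean tetrahedron volume and mean tetrahedrality
over tetrahedra incident to the mutated vertex, depth class, number of
retained edges to surface positions, and three-state secondary structure.
Positions with fewer than six neighbors cannot be encoded and their
variants are excluded, with an exclusion manifest. The alternative
encoding uses the per-chain split of the full EP vector (optionally plus
a 3-attribute variant ID).

Depth classes: *surface* = convex-hull vertex of the point set;
*undersurface* = non-surface position sharing a retained edge with a
surface position; *buried* = the rest. This hull-based definition and
the edge-length-variance tetrahedrality T = Σ_{i<j}(l_i−l_j)²/(15·l̄²)
are documented, configurable choices — the three depth names and
"tetrahedrality" are standard but not uniquely defined in the field.

Activity conventions for log2(effect size): Superior (> 0), Similar
([−2, 0]), Inferior (< −2); the binary split is unaffected (≥ −2) versus
affected (< −2), with "affected" the positive class of all metrics.

Learners are contract-level counterparts of the Weka 3.6 algorithms used
in the original analyses, built on scikit-learn: random forest
(100 trees), RBF SVM with Platt-calibrated probabilities and
standardized inputs (Weka's SMO normalizes by default), decision tree
(optionally bagged), one-hidden-layer perceptron with logistic
activations and standardized inputs (default 16 hidden units, 2000
epochs — enough for convergence on datasets of a few thousand rows),
a reduced-error-pruned regression tree (cost-complexity level chosen on
an internal 25% validation split), and RBF SVR. Bit-compatibility with
Weka is explicitly not a goal; cross-validation estimates are stochastic,
so reproduction of published performance tables is approximate by nature.
Categorical attributes are one-hot encoded model-side with a
deterministic column order. Evaluation uses stratified 10-fold CV or
LOOCV; every row is predicted exactly once; regression predictions are
additionally thresholded at −2.0 to yield classification metrics.
Se/Sp/PPV/BAR/MCC follow the standard confusion-matrix formulas and AUC
is the rank (Mann–Whitney) statistic with ties averaged; metrics with
empty denominators or single-class truth are NaN, never silently 0.
The combined classifier averages per-class probabilities across
classifiers and predicts the argmax, breaking exact ties toward
"affected". Permutation controls shuffle the output labels only and
rerun the identical CV protocol; learning curves subsample with
per-class proportional allocation.

## Synthetic fixtures

The generator produces compact self-avoiding random walks with the
3.8 Å consecutive C-alpha spacing of real backbones, biased into a
globule of radius ≈ 3·n^(1/3) Å (protein-like packing density), with a
4 Å self-avoidance distance. Homodimer mode mirrors the chain across a
plane at a configurable interface gap; an optional `asymmetry` jitter
(Gaussian, ~0.3 Å) emulates the subtle chain differences of real crystal
structures and breaks the exact mirror symmetry. Sequences are drawn
uniformly (or from a given composition). All randomness flows from the
seed in the spec; generators never touch global RNG state.

Toy training potentials are derived from 25 independent 100-residue
fixtures; because a few thousand tetrahedra cannot cover 8855 quadruplet
types, the toy potential uses a pseudocount of 1 so every quadruplet is
scoreable during exhaustive mutagenesis. (With pseudocount 0, unobserved
quadruplets are explicitly *unscored* and scoring them is an error —
energies are never invented silently.)

Synthetic activities couple labels to computed residual scores:
log2 = slope·residual + offset + Gaussian noise (defaults: slope 1,
noise sd 0.5 ≈ 0.15 × the residual spread). The offset is calibrated so
the noiseless class balance matches the experimental Gal4 split
(453 unaffected / 631 affected, i.e. 58% affected); a slope alone cannot
reach that balance because the toy potential's residual distribution is
roughly symmetric about zero, unlike real proteins where most
substitutions are destabilizing. These fixtures exercise tessellation
topology, scoring algebra and ML plumbing end to end; they are geometric
stand-ins, not folded proteins, so passing tests demonstrate correctness
of the machinery, not predictive validity on real structures.

## Problem sizes and numerical choices

Default test and acceptance runs use 100-residue fixtures, 300 variants,
10-fold CV and 100-shuffle permutation controls — large enough for the
signal-versus-null contrast (observed BAR ≳ 0.9 against a null centred
on 0.5) while keeping a full run in minutes on one core. Degenerate
(cospherical) point sets are retried once with a deterministic 1e-6 Å
joggle, logged. Coplanar quadruples report volume 0. Zero RES/CMP values
are assigned to the positive quadrant side for determinism. Neighbor
distance ties break by lower flat index.

## Known limitations

* The published Gal4 analyses depend on the 3coq crystal structure, the
  published 1,417-structure potential table and the experimental variant
  activities; none are bundled. The corresponding checks run only when
  those files are supplied under `data/reference/` (see
  `tests/test_acceptance.py`); everything else is generated.
* The log base of the potential is configurable (natural log by
  default); tables loaded from text are taken as-is, where the base is
  immaterial.
* Mutagenesis never repacks side chains or relaxes coordinates; residual
  scores are sequence-structure compatibility changes, not physical ΔΔG.
* DNA and other non-protein components are invisible to the
  residue-level representation.
* Secondary structure comes from PDB HELIX/SHEET header records
  (three-state); structures without headers are treated as all-coil.
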