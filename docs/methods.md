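# Methods

## The screening workflow

The package models a structure-based virtual screen as a deterministic
pipeline over explicit data types. A raw catalog of molecules is reduced to a
screen-ready library by (i) property-range filters over computed descriptors
(MW, cLogP, Lipinski donor/acceptor atom counts, rotatable bonds, TPSA),
(ii) structural-alert rejection against a SMARTS list (reactive warheads,
assay-interference motifs, a PAINS-style subset), optionally augmented by
similarity ≥ 0.85 to a packaged reference list of aggregator chemotypes, and
(iii) chemotype-novelty exclusion: any candidate with Tanimoto similarity
strictly greater than 0.5 (ECFP-style Morgan radius-2, 1024-bit) to any known
binder of the target or of homologs at ≥ 70% global-alignment sequence
identity is removed; for kinase-annotated targets the reference set extends to
every kinase-annotated binder in the database. Each pass preserves input order
and emits a rejection log, so retained plus rejected always partitions the
input — the workflow is auditable end to end and nothing is cherry-picked.

Fingerprint conventions: bit-level circular fingerprints are not portable
across toolkits, so the package standard is RDKit's Morgan radius-2 hash
folded to 1024 bits, pinned by a cross-check against the toolkit's native bit
vectors in the test suite. Tanimoto over two all-zero vectors is defined as 0
(not NaN) to keep exclusion logic total. By default structures are
standardized (largest fragment, neutralized) before canonicalization;
this can be disabled per call.

Sequence identity is computed from a global alignment (match +1, mismatch 0,
gap −1, terminal gaps penalized) as matched columns divided by alignment
length × 100. This is a declared convention; profile-based homology search is
out of scope.

## The scorer

A complex graph has one vertex per heavy atom carrying a one-hot Sybyl/MOL2
atom type (element × aromaticity × hybridization with special cases N.am,
O.co2, C.cat, …; unknown combinations fall back to `<element>.generic`) plus a
ligand/receptor role bit. Receptor atoms farther than 7 Å from every ligand
atom are excluded before featurization. Edge sets are built per cutoff radius:
every atom pair with 0 < d ≤ r is connected in both directions, annotated with
its distance. Boundary conventions are closed on both counts (kept at exactly
7 Å; connected at exactly the cutoff) — literal and testable. Hydrogens are
dropped by default everywhere. Connectivity for atom typing comes from the
input bond block when present (SDF/MOL2) and from covalent-radius distance
rules otherwise (sum of radii + 0.45 Å). The 7 Å truncation is atom-wise;
residue-wise truncation would keep whole residues and is not the default
reading implemented here.

The network is five blocks of gated message passing,

    h'_v = ReLU(W_self h_v + b + Σ_{u∈N(v)} φ(d_uv) · W_nbr h_u),

with φ(d) a linear projection of a Gaussian radial-basis expansion of the
distance (centers every 0.5 Å on (0, 7.5], width 0.5 Å) to a scalar gate.
This is the minimal operator honouring pairwise, distance-dependent edges: no
angular features, bond orders, or attention. Blocks: (5 Å, 64, all atoms) × 2,
(7 Å, 128, all atoms), (7 Å, 128, ligand-only) × 2, where ligand-only blocks
update only ligand vertices using only ligand–ligand edges. A sum-pool over
ligand vertices (permutation-invariant by construction; rigid-motion-invariant
because only distances enter) feeds a three-task head: sigmoid bioactivity,
sigmoid pose quality, linear docking-score surrogate.

Implementation: plain NumPy with hand-derived gradients, validated against
central finite differences in the test suite. Message passing uses a sparse
gated-adjacency matrix product. The numerically stable softplus form of
binary cross-entropy is used on the logit scale during training; the public
probability-scale loss clips probabilities at 1e-7.

## Training protocol

Six models on six cross-validation folds. Targets are single-linkage
clustered at ≥ 70% identity (clusters are fold-atomic), then clusters are
packed greedily — largest total active count first into the lightest fold —
which balances active counts while provably keeping every ≥ 70% pair inside
one fold. Member m holds out fold m. Each optimizer step draws one target
with probability proportional to its active-compound count (with replacement)
and takes a minibatch (default 32) of that target's examples; an epoch makes
⌈n/batch⌉ draws. ADAM, lr 0.001, 10 epochs, equal task weights. Missing task
labels (NaN) are masked out of loss and gradient. Dock-score labels are
z-scored internally (raw counts would dominate the equal-weight loss through
the MSE term); predictions are mapped back to the raw scale. All randomness
flows from a single integer seed; two identically-seeded runs produce
bit-identical parameters.

Ensemble scoring of a library aggregates per-ligand pose scores (max by
default, mean optional), averages the members' activity probabilities, and
sorts descending with ties broken by canonical SMILES — output order is
independent of input order.

## Selection and follow-up

The top 30,000 ranked molecules (desk-scale runs use smaller k) are clustered
with the Butina sphere-exclusion algorithm; two molecules are neighbours iff
Tanimoto ≥ 0.35. The similarity reading of the cutoff is the default because
it yields broad chemotype clusters and maximal diversity; the distance
reading (1 − sim ≤ cutoff) is a config switch. Centroid ties break to the
lower input index and exemplar ties to canonical SMILES, making the whole
top-k → cluster → exemplar chain a pure function of (scores, fingerprints,
config). Exemplars are plated with DMSO negative controls, positions
scrambled by a seeded Fisher–Yates shuffle (stable across NumPy versions),
and a blinded copy withholds compound identities. Molecules active on two or
more targets are flagged as frequent hitters and excluded from analytics.

Analog expansion takes a confirmed hit, pulls its 1000 nearest neighbours by
fingerprint similarity, optionally augments with a substructure search using
the hit's Murcko framework (whole molecule when acyclic), ranks candidates
with a potency-regression variant of the network (identical trunk, single
linear head, MSE on pIC50-like labels), and composes a 20–35 compound
follow-up set from the top-ranked analogs subject to a 0.35 similarity floor
to the parent. The floor and the score-over-similarity precedence are
declared conventions; MCS and graph-edit-distance augmentation are out of
scope for the core.

## Campaign analytics

Hit rate is 100·hits/tested. Portfolio summaries are unweighted means across
projects (each campaign counts once regardless of size), reported to printed
precision with half-up rounding; a tested-weighted variant is also reported
since the two can differ widely when screen sizes vary. Projects reporting an
analog count but no analog rates are excluded from analog-rate means.
Reconfirmation rate is the share of projects with any dose–response-confirmed
hit. The hit-rate-versus-training-data regression is closed-form OLS with a
two-sided t-test on the slope, cross-checked against an independent
statistics library at 1e-8. Scaffold novelty is the per-hit maximum Tanimoto
to the training actives, defined as 0 when no actives exist.

## The synthetic benchmark

The generator emulates the *shapes* of screening inputs, not their physics.
Molecules come from a fragment grammar (8 rings × 10 linkers × 14
decorations, deduplicated by canonical structure), guaranteeing validity and
giving planted rules chemical meaning. Pockets are 24 receptor atoms
(C/N/O/S at 60/15/15/10%) on a hemispherical shell of radius 6 Å; ligand
poses are centred 2D template coordinates plus Gaussian jitter (0.3 Å), and
decoy poses are rigid 6 Å translations, keeping pose-quality labels
geometrically unambiguous. Activity is a declarative predicate over computed
ligand features — default `tpsa >= 30`, which splits the grammar library
roughly in half — XOR-ed with Bernoulli(0.10) label noise. The dock surrogate
is the negative count of ligand–receptor contacts within 4 Å plus unit
Gaussian noise. Target sequences are random 120-mers with every fifth target
a ~90%-identity mutant of its predecessor, so fold assignment faces real
identity constraints. The default benchmark is 960 ligands over 12 targets,
one good and one decoy pose each (~1900 complexes) — sized so a full
six-member training run takes about two minutes on one CPU.

What this shows and does not show: recovering the planted signal (held-out
AUC ≥ 0.8 per member at the documented seed, against a ceiling of ≈0.90 set
by the 10% label noise) demonstrates that the architecture, featurization,
folds, sampler, and optimizer are wired correctly and can extract a
ligand-level structure–activity rule from 3D complex graphs. It does not
demonstrate transfer to real protein pockets, real binding physics, assay
noise structure, or catalog-scale chemistry.

The shuffled-label control permutes activity labels *within each target*
(grouped permutation). A global shuffle would leave per-target base rates
unequal by chance and per-fold AUC — two targets per fold — would absorb that
target-level confound; the within-group permutation removes it, and the
control statistic is the pooled cross-validated ensemble AUC, expected in
[0.4, 0.6].

## Known limitations

- No pose generation or docking: poses are inputs (or synthetic).
- The convolution operator is the declared minimal form; production-scale
  variants with richer edge features would need a different operator module.
- Sequence identity is pairwise global alignment only.
- The alert list is a documented representative subset, not a complete
  transcription of any published rule collection.
- Pipelines are single-CPU NumPy; the design favours reproducibility and
  auditability over throughput.
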