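# Methods

`voxscreen` implements a structure-based virtual-screening pipeline for
antibody-antigen docking poses: featurize each pose's interaction site as a
4D voxel grid, predict pose quality (fnat) with a small 3D convolutional
rescorer, classify poses as binder/non-binder, aggregate pose scores into
pairing scores, fuse them with the docking engine's own score, and rank
candidate antibodies per antigen.  This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Interface definitions

Surface exposure is Shrake-Rupley SASA (via biotite, element radii, heavy
atoms only) normalised by per-residue-type theoretical maxima (Tien et al.
2013 values; unknown residue types fall back to 200 A^2 with a warning).
A residue is *surface exposed* at relative exposure >= 0.15; the threshold
is configurable because published interface pipelines differ on it.
Exposure is computed per separated partner ("partner-split") before any
interface rule is applied, so interface residues buried in the complex
still count as surface on the lone partner.

The epitope is every atom of an exposed antigen residue with any heavy atom
strictly under 4.0 A of a heavy atom of an exposed antibody residue; the
allowed docking interface additionally includes exposed antigen residues
within 4.0 A of any epitope atom.  The paratope is either the mirror-image
contact definition (crystal structures) or the IMGT CDR loops plus two
flanking residues per side (modelled antibodies).  IMGT numbering is *not*
assigned here: chains either already carry IMGT numbers (CDR1 = 27-38,
CDR2 = 56-65, CDR3 = 105-117) or an explicit per-chain CDR range table is
supplied.  All distance comparisons are strict `<` at the cutoff.

## Pose quality

fnat is the fraction of the native complex's residue-residue contacts
recapitulated in a pose, with contacts re-evaluated at the native cutoff
and residue correspondence by (chain, number, insertion code) — valid for
rigid-body docking, which preserves numbering.  The fnat contact cutoff
defaults to 5.0 A heavy-atom distance (CAPRI convention) and is deliberately
a separate parameter from the 4.0 A epitope/centre cutoff; conflating them
would silently change labels.  Interface RMSD uses C-alpha atoms of native
residues within 10 A of the partner after least-squares (Kabsch)
superposition; ligand RMSD superposes antigens and measures the antibody.
CAPRI acceptability: fnat > 0.1 and (iRMSD < 4 A or LRMSD < 10 A).

The interaction centre is the midpoint of the two partners' mean
surface-exposed-atom coordinates within 4.0 A of the other partner.  Poses
with no such interaction are invalid and discarded before featurization.
Because rigid docking leaves each partner's isolated SASA unchanged, the
native partner-split exposure is reused across poses.

## Featurization

A pose is discretised into `channels x side^3` occupancy: the production
spec is radius 24 A at 0.5 A resolution (96^3 voxels); the desk-scale spec
used throughout tests is radius 9 A at 0.75 A (24^3), chosen so the whole
synthetic interface patch fits in the box.  Default channels: {C, N, O,
other} x {antibody, antigen} (8 channels; hydrogens unmapped).  The exact
atom-typing scheme is a loadable JSON config; the default makes no claim
beyond being the minimal partner-separated element scheme.

Voxels are half-open (`[centre - r + i*res, centre - r + (i+1)*res)`), atoms
map by floor; binary nearest-voxel occupancy is the default because it
obeys exact counting invariants (total mass = in-box mapped atoms).  A
Gaussian mode (sigma = vdW radius, truncated at 1.5 sigma, unit mass per
atom over the truncated support) is provided for density-style precedents.
Train-time augmentation applies a uniform random SO(3) rotation about the
interaction centre (random normalized quaternions) followed by independent
per-axis uniform shifts in [-2, 2] A.

## Models and training

The rescorer head emits a probability distribution over 11 fnat bins — a
dedicated bin for fnat = 0 plus ten width-0.1 intervals over (0, 1],
upper-inclusive so fnat = 1 is representable and bin 0 is strictly for
zero-contact poses.  The prediction is the expectation over bin
representatives; representatives default to interval midpoints (0.05 ...
0.95, zero bin 0.0), the unbiased choice given only "weighted averaging";
they are configurable.  The binder classifier emits a single binding
probability.  Pairing-level classifier scores average ensemble members.

Networks are small 3D conv stacks (im2col convolutions over BLAS, ReLU,
global average pooling, a dense head) implemented in numpy with
hand-derived, numerically verified gradients, trained with rectified Adam.
`arch_a`/`arch_b` are two stacks of different depth/width for ensembling;
`tiny_test` (two stride-2 blocks, 8/16 channels) trains on one CPU in
minutes at the reduced grid spec.  These are documented stand-ins, not
replicas of any published architecture.

Training rules: the rescorer samples poses stratified by fnat bin
(uniform over occupied bins, then uniform within, with replacement) to
counter the heavy low-fnat imbalance of docking outputs; the classifier
samples exactly class-balanced batches.  Reference step counts are 200k
(rescorer) and 50k (classifier) parameter updates; the desk profile uses
1500/800 steps, batch 16, learning rate 5e-3, snapshot selection every
250/200 steps.  Snapshots: highest validation average precision for the
classifier; lowest validation loss for the rescorer (average precision is
not meaningful for an 11-way regression-by-classification head, so the
rescorer uses loss; both choices are exposed in config).  Batch size and
learning rate are the package's own defaults.

The desk profile trains with augmentation off: under full SO(3)
augmentation the tiny network must additionally become rotation-invariant,
which demands far more capacity and steps than a CPU-minutes budget —
augmented training left the loss at the uniform-prediction level while the
same run without augmentation learned immediately.  Augmentation remains
the default for production-scale configs and its rigidity/shift-bound
invariants are tested directly.

Classifier training-set assembly per pairing: up to 50 poses with
fnat > 0.7 as positives (descending fnat); exactly five poses with
fnat < 0.1 as same-pairing negatives, chosen by ascending fnat (the
hardest-to-confuse negatives — the rule says only "five poses"); the
decoy pairing's top rescorer-reranked pose as a cross-pairing negative.

## Screening

Per pairing, all valid poses are rescored and reranked by predicted fnat
(stable sort, ties keep docking order).  The pairing's *rescore max* (the
highest predicted fnat over its poses) flags pairings likely to contain a
good pose; thresholding ranks all pairings by it and retains the top
`ceil((1-f) n)` for f in {0.4, 0.6, 0.8}.  The classifier pairing score
averages the ensemble-averaged scores of the top 10 reranked poses (fewer
if fewer survive).  The docking baseline is the docking score of the
engine's original top pose — taken before the interaction-centre filter,
which exists only for featurization.  Fusion min-max normalises the two
channels per antigen and averages them; a degenerate channel maps to 0.5.

Evaluation: the cognate's rank resolves ties pessimistically (equal-scored
decoys are placed ahead of it) and top-q membership uses the ceiling rule
`rank <= ceil(q * n_candidates)` — both pinned by boundary fixtures.  The
success-ratio standard deviation is approximated as sqrt(c)/n (Poisson
count).  Rate comparisons use the exact conditional (binomial) Poisson
test via statsmodels (`test_poisson_2indep`, method "exact-cond"); mean
comparisons use the two-sided Welch t-test.

## Splits and decoys

Antibody identity is the concatenated H1,H2,H3,L1,L2,L3 CDR sequence.
Identity is positional for equal lengths, `1 - Levenshtein/max(len)`
otherwise.  Clustering is greedy and CD-HIT-like: sequences in descending
length (id tie-break) join the first cluster whose founder has identity
>= 0.9, else found a new cluster; CD-HIT's word-filter heuristics are not
replicated because exact identities are affordable at this scale.  Folds
are assigned at cluster level (round-robin after a seeded shuffle, sizes
within one cluster), and each fold carries two disjoint ~10% validation
carvings of its training clusters, supporting a 2-architecture x
2-validation-set ensemble per fold.  Decoy antibodies are sampled
uniformly without replacement from the pool after removing the cognate and
anything with >= 90% CDR identity to it.

## The synthetic generator

The generator exists so every pipeline stage is exercisable with no
downloads; it is deliberately non-physical.  Bodies are pseudo-proteins on
a C-alpha lattice (3.8 A backbone spacing): the binding interface is a
4 x 3 serpentine patch of residue pairs (12 planted contacts), antibody
plane 4.7 A above the antigen plane, with a probe pseudo-side-chain 0.9 A
below each antibody patch residue so that exactly the planted pairs are in
contact at both the 5 A fnat cutoff and the 4 A epitope cutoff (margins
>= 0.2 A against the +-0.05 A coordinate jitter).  Patch residues draw
small residue types (Gly/Ala/Ser/...) so single-pseudo-atom residues stay
above the 0.15 exposure threshold; tails carry N/O/S atoms for channel
diversity.  Chains: heavy (patch + rising tail), light (non-contacting
tail, carries L1-L3), antigen (patch + in-plane tail).  Total CDR length
is 24 so single-mutation family members stay above 95% identity.

Pose ensembles perturb the antibody rigidly.  Tilts about a horizontal
axis through a random patch corner (oriented to peel the patch away from
the antigen, jittered in azimuth) sweep fnat from 1 down to 1/12 as
successive rows lift past the contact cutoff.  Register shifts by one
lattice vector give fnat = 0 with a valid centre — on a grid they are
indistinguishable from a perfect interface (they model wrong-register
docks) and are therefore *excluded from the rescorer learnability task*,
whose zero-bin examples are instead near-miss poses (antibody lifted
1.4-2.6 A, closest approach just past 5 A, gridded on the closest-pair
midpoint since the pipeline centre is undefined without a sub-4 A
contact).  Off-site poses dock the antibody onto the antigen tail
(fnat = 0, valid centre, line-contact geometry).  Far translations
(+50 A) exercise the discard path.  Clash placements (antibody pushed into
the antigen plane) are the non-binder geometry for classifier training and
decoy pairings.

Synthetic docking scores are `10 + 8 * fnat + N(0, 2)` for cognate poses —
Spearman(dock, fnat) ~ 0.7-0.8, an informative but imperfect baseline —
and `15.5 + N(0, 2)` for non-binder poses, an offset at which the
top-pose score distributions of cognates and decoys overlap: ranking by
docking score alone retrieves the cognate at well above chance but far
below the fused score, the regime in which fusion is worth doing.

What passing tests on this generator do and do not show: they verify the
pipeline's mechanics, contracts, invariants and learnability end to end;
they do not show that the models learn real antibody-antigen binding
chemistry — the synthetic binder/non-binder distinction is geometric
(complementary gap vs clash) and linearly easier than the real task, and
the pseudo-bodies have no rotamers, no energetics and no H3 loop
variability.

## Desk-scale profile and determinism

All tests and the acceptance script run on one CPU: reduced 24^3 grids,
`tiny_test` models, 1500/800 training steps, screens of 50 antigens x
(1 cognate + up to 50 decoys) x 12-16 poses.  Every stochastic component
takes a `numpy.random.Generator`; identical seeds give identical results
(single-threaded), including byte-identical synthetic PDB files and
training trajectories.

## Known limitations

- No IMGT numbering assignment, antibody modelling, or docking engine:
  poses and numbering are consumed, not produced.
- The default channel map is a generic partner x element scheme, not a
  reproduction of any published atom-typing supplement.
- fnat's contact cutoff in the original pipeline is unrecorded; 5.0 A is
  the CAPRI-conventional default and a config knob.
- Register-shifted poses are unlearnable by construction from grids alone;
  they are kept in pose ensembles for realism but any grid-based rescorer
  will score them as good interfaces.
- The numpy network is CPU-only and sized for desk-scale grids;
  production-scale 96^3 training would need a GPU framework behind the
  same contracts.
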