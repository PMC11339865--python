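# Methods

## Problem

The acid–base dissociation constant (pKa) governs a drug candidate's charge
state at physiological pH and with it solubility, permeability and binding.
`pkaret` predicts the macroscopic (whole-molecule) pKa of small organic
molecules from their SMILES with a message-passing neural network whose
attention-like operator is a *retention* mechanism, and trains it with a
multi-fidelity protocol: pretraining on abundant, cheap, systematically
biased computed labels, then fine-tuning on scarce experimental-quality
labels. Acidic (deprotonation) and basic (protonation) equilibria are
modeled as separate datasets.

## The retention mechanism

Sequence-mode retention is defined by the recurrence

    S_n = γ · S_{n−1} + K_nᵀ V_n,        out_n = Q_n S_n,     S_0 = 0,

with Q, K, V linear projections of the input and γ ∈ (0, 1) a decay
hyperparameter. Expanding the recurrence gives the exactly equivalent
parallel form `out = ((Q Kᵀ) ⊙ D) V` with the causal decay matrix
`D[n, m] = γ^(n−m)` (n ≥ m). Both forms are implemented; their equivalence
is asserted to 1e-5 over random instances, and the recurrent form serves as
the oracle for the parallel one used in training.

Atoms in a molecule carry no canonical order, so inside the network the
causal decay is replaced by the symmetric graph-mode decay

    D[i, j] = γ^d(i, j),

where d is the topological (bond-hop) distance. This preserves the
mechanism's locality principle — the fewer bonds between two atoms, the
stronger their interaction — while making the operator permutation-
equivariant. The sequence-mode recurrence remains available and tested; the
graph-mode decay is this package's documented interpretation of how an
order-dependent recurrence applies to unordered atoms.

Per-head decays follow the schedule γ_h = 1 − 2^(−5−h), spanning strong to
weak decay. Multi-head retention adds one scaled inter-atomic matrix
(adjacency, topological distance, or Coulomb) as an additive bias on each
head's pre-decay score matrix Q Kᵀ, heads assigned round-robin across the
three matrices (hence the number of heads must be divisible by three when
bias injection is on). The concatenated heads are group-normalized before
the output mix; GroupNorm's invariance to positive rescaling keeps the
un-normalized decay weighting numerically safe. GroupNorm eps defaults to
1e-5; the scale-invariance property holds exactly only in the eps → 0
limit, which is how it is tested.

## Network

1. **Bond initialization.** Each directed bond v→w starts at
   h⁰ = ReLU(W_init·[x_v ; e_vw]) from the source-atom and bond features.
   Features are the conventional directed-MPNN set: element one-hot over
   {H,C,N,O,F,P,S,Cl,Br,I,other}, degree 0–5, formal charge, aromaticity,
   ring flag, total H count 0–4, hybridization one-hot for atoms; bond-order
   one-hot, conjugation, ring membership and stereo one-hot for bonds.
   Hydrogens are implicit (heavy-atom graph) and recorded as H-counts.
2. **Bond message passing.** For T iterations (default 3) each directed
   bond sums the hidden states of incoming bonds excluding its own reverse,
   the summed messages pass through an unbiased graph-mode retention block
   whose decay uses the topological distance between the bonds' source
   atoms, and states update residually against h⁰ with ReLU and dropout.
   The retention block weights are shared across iterations.
3. **Atom readout.** Incoming bond states are summed per atom, concatenated
   with the atom features, projected, and refined by the biased multi-head
   atom retention block described above.
4. **Aggregation and head.** Atom states are sum-aggregated (size-extensive
   and permutation-invariant) to a molecule vector, concatenated with the
   five per-molecule quantum-mechanical scalars — enthalpy, free energy,
   HOMO, LUMO and the HOMO–LUMO gap, z-scored with training-set constants
   stored in the checkpoint — and a two-layer ReLU feed-forward head with
   dropout emits the pKa.

Ablation toggles construct the variant grid from configuration alone:
single- vs multi-fidelity, QM fusion on/off, and retention vs a softmax
scaled-dot-product attention stand-in that keeps the identical bias-matrix
injection so the comparison isolates the decay mechanism.

## Inter-atomic matrices

* Adjacency A: binary, zero diagonal.
* Topological distance: all-pairs bond hops (Dijkstra on the unweighted
  graph; an independent Floyd–Warshall implementation is the test oracle).
  Disconnected pairs carry the sentinel n_atoms — larger than any real
  path — so γ^d treats them as effectively zero-weight without infinities.
* Coulomb matrix: the standard descriptor C[i,j] = Z_i Z_j / ‖R_i − R_j‖
  (distances in Bohr), diagonal 0.5·Z^2.4. Geometries come from an SDF when
  supplied (Å converted at 1.8897259886 Bohr/Å), otherwise from a
  deterministic ETKDG distance-geometry embedding seeded by a hash of the
  canonical SMILES. The embedding is computed on the canonical-order
  molecule and mapped back through the substructure match, so every SMILES
  rendering of a molecule receives identical per-atom coordinates — this is
  what makes end-to-end predictions invariant to atom reordering.
* Each matrix is independently scaled by its per-molecule maximum absolute
  entry before use as a bias (dimensionless, preserves zeros and symmetry,
  bounded magnitude). An all-zero matrix is left unchanged.

## Curation rules

Records outside pKa [0, 14] are excluded (bounds inclusive: the rule drops
only values strictly above 14 or below 0). Molecules with no ionization
site detectable by the SMARTS library are omitted. Each molecule then keeps
only its most acidic value (minimum among acidic-class records — the
strongest acid ionizes at the lowest pKa) and its most basic value (maximum
among basic-class records), per fidelity tier, so cross-tier duplicates —
the premise of multi-fidelity learning — survive. Finally records are
partitioned into acidic and basic datasets by detected site class;
amphoteric molecules appear in both. Splits are uniform random 8:1:1
(train/validation/test), floor-allocated with the remainder to train, and
fully determined by the seed. Dataset diversity is reported as the mean
pairwise Tanimoto coefficient over 166-bit MACCS keys.

The shipped SMARTS library is a curated set of ~20 common ionizable-group
patterns (carboxylic and sulfonic acids, phenol, sulfonamide N–H, imide,
tetrazole, thiol, hydroxamic acid, aliphatic amines of all orders, aniline,
pyridine-type aromatic N, amidine, guanidine, …), each written with the
titratable atom first so distinct-site counting is well defined. A custom
library can be supplied as a two-column text file.

## Synthetic benchmark

The generator assembles unique molecules from a fragment grammar: alkyl
chains (1–7 carbons, optionally branched and decorated with F, Cl, methyl
or methoxy) or substituted benzene rings, each carrying exactly one
ionizable head group. Group base values — carboxylic acid 4.0, phenol 10.0,
sulfonamide 10.1, primary amine 10.5, pyridine 5.2, amidine 11.5 — cluster
acids low and bases high, spanning [0, 14] realistically. The noise-free
truth label adds documented, graph-local shifts (+0.04 per sp³ carbon,
−0.55 per Cl, −0.45 per F, +0.12 per ether oxygen, −0.35 if aromatic);
these constants are generator bookkeeping, not claimed chemistry, chosen so
a graph network can in principle recover the labels exactly.

High-fidelity labels add N(0, σ_high = 0.3) noise; low-fidelity labels add
a systematic bias b = +0.5 plus N(0, σ_low = 0.7) on top of the same
high-fidelity draw, giving the high correlation (> 0.8) with a systematic
offset that makes transfer learning beneficial by construction. All labels
clip to [0, 14]. The five synthetic QM scalars are noisy deterministic
functions of elemental composition; the gap is LUMO − HOMO exactly and the
enthalpy is strictly decreasing in heavy-atom count at zero noise. The
default benchmark draws 2000 low-fidelity and 400 high-fidelity molecules
with disjoint molecule sets; everything is byte-reproducible from
(spec, seed).

What the generator does **not** emulate: real substituent electronic
effects (Hammett behavior), tautomerism, multiprotic coupling between
sites, conformer-dependent properties, and the scale and chemical breadth
of real pretraining corpora. Passing the recovery tests therefore shows the
architecture and protocol can learn a graph-local additive pKa model
through noise and fidelity bias — not that it attains literature accuracy
on experimental data.

## Training

MSE loss, Adam (lr 1e-3, two-epoch linear warmup then ×0.99/epoch decay),
batch size 64, dropout 0.1, pretrain 100 epochs and fine-tune 50 by
default. Fine-tuning updates all layers. The best-validation-RMSE state is
retained; a NaN loss aborts with a diagnostic. One integer seed fixes the
splits, initialization, shuffling and dropout, making loss traces
bit-reproducible. Gradients come from a minimal in-package reverse-mode
autodiff engine over NumPy arrays (`pkaret.autodiff`); numerical gradient
checks back its primitives.

Default width is hidden 300 with 6 heads. The test suite and the
acceptance script run reduced problem sizes chosen to keep single-CPU runs
in minutes — hidden 24–48, depth 2, benchmark draws of 600–1000 low- /
150–300 high-fidelity molecules, 8–18 pretrain and 12–35 fine-tune epochs;
the overfitting oracle uses 32 molecules with dropout 0 and an early stop
once train MAE reaches 0.08. Metrics are R² = 1 − SS_res/SS_tot, MAE and
RMSE in pKa log units; R² is reported as NaN with a warning when labels
have zero variance, and MAE ≤ RMSE is asserted on every evaluation.

## Numerical and design choices

* Degenerate inputs: bondless molecules featurize to an empty directed-bond
  matrix and skip message passing; an empty molecule cannot be aggregated
  and raises; coincident atoms make the Coulomb matrix undefined and raise.
* Duplicate records of one molecule/class/tier are resolved by the macro
  collapse itself (min or max); overlaps between pretraining and
  fine-tuning molecule sets are allowed and logged, never deduplicated.
* The bond retention block's decay distance is measured between the two
  directed bonds' *source* atoms — the only bond-pair metric already
  available from the atom distance matrix.
* `n_restarts` for repeated independent training sessions is exposed but
  defaults to 1.
* Checkpoints are single `.npz` archives carrying weights, configuration,
  QM standardization constants, seed and a schema version.

## Known limitations

Macro-pKa only — no site-level (micro) predictions. No uncertainty
estimates, ensembling, conformer averaging or charge assignment beyond
formal charges. Training is single-process NumPy: fine for the synthetic
benchmark and small datasets, not for corpus-scale pretraining.
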