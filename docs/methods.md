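# Methods

`poligen` implements latent-conditioned, pocket-aware equivariant diffusion
for de novo ligand generation, together with the evaluation metrics used to
judge generated poses.  This note documents the model, its assumptions, the
numerical choices, and what the synthetic study conditions do and do not
demonstrate.

## The generative model

A ligand is the triple M = (X, H, E): heavy-atom coordinates X (N x 3, A),
one-hot element types H over a configurable vocabulary (default C, N, O, F,
S, Cl, P, Br, B, I plus a padding class), and a symmetric bond-category
matrix E over {none, single, double, triple} (aromatic bonds are kekulized
on input).  The protein pocket P contributes fixed context atoms grouped by
residue: a residue belongs to the pocket iff any of its atoms lies within a
cutoff (default 5 A, inclusive at the boundary) of any ligand atom, and
included residues contribute all their atoms.  The joint message-passing
graph is fully connected within the ligand (edges carry the bond category,
including `none`) and a 5 A radius graph for pocket-pocket and
ligand-pocket pairs (category `none`).

The forward process corrupts each modality independently:

* coordinates follow a Gaussian diffusion restricted to the zero
  center-of-mass subspace, X_t = sqrt(ab_t) X_0 + sqrt(1 - ab_t) eps with
  eps itself CoM-projected;
* atom and bond categories follow categorical chains whose single-step
  kernel mixes the identity with a fixed prior p, Q_t = a_t I + (1 - a_t)
  1 p^T; the prior is the Laplace-smoothed (+1 pseudo-count) empirical
  category distribution of the training corpus.  Bond noise is drawn on the
  upper triangle only and mirrored, so E stays symmetric.

The cumulative coefficient per modality is the adaptive cosine schedule
ab(t) = cos((pi/2) ((t/T + s)^nu) / (1 + s))^2 with T = 500 steps by
default, offset s = 0.008 (the standard cosine-schedule offset; the source
formulation leaves it open) and modality exponents nu = 2.5 (coordinates),
1.5 (bonds), 1.0 (atoms), so coordinate signal decays slowest.  Two
numerical guards apply: for nu > 1, s > 0 the raw cosine argument slightly
exceeds pi/2 in the last few steps (ab would turn back up), so the argument
is capped at pi/2; after clamping ab into [1e-5, 1 - 1e-5] a running
minimum with a 1e-9 relative decrement enforces strict decrease, which the
posterior coefficients require.  nu = 1 recovers the standard cosine
schedule exactly (up to these guards).

The network is trained under the data parameterization: it predicts the
clean sample M0_hat and the reverse chain samples the tractable posteriors
q(X_{t-1} | X_t, X0_hat) (Gaussian) and q(x_{t-1} | x_t, x0_hat) with
q proportional to Q_t[:, x_t] * (Qbar_{t-1}^T x0_hat) (categorical).  The
final reverse step is deterministic: posterior mean for coordinates, argmax
for categories.

## Networks

Both networks are E(3)-aware message-passing networks over invariant scalar
messages built from radial-basis distance features plus edge categories.
The **latent encoder** (default 8 layers, width 128, 16 edge features, 5 A
neighbor graph) never reads absolute coordinates, so its attention-pooled
latent z (k = 128 by default) is invariant to rotations, translations and
atom permutations by construction; it is deterministic (a point-mass
posterior rather than a reparameterized Gaussian).  The **denoiser**
(default 12 layers, width 256, 128 edge features) updates ligand
coordinates along relative difference vectors — rotation-equivariant by
construction — and never predicts pocket atoms.  Layer internals are
EGNN-style (invariant messages, gated coordinate updates); the configured
widths/depths and the symmetry contracts are the specified interface, the
layer algebra is an implementation choice.  The diffusion step t enters as
a sinusoidal embedding of t/T concatenated to the node scalars.

The latent conditions the denoiser through adaptive layer normalization
after every message-passing layer: with per-channel mean/std taken across
the node axis,

    AdaLN(H, z, lam) = ((1 - lam) + lam * s(z)) * H_norm + lam * b(z).

The gate interpolates plain layer normalization (lam -> 0, the
unconditional model) and full AdaLN (lam = 1).  A literal variant in which
the entire output is scaled by lam is available behind
`DenoiserConfig(literal_gate=True)`; it is not the default because its
output vanishes as lam -> 0 instead of reverting to an unconditional model.
The s, b heads are initialized at the identity (s(z) = 1, b(z) = 0), the
usual stabilization for adaptive-normalization conditioning in diffusion
models: conditioning starts as plain LN and deviations are learned
gradually.  In this implementation identity initialization also made the
lam-response of a briefly-trained model markedly more monotone.

Standard-deviation guard in AdaLN: channels with sigma < 1e-6 get an extra
1e-5 in the denominator.

## Training

Per optimization step, a batch of complexes and one step t ~ U{1..T} are
drawn; each complex is translated so the ligand CoM is at the origin
(pocket moved identically, as the zero-CoM prior requires); each clean
ligand is encoded to z; all modalities are corrupted at their own ab_t; and
the loss

    L = w_s(t) (3 ||X0 - X0_hat||^2 + 0.4 CE(H) + 2 CE(E))
        + 1.0 * MMD^2(Z, Z_prior) + 0.1 * CE(node count) + 1.0 * L_comp

is minimized with AdamW (lr 2e-4, weight decay 1e-12, gradient-norm clip
10).  Reductions: the coordinate term is summed over atoms, the
cross-entropies averaged over atoms / upper-triangle bond entries,
everything batch-averaged.  w_s(t) is the truncated SNR of the coordinate
schedule, clip(ab/(1-ab), 0.05, 1.5).  The MMD term (unbiased squared MMD,
multi-bandwidth Gaussian kernel with median-heuristic base bandwidth scaled
by {1/4, 1/2, 1, 2, 4}) matches the latent batch to an isotropic Gaussian.
Two self-supervised heads regularize the encoder: node-count classification
(range 1-64 by default) and L_comp, squared error between a
softmax-composition head on z and the ligand's true atom-type fractions.
The composition task follows the general recipe of regressing cheaply
computable chemical properties from the latent; it is what makes z encode
composition reliably at small scale.  Encoder and denoiser train jointly —
the encoder's only path to the diffusion loss is through z.

Conditioning strength during training: by default every example trains at
lam = 1.  With `TrainConfig(lam_min < 1)`, half the examples instead draw
lam ~ U(lam_min, 1).  This exercises the sampling-time knob during
training; without it a briefly-trained model showed no reliable monotone
response at intermediate lam (the knob was never taught).  The desk-scale
study uses lam_min = 0.25.

MMD and auxiliary-task weights (1.0, 0.1, 1.0) are package defaults, all
configurable.  No EMA of weights (flag available).  Training aborts with a
diagnostic on a non-finite loss.

## Sampling

Generation draws M_T from the prior (zero-CoM Gaussian coordinates,
empirical categorical atom/bond types with symmetric bonds) at the seed
ligand's atom count by default (shape-preserving hit expansion; an explicit
count or the empirical size distribution are alternatives), iterates the
reverse chain t = T..1 with the denoiser conditioned on (P, z, t, lam), and
returns ligands in the pocket frame (the seed-CoM centering undone).
`unconditional=True` is the lam = 0 limit (plain LN, no latent); lam
itself must lie in (0, 1].

Importance-sampling guidance (`generate_guided`) maintains K parallel
trajectories (default K = 8) and, every `resample_every` steps (default
50), resamples them multinomially with weights proportional to
exp(score / tau) (default tau = 0.1) of the surrogate
synthetic-accessibility head, which branches from the denoiser's final
layer (mean-pooled ligand features -> MLP -> sigmoid) and is trained by
squared-error regression against normalized SA scores when
`TrainConfig(sa_head_weight > 0)`.  These guidance defaults are
approximations documented as such; the temperature -> infinity limit is
unguided sampling up to trajectory resampling noise.

Reconstruction builds an RDKit molecule from categories + coordinates;
validity requires valence sanitization and a single connected component
(`require_connected=False` relaxes the latter).

## Metrics

* **Shape similarity**: Tanimoto of Gaussian overlap volumes,
  V_AB / (V_AA + V_BB - V_AB), every heavy atom an identical isotropic
  Gaussian whose width matches a hard sphere of the carbon vdW radius
  (1.70 A, amplitude p = 2.7).  Computed in the shared pocket frame without
  alignment — the use-case is in-pocket comparison of generated and
  reference poses.
* **Chemical similarity**: Tanimoto of 2048-bit ECFP4 (Morgan radius-2)
  fingerprints.  Valence-invalid molecules are fingerprinted on their raw
  connectivity (ring perception + property cache only) so that similarity
  trends remain measurable for imperfect generations.
* **Drug-likeness**: QED, Crippen logP, H-bond acceptor/donor counts,
  heavy-atom count, normalized synthetic accessibility (10 - SA_raw)/9 in
  [0, 1], higher = easier.  The Lipinski-style count uses five criteria
  (MW <= 500, logP <= 5, HBD <= 5, HBA <= 10, rotatable bonds <= 10) — the
  five-rule convention of structure-based-design benchmarks, which makes
  counts above 4 possible.
* **Clash count**: (ligand, pocket) heavy-atom pairs with distance below
  r_vdw(i) + r_vdw(j) - 0.5 A, Bondi radii (configurable).
* **H-bond fingerprints**: bits over (residue id, direction), direction
  being donor-to-ligand or acceptor-from-ligand.  Ligand donors are N/O
  with unused valence (implicit H); acceptors all N/O; pocket N/O may take
  either role since explicit hydrogens are unavailable, and the criterion
  is distance-only (donor-acceptor heavy atoms <= 3.5 A).  Recovery is the
  mean over generated ligands of the percentage of reference bits
  recovered; a reference with an empty fingerprint is excluded with a
  warning (NaN).
* **Strain energy**: pose energy (MMFF94, UFF fallback; heavy atoms
  pinned, added hydrogens relaxed) minus the minimum energy over m = 20
  freshly embedded, fully relaxed conformers.  Negative values
  (conformer-search noise) clip to zero with a warning.  The force field
  and m are implementation choices, configurable.

## Synthetic study conditions

The fixture generator emulates valence-valid heavy-atom ligands of 5-15
atoms over {C, N, O} in cage pockets of 3-5-atom residues whose nearest
atom lies 3-6 A from the ligand.  Two families make latent conditioning
testable: family A, oxygen-terminated acyclic carbon chains; family B,
5/6-membered azacycles with carbon tails and no oxygen.  Geometry is
deliberately simplistic (bond lengths ~1.5 A with jitter, no angular
realism): sufficient for diffusion, conditioning, graph and interaction
tests; not for realistic strain energies, whose tests use separately
embedded and relaxed molecules.

The desk-scale conditioning study trains a 2-layer denoiser (width 48,
k = 16) with a 3-layer encoder on 200 complexes at T = 50 for 40 epochs,
batch 8, lr 2e-3 (larger than the full-scale default — small models at
small T train stably at larger steps), lam_min = 0.25.  This takes a few
minutes on one CPU core.  Conditioning efficacy is then measured as mean
ECFP4 similarity of generated samples to their seed, aggregated over 5
family-A seed complexes x 10 samples per condition (the lam sweep is a
set-level statement; a single toy pocket is idiosyncratic at this scale),
with common random numbers across conditions: the same RNG stream per
(pocket, sample) for every lam, so conditions share prior draws and
trajectory noise and differ only through lam — the standard paired-design
variance reduction.

What passing shows: the latent pathway carries seed information into the
reverse chain (conditioned similarity > unconditional), and the lam knob
modulates it monotonically.  What it does not show: absolute similarity,
validity or pose-quality levels comparable to a fully trained model —
validity of these tiny models is low single-digit percent, and strain
energies of toy geometries are meaningless.  Scaling depth/width/epochs to
the full defaults is a compute, not a code, change.

## Known limitations

* No docking integration; binding-affinity proxies are out of scope.
* Pocket atoms are fixed context; no protein flexibility.
* First PDB model only; no mmCIF; no protonation-state assignment.
* Bond vocabulary excludes a dedicated aromatic class (kekulized input).
* The minimal autodiff backend is single-threaded CPU float64; it is sized
  for desk-scale studies, not production training.
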