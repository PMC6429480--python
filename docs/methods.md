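# Methods

## Model and procedure

`groovedock` treats peptide–MHC binding as an anchored loop-modelling
problem. The premise is structural: class I grooves are closed at both
ends, and the peptide's first and last two residues occupy conserved
pockets whose backbone geometry varies little across solved complexes of
the same peptide length. Anchor coordinates can therefore be *transferred*
from one length-matched template onto any receptor of the same fold, after
a rigid groove superposition, reducing docking to (i) sampling backbones
that satisfy two fixed ends, (ii) packing sidechains, and (iii) local
energy refinement with a filter that rejects poses whose anchors left
their pockets.

Assumptions worth stating explicitly:

* the receptor backbone is rigid throughout; only sidechains near the
  peptide move, and only during minimization;
* peptide bonds are trans (ω = 180°); cis peptides are not sampled;
* all modelling is heavy-atom only, with hydrogen-bond capability encoded
  in donor/acceptor atom types rather than explicit protons;
* anchor transfer presumes the canonical binding register — peptides that
  bind with termini outside the A/F-pocket region fall outside the model.

## Stage details and numerical choices

**Superposition / RMSD.** Kabsch via SVD with a determinant correction (no
reflections). Degenerate (collinear or < 3-point) inputs raise. Angles are
degrees on [−180, 180) externally, radians internally.

**Chain building.** NeRF placement with Engh–Huber backbone geometry
(N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; N–CA–C 111.2°,
CA–C–N 116.6°, C–N–CA 121.7°, CA–C–O 120.8°). Carbonyl O sits in the
peptide plane anti to the next N.

**Closure.** The first two residues are copied verbatim from the anchor
spec; ψ of residue 2 is implied by the spec's residue-2 carbonyl O. Free
torsions (φ/ψ of the interior residues, plus the closing-end φ/ψ whose
rotations move only target atoms) start from a 3-basin Ramachandran
mixture — β (−120, 140), α (−63, −43), αL (60, 45), weights
0.45/0.45/0.10, σ = 20°; glycine mirrors with probability ½; proline's φ is
truncated-normal at −65 ± 25°. CCD visits torsions in random order and
applies the closed-form arctan rotation that minimizes the summed squared
distance of the six target atoms (N/CA/C of the last two residues) to the
anchors. Because plain CCD crawls in the endgame, once the target error
falls below 0.6 Å a Gauss–Newton step over all free torsions (analytic
rotation Jacobian, least squares, ±0.3 rad clip) polishes to the 0.1 Å
closure target; sweeps abort after 12 stalls. Odd restarts solve the
mirrored problem — the chain grown C→N from the C-terminal anchors with
targets at the N-terminus — then regenerate forward from the exact
N-terminal anchors, so both directions return NeRF-self-consistent chains
with residues 1–2 bit-exact on the spec. Torsions whose rotation block
would include seeded anchor atoms are excluded from the backward free set;
they are implied by the anchor coordinates. Anchor gaps beyond
3.9 Å × (intervening residues + 1) are rejected before iterating.

**Steric screening.** A conformation is discarded if any backbone heavy
atom sits closer than 0.6 × (R_i + R_j) to a receptor atom or to a peptide
atom ≥ 4 bonds away (radii: C 1.9, N 1.8, O 1.7, S 2.0, P 2.1 Å). The
factor is deliberately permissive: minimization downstream resolves soft
contacts, and the published stage this emulates also passed near-clashing
conformations through to refinement.

**Sidechains.** Ideal residue geometry and intra-residue connectivity come
from the CCD chemical-component templates bundled with biotite; each
residue is rigidly attached to its own N/CA/C frame and set to discrete
rotamers from a small backbone-independent library (1–4 entries per type,
canonical gauche/trans combinations, bundled as plain text). Greedy N→C
selection minimizes the clash count against the receptor plus the peptide
built so far, ignoring contacts with the adjacent residue (template
geometry keeps those physical); ties break to the higher prior weight,
then the lower library index. Proline keeps its template ring pucker.
Receptor threading (sequence onto a template backbone, indels unsupported)
uses the same placement but with exact bond-separation-aware clash
counting, since its output is judged by the global clash oracle.
Combinatorial packing is deliberately out of scope — the continuous χ
refinement during minimization does the fine-tuning.

**Scoring.** Weighted sum of Vina-family pair terms over the surface
distance d = r − (R_i + R_j): gauss1 = exp(−(d/0.5)²),
gauss2 = exp(−((d−3)/2)²), repulsion = d² (d < 0), hydrophobic (both
apolar): 1 for d ≤ 0.5 fading linearly to 0 at 1.5, hbond (donor–acceptor):
1 for d ≤ −0.7 fading to 0 at 0. Default weights −0.0356, −0.00516, 0.840,
−0.0351, −0.587 (published Vina values), cutoff 8 Å. An optional
screened-Coulomb term q_iq_j / max(r, 2)² with coarse per-type charges
(weight 0 by default) records the electrostatics option without asserting
a parameterization. Pairs: peptide–receptor within the cutoff plus
peptide-internal pairs ≥ 4 bonds apart; summation order is fixed, so equal
inputs give bit-equal sums. Atom typing is per-code: carbons bonded to
heteroatoms still count as hydrophobic (a coarsening relative to schemes
that demote them), and type-level charges are crude — both acceptable
because the terms they affect are weak or disabled by default.

**Minimization.** Torsional: peptide φ/ψ/χ, a 6-DOF rigid transform about
the initial centroid, and χ of receptor residues with sidechain atoms
within 4 Å of the peptide (GLY/ALA/PRO excluded). Coordinates are rebuilt
from internal coordinates each evaluation, so covalent geometry is ideal by
construction and the receptor backbone plus non-flexible sidechains are
bit-unmoved. Gradients are analytic — per-atom forces from the closed-form
term derivatives are contracted onto each torsion's rotation axis (exact
for this rebuild, since a torsion moves its downstream block rigidly); the
rigid rotation uses the SO(3) right Jacobian. This replaces naive
finite differencing, which costs 2 × DOF rebuilds per gradient and made
ensemble-scale studies impractical; agreement with central differences is
~1e−7. L-BFGS runs up to 30 iterations (gradient-norm tolerance 1e−3),
enough for local settling at ~0.3 s per pose; candidate receptor pairs are
gathered once with a 3 Å margin beyond the cutoff, and the returned pose is
re-scored exactly — if descent failed to improve the exact score, the input
pose is returned unchanged, so the final total never exceeds the initial.
Poses with near-coincident atoms get a short repulsion-only pre-descent;
anything still unscoreable is dropped, mirroring the published filter
behaviour.

**Rounds.** "Best scored" means lowest total over the pooled ensemble
(`--carry last-round` restores the literal previous-round reading; the two
coincide whenever rounds improve monotonically). The minimized receptor is
recycled; the groove superposition and anchor spec are recomputed against
it each round. Anchor-template recycling (re-deriving anchors from the
best pose) is implemented but disabled by default. The evaluation RMSD
superposes receptor grooves and then measures the peptide without
re-fitting; symmetry-equivalent sidechain atoms (PHE/TYR ring flips, etc.)
are not relabelled, which can overstate full-atom RMSD slightly.

## The synthetic groove

Real benchmarks need hundreds of PDB structures; the bundled generator
builds a desk-scale analogue instead: two poly-alanine α-helices (φ/ψ
−57/−47) run along x, 15.2 Å apart, above a five-strand floor (−120/140),
188 residues in one chain. The groove is *closed at both ends* by short
wall strands 6.0 Å beyond the planted peptide's terminal CA positions —
the toy counterpart of the A/F pockets, and the feature that makes the
anchor concept meaningful: without closed ends, unconstrained minimization
slides peptides along the groove axis. Helix CB stubs are omitted near the
ends (shallow clefts, giving the anchors ≥ 4 Å clearance to sample), and a
sculpting pass prunes any CB that interpenetrates another segment at the
0.6 clash factor, so the receptor is internally consistent under the same
criterion the pipeline applies. Planted peptides have leucine termini
(anchor-sidechain analogue) and chi-light interiors; the middle residues
get σ = 5° dihedral jitter while the terminal two at each end keep exact
extended geometry (anchor conservation), and the planted pose is locally
energy-relaxed before the anchor spec is derived — the planted reference
is a minimum of the scoring function, as a crystal structure is of
nature's.

What passing tests on this system do **not** show: realism of the MHC
fold, sequence-specific pocket preferences, β2-microglobulin effects,
water-mediated hydrogen bonding, or performance on crystallographic
receptors. The fixture validates the *machinery* — closure statistics,
packing, scoring exactness, descent, filtering, pooling, and the ability
to recover a planted binding mode (3 rounds × 50 samples recovers the
planted 9-mer to ≤ 0.73 Å minimum CA RMSD in 10/10 seeds at the default
settings; problem sizes chosen to keep the full study in the minutes
range on one core).

`perturb_pose` adds calibrated Cartesian jitter and re-idealizes covalent
geometry through the internal-coordinate rebuild, solving a one-parameter
amplitude model so the realized RMS displacement matches the request
within ~10%.

## Defaults

| parameter | default | meaning |
|---|---|---|
| samples / round | 100 | backbone conformations attempted per round |
| rounds | 10 | receptor-recycling iterations |
| anchor tolerance | 1.0 Å | allowed anchor-atom deviation during sampling |
| closure target | 0.1 Å | RMSD of closing-end N/CA/C to the anchors |
| clash factor | 0.6 | fraction of summed vdW radii treated as a clash |
| anchor filter | 2.0 Å | max post-minimization anchor CA deviation |
| flexible radius | 4.0 Å | receptor sidechains freed near the peptide |
| cutoff | 8.0 Å | pair-term interaction range |
| templates | 2VAA/1DUZ/1I4F/2NW3 | default anchor templates, 8–11-mers |

Lengths 12–15 require a user template; no default is bundled.

## Known limitations

* No cis-proline or D-amino-acid sampling; no symmetry-aware RMSD.
* The rotamer library is coarse by design; χ accuracy comes from the
  continuous refinement, not the discrete set.
* Binding-affinity ranking across different peptides is out of scope: the
  empirical score orders conformations of one peptide, not binders against
  non-binders.
* Template threading substitutes sidechains only — no indels, no backbone
  adjustment, no model quality assessment.
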