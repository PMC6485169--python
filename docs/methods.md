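# Methods

## Conformation representation

A chain of *l* residues is parameterized by its backbone dihedrals
(φ, ψ, ω), one triple per residue, normalized to (−180°, 180°]. Cartesian
coordinates of a reduced-atom chain — N, CA, C, carbonyl O and a single
side-chain centroid pseudo-atom CEN per residue — are a pure function of
the dihedrals and a fixed ideal trans-peptide geometry (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å, C–O 1.231 Å, CA–CEN 1.53 Å; textbook bond
angles). Atoms are placed sequentially by three-atom frame construction
(NeRF style), with residue 1 anchored at a canonical origin frame so that
rebuilds are bit-reproducible; because every score depends only on
internal distances, the canonical frame is immaterial. φ of residue 1 and
ψ/ω of residue *l* are stored but geometrically inert; the extended chain
is defined as all torsions at 180°. CEN is identity-independent: at this
resolution the model resolves topology, not side-chain packing.

The dihedral sign convention is IUPAC (checked against an independent
structural-biology library); consecutive CA–CA distance under ω = 180° is
3.804 Å and an ideal α-helix ((−57°, −47°)) has a rise of ≈1.55 Å/residue
with O(i)···N(i+4) ≈ 3.09 Å and O(i)···N(i+3) ≈ 3.21 Å — both inside the
hydrogen-bond window below, which is what lets the score see helices.

## Energy model

The staged scores are self-consistent analogs of the staged scoring used
by fragment-assembly protocols. They preserve each stage's *role*; their
values are in arbitrary units (a.u.) and are not comparable to any force
field's. All comparisons made with them in this package are internal.

* **steric** (stage-0 role): Σ ((r_clash − d)/r_clash)² over CA–CA and
  CEN–CEN pairs with sequence separation ≥ 2 and d < r_clash = 4.0 Å.
  Always ≥ 0; zero for the extended chain.
* **hydrogen bonds**: −1 a.u. per realized O(i)···N(j) bond, |i−j| ≥ 3,
  with the O···N distance in [2.6, 3.4] Å. There is no angular term, but
  donors and acceptors saturate: candidate in-window pairs are matched
  greedily by increasing distance, each O and each N realizing at most one
  bond. Saturation is essential, not cosmetic — counting every in-window
  pair makes the global optimum a maximally dense collapsed blob (an atom
  can harvest unbounded bond credits), and no weight assignment rescues
  that; one amide N–H donates one hydrogen bond. The missing angular term
  remains a real limitation: the model cannot distinguish a straight helix
  from a gently curved one, which bounds how precisely any search can
  recover an ideal-helix target (see "What the toy studies show").
* **score1** (stage-1 role) = w_steric·steric + w_hb·(hb_sr + hb_lr):
  collision avoidance plus secondary-structure formation.
* **score3** (stage-3 role) = score1 + w_rg·max(0, Rg − Rg₀(l))², with Rg
  the CA radius of gyration and Rg₀(l) = 2.2·l^0.38 Å, the empirical
  scaling of folded globular chains. Compaction enters the search only at
  this stage, which is the sense in which it is upweighted. The default
  w_rg = 0.3 is calibrated on the toy panel: it is the largest value at
  which a straight ideal helix still outscores kinked/collapsed
  alternatives (a kink buys ~25 a.u. of Rg relief for ~4 lost bonds at
  l = 30), while an extended chain still pays a dominant penalty
  (~166 a.u.). Larger values turn every native-like topology into a
  score3 loser against collapsed bundles.
* **objectives** (three-way decomposition whose sum is the total energy):
  E_sr = w_hb·(bonds with |i−j| ≤ s_cut = 4, i.e. helical i,i+3/i,i+4),
  E_lr = w_hb·(bonds with |i−j| > 4), E_other = weighted steric +
  compactness + a torsion-preference penalty of w_torsion = 0.1 a.u. per
  residue whose (φ, ψ) lies farther than 30° (Euclidean, wrapped) from
  every canonical basin center (helix (−57, −47), strand (−120, 120),
  left-handed (60, 45)).

Defaults: w_steric = w_hb = 1, w_rg = 0.3, w_torsion = 0.1; all exposed
under `energy:` in the YAML configuration. One *energy evaluation* is one
scoring call of any stage; the counter drives the run budget.

## Search operators

* **Metropolis rule**: downhill always accepted; uphill accepted with
  probability exp(−ΔE/α). α = 0 accepts only strictly lowering moves.
  ΔE = 0 at α > 0 is accepted with certainty (exp(0) = 1) — harmless for
  continuous scores, but the square-well score is piecewise constant, so
  flat-plateau walks are common; stage-2 initialization therefore carries
  an explicit attempt cap.
* **Initialization**: N extended chains; stage 1 randomizes each with f=9
  fragment moves under steric-only scoring at α = 0 (5·l attempted moves
  by default; fragment-assembly protocols do not standardize this length);
  stage 2 forms secondary structure under score1 at α = 2 until *l*
  consecutive rejections or 20·l attempts, whichever first.
* **Variation**: exactly one f=3 fragment replacement, unconditionally
  accepted (no Metropolis test) — pure exploration, ≤ 9 dihedrals changed.
* **Improvement**: greedy descent on score3 with f=3 moves; a move is
  accepted only if it strictly lowers the score (ties fail); stops after
  *k* consecutive failures. *k* defaults to *l*, mirroring the stage-2
  failure budget (no standard value exists; configurable). Most of the
  evaluation budget is spent here.
* **Selection** (`selection:` key): `evo_diverse` takes whole
  non-dominated fronts while they fit, then fills from the next front in
  descending crowding distance; `mea`, `mea_pr`, `mea_prpc` are the
  published baseline selectors. Strong dominance throughout; PR/PC are
  computed only within the current 2N individuals (no archive). All ties
  anywhere are broken by stable input order, so runs are reproducible
  bit-for-bit under a fixed seed.

## Engine and budget accounting

A run terminates on its evaluation budget only (default 10,000,000, the
full-scale protocol; desk-scale studies use ≤ 2×10⁵). Initialization
always completes — a run cannot proceed without a population — and the
generation loop then enforces the cap through a hard limit on the score
model: when an offspring pipeline would cross it, the engine finalizes
with the last complete population, so the consumed count never exceeds the
budget whenever the budget covers initialization. Every sampled decoy (the
initial population plus every improved offspring, surviving or not) is
archived: "lowest energy ever reached" and "lowest lRMSD ever reached" are
over everything sampled. `multi_run` executes R runs at seeds
seed+0…seed+R−1 (default 5) and summarizes extrema and
average-of-10-best per metric over the pooled archive.

## Structure metrics

CA lRMSD uses closed-form Kabsch superposition (SVD, reflections
excluded). TM-score (d₀ = max(0.5, 1.24(L−15)^⅓ − 1.8)) and GDT_TS (mean
maximal fraction within 1, 2, 4, 8 Å) both require maximizing over
superpositions; the search is the standard deterministic heuristic —
seeds from every contiguous window of lengths L, L/2, L/4, each refined by
re-superposing on the residues within d₀ (TM) or within the cutoff (GDT)
until the included set stabilizes. Tests bound the heuristic against an
independent exhaustive-seed reimplementation; like published reference
tools, the search is heuristic, so third-party implementations may differ
in the last digits.

## Exact tests

Head-to-head tables credit a target to an algorithm when its value is
strictly better *or tied* (a tie credits both sides — the convention
recovered from the published win counts, which sum to 11 over 10 targets
when one target ties). Fisher's one-sided test is the hypergeometric upper
tail P(X ≥ a), computed in exact integer arithmetic; two-sided values use
the doubling convention min(1, 2·one-sided), which the published two-sided
values follow exactly. Barnard's one-sided test is the unconditional
pooled-Wald variant: the p-value is the supremum over the nuisance success
probability π of P(T ≥ T_obs) under independent binomial rows, ties
included in the rejection region and zero-variance outcomes assigned
T = 0, evaluated on a π grid of step 10⁻⁴ with bounded local refinement.
This variant reproduces the published Barnard values to ~6 significant
digits on all non-degenerate tables; for the fully tied table the supremum
tends to 1 as π → 0, so the grid edge sets the fourth decimal.

## Synthetic data: what it emulates and what it does not

Toy targets are ideal-geometry folds (helix-20/30, a β-hairpin with a
tuned 4-residue turn, a mixed helix+strand topology). Synthetic fragment
libraries mimic server-built ones: at each position, a fraction
(default 30%) of the ≤ 200 configurations are the native window's torsions
plus Gaussian noise (default sd 10°), the rest draw (φ, ψ) from the three
canonical Ramachandran basins with near-trans ω. They emulate the
*structure* of real libraries — local, position-specific, mostly-wrong —
but not their sequence specificity, loop diversity, or the systematic
biases of fragment pickers; and the toy natives are idealized, clash-free
and single-chain. Passing the desk-scale studies therefore demonstrates
the mechanics of the algorithm (initialization, variation, improvement,
multi-objective survival, budget accounting) and the internal consistency
of energy and metrics — not predictive performance on real proteins.

## What the toy studies show (and their problem sizes)

The recovery study uses the helix-30 target, 30% near-native libraries at
10° noise, N = 50, a 2×10⁵-evaluation budget and 5 runs — sizes chosen so
the full study runs in about a minute per selector on one CPU. Under the
distance-only hydrogen-bond well, score3 is nearly flat across
locally-correct helices that differ by slow axis curvature, so recovery
below 2 Å rests on how densely the sampler populates that plateau; the
front+crowding selector also maintains the spread over E_sr/E_lr extremes
that keeps strongly bonded decoys alive. At these conditions 4–5 of 5
seeded runs reach < 2 Å and the diverse selector covers at least as many
1 Å lRMSD bins as total-energy truncation.

## Known limitations

No angular hydrogen-bond term, identity-independent centroid, no
solvation/electrostatics/statistics terms, single chain only, no
cis-proline, no crossover, no checkpointing or parallelism. Energies are
in a.u. and cannot be compared to published force-field values; published
benchmark results are reproduced at the statistics layer (from their
printed per-target values), not by re-running the benchmark.
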