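# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Precursor model

Actinoporin transcripts encode a prepropeptide: signal peptide, propeptide,
mature toxin. The package treats the signal length as a **family constant**
(default 19 residues) rather than running a signal-peptide predictor: within
this family the signal is invariant, and a fixed length keeps annotation
deterministic and auditable. The propeptide boundary is the first dibasic
Lys-Arg dimer strictly after the signal and within a bounded search window
(default 45 residues from the precursor start). The window prevents false
hits on Lys-Arg pairs inside the mature chain, which are common in these
lysine-rich toxins. Both values are arguments on every entry point.

Coordinates are 1-based and inclusive throughout, with mature-chain
numbering restarting at 1 at the first mature residue; this is the numbering
in which diagnostic residues ("Asn78") are expressed. ORF coordinates
exclude the stop codon, so a 209-residue precursor corresponds to a 627-nt
coding length. Kozak flags report adenines at −3 and +4 around the start
codon; they are annotations, not filters. Ambiguous `N` bases translate to
`X`; columns containing `X` are excluded from distance statistics together
with gap columns (flagged, never silently dropped).

## Substitution model and distances

The rate matrix is the published JTT empirical amino-acid replacement
matrix: symmetric exchangeabilities S and stationary frequencies π, with
Q = S·diag(π) rescaled so −Σᵢ πᵢQᵢᵢ = 1. Distances are therefore in
expected substitutions per site. Transition matrices come from the
symmetrised eigendecomposition (exact for a reversible Q), which the test
suite checks against the standard identities (zero row sums, detailed
balance, P(0)=I, Chapman–Kolmogorov, P(∞)→π) at 1e−10.

Rate heterogeneity is discrete-gamma with shape α = 1.7014 — the shape
under which this family's divergence values are defined — and k = 8
equal-probability categories, each represented by its conditional mean rate
(mean-per-category discretisation). k = 8 is close to the continuous
distribution at this α while staying cheap; k and α are arguments
everywhere. The probability-weighted mean of the category rates is exactly
1 for every (α, k) by construction.

A pairwise distance maximises the site-summed log-likelihood of the pooled
20×20 substitution counts over t ∈ [1e−9, 10] (Brent, tolerance 1e−8).
Identical rows short-circuit to exactly 0. Estimates pushed against the
upper bound are returned flagged `saturated`; a curvature standard error
(central differences at the optimum) is available on request. The estimator
is validated three ways: against a 1e−4 grid search of the same likelihood,
against R phangorn's `dist.ml` on frozen fixtures (agreement ~2e−5), and by
simulation calibration — mean bias ≤ 2% at d ∈ {0.05, 0.1, 0.3, 0.7} with
10⁴ sites and 100 seeded replicates.

Gap policy for all family statistics is **complete deletion** (only columns
with no gap and no `X` in any row), matching how the family's divergence
values are defined; pairwise deletion is available behind a flag. Group
divergence is reported as mean ± SD of the pairwise distances within or
between groups; singleton groups report undefined intra-group statistics
rather than zeros.

## Alignment

The family is indel-poor (members are ~93–99% identical), so a classic
progressive scheme suffices: 3-mer guide distances, average-linkage guide
tree, profile-profile Needleman–Wunsch/Gotoh merges with affine gaps
(BLOSUM62, open −10, extend −0.5). The pairwise step is verified against
Biopython's full-DP `PairwiseAligner` scores. Tie-breaking in the DP is
fixed (match, then gap-in-first, then gap-in-second), making alignments
deterministic. One row (by default the first) anchors the reference
numbering through a column map; all rule positions resolve through that
map, which is how A-type and S-type isoforms with different N-termini share
one position scheme.

## Trees

Topology inference is deliberately limited to neighbor joining — exact on
additive matrices and sufficient for validating cluster structure; ML
topology search is out of scope. Conventions: the Q-criterion minimum is
taken at the lowest (i, j) index pair on ties; negative branch lengths are
clamped to zero and counted on the returned tree. The implementation is
checked against closed-form three-taxon formulas, exhaustive least-squares
topology enumeration for n ≤ 6, and dendropy's NJ on near-additive
matrices. Bootstrap support is the percentage of column-resampled replicate
NJ trees containing each bipartition of the point tree (default 200
replicates); the resampling generator is explicit and seeded, so supports
are bit-reproducible.

## Physicochemistry

Masses are average (not monoisotopic) residue masses from the IUPAC table
shipped with Biopython, plus one water — the convention under which this
family's ~19.1–19.5 kDa values are computed. Net charge is a
Henderson–Hasselbalch sum over D, E, C, Y, H, K, R and the termini; pI is
the bisection root (|charge| < 1e−4, bracket < 1e−6 pH). The default pKa
set is the Bjellqvist/ExPASy-style table; because published pI values for
proteins like these are invariably web-tool outputs whose pKa sets are
unstated, the table is a named, swappable object and every profile records
which table produced it. Cross-checking against Biopython's independent
Bjellqvist implementation agrees within a few tenths of a pH unit (the two
differ in residue-specific terminal pKa refinements).

## Electrostatic descriptors

The N-terminal fragment (default residues 1–27, configurable — the fragment
definition behind published dipole tables is model-specific) is not
charge-neutral, so a dipole moment requires an origin convention: we use
the fragment centre of mass (unit atom masses unless masses are supplied)
and report it with every result. Directions are unit vectors in the input
structure's frame; 1 e·Å = 4.80320 D in one constant. For charge-neutral
fragments the moment is origin-independent; for charged fragments shifting
the origin by δ changes it by exactly −Qδ (asserted analytically in the
tests).

Potential comparison uses a **screened-Coulomb** field,
φ(p) = Σ qᵢ·exp(−dᵢ/λ)/(ε·dᵢ) with ε = 80 and optional Debye length λ,
sampled on a "skin" of lattice points whose distance to the nearest atomic
surface lies in [3, 7] Å (1 Å spacing; all configurable). This is a linear,
superposable simplification of a Poisson–Boltzmann solution: it preserves
the sign structure and relative geometry of the surface potential — which
is all the Hodgkin similarity index consumes — but not absolute magnitudes,
dielectric boundary effects, or ionic-strength response. Absolute dipole
magnitudes of molecular-dynamics-derived models are likewise out of scope;
the dipole machinery is validated on analytic fixtures instead. Clade
clustering is average-linkage on D = √(2 − 2·SI) over grids built on one
shared lattice, cut at k = 3; clade labels are assigned deterministically
by cluster size, then smallest member id.

## Synthetic data generator

The generator emulates the study system: a duplicated family of
near-identical precursors. Defaults are the study conditions — 43 members
(the family's size), a Yule tree scaled to height 0.05 substitutions/site
on the mature region, JTT+Γ(α = 1.7014) site evolution with per-site
category assignment, a conserved 19 + 15 prepropeptide evolving at 0.05×
the mature rate with the initiator Met and the Lys-Arg site pinned, and an
alternating A/S plan. Height 0.05 puts mean pairwise divergence near 0.07
substitutions/site with most pairwise identities in the family's 93–99%
band (extreme pairs on deep splits can fall somewhat below). The ancestor
is a synthetic 209-residue precursor carrying the family's functional
landmarks (³⁰SRK³², Lys77, aromatic 112, an RGD motif) and deliberately
*non*-diagnostic residues at every classification position, so group labels
exist only where the group plan injects them.

Design choices worth recording: simulation is protein-level with
uniform-codon reverse translation (downstream statistics are protein-level;
nucleotide identity is not a simulation target); diagnostic residues and
the A/S first residue are overwritten *after* evolution so ground-truth
labels are exact; no indels are simulated (the family is indel-poor), so
generated alignments are trivially gap-free. Transcripts embed the coding
sequence at positions 40–666 of a 747-nt message with Kozak adenines at −3
and +4 and no upstream ATG.

What passing tests on generator output do **not** show: robustness to
indels or alignment error, to codon-level selection, to base-composition
artefacts in real cDNA, or to model misspecification (data are simulated
under the same JTT+Γ family used for estimation — which is precisely what
makes the calibration checks interpretable).

Charged-structure fixtures are ideal α-helices (rise 1.5 Å, 100°/residue,
one charge per residue) with optional rotation and Gaussian coordinate
noise; three charge layouts mimic the membrane-directed, core-directed and
intermediate dipole archetypes observed across such families.

## Deposited-data analyses

Statistics of the real cloned family (mean intraspecific divergence, group
IC divergence, specific pairwise distances, S/A counts, mass and pI ranges)
are reproduced by the same code paths from the public GenBank records
(MG887781–MG887823 plus previously published isoforms). The package ships
no copy of those records; `actinofam.io.load_deposited_dataset` documents
the expected local layout and fails with an explicit error when the data
are absent. Two caveats apply even with the data in place: the exact
membership of the published dataset behind the intraspecific mean is not
enumerated, and the discretisation inside the original distance software is
not stated — both are absorbed by the ±0.005 tolerance used for those
checks.

## Problem sizes

Default test and acceptance runs use families of 8–16 leaves (43 for the
family-statistics summary), 175-site matures (1200 sites where topology
recovery needs resolution), 10⁴-site pairs × 100 replicates for estimator
calibration, 5–25 bootstrap replicates in tests (200 is the analysis
default), and 12 charged structures on 1.5 Å lattices for clade recovery.
These sizes keep the whole suite fast while leaving every statistical check
comfortably powered.

## Known limitations

- Signal peptides are fixed-length by design; a precursor with an atypical
  signal would need the length argument changed.
- NJ is the only tree method; deep or rate-heterogeneous phylogenies
  deserve a likelihood topology search outside this package.
- The screened-Coulomb skin potential is not a Poisson–Boltzmann solution;
  similarity *rankings* are meaningful, absolute potentials are not.
- pI values inherit the arbitrariness of the chosen pKa table (±0.1–0.3 pH
  between reasonable tables).
- The activity summary ingests measured activities as annotations; the
  package does not predict hemolytic activity from sequence.
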