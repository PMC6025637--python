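# actinofam

Analysis toolkit for a sea-anemone **actinoporin multigene family**:
pore-forming ~19–20 kDa toxins expressed as prepropeptide transcripts and
diversified by gene duplication.  The package is aimed at molecular
toxinologists and molecular-evolution researchers who need to go from cloned
cDNA sequences to a quantitative picture of a toxin family: precursor
architecture, isoform typing, divergence statistics, phylogenetic clusters,
diagnostic-residue groups, physicochemical profiles, and N-terminal
electrostatic descriptors.

## What it computes

**Precursor annotation.** Each transcript is scanned for ATG..stop open
reading frames (with Kozak-context flags at −3/+4); the translated precursor
is segmented into a fixed-length signal peptide (family consensus: 19
residues), a propeptide ending at the first dibasic Lys-Arg cleavage site,
and the mature toxin, typed **A** or **S** by its first residue.

**Divergence.** Pairwise distances are maximum-likelihood estimates under
the JTT empirical substitution model with discrete-gamma rate heterogeneity
(shape α = 1.7014, 8 equal-probability categories by default), computed on
gap-free alignment columns (complete deletion).  For aligned rows *x*, *y*
the distance *t̂* maximises

    ℓ(t) = Σ_sites log[ π_a · (1/k) Σ_c P(b | a, r_c t) ]

with *P(t) = exp(Qt)*, *Q* the JTT rate matrix normalised to one expected
substitution per site, and *r_c* the discrete-gamma category rates.  Group
divergence is reported as mean ± SD of pairwise distances; trees are
neighbor-joining with column-bootstrap support percentages.

**Classification.** Sequence groups (IA, IB, IC, ID with subgroups, IE) are
assigned from a declarative table of diagnostic residues at mature-reference
positions (e.g. Asn78 + Glu82 + Asp96 → IC; Asp/Glu10 + Lys21 + Asp78 → ID),
with functional hotspot checks (³⁰SRK³², Lys77, the aromatic POC site, the
RGD motif).

**Physicochemistry.** Average molecular mass, Henderson–Hasselbalch net
charge, and bisection isoelectric points under a swappable pKa table
(Bjellqvist/ExPASy-style by default).

**Electrostatics.** From PQR structures: N-terminal fragment dipole moments
(μ = Σ qᵢ(rᵢ − r_com), 1 e·Å = 4.80320 D) and clade clustering of
screened-Coulomb skin potentials by Hodgkin similarity,
SI = 2⟨φ₁φ₂⟩/(⟨φ₁²⟩+⟨φ₂²⟩).

**Synthetic families.** A seeded generator produces actinoporin-like gene
families on Yule trees with exact ground truth (tree, path distances, A/S
plan, injected group residues, charged helix structures), so the entire
pipeline is testable without any downloads.

## Worked example

Simulate an eight-member family, annotate the transcripts, and estimate
divergence:

```text
$ actinofam simulate --n-leaves 8 --seed 11 --out-prefix fam
wrote fam_protein.fasta, fam_cdna.fasta, fam_truth.json

$ actinofam annotate fam_cdna.fasta
iso01   signal=1-19     pro=20-34       mature=35-209   n_type=S
iso02   signal=1-19     pro=20-34       mature=35-209   n_type=A
...
```

Every precursor is 209 residues: a 19-residue signal, a 15-residue
propeptide ending Lys-Arg at position 34, and a 175-residue mature chain
starting Ala (A-type) or Ser (S-type).

```text
$ actinofam distances fam_protein.fasta | head -4
id_a    id_b    distance        log_likelihood  converged       saturated
iso01   iso02   0.0895  -701.85 True    False
iso01   iso03   0.0728  -685.40 True    False
iso01   iso04   0.0883  -701.30 True    False
```

Distances are in expected substitutions per site: iso01 and iso02 differ by
about 0.09 substitutions per site under JTT+Γ, typical intra-family
divergence for this kind of duplicated toxin family (~0.07 on average).

```text
$ actinofam activity
        geometric_mean_hu_per_mg
Clade I 29776.11105907656
Clade II        1613.4286460245435
```

The packaged activity table (hemolytic units per mg for the family's
recombinant members) gives Clade I a geometric-mean activity ~18-fold above
Clade II — the order-of-magnitude gap that tracks the membrane-directed
N-terminal dipole of Clade I members.

The full pipeline (`actinofam run --input-fasta ... --output-dir out`)
writes isoform, physicochemistry, distance, group, hotspot and logo tables,
a Newick tree with bootstrap supports, and a run log; outputs embed the
configuration hash and are byte-identical on re-runs with the same inputs
and seed.

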