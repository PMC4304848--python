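# quadpot

Tessellation-based four-body statistical potentials and structure-based
computational mutagenesis for proteins.

## The problem

How much does a single amino-acid substitution perturb a protein's
structure, and can that perturbation predict whether the mutant keeps its
function? `quadpot` answers this with a coarse-grained, knowledge-based
approach: each residue is reduced to its Cα atom, the Delaunay tessellation
of the Cα point set objectively identifies every quadruplet of
nearest-neighbor residues as the four vertices of a tetrahedron, and a
statistical potential over quadruplet types converts structure into score.
The toolkit is aimed at structural bioinformaticians who want to train such
potentials on structure corpora, score variants of a target protein (the
reference use case is *E. coli* thymidylate synthase), and build predictive
models of variant activity.

## The model

For a corpus of tessellated structures (edges longer than 12 Å removed,
along with every tetrahedron using them), the observed relative frequency
f<sub>ijkl</sub> of each of the C(23, 4) = 8,855 unordered residue
quadruplets (i, j, k, l) is compared with its multinomial chance
expectation

&nbsp;&nbsp;&nbsp;&nbsp;p<sub>ijkl</sub> = 4! / (∏<sub>n</sub> t<sub>n</sub>!) · ∏<sub>n</sub> a<sub>n</sub><sup>t<sub>n</sub></sup>,

where a<sub>n</sub> is the corpus amino-acid composition and t<sub>n</sub>
counts repeats of type n in the quadruplet. The quadruplet score is the
log-likelihood ratio s<sub>ijkl</sub> = log(f<sub>ijkl</sub>/p<sub>ijkl</sub>)
(inverted-Boltzmann form; the sign convention is configurable). From the
8,855 scores everything else follows:

- **total potential** tp = Σ tetrahedron scores of a structure;
- **residue environment score** q<sub>i</sub> = Σ scores of tetrahedra
  incident to position i (the vector over positions is the 3D-1D profile,
  with Σ q<sub>i</sub> = 4·tp);
- **computational mutagenesis**: a substitution relabels one Cα vertex
  without re-tessellating; EP<sub>i</sub> = q<sub>i,mut</sub> −
  q<sub>i,wt</sub> is nonzero only at the mutated position and its
  tessellation neighbors, and the EP at the mutated position — the
  **residual score** — identically equals tp<sub>mut</sub> − tp<sub>wt</sub>;
- **CMP<sub>i</sub>** = mean residual score of the 19 possible
  substitutions at position i.

Variants are encoded as 27-attribute feature vectors (position, native and
replacement residues, residual score, EP/identity/sequence-offset of the
six nearest neighbors, mean incident-tetrahedron volume and tetrahedrality,
secondary structure, tessellation depth, surface-edge count) and fed to
RF / SVM / DT / NN classifiers with LOOCV, repeated 10-fold CV,
label-permutation significance tests and learning curves.

## Worked example

Everything below runs offline on synthetic data generated by the package
itself (a real workflow would replace the simulated corpus and target with
PDB files):

```bash
quadpot simulate corpus --n 6 --min-size 60 --max-size 100 --seed 11 --out corpus
quadpot train-potential --corpus corpus/manifest.txt --out potential.tsv
# -> trained on 6 chains (2031 tetrahedra); wrote potential.tsv

quadpot simulate structure --n 100 --seed 5 --out target.pdb
quadpot score --pdb target.pdb --potential potential.tsv --variant F10A --out profile.tsv
# -> residual score of F10A: 0.227686; wrote profile.tsv
```

`profile.tsv` holds the residual profile; its nonzero rows are exactly the
mutated position 10 and its tessellation neighbors:

```
position  aa        ep
       5   Q  0.194722
       6   S  0.583724
       8   G  0.176239
       9   R -0.018336
      10   F  0.227686   <- residual score (= tp_mut - tp_wt)
      11   T -0.337702
      ...
```

The per-position native environment scores and comprehensive mutational
profile come from `quadpot cmp`:

```bash
quadpot cmp --pdb target.pdb --potential potential.tsv --out cmp.tsv
# -> total potential -46.377735; wrote cmp.tsv
```

Regressing CMP on the native environment score across the 100 positions of
this toy target gives slope −0.700, R² = 0.655 — the inverse
CMP-vs-RES correlation characteristic of this methodology: positions with
favorable native environments are, on average, the ones most damaged by
substitution.

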