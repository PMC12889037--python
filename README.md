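# wmkdiv

Sequence and conformational-ensemble divergence analysis for families of
two-domain DNA-binding homologs, built around the Wmk (WO-mediated
killing) proteins of *Wolbachia* — candidate male-killing factors whose
homologs split into a "type-I" group (≥ 72% identity to the wMel
reference) and highly divergent "distant" homologs (wZbi-Wmk, wBif-Wmk)
that carry large inter-domain-linker (IDL) deletions yet keep both
helix-turn-helix (HTH) domains.

The package is for structural bioinformaticians who have per-homolog
conformational ensembles (e.g. snapshots from MD simulations of predicted
structures) plus sequences and an MSA, and want to quantify:

- **sequence divergence** — global-alignment identity and type-I/distant
  classification, per-position Shannon-entropy conservation
  (score = 1 − H/log₂20) and the conservation *differential* between an
  alignment with and without the distant homologs, indel blocks mapped to
  reference numbering, HTH fingerprint motifs ("shs"/"phs" triplets) and
  sliding net-charge profiles, and domain arithmetic;
- **ensemble behaviour per homolog** — RMSD/Rg series after a 20 ns
  equilibration offset, median ± MAD summaries, pairwise Wilcoxon
  rank-sum tests across homologs, the dynamic cross-correlation matrix
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) and Cartesian trajectory PCA
  with principal-motion interpolation;
- **structural divergence across homologs** — exhaustive pairwise
  TM-scores, TM = (1/L)Σ 1/(1+(d_i/d0)²) with
  d0 = max(1.24(L−15)^⅓ − 1.8, 0.5), over an MSA-fixed correspondence on
  eight conformations sampled per homolog (25–95 ns, 10 ns steps);
  iterative core-residue finding; joint PCA anchored on the core; outlier
  ranking and progressive outlier removal.

A seeded synthetic homolog-family generator (`wmkdiv.synthdata`) produces
families with known ground truth — planted group labels, indels, hinge
angles, stable-domain positions — so every stage has a recovery test
without any downloads. See `docs/methods.md` for models, conventions and
limitations.

## Worked example

Generate a synthetic family (reference + 5 type-I + 2 distant homologs,
21-frame hinge ensembles each) and run the full pipeline:

```bash
wmkdiv simulate --seed 11 --out-dir results/family
wmkdiv run-all --data-dir results/family --out-dir results/out --seed 11
```

or, stage by stage, the numbered drivers:

```bash
python analysis/01_simulate_family.py 11
python analysis/02_sequence_divergence.py
python analysis/03_ensemble_descriptors.py
python analysis/04_single_homolog_dynamics.py
python analysis/05_structural_divergence.py
```

Output of the drivers at seed 11 (abridged):

```
classification: 7/7 non-reference labels recovered
indel recovery exact: True
domain lengths: {'N-ext': 20, 'N-domain': 55, 'linker': 62, 'C-domain': 55, 'C-ext': 30}
inter-domain gaps: {... 'linker..C-domain': 0 ...}
ref: inter-domain DCCM -0.72, PC1 77.8% of variance, |Spearman(PC1, hinge angle)| = 1.000
core: 55 positions, 100% inside the stable domain 21-75
TM between_group: median 0.45 (range 0.44-0.47, n=768)
TM within_group: median 0.55 (range 0.45-0.73, n=1024)
TM within_homolog: median 0.78 (range 0.51-0.92, n=224)
outlier ranking: ['d1', 'd2', 't1', 't3', 't5', 't2', 'ref', 't4']
progressive removal: ['d1', 'd2'] medians [0.473, 0.504, 0.566]
```

Reading this: classification recovers the planted type-I/distant split
from sequence identity alone; the two distant homologs' planted
~32–36-residue linker deletions and ~7–9-residue post-domain insertions
are recovered exactly from the MSA; each ensemble shows the anti-correlated
(negative DCCM) hinge motion of its two domains, with PC1 carrying most of
the variance and tracking the true hinge angle; the core residues of
minimal positional variability all fall in the stable N-domain; and the
TM-score medians order as within-homolog > within-group > between-group,
so conformational spread within a homolog is smaller than fold divergence
between groups — removing the two most outlying homologs raises the
between-homolog median from 0.47 to 0.57.

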