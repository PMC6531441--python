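# bowspace

Drug–target interaction prediction from a joint protein–ligand descriptor
("bow-pharmacological space") with probabilistic sum-of-trees
classification.

## The problem

Given a protein (by sequence), a small molecule (by structure), and a
network of already-known protein–ligand interactions, predict whether the
pair interacts — and how confidently. Classical chemogenomic models encode
the protein and the ligand; `bowspace` additionally encodes the
*interaction space*: what a protein's known ligands look like, so a
candidate can be judged against the protein's established pharmacology.
The package is aimed at computational chemists and bioinformaticians
triaging candidate interactions before experiments.

## The descriptor and the model

A pair (p, ℓ) becomes a 439-dimensional vector

```
x(p, ℓ) = [ F1…F10(p) | MACCSL(ℓ) | MACCSP(p) ]      (107 + 166 + 166)
```

* **F1–F10** — ten sequence feature sets: composition vector CVᵢ =
  nᵢ/N; composition moment vectors CMVᵢᵏ = Σⱼ n₍ᵢⱼ₎ᵏ / N(N−1)…(N−k) for
  k = 1, 2; three physicochemical descriptors over seven property scales —
  summed values (BPC), neighbourhood terms Σᵢ |Pᵢ² − Pᵢ₋₁Pᵢ₊₁| (NPC), and
  the sequence-order correlation IPC = (Σₖ δₖ)/(N−1) with
  δₖ = (1/(N−k)) Σᵢ [P(Rᵢ₊ₖ) − P(Rᵢ)]² on standardized scales; and five
  residue-grouping compositions (R, electronic, exchange, hydrophobicity,
  side-chain groups).
* **MACCSL** — the 166 informative MACCS structural keys of the ligand.
* **MACCSP** — the element-wise mean of the MACCS fingerprints of the
  protein's known ligands in a reference network (zeros for proteins with
  no known partner).

Five classifiers consume this matrix behind one interface: Bayesian
additive regression trees (probit sum-of-trees fitted by backfitting MCMC,
emitting a posterior-mean interaction probability *and* a 95% posterior
interval), logistic regression (C = 1e5), an RBF SVM (gamma = 1e−4,
C = 100), a decision tree and a random forest. Probabilities above 0.5
mean "interaction". Boruta-style shadow-feature selection and
ROC/AUC/confusion-matrix evaluation with stratified 10-fold CV complete
the pipeline. See `docs/methods.md` for model details and design choices.

## Worked example

```python
import pandas as pd
from bowspace.protein import ProteinSequence, protein_feature_frame, protein_feature_block
from bowspace.ligand import LigandRecord, fingerprint_table
from bowspace.bow import InteractionNetwork, assemble_bow

seq = ProteinSequence("kinase1",
    "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ")
block = protein_feature_block(seq)
print("cv_A =", round(block.cv[0], 4),
      " ipc_hydrophobicity =", round(block.ipc[0], 4))

ligs = [LigandRecord(id="aspirin",   structure="CC(=O)Oc1ccccc1C(=O)O"),
        LigandRecord(id="caffeine",  structure="Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
        LigandRecord(id="ibuprofen", structure="CC(C)Cc1ccc(cc1)C(C)C(=O)O")]
fps, rejects = fingerprint_table(ligs)
print("fingerprint bits set:", {k: int(v) for k, v in fps.sum(axis=1).items()})

net = InteractionNetwork.from_edges(
    [("kinase1", "aspirin"), ("kinase1", "ibuprofen")], ligands=["caffeine"])
vec = assemble_bow("kinase1", "caffeine",
                   protein_feature_frame([seq]), fps, net)
print("bow vector length:", vec.shape[0])
```

prints

```
cv_A = 0.1061  ipc_hydrophobicity = 2.3943
fingerprint bits set: {'aspirin': 21, 'caffeine': 46, 'ibuprofen': 15}
bow vector length: 439
```

`cv_A` is the alanine fraction of the sequence; `ipc_hydrophobicity` is
the hydropathy sequence-order correlation (0 for a homopolymer, larger
the more hydropathy varies along the chain); the bit counts are how many
of the 166 substructure keys each molecule sets. The last 166 entries of
`vec` average aspirin's and ibuprofen's fingerprints — kinase1's known
pharmacology — so each MACCSP entry here is 0, 0.5 or 1. The vector can
be fed to `bowspace.classifiers.train` / `predict_proba`, which for the
`bart` model also returns a per-pair posterior interval.

The same pipeline runs from the shell (`bowspace simulate | featurize-*
| build-bow | make-dataset | train | predict | crossval |
select-features`), with each output accompanied by a reproducibility
manifest.

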