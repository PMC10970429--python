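# wpcna — weighted peptide co-expression network analysis

`wpcna` links a phosphopeptide log2-intensity matrix to a behavioral
outcome — a home-cage discrimination-learning index — through a weighted
co-expression network. It targets studies of the kind where ~20 mice in
four genotype × exposure groups (tau-transgenic rTg4510 vs non-carrier,
blast vs sham) are profiled by quantitative phosphoproteomics and
phenotyped on a CognitionWall task, and the question is which groups of
co-regulated phosphopeptides track, and predict, learning.

## The model

**Behavior.** Each animal's learning index over a 48-h session is

```
LI = (CE₂ − IE₂)/TE₂ − (CE₁ − IE₁)/TE₁
```

with CE/IE/TE the correct/incorrect/total entry counts per day. The
index is banded into a 5-point learning level by standard deviations
from the cohort mean (level ≥ 4 ⇔ index ≥ mean).

**Network.** For peptide profiles xᵢ over animals:

```
sᵢⱼ = |cor(xᵢ, xⱼ)|                      similarity
aᵢⱼ = sᵢⱼ^β                              soft-thresholded adjacency
TOMᵢⱼ = (Σᵤ aᵢᵤ aᵤⱼ + aᵢⱼ) / (min(kᵢ, kⱼ) + 1 − aᵢⱼ)
```

β is chosen so the connectivity distribution approximates a power law
(scale-free topology criterion). Modules are branches of the
average-linkage dendrogram on 1 − TOM, read off with a static,
dynamic, or dynamic-hybrid tree cut; unassigned peptides are "grey".
Each module is summarized by its **eigenpeptide** (first principal
component over animals), with membership kME(i) = cor(xᵢ, ME).

**Inference.** Peptide significance PS = cor(xᵢ, LI) drives marginal
screening and module significance (mean |PS|); module eigenpeptides are
scored as classifiers of the binarized learning level via nonparametric
ROC (Mann–Whitney AUC, Hanley–McNeil CI, K-S separation). Candidate
peptides come from an individual-level cumulative distance for a focal
outlier animal, `(I₀−avg I_bt) + (I₀−avg I_st) + (I₀−avg I_sn)`, and a
five-contrast integrative rank sum over |log2 fold change| and −log10 p.

A fully tested synthetic-data generator plants known modules, a known
trait association and matching entry logs, so every stage can be checked
against ground truth.

## Worked example

```python
import wpcna
from wpcna import network as net
from wpcna.modules import cut_dynamic_hybrid, peptide_tree

study = wpcna.simulate_study(seed=0)          # 20 animals, 1000 peptides
X, _ = net.drop_unusable_peptides(study.intensities)
S = wpcna.similarity_matrix(X)
D = wpcna.tom_dissimilarity(wpcna.tom_similarity(wpcna.adjacency(S, 8)))
tree, ids = peptide_tree(D)
modules = cut_dynamic_hybrid(tree, ids, D)

outcomes = wpcna.outcomes_from_entry_logs(study.entry_logs)
ME, _ = wpcna.module_eigenpeptides(X, modules)
print(wpcna.predict_learning(ME, outcomes.loc[list(ME.columns)]))
```

prints (see `examples/predict_learning.py` for the full script):

```
             auc     se  ci_lo  ci_hi  p_value     ks  n_pos  n_neg
module
turquoise  0.885  0.085  0.718  1.000    0.004  0.667      8     12
blue       0.667  0.129  0.415  0.919    0.217  0.417      8     12
brown      0.438  0.133  0.177  0.698    0.643  0.500      8     12
```

The turquoise module — the detected module carrying the planted
learning-associated factor — separates above- from below-average
learners with AUC 0.885 (chance = 0.5) and a K-S separation of 0.667;
the other modules sit near chance, as they should.

`examples/` contains one narrative script per capability (simulation,
behavior, network construction, module detection, prediction, candidate
prioritization, and the end-to-end pipeline); each builds a small input,
runs the method and explains the numbers it prints.
`wpcna.run_pipeline` chains all stages and writes TSV artifacts plus a
JSON run manifest.

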