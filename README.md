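# em3p2 — uncertainty-aware few-shot molecular property prediction

Supervised molecular property prediction (toxicity, side effects, target
binding) suffers from two chronic problems: labeled data are scarce and
heavily imbalanced, and standard classifiers are overconfident exactly where
they are wrong.  `em3p2` implements an **evidential meta-model**: a Graph
Isomorphism Network (GIN) classifier whose head outputs Dirichlet *evidence*
rather than softmax probabilities, trained across many related property tasks
under a MAML-style meta-learning loop so it can adapt to a new task from a
handful of labeled molecules — and that says *"I don't know"* when its
uncertainty is too high.

It is aimed at computational chemists and ML researchers working on few-shot
molecular property prediction who need per-prediction uncertainty for
selective prediction or triage.

## The model

**Encoder.** A K-layer GIN over the molecular graph,

    h_v^(k) = MLP^(k)( (1 + ε^(k)) · h_v^(k−1) + Σ_{u∈N(v)} h_u^(k−1) ),

with h_v^(0) the summed learned embeddings of categorical atom features and a
mean readout h_g = MEAN_v h_v^(K).

**Evidential head.** A shared MLP Ψ maps h_g to C raw outputs.  ReLU turns
them into evidence e ≥ 0; with Dirichlet concentration α_c = e_c + 1 and
strength S = Σ_c α_c,

    p̂_c = α_c / S,   confidence = max_c p̂_c,   uncertainty u = C / S,

so u + Σ_c e_c/S = 1 (subjective logic): zero evidence means u = 1.

**Losses.** Training combines the Dirichlet cross-entropy
Σ_j y_j (ψ(S) − ψ(α_j)) (ψ the digamma), a belief regularizer
‖e ⊙ (1−y)‖₁ penalizing evidence on false classes, and an
accuracy-versus-uncertainty (AvUC) calibration term
−λ_c Σ_correct p log(1−u) − (1−λ_c) Σ_incorrect (1−p) log u.
The regularizer weights anneal from λ₀ up to (1.0, 0.1) over training.

**Meta-learning.** Each epoch, every training task contributes: adapt
Θ′ = Θ − α∇L_support (plain cross-entropy, 1 step), evaluate the adapted
model's evidential loss on a **class-balanced query set** (exactly M/C per
class — the query-balancing step that prevents majority-class collapse under
imbalance), then update Θ through a task-attention-weighted sum of query
losses with second-order MAML gradients.  At test time the meta-model adapts
to the new task's support set under the evidential loss and reports evidence,
uncertainty and a predict/reject decision per query molecule.

Inputs are MoleculeNet-dialect CSVs (a `smiles` column plus one binary column
per task, blanks = unlabeled) or the package's own JSONL fixture format.  A
synthetic generator produces planted-motif graph-classification task families
with controllable class imbalance, so the full pipeline runs and is tested
without any downloads.

## Worked example

Train on four synthetic planted-motif tasks and adapt to two held-out tasks
(10 labeled molecules each):

```python
import numpy as np
from em3p2 import learning_sanity_run, evaluate_meta_test, roc_auc, threshold_curve

state, collection, config = learning_sanity_run(seed=1)   # 30 epochs, ~5 s
results = evaluate_meta_test(state, collection, config, eval_seed=7)
for r in results:
    auc = roc_auc([o.probs[1] for o in r.outputs], r.labels)
    u = np.array([o.uncertainty for o in r.outputs])
    pred = np.array([o.predicted_class for o in r.outputs])
    print(f"{r.task_id}: ROC-AUC {auc:.3f}, "
          f"mean u correct {u[pred == r.labels].mean():.3f}, "
          f"mean u wrong {u[pred != r.labels].mean():.3f}")

outputs = [o for r in results for o in r.outputs]
labels = np.concatenate([r.labels for r in results])
curve = threshold_curve(outputs, labels, [0.1, 0.4, 1.0])
for t, acc, cov in zip(curve.thresholds, curve.accuracy_at, curve.coverage_at):
    print(f"u <= {t}: accuracy {acc if acc is None else round(acc, 3)}, coverage {cov:.2f}")
```

prints

```
task3-C6: ROC-AUC 0.992, mean u correct 0.366, mean u wrong 0.843
task5-C8: ROC-AUC 1.000, mean u correct 0.451, mean u wrong 0.997
u <= 0.1: accuracy None, coverage 0.00
u <= 0.4: accuracy 0.982, coverage 0.40
u <= 1.0: accuracy 0.664, coverage 1.00
```

The meta-model ranks held-out-task molecules almost perfectly (ROC-AUC 0.99+),
its wrong predictions carry visibly higher uncertainty than its correct ones,
and rejecting predictions with u > 0.4 raises accuracy from 66% to 98% while
keeping 40% of the molecules — the selective-prediction trade the evidential
head exists for.

The same pipeline is available from the shell:

```bash
em3p2 simulate --config sim.yaml --out tasks.jsonl
em3p2 train    --data tasks.jsonl --config train.yaml --out run/
em3p2 test     --run run/ --task task5-C8 --n-shot 10 --threshold 0.3
em3p2 evaluate --run run/ --report report.json
```

`train` writes a self-describing run directory (resolved config, manifest with
seeds and library versions, checkpoints, per-epoch loss/attention logs);
`evaluate` writes per-task ROC-AUC, minority-class precision, threshold
curves, AvUC counts and per-molecule evidence records as JSON.

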