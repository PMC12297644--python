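# cardiovault

Secured heart-disease prediction as a single, testable Python library:
synthetic patient cohorts on the Cleveland heart-disease schema are
encrypted with a matrix-RSA hybrid block cipher, committed to a
Merkle-rooted hash-chain ledger, audited, decrypted, and classified by a
small neural network whose hyperparameters are tuned by the Archimedes
Optimization Algorithm (AOA).

It is aimed at researchers studying secure clinical-ML pipelines who need
every stage — cryptography, integrity auditing, training, tuning,
evaluation — reproducible, inspectable, and verifiable against ground
truth, without real patient data or external services.

> **Security note.** The cipher here is an *educational / fidelity*
> construction (Hill-style mixing over Z_n composed with textbook RSA).
> It is not audited cryptography: no padding scheme, no constant-time
> guarantees, test-scale keys by default. Do not protect real data with it.

## The pieces

**Archimedes Optimization Algorithm.** A population metaheuristic: each
candidate is an "object" with position Z, density, volume and acceleration.
Densities and volumes are pulled toward the best object,
`Den' = Den + R (Den_best − Den)`, a transfer operator
`TO = exp((T − T_max)/T_max)` switches from collision-driven exploration
(TO ≤ 0.5) to buoyant exploitation around the best object (TO > 0.5), and a
decreasing density factor shrinks step sizes to 0 at the final iteration.
Two formula dialects are implemented (`canonical`, default, and `paper`);
see `docs/methods.md`.

**Matrix-RSA cipher.** Keys are an RSA pair (n = xy, e, d) plus an
invertible k×k matrix A over Z_n with its modular inverse. Encryption of a
k-block M is `c_i = (A·M)_i^e mod n`; decryption applies d then A⁻¹.
Because n is squarefree the map is a bijection on all of Z_n.

**Ledger.** SHA-256 Merkle trees (leaf prefix `0x00`, node prefix `0x01`,
odd-node duplication) over ciphertext digests; blocks hash-chained from a
zero genesis; audit, log-generation and log-checking roles with
hash-chained audit logs. Any single-bit tamper is detected.

**Classifier.** Optional 1-D convolution + batch-norm over the ordered
13-feature vector, a 100-unit dense ReLU layer, inverted dropout, 2-way
softmax; explicit mini-batch SGD with momentum and hand-derived gradients
(finite-difference checked). Baseline setting: lr 0.1, 32 epochs, dropout
0.243, batch 8.

**Tuning.** AOA searches a unit box decoding to (learning rate on log10
scale, momentum, epochs, dropout); fitness is mean stratified 3-fold CV
accuracy.

**Metrics.** Precision TP/(FP+TP), accuracy, recall (standard TP/(TP+FN)
and a literal TP/(TN+TP) dialect kept for fidelity), F1, and a security
ratio hacked/original reported with its complement (protection).

**Synthetic cohorts.** Labels drawn at a configurable prevalence; features
class-conditional (Gaussians for age, blood pressure, cholesterol, max
heart rate, ST depression; tables for the categoricals) with separation set
by `effect_scale`. The generative model yields an exact Bayes oracle that
upper-bounds any classifier. A reader for the processed-Cleveland CSV
dialect (14 columns, `?` for missing) is included but never required.

## Worked example

```bash
python examples/train_classifier.py
```

```
final training accuracy: 0.997
held-out accuracy:       0.970
held-out recall / F1:    0.938 / 0.968
Bayes-oracle accuracy:   0.960
              pred 0   pred 1
  true 0         52        0
  true 1          3       45
```

A 400-patient cohort at `effect_scale=2` is split 75/25, the baseline
network trained, and the held-out confusion matrix printed. The Bayes
oracle — the true generative posterior thresholded at 0 — shows how much
headroom is left; here the classifier sits at the oracle's level (sampling
noise makes the oracle occasionally lose a point on a finite test set).

The other examples each exercise one capability:
`optimize_sphere.py` (AOA convergence), `encrypt_and_audit.py`
(encryption, ledger commit, tamper localization),
`tune_hyperparameters.py` (AOA search vs. the baseline), and
`run_full_pipeline.py` (all ten stages end to end).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runs the complete ten-stage pipeline on a freshly generated 200-patient
cohort under the given seed — encryption, ledger commit, audit, decryption
with byte-equality assertion, training, prediction, metrics, alerts — and
writes the results JSON to `--out`. Exits non-zero if any integrity check
fails.
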