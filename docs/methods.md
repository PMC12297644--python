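# Methods

This note documents the models and procedures implemented in cardiovault,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open. It states no empirical result
that the test suite does not itself compute.

## Archimedes Optimization Algorithm

Candidates are material objects j with position `Z_j`, density `Den_j`,
volume `Vol_j` and acceleration `ACL_j`, all vectors of the search
dimension. Initialization draws positions and accelerations uniformly in
the box and densities/volumes uniformly in (0, 1] (exact zeros rejected so
acceleration denominators are positive by construction).

Each iteration T (1-based, out of `max_iter`):

1. **Density/volume pull.** `Den' = Den + R∘(Den_best − Den)` and likewise
   for volume, with fresh uniform R per component.
2. **Schedules.** Transfer operator `TO = exp((T − T_max)/T_max)`,
   increasing from ≈e⁻¹ to 1; density factor `d`, decreasing to 0 at
   T = T_max.
3. **Acceleration.** Exploration (TO ≤ 0.5): from a uniformly drawn
   collision partner's previous-iteration properties,
   `ACL' = (Den_ref + Vol_ref∘ACL_ref) / (Den'∘Vol')`; exploitation
   (TO > 0.5): the same with the best object as reference. The denominator
   is floored at 1e−12.
4. **Normalization.** Per component across the population, min–max into
   [λ, λ+χ] with χ = 0.9, λ = 0.1. When a component is constant the
   midpoint λ+χ/2 is used so motion never freezes (tie rule).
5. **Move.** Exploration: `Z' = Z + c₁·R·ACLn·d·(Z_rand − Z)` with c₁ = 2.
   Exploitation: `Z' = Z_best + flag·c₂·R·ACLn·d·(T_s·Z_ref − Z)` with
   c₂ = 6, `T_s = c₃·TO`, c₃ = 2, and `flag = +1 if 2R − K₄ ≤ 0.5 else −1`
   (K₄ = 0.5). Positions are clipped componentwise into the box.
6. **Selection.** Objects keep their new positions (an objective returning
   NaN leaves that object in place); the global best is retained greedily,
   so the best-so-far history is non-increasing.

**Dialects.** The `canonical` dialect (default) uses the density factor
`exp((T_max−T)/T_max) − T/T_max` and exploits toward the best object
(`Z_ref = Z_best`). The `paper` dialect keeps two printed variants found in
derivative write-ups: the density factor shares the transfer operator's
negative exponent, and the exploitation reference is a random object.
Canonical is the default because it converges reliably; the paper dialect
is retained for fidelity testing (both satisfy all structural invariants).

**Defaults.** Population 50, 100 iterations (the reference setting);
the constants c₁ = 2, c₂ = 6, c₃ = 2, K₄ = 0.5 are the canonical
literature values (the source material names only two of its constants);
χ/λ are unstated there and fixed at the canonical 0.9/0.1. The core
minimizes; the tuner negates accuracy.

## Matrix-RSA cipher

Key generation (seeded): distinct primes x ≠ y of ≈`bit_length`/2 bits
(random candidates tested with sympy's deterministic primality check),
n = xy, φ = (x−1)(y−1), e = 65537 when coprime to φ else the next odd
coprime, d = e⁻¹ mod φ. The k×k mixing matrix A is sampled uniformly over
Z_n until invertible mod n (the modular inverse is computed via sympy's
`inv_mod`; failure after 1000 draws errors out, though a random matrix is
invertible with overwhelming probability). The "not invertible" error never
discloses gcd(det A, n), which could factor n.

Byte codec: a record is length-prefixed, split into big-endian chunks of
`⌊(bits(n)−1)/8⌋` bytes (so each chunk integer is < n), zero-padded to a
multiple of k. Encryption per k-block M: `c = (A·M mod n)^e mod n`
componentwise; decryption applies d then A⁻¹. n squarefree makes x ↦ xᵉ a
bijection on all of Z_n (CRT argument), so the round trip is exact even for
residues sharing a factor with n.

Optional chaining adds the previous cipher block (mod n) to the next plain
block before mixing, hiding plaintext-block repetition; default off.

## Ledger and audit

SHA-256 throughout. Merkle leaves are hashed as `H(0x00‖leaf)`, internal
nodes as `H(0x01‖left‖right)`; an odd node is duplicated at each level.
The domain-separation prefixes prevent the internal-node-as-leaf
second-preimage forgery (explicitly tested). Blocks serialize canonically
(fixed field order, big-endian integers, length-prefixed IDs) and carry:
index, previous block hash (genesis: 32 zero bytes), Merkle root over the
payload's ciphertext digests, an integer timestamp, a random nonce (a tag
only — no proof-of-work, consensus is out of scope), and the payload of
(record-ID, digest) pairs.

`verify_chain` recomputes linkage and Merkle roots and names the first bad
block. The audit role recomputes each stored ciphertext's digest and its
Merkle membership; the log-generator appends hash-chained audit entries;
the log-checker revalidates that chain. One inherent limit: a mutation
confined to the *tip block's* timestamp/nonce is not detectable from the
chain alone (nothing downstream commits to the tip header); detecting it
requires an external anchor to the tip hash. Tests therefore target header
mutations at non-tip blocks, and payload/Merkle mutations anywhere.

## Classifier

Stack: optional 1-D convolution (single input channel, stride 1, same
padding) over the ordered 13-feature vector → batch normalization → ReLU →
flatten → dense(100) → ReLU → inverted dropout → dense(2) → softmax. With
`use_conv=false` (default, for speed) the conv/batch-norm block is absent
and the parameter count is 13·100+100+100·2+2 = 1602. When batch-norm is
enabled the conv bias is omitted (its gradient is identically zero because
the normalization removes additive constants).

Training: mini-batch SGD with classical momentum
(`v ← μv − η∇; w ← w + v`) on the (optionally class-weighted)
cross-entropy. Initialization is He-scaled seeded normal. Per-epoch report
entries are full-set loss/accuracy in inference mode, which makes the
small-learning-rate monotonicity check meaningful. If an epoch produces a
non-finite parameter (possible at aggressive learning rates), that epoch is
rolled back and training stops early, repeating the last finite metrics so
report lengths equal `epochs`.

Defaults follow the baseline parameter table: lr 0.1, 32 epochs, dropout
0.243, batch 8. That table states no momentum; 0.9 — the only momentum the
source states, and the field-standard value — was fixed a priori. The
conflicting "10 input / 20 hidden / 2 output" row of the same table
contradicts the 100-neuron dense-layer statement and is not used.

Class weighting (`inverse_frequency`, off by default) scales each sample by
n/(2·n_class). Prediction ties (probability exactly 0.5/0.5) break toward
class 0 by declared rule.

## Hyperparameter search

Search space: learning rate [1e−5, 1e−1] decoded on the log10 scale,
momentum [0.5, 0.99], epochs [10, 50] (rounded to integer), dropout
[0, 0.5] — chosen so the example tuned optimum (1e−4, 0.900, 30, 0.2) and
the baseline all lie inside. Fitness is mean accuracy over stratified
3-fold CV (3 rather than 5 folds keeps the search budget tractable at desk
scale); folds deal each class round-robin after a seeded shuffle. The AOA
runs on [0,1]⁴ minimizing the negated fitness; positions are memoized
(rounded to 12 decimals) so repeated evaluations are free. The default
search budget is population 6 × 8 iterations; the full reference budget
(50 × 100) is a config away.

## Synthetic cohort generator

The generator emulates the processed-Cleveland schema, not real patients.
Label ~ Bernoulli(prevalence), default 0.46 (the real cohort's rate).
Continuous features are class-conditional Gaussians centred at
published-range means (age 54±9, resting BP 131±17, cholesterol 246±51,
max HR 149±23, ST depression 1.0±1.1) with class means separated by
`effect_scale·σ_f·w_f` along the fixed direction
w = (age 0.4, trestbps 0.3, chol 0.3, thalach −0.8, oldpeak 0.9) —
disease raises age/BP/cholesterol/ST-depression and lowers max heart rate.
Values are clipped to physiological ranges and rounded like the real file.
Categoricals come from class-conditional tables (rough Cleveland empirical
frequencies) whose separation interpolates from pooled (independent of the
label) at `effect_scale=0` to the full tables at `effect_scale≥2`.
Missing values (`?`) are injected only into `ca`/`thal`, the fields missing
in the real data. Default `effect_scale` is 1.0 (moderate overlap).

Because the continuous model is an equal-covariance two-Gaussian mixture,
the exact posterior is computable: `bayes_oracle` thresholds the true log
posterior odds (prior + Gaussian + table log-likelihood ratios) at 0. It
ignores the clipping/rounding applied after sampling — a negligible
approximation except for ST depression, whose truncation at 0 attenuates
its observed class gap (the mean-separation test accounts for this).

What a green test does *not* establish: the generator has no feature
correlations within a class, no measurement noise model, no site effects,
and its categorical tables are stylized. Accuracy numbers on this cohort
characterize the pipeline's mechanics, not clinical performance.

## Pipeline

Ten stages in fixed order (cohort, keygen, encryption, ledger commit,
audit + log check, decryption with byte-equality assertion, training or
tuning on the decrypted split, prediction, metrics, alerts). All
randomness derives from one root seed via `SeedSequence` splitting; ledger
timestamps come from a deterministic logical clock; wall-clock durations
(key generation, encryption, decryption — hardware-dependent by nature)
are quarantined in their own report section, making the rest of the report
bitwise reproducible. Records are serialized canonically
(`id|label|repr(float)...`) so byte equality after decryption is exact.
Authentication is a local salted-SHA-256 credential store standing in for
the distributed key-issuing narrative (no network protocol is specified
for it); alert delivery is an in-report object, not SMS.

## Evaluation metrics

Precision TP/(FP+TP), accuracy (TP+TN)/total, recall with two dialects —
standard TP/(TP+FN) (default; retrieval completeness is what the prose
defines) and the literal TP/(TN+TP) kept for fidelity — and F1 as the
harmonic mean using the chosen recall. The security ratio hacked/original
is reported with protection = 1 − ratio, since a "98% secure" system is
one with 2% of its data compromised, not 98%. Zero denominators return 0
with a logged warning, keeping every metric total. Timing helpers
(`time_phase`) exist for parity with the encryption/key/decryption time
definitions but are hardware-dependent and carry no assertions beyond
non-negativity.

## Known limitations

- The cipher is deterministic per record (no randomized padding): equal
  plaintexts yield equal ciphertexts unless chaining is enabled.
- Batch-norm statistics use a fixed 0.9 exponential decay; very short
  trainings under-converge the running moments.
- The baseline learning rate 0.1 with momentum 0.9 is aggressive; on hard
  (low-separation) cohorts individual runs can diverge and fall back to
  the rollback path. The tuner reliably steers away from that region.
- The tip-block header anchoring limit described above.
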