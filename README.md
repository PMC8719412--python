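# gazetag

Dictionary-augmented multi-task BiLSTM-CRF tagger for character-level
clinical named entity recognition (NER).

Clinical records in Chinese are labelled one character at a time, and many
of the entities worth finding — drugs, operations, anatomy, symptoms — are
*rare*: they occur a handful of times, or never, in the annotated training
data. Hospitals do, however, maintain curated lists (drug formularies,
operation catalogues, charging items) that cover exactly those long-tail
surface forms. `gazetag` implements a sequence tagger that injects such an
external dictionary into a neural model, together with character radicals,
and trains the recognizer jointly with an auxiliary segmentation task. It
is aimed at practitioners building clinical information extraction
pipelines, and at anyone who wants a transparent, dependency-light
(NumPy-only) reference implementation of a gazetteer-augmented BiLSTM-CRF.

## Model

Each character `x_t` of a sentence is represented by the concatenation

```
x_t  ->  p_t ⊕ r_t ⊕ d_t          (100 + 50 + 30 dims by default)
```

* `p_t` — a trainable character embedding (uniform init on
  `[-sqrt(3/dim), +sqrt(3/dim)]`; a pretrained table can be plugged in),
* `r_t` — a trainable embedding of the character's radical,
* `d_t` — a fixed 30-bit gazetteer code: ten n-gram windows (for each size
  n = 2..6, the window ending at `t` and the window starting at `t`) are
  matched exactly against the entity dictionary, and each window
  contributes the 3-bit code of its entity type, or `(0,0,0)` if unmatched.

A shared bidirectional LSTM encoder `h_t = [h→_t ; h←_t]` feeds two
parallel heads:

* **segmentation** (auxiliary): `q_t = σ(w·h_t + b)`, the probability that
  the token is inside any entity, with masked cross-entropy
  `loss₁ = −Σ_t [p_t(1) log q_t(1) + p_t(0) log q_t(0)]`;
* **recognition** (primary): a linear-chain CRF over BIO labels,
  `p(y|z) ∝ exp( start(y₁) + Σ_i T(y_{i−1}, y_i) + e_i(y_i) )`,
  with `loss₂ = log Z − score(y_gold)` computed by the forward algorithm.

Training minimizes `L = α·loss₁ + β·loss₂` (default `α:β = 2:3`) with Adam;
prediction uses only the CRF head, decoded by Viterbi. Evaluation is
entity-level exact-match precision/recall/F (harmonic mean
`F = 2PR/(P+R)`), reported overall, per type, and stratified by how often
each test mention occurred in training (buckets 0/1/2/3 — "unseen" to
"rare").

All forward and backward passes (BPTT, CRF forward-backward) are written
in NumPy with analytic gradients, verified against finite differences in
the test suite.

## Worked example

Everything below runs offline on synthetic data — the generator plants
dictionary surfaces into random private-use-unicode text, so gold spans
are exact by construction:

```bash
gazetag gen-synthetic demo --sentences 30 --test-sentences 10 --seed 5
cat > demo/cfg.yaml <<EOF
epochs: 60
batch_size: 8
learning_rate: 0.005
dropout_rate: 0.2
char_unk_rate: 0.3
hidden_size: 32
char_dim: 16
radical_dim: 8
seed: 5
EOF
gazetag train   --corpus demo/train.conll --dict demo/dictionary.tsv \
                --radicals demo/radicals.tsv --scheme demo/scheme.json \
                --config demo/cfg.yaml --out demo/model
gazetag predict --model demo/model --input demo/test.conll \
                --dict demo/dictionary.tsv --radicals demo/radicals.tsv \
                --scheme demo/scheme.json --out demo/pred.conll
gazetag evaluate --gold demo/test.conll --pred demo/pred.conll \
                 --train demo/train.conll
```

which prints:

```
cell                      P%      R%      F%  support
overall                82.61   73.08   77.55       26
type1                  50.00   50.00   50.00        2
type2                 100.00   83.33   90.91        6
type3                 100.00   50.00   66.67        4
type4                 100.00   62.50   76.92        8
type5                  66.67  100.00   80.00        6
rare bucket 0                  46.15               13
rare bucket 1                 100.00                6
rare bucket 2                 100.00                4
rare bucket 3                 100.00                3
```

Reading: of the 26 gold mentions in the 10 test sentences, 73% were
recovered with exactly matching type and span (F = 77.6% at this tiny
30-sentence training size; the standard 200-sentence protocol reaches
F ≈ 95–98%). The rare-bucket rows stratify recall by training-set
occurrence count: even *unseen* surfaces (bucket 0) are found 46% of the
time because the gazetteer code marks their boundaries, while surfaces
seen even once are recovered reliably.

The same pipeline is available as a library (`gazetag.train`,
`gazetag.predict`, `gazetag.evaluate`, `gazetag.SynthSpec`, ...).

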