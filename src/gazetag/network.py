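"""Shared BiLSTM encoder, segmentation head and CRF head, with exact gradients.

The model is a hard-parameter-sharing multi-task network: one bidirectional
LSTM encoder feeds two parallel heads.

* The *segmentation* head is a per-token sigmoid classifier (is this token
  inside any entity?) trained with a masked cross-entropy sum,

      loss1 = -sum_t [ p_t(1) log q_t(1) + p_t(0) log q_t(0) ].

* The *recognition* head is a linear-chain CRF over BIO labels.  A path
  y_1..y_n is scored by emission and transition potentials,

      score(y) = start(y_1) + e_1(y_1) + sum_{i>1} T(y_{i-1}, y_i) + e_i(y_i),

  the conditional probability is exp(score) normalised over all L^n paths,
  and the loss is the negative log-likelihood

      loss2 = log Z(e) - score(y_gold),

  with log Z computed by the forward algorithm in log space.

The joint objective is L = alpha * loss1 + beta * loss2 (default weights
0.4 / 0.6, the 2:3 ratio).  Prediction uses only the CRF head, decoded with
the Viterbi algorithm; ties at a backpointer break toward the lowest label
index so decoding is deterministic.

All forward and backward passes are written directly in NumPy; gradients are
analytic (backpropagation through time for the LSTM, forward-backward
marginals for the CRF) and are verified against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureConfig

_EPS = 1e-12  # probability clamp inside cross-entropies


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _logsumexp(a: np.ndarray, axis=None):
    if axis is None:
        m = float(np.max(a))
        return m + float(np.log(np.sum(np.exp(a - m))))
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


# ---------------------------------------------------------------------------
# LSTM cell


@dataclass
class LSTMParams:
    """One direction's LSTM weights.

    ``W_x*`` act on the input, ``W_h*`` on the previous hidden state; gates
    are input (i), forget (f), cell candidate (c) and output (o)."""

    W_xi: np.ndarray
    W_hi: np.ndarray
    W_xf: np.ndarray
    W_hf: np.ndarray
    W_xc: np.ndarray
    W_hc: np.ndarray
    W_xo: np.ndarray
    W_ho: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_hi.shape[0]

    @classmethod
    def from_fused(cls, W_x: np.ndarray, W_h: np.ndarray, b: np.ndarray) -> "LSTMParams":
        """Views into fused (d_in, 4H) / (H, 4H) / (4H,) arrays with gate
        order [i, f, c, o]."""
        H = W_h.shape[0]
        s = [slice(k * H, (k + 1) * H) for k in range(4)]
        return cls(
            W_xi=W_x[:, s[0]], W_hi=W_h[:, s[0]],
            W_xf=W_x[:, s[1]], W_hf=W_h[:, s[1]],
            W_xc=W_x[:, s[2]], W_hc=W_h[:, s[2]],
            W_xo=W_x[:, s[3]], W_ho=W_h[:, s[3]],
            b_i=b[s[0]], b_f=b[s[1]], b_c=b[s[2]], b_o=b[s[3]],
        )


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LSTMParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM recurrence step.

    i = sigma(W_xi x + W_hi h + b_i), f and o likewise,
    c = f*c_prev + i*tanh(W_xc x + W_hc h + b_c), h = o*tanh(c).
    """
    p = params
    if x_t.shape[-1] != p.W_xi.shape[0] or h_prev.shape[-1] != p.W_hi.shape[0]:
        raise ValueError("lstm_step: shape mismatch between inputs and parameters")
    i = sigmoid(x_t @ p.W_xi + h_prev @ p.W_hi + p.b_i)
    f = sigmoid(x_t @ p.W_xf + h_prev @ p.W_hf + p.b_f)
    g = np.tanh(x_t @ p.W_xc + h_prev @ p.W_hc + p.b_c)
    o = sigmoid(x_t @ p.W_xo + h_prev @ p.W_ho + p.b_o)
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def _lstm_forward(X, mask, W_x, W_h, b, reverse: bool):
    """Batched unidirectional pass; returns hidden states and per-step caches.

    Padding positions (mask 0) zero the carried state, so the backward
    direction effectively starts fresh at each sentence's last real token.
    """
    B, T, _ = X.shape
    H = W_h.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.zeros((B, T, H))
    caches = []
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        m = mask[:, t : t + 1]
        g = X[:, t] @ W_x + h @ W_h + b
        gi = sigmoid(g[:, :H])
        gf = sigmoid(g[:, H : 2 * H])
        gc = np.tanh(g[:, 2 * H : 3 * H])
        go = sigmoid(g[:, 3 * H :])
        c_new = gf * c + gi * gc
        tanh_c = np.tanh(c_new)
        h_new = go * tanh_c
        caches.append((t, h, c, gi, gf, gc, go, tanh_c, m))
        h = m * h_new
        c = m * c_new
        Hs[:, t] = h
    return Hs, caches


def _lstm_backward(dHs, X, W_x, W_h, caches):
    """BPTT through `_lstm_forward`; returns (dX, dW_x, dW_h, db)."""
    B, T, d = X.shape
    H = W_h.shape[0]
    dX = np.zeros_like(X)
    dW_x = np.zeros_like(W_x)
    dW_h = np.zeros_like(W_h)
    db = np.zeros(4 * H)
    dh_carry = np.zeros((B, H))
    dc_carry = np.zeros((B, H))
    for t, h_prev, c_prev, gi, gf, gc, go, tanh_c, m in reversed(caches):
        dh_out = dHs[:, t] + dh_carry
        dh_new = m * dh_out
        dc_new = m * dc_carry
        do = dh_new * tanh_c
        dc_new = dc_new + dh_new * go * (1.0 - tanh_c**2)
        di = dc_new * gc
        df = dc_new * c_prev
        dgc = dc_new * gi
        dc_carry = dc_new * gf
        dg = np.concatenate(
            [
                di * gi * (1.0 - gi),
                df * gf * (1.0 - gf),
                dgc * (1.0 - gc**2),
                do * go * (1.0 - go),
            ],
            axis=1,
        )
        dW_x += X[:, t].T @ dg
        dW_h += h_prev.T @ dg
        db += dg.sum(axis=0)
        dX[:, t] += dg @ W_x.T
        dh_carry = dg @ W_h.T
    return dX, dW_x, dW_h, db


# ---------------------------------------------------------------------------
# CRF


@dataclass
class CRFParams:
    """Linear-chain CRF potentials over L labels plus a START row.

    ``transition_weights`` and ``transition_bias`` are (L+1, L); row L is the
    learned transition out of the START state into y_1 (no STOP transition).
    The effective transition matrix is their sum.  ``emission_projection``
    (optional here) is the linear map from encoder output to the per-label
    emission scores consumed by the scoring functions below.
    """

    transition_weights: np.ndarray
    transition_bias: np.ndarray
    emission_projection: tuple[np.ndarray, np.ndarray] | None = None
    constraint: np.ndarray | None = None  # optional additive mask (-inf entries)

    def __post_init__(self) -> None:
        L = self.n_labels
        if self.transition_weights.shape != (L + 1, L) or self.transition_bias.shape != (L + 1, L):
            raise ValueError("transition matrices must be (L+1, L) with a START row")
        if not (np.isfinite(self.transition_weights).all() and np.isfinite(self.transition_bias).all()):
            raise ValueError("non-finite transition parameters")

    @property
    def n_labels(self) -> int:
        return self.transition_weights.shape[1]

    @property
    def effective(self) -> np.ndarray:
        t = self.transition_weights + self.transition_bias
        if self.constraint is not None:
            t = t + self.constraint
        return t

    @property
    def pair(self) -> np.ndarray:
        """(L, L) label-to-label block."""
        return self.effective[:-1]

    @property
    def start(self) -> np.ndarray:
        """(L,) START-to-label row."""
        return self.effective[-1]


def bio_constraint_mask(labels: list[str]) -> np.ndarray:
    """Additive (L+1, L) mask sending BIO-invalid transitions to -inf:
    I-x may only follow B-x or I-x (START may not enter I-x either)."""
    L = len(labels)
    mask = np.zeros((L + 1, L))
    for j, lab in enumerate(labels):
        if not lab.startswith("I-"):
            continue
        etype = lab.split("-", 1)[1]
        for i in range(L + 1):
            prev = labels[i] if i < L else "<START>"
            if prev not in (f"B-{etype}", f"I-{etype}"):
                mask[i, j] = -np.inf
    return mask


def _check_path(path, n_labels: int, length: int) -> np.ndarray:
    p = np.asarray(path, dtype=np.int64)
    if p.shape != (length,):
        raise ValueError("path length must equal emission length")
    if p.min() < 0 or p.max() >= n_labels:
        raise ValueError("label index out of range")
    return p


def crf_score(emissions: np.ndarray, transitions: CRFParams, path) -> float:
    """Log-potential sum of one label path (START transition included)."""
    n, L = emissions.shape
    p = _check_path(path, L, n)
    s = transitions.start[p[0]] + emissions[0, p[0]]
    for i in range(1, n):
        s += transitions.pair[p[i - 1], p[i]] + emissions[i, p[i]]
    return float(s)


def crf_log_partition(emissions: np.ndarray, transitions: CRFParams) -> float:
    """log sum over all L^n paths of exp(score), by the forward algorithm."""
    n, L = emissions.shape
    a = transitions.start + emissions[0]
    for i in range(1, n):
        a = _logsumexp(a[:, None] + transitions.pair, axis=0) + emissions[i]
    return float(_logsumexp(a))


def crf_nll(emissions: np.ndarray, transitions: CRFParams, gold_path) -> float:
    """Negative log-likelihood of the gold path: log Z - score(gold)."""
    return crf_log_partition(emissions, transitions) - crf_score(emissions, transitions, gold_path)


def crf_nll_grad(emissions: np.ndarray, transitions: CRFParams, gold_path):
    """NLL and its gradients: (nll, d_emissions, d_transitions) where
    d_transitions is (L+1, L) including the START row.

    Gradients are expected feature counts (forward-backward marginals) minus
    the observed gold counts.
    """
    n, L = emissions.shape
    p = _check_path(gold_path, L, n)
    pair = transitions.pair
    start = transitions.start

    alpha = np.zeros((n, L))
    alpha[0] = start + emissions[0]
    for i in range(1, n):
        alpha[i] = _logsumexp(alpha[i - 1][:, None] + pair, axis=0) + emissions[i]
    logZ = _logsumexp(alpha[n - 1])

    beta = np.zeros((n, L))
    for i in range(n - 2, -1, -1):
        beta[i] = _logsumexp(pair + (emissions[i + 1] + beta[i + 1])[None, :], axis=1)

    d_em = np.exp(alpha + beta - logZ)
    d_trans = np.zeros((L + 1, L))
    for i in range(1, n):
        pm = np.exp(
            alpha[i - 1][:, None] + pair + (emissions[i] + beta[i])[None, :] - logZ
        )
        d_trans[:L] += pm
    d_trans[L] = d_em[0]

    d_em[np.arange(n), p] -= 1.0
    for i in range(1, n):
        d_trans[p[i - 1], p[i]] -= 1.0
    d_trans[L, p[0]] -= 1.0

    nll = logZ - crf_score(emissions, transitions, p)
    return nll, d_em, d_trans


def viterbi_decode(emissions: np.ndarray, transitions: CRFParams):
    """Highest-scoring label path and its score; backpointer ties break
    toward the lowest label index."""
    n, L = emissions.shape
    delta = transitions.start + emissions[0]
    backptr = np.zeros((n, L), dtype=np.int64)
    for i in range(1, n):
        scores = delta[:, None] + transitions.pair
        backptr[i] = np.argmax(scores, axis=0)  # first max -> lowest index
        delta = scores[backptr[i], np.arange(L)] + emissions[i]
    best_last = int(np.argmax(delta))
    path = [best_last]
    for i in range(n - 1, 0, -1):
        path.append(int(backptr[i, path[-1]]))
    path.reverse()
    return path, float(delta[best_last])


# ---------------------------------------------------------------------------
# heads and losses


def seg_forward(encoded: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    """Per-token entity probability sigma(w . z_t + b)."""
    return sigmoid(encoded @ w + b)


def seg_bce_loss(probs: np.ndarray, seg_labels: np.ndarray, mask: np.ndarray) -> float:
    """Masked cross-entropy sum with one-hot targets; probabilities are
    clamped to [1e-12, 1-1e-12]."""
    q = np.clip(np.asarray(probs, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(seg_labels, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    if not (q.shape == y.shape == m.shape):
        raise ValueError("probs, labels and mask must be aligned")
    return float(-np.sum(m * (y * np.log(q) + (1.0 - y) * np.log(1.0 - q))))


@dataclass
class LossWeights:
    """Weights alpha (segmentation) and beta (recognition) of the joint loss;
    the default is the 2:3 ratio."""

    alpha: float = 0.4
    beta: float = 0.6

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError("loss weights must be nonnegative with positive sum")


def combined_loss(loss1: float, loss2: float, w: LossWeights) -> float:
    """L = alpha * loss1 + beta * loss2."""
    return w.alpha * loss1 + w.beta * loss2


# ---------------------------------------------------------------------------
# the full model


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(3.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


@dataclass
class TaggerModel:
    """All trainable state of the multi-task tagger.

    ``params`` maps names to float64 arrays: character and radical embedding
    tables, fused LSTM weights per direction, the segmentation head, the
    emission projection and the CRF transition parameters. ``vocab`` maps
    characters to embedding rows (0 = padding, 1 = unknown).
    """

    labels: list[str]  # BIO tag inventory, "O" first
    vocab: dict[str, int]
    n_radicals: int
    feature_config: FeatureConfig
    hidden_size: int = 128
    dropout_rate: float = 0.5
    constrain_bio: bool = False
    params: dict[str, np.ndarray] = field(default_factory=dict)

    PAD_ID = 0
    UNK_ID = 1

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def crf(self) -> CRFParams:
        return CRFParams(
            transition_weights=self.params["trans_W"],
            transition_bias=self.params["trans_b"],
            emission_projection=(self.params["emit_W"], self.params["emit_b"]),
            constraint=bio_constraint_mask(self.labels) if self.constrain_bio else None,
        )

    def lstm(self, direction: str) -> LSTMParams:
        return LSTMParams.from_fused(
            self.params[f"{direction}_Wx"],
            self.params[f"{direction}_Wh"],
            self.params[f"{direction}_b"],
        )

    @classmethod
    def build(
        cls,
        labels: list[str],
        vocab: dict[str, int],
        n_radicals: int,
        feature_config: FeatureConfig | None = None,
        hidden_size: int = 128,
        dropout_rate: float = 0.5,
        seed: int = 0,
        pretrained_char: dict[str, np.ndarray] | None = None,
        constrain_bio: bool = False,
    ) -> "TaggerModel":
        fc = feature_config or FeatureConfig()
        rng = np.random.default_rng(seed)
        d_in = fc.input_dim
        H = hidden_size
        L = len(labels)
        bound_emb = np.sqrt(3.0 / fc.char_dim)
        E_char = rng.uniform(-bound_emb, bound_emb, size=(len(vocab), fc.char_dim))
        if pretrained_char:
            for ch, vec in pretrained_char.items():
                if ch in vocab:
                    if len(vec) != fc.char_dim:
                        raise ValueError("pretrained vector width != char_dim")
                    E_char[vocab[ch]] = vec
        bound_rad = np.sqrt(3.0 / fc.radical_dim)
        params = {
            "E_char": E_char,
            "E_rad": rng.uniform(-bound_rad, bound_rad, size=(n_radicals, fc.radical_dim)),
            "seg_w": _uniform_init(rng, (2 * H,), 2 * H),
            "seg_b": np.zeros(()),
            "emit_W": _uniform_init(rng, (2 * H, L), 2 * H),
            "emit_b": np.zeros(L),
            "trans_W": 0.01 * rng.standard_normal((L + 1, L)),
            "trans_b": np.zeros((L + 1, L)),
        }
        for d in ("fw", "bw"):
            params[f"{d}_Wx"] = _uniform_init(rng, (d_in, 4 * H), d_in)
            params[f"{d}_Wh"] = _uniform_init(rng, (H, 4 * H), H)
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias, standard stabilizer
            params[f"{d}_b"] = b
        return cls(
            labels=list(labels),
            vocab=dict(vocab),
            n_radicals=n_radicals,
            feature_config=fc,
            hidden_size=hidden_size,
            dropout_rate=dropout_rate,
            constrain_bio=constrain_bio,
            params=params,
        )

    # -- forward pieces ----------------------------------------------------

    def embed(self, char_ids: np.ndarray, rad_ids: np.ndarray, dict_feats: np.ndarray) -> np.ndarray:
        """(B, T, d_in) assembled inputs: char emb + radical emb + 30-bit code."""
        return np.concatenate(
            [self.params["E_char"][char_ids], self.params["E_rad"][rad_ids], dict_feats],
            axis=-1,
        )

    def encode(self, X: np.ndarray, mask: np.ndarray):
        """BiLSTM encoding of a batch: (B, T, 2H) plus the two cache lists."""
        Hf, cf = _lstm_forward(X, mask, self.params["fw_Wx"], self.params["fw_Wh"], self.params["fw_b"], reverse=False)
        Hb, cb = _lstm_forward(X, mask, self.params["bw_Wx"], self.params["bw_Wh"], self.params["bw_b"], reverse=True)
        return np.concatenate([Hf, Hb], axis=-1), (cf, cb)


def bilstm_encode(inputs: np.ndarray, model: TaggerModel) -> np.ndarray:
    """Encode a single sentence (n, d_in) -> (n, 2*hidden): forward and
    backward hidden states concatenated, zero initial states."""
    if inputs.ndim != 2 or inputs.shape[0] == 0:
        raise ValueError("inputs must be a non-empty (length, d_in) matrix")
    X = inputs[None]
    mask = np.ones((1, inputs.shape[0]))
    out, _ = model.encode(X, mask)
    return out[0]
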