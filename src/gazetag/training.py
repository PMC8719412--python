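"""Batch construction, the joint optimization loop, checkpointing, prediction.

Training minimizes L = alpha*loss1 + beta*loss2 over mini-batches with Adam
(initial learning rate 5e-4, no schedule). Sentences are bucketed by length,
padded per batch (capped at ``max_len``, default 250) and fully masked, so
padding contributes to neither loss. A single integer seed drives parameter
initialization, shuffling and dropout, making runs bitwise reproducible.

Prediction uses only the CRF head (Viterbi); the segmentation head exists
only as a training-time regularizer.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, TaggedSentence, bio_to_segmentation
from .features import (
    EntityDictionary,
    FeatureConfig,
    RadicalTable,
    TypeCodeScheme,
    encode_sentence_dict,
    radical_of,
)
from .network import (
    LossWeights,
    TaggerModel,
    _lstm_backward,
    crf_nll_grad,
    seg_forward,
    viterbi_decode,
)

logger = logging.getLogger(__name__)

_EPS = 1e-12


class IncompatibleCheckpointError(RuntimeError):
    """Checkpoint metadata does not match the requested configuration."""


@dataclass
class TrainConfig:
    """Hyperparameters of a training run (defaults follow the published
    protocol: batch 32, up to 300 epochs, Adam at 5e-4, pad length 250,
    dropout 0.5, loss ratio 2:3)."""

    batch_size: int = 32
    epochs: int = 300
    learning_rate: float = 0.0005
    max_len: int = 250
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    early_stop_patience: int | None = None
    hidden_size: int = 128
    dropout_rate: float = 0.5
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    constrain_bio: bool = False
    #: training-time probability of replacing a character id with UNK; forces
    #: the model to lean on gazetteer and radical features (helps unseen
    #: entities); 0 disables.
    char_unk_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("batch_size", "epochs", "max_len", "hidden_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.char_unk_rate < 1:
            raise ValueError("char_unk_rate must be in [0, 1)")


def bio_labels(label_inventory: list[str]) -> list[str]:
    """The BIO tag list for an entity-type inventory, O first."""
    out = ["O"]
    for t in label_inventory:
        out += [f"B-{t}", f"I-{t}"]
    return out


def build_vocab(corpus: Corpus) -> dict[str, int]:
    """Character vocabulary in first-appearance order; 0 and 1 are reserved
    for padding and unknown characters."""
    vocab: dict[str, int] = {"<PAD>": TaggerModel.PAD_ID, "<UNK>": TaggerModel.UNK_ID}
    for sent in corpus:
        for ch in sent.chars:
            vocab.setdefault(ch, len(vocab))
    return vocab


@dataclass
class _Encoded:
    """A sentence converted to model inputs."""

    char_ids: np.ndarray
    rad_ids: np.ndarray
    dict_feats: np.ndarray
    seg: np.ndarray
    path: np.ndarray  # gold label ids; empty at prediction time

    def __len__(self) -> int:
        return len(self.char_ids)


def encode_sentence(
    sent: TaggedSentence,
    vocab: dict[str, int],
    labels: list[str],
    gazetteer: EntityDictionary,
    scheme: TypeCodeScheme,
    radicals: RadicalTable,
    with_gold: bool = True,
) -> _Encoded:
    label_ids = {lab: i for i, lab in enumerate(labels)}
    chars = sent.chars
    char_ids = np.array([vocab.get(c, TaggerModel.UNK_ID) for c in chars], dtype=np.int64)
    rad_ids = np.array([radical_of(c, radicals) for c in chars], dtype=np.int64)
    dict_feats = encode_sentence_dict(chars, gazetteer, scheme)
    seg = np.asarray(sent.seg_labels, dtype=np.float64)
    if with_gold:
        try:
            path = np.array([label_ids[t] for t in sent.tags], dtype=np.int64)
        except KeyError as e:
            raise ValueError(f"tag {e.args[0]!r} not in the model's label inventory") from e
    else:
        path = np.zeros(0, dtype=np.int64)
    return _Encoded(char_ids, rad_ids, dict_feats, seg, path)


def _make_batch(encoded: list[_Encoded], max_len: int):
    """Pad a batch to its own max length (capped at max_len); longer
    sentences are truncated."""
    lens = [min(len(e), max_len) for e in encoded]
    T = max(lens)
    B = len(encoded)
    char_ids = np.zeros((B, T), dtype=np.int64)
    rad_ids = np.zeros((B, T), dtype=np.int64)
    dict_feats = np.zeros((B, T, 30))
    mask = np.zeros((B, T))
    seg = np.zeros((B, T))
    paths = []
    for b, (e, n) in enumerate(zip(encoded, lens)):
        char_ids[b, :n] = e.char_ids[:n]
        rad_ids[b, :n] = e.rad_ids[:n]
        dict_feats[b, :n] = e.dict_feats[:n]
        mask[b, :n] = 1.0
        seg[b, :n] = e.seg[:n]
        paths.append(e.path[:n])
    return char_ids, rad_ids, dict_feats, mask, seg, paths, lens


def forward_backward(
    model: TaggerModel,
    batch,
    weights: LossWeights,
    dropout_rng: np.random.Generator | None = None,
):
    """One joint forward/backward pass over a padded batch.

    Returns (loss1, loss2, total, grads): the batch means of the per-sentence
    segmentation cross-entropy sum and CRF NLL, their weighted combination,
    and the gradient of the combination w.r.t. every model parameter.
    """
    char_ids, rad_ids, dict_feats, mask, seg, paths, lens = batch
    B, T = mask.shape
    p = model.params
    fc = model.feature_config
    rate = model.dropout_rate

    X = model.embed(char_ids, rad_ids, dict_feats)
    if dropout_rng is not None and rate > 0:
        keep1 = (dropout_rng.random(X.shape) >= rate) / (1.0 - rate)
        X = X * keep1
    else:
        keep1 = None
    Hout, (cache_f, cache_b) = model.encode(X, mask)
    if dropout_rng is not None and rate > 0:
        keep2 = (dropout_rng.random(Hout.shape) >= rate) / (1.0 - rate)
        Hd = Hout * keep2
    else:
        keep2 = None
        Hd = Hout

    # segmentation head
    probs = seg_forward(Hd, p["seg_w"], float(p["seg_b"]))
    q = np.clip(probs, _EPS, 1.0 - _EPS)
    loss1 = float(-np.sum(mask * (seg * np.log(q) + (1 - seg) * np.log(1 - q)))) / B
    dlogit = (probs - seg) * mask * (weights.alpha / B)

    # CRF head
    emissions = Hd @ p["emit_W"] + p["emit_b"]
    crf = model.crf
    d_em = np.zeros_like(emissions)
    d_trans = np.zeros_like(p["trans_W"])
    loss2 = 0.0
    for b in range(B):
        n = lens[b]
        nll, g_em, g_tr = crf_nll_grad(emissions[b, :n], crf, paths[b])
        loss2 += nll
        d_em[b, :n] = g_em * (weights.beta / B)
        d_trans += g_tr * (weights.beta / B)
    loss2 /= B
    total = weights.alpha * loss1 + weights.beta * loss2

    # backward
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    grads["trans_W"] = d_trans
    grads["trans_b"] = d_trans.copy()
    flat_H = Hd.reshape(B * T, -1)
    grads["emit_W"] = flat_H.T @ d_em.reshape(B * T, -1)
    grads["emit_b"] = d_em.sum(axis=(0, 1))
    grads["seg_w"] = (Hd * dlogit[:, :, None]).sum(axis=(0, 1))
    grads["seg_b"] = np.asarray(dlogit.sum())

    dHd = d_em @ p["emit_W"].T + dlogit[:, :, None] * p["seg_w"]
    dHout = dHd * keep2 if keep2 is not None else dHd
    H = model.hidden_size
    dXf, gWxf, gWhf, gbf = _lstm_backward(dHout[:, :, :H], X, p["fw_Wx"], p["fw_Wh"], cache_f)
    dXb, gWxb, gWhb, gbb = _lstm_backward(dHout[:, :, H:], X, p["bw_Wx"], p["bw_Wh"], cache_b)
    grads["fw_Wx"], grads["fw_Wh"], grads["fw_b"] = gWxf, gWhf, gbf
    grads["bw_Wx"], grads["bw_Wh"], grads["bw_b"] = gWxb, gWhb, gbb
    dX = dXf + dXb
    if keep1 is not None:
        dX = dX * keep1
    np.add.at(grads["E_char"], char_ids, dX[:, :, : fc.char_dim])
    np.add.at(grads["E_rad"], rad_ids, dX[:, :, fc.char_dim : fc.char_dim + fc.radical_dim])
    return loss1, loss2, total, grads


class Adam:
    """Adaptive-moment optimizer with the standard moment defaults."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batches(encoded: list[_Encoded], batch_size: int, rng: np.random.Generator):
    """Length-bucketed batches in shuffled order."""
    order = rng.permutation(len(encoded))
    order = sorted(order, key=lambda i: len(encoded[i]))
    chunks = [order[i : i + batch_size] for i in range(0, len(order), batch_size)]
    rng.shuffle(chunks)
    return chunks


def train(
    corpus: Corpus,
    gazetteer: EntityDictionary,
    scheme: TypeCodeScheme,
    radicals: RadicalTable,
    cfg: TrainConfig,
    dev_corpus: Corpus | None = None,
) -> TaggerModel:
    """Train the multi-task tagger on ``corpus``.

    With ``early_stop_patience`` set and a ``dev_corpus`` given, training
    stops once the dev combined loss has not improved for that many epochs;
    otherwise the full epoch budget is used.
    """
    if len(corpus) == 0:
        raise ValueError("cannot train on an empty corpus")
    master = np.random.default_rng(cfg.seed)
    init_seed = int(master.integers(2**31))
    shuffle_rng = np.random.default_rng(int(master.integers(2**31)))
    dropout_rng = np.random.default_rng(int(master.integers(2**31)))

    labels = bio_labels(corpus.label_inventory)
    vocab = build_vocab(corpus)
    model = TaggerModel.build(
        labels=labels,
        vocab=vocab,
        n_radicals=radicals.n_radicals,
        feature_config=cfg.feature_config,
        hidden_size=cfg.hidden_size,
        dropout_rate=cfg.dropout_rate,
        seed=init_seed,
        constrain_bio=cfg.constrain_bio,
    )
    encoded = [
        encode_sentence(s, vocab, labels, gazetteer, scheme, radicals) for s in corpus
    ]
    dev_encoded = (
        [encode_sentence(s, vocab, labels, gazetteer, scheme, radicals) for s in dev_corpus]
        if dev_corpus is not None
        else None
    )
    opt = Adam(model.params, cfg.learning_rate)
    w = cfg.loss_weights
    best_dev = np.inf
    stale = 0
    for epoch in range(1, cfg.epochs + 1):
        tot1 = tot2 = tot = 0.0
        nb = 0
        for idx in _batches(encoded, cfg.batch_size, shuffle_rng):
            batch = _make_batch([encoded[i] for i in idx], cfg.max_len)
            if cfg.char_unk_rate > 0:
                char_ids, rest = batch[0].copy(), batch[1:]
                mask = batch[3]
                drop = (dropout_rng.random(char_ids.shape) < cfg.char_unk_rate) & (mask > 0)
                char_ids[drop] = TaggerModel.UNK_ID
                batch = (char_ids, *rest)
            l1, l2, L, grads = forward_backward(model, batch, w, dropout_rng)
            if not np.isfinite(L):
                raise RuntimeError(f"non-finite loss at epoch {epoch} (loss1={l1}, loss2={l2})")
            opt.step(grads)
            tot1 += l1
            tot2 += l2
            tot += L
            nb += 1
        logger.info(
            "epoch %d: loss1=%.4f loss2=%.4f L=%.4f", epoch, tot1 / nb, tot2 / nb, tot / nb
        )
        if cfg.early_stop_patience is not None and dev_encoded is not None:
            dev_loss = evaluate_loss(model, dev_encoded, cfg, w)
            if dev_loss < best_dev - 1e-6:
                best_dev = dev_loss
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    logger.info("early stop at epoch %d (dev loss %.4f)", epoch, best_dev)
                    break
    return model


def evaluate_loss(model: TaggerModel, encoded: list[_Encoded], cfg: TrainConfig, w: LossWeights) -> float:
    """Combined loss over a held-out set, dropout disabled."""
    tot = 0.0
    nb = 0
    for i in range(0, len(encoded), cfg.batch_size):
        batch = _make_batch(encoded[i : i + cfg.batch_size], cfg.max_len)
        _, _, L, _ = forward_backward(model, batch, w, dropout_rng=None)
        tot += L
        nb += 1
    return tot / max(nb, 1)


def predict(
    model: TaggerModel,
    sentences,
    gazetteer: EntityDictionary,
    scheme: TypeCodeScheme,
    radicals: RadicalTable,
    batch_size: int = 32,
    max_len: int = 250,
) -> Corpus:
    """Viterbi-decode BIO tags for sentences (strings, TaggedSentences, or a
    Corpus); the segmentation head is not consulted. Padding is stripped."""
    for t in set(gazetteer.entries.values()):
        if t not in scheme.codes:
            raise ValueError(f"dictionary type {t!r} has no 3-bit code in the scheme")
    sents: list[TaggedSentence] = []
    for s in sentences:
        if isinstance(s, TaggedSentence):
            sents.append(s)
        else:
            chars = list(s)
            sents.append(TaggedSentence(chars, ["O"] * len(chars)))
    out: list[TaggedSentence] = []
    crf = model.crf
    p = model.params
    for i in range(0, len(sents), batch_size):
        chunk = sents[i : i + batch_size]
        encoded = [
            encode_sentence(s, model.vocab, model.labels, gazetteer, scheme, radicals, with_gold=False)
            for s in chunk
        ]
        char_ids, rad_ids, dict_feats, mask, _, _, lens = _make_batch(encoded, max_len)
        X = model.embed(char_ids, rad_ids, dict_feats)
        Hout, _ = model.encode(X, mask)
        emissions = Hout @ p["emit_W"] + p["emit_b"]
        for b, sent in enumerate(chunk):
            n = lens[b]
            path, _ = viterbi_decode(emissions[b, :n], crf)
            tags = [model.labels[j] for j in path]
            if n < len(sent):  # truncated tail is tagged O
                tags = tags + ["O"] * (len(sent) - n)
            out.append(
                TaggedSentence(list(sent.chars), tags, bio_to_segmentation(tags))
            )
    return Corpus(out, label_inventory=sorted({t.split("-", 1)[1] for t in model.labels if t != "O"}))


# ---------------------------------------------------------------------------
# checkpointing


def _config_meta(model: TaggerModel) -> dict:
    fc = model.feature_config
    return {
        "labels": model.labels,
        "vocab": model.vocab,
        "n_radicals": model.n_radicals,
        "char_dim": fc.char_dim,
        "radical_dim": fc.radical_dim,
        "dict_dim": fc.dict_dim,
        "hidden_size": model.hidden_size,
        "dropout_rate": model.dropout_rate,
        "constrain_bio": model.constrain_bio,
    }


def _config_hash(meta: dict) -> str:
    return hashlib.sha256(json.dumps(meta, sort_keys=True, ensure_ascii=False).encode()).hexdigest()


def save_checkpoint(model: TaggerModel, path) -> None:
    """Write the parameter archive (.npz) and a JSON sidecar with the label
    inventory, vocabulary, dims and a config hash."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **model.params)
    meta = _config_meta(model)
    meta["config_hash"] = _config_hash(_config_meta(model))
    with open(_sidecar(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, ensure_ascii=False)


def _sidecar(path: str) -> str:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".meta.json"


def load_checkpoint(path, expect_labels: list[str] | None = None) -> TaggerModel:
    path = str(path)
    npz_path = path if path.endswith(".npz") else path + ".npz"
    with open(_sidecar(path), encoding="utf-8") as fh:
        meta = json.load(fh)
    stored_hash = meta.pop("config_hash")
    if stored_hash != _config_hash(meta):
        raise IncompatibleCheckpointError("checkpoint sidecar hash mismatch")
    if expect_labels is not None and list(expect_labels) != meta["labels"]:
        raise IncompatibleCheckpointError(
            f"label inventory mismatch: checkpoint has {meta['labels']}, expected {list(expect_labels)}"
        )
    with np.load(npz_path) as npz:
        params = {k: npz[k] for k in npz.files}
    fc = FeatureConfig(meta["char_dim"], meta["radical_dim"], meta["dict_dim"])
    return TaggerModel(
        labels=meta["labels"],
        vocab=meta["vocab"],
        n_radicals=meta["n_radicals"],
        feature_config=fc,
        hidden_size=meta["hidden_size"],
        dropout_rate=meta["dropout_rate"],
        constrain_bio=meta["constrain_bio"],
        params=params,
    )
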