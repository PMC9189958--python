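"""The recurrent relative-risk network: forward pass and backpropagation.

Architecture, in order:

1. each coded event is embedded as (code embedding + type embedding) and
   concatenated with the scalar months-since-previous-event Δt, giving a
   vector of size ``embedding_dim + 1``;
2. three stacked bidirectional GRU layers, hidden size per direction equal
   to the input size (``embedding_dim + 1``), with inter-layer dropout;
   the two directions' outputs are concatenated at each position;
3. dot-product attention with a single learned query vector pools the
   positions into one context vector (an empty history yields the zero
   context vector);
4. the context vector is concatenated with the pre-specified covariate
   vector, passed through a size-preserving fully connected layer with ELU
   activation, and mapped to the scalar log relative risk f.

Everything is implemented directly on numpy arrays with hand-derived
backward passes (reverse-mode through the GRU recurrences, attention
softmax and head). The network is trained by maximizing the Cox partial
likelihood over case-control pairs; see :mod:`seqsurv.training`.

Sequences are padded with token index 0 and masked: padded positions never
update the hidden state and receive zero attention weight, so they carry
no gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_CODE_TYPES = 5  # + padding row 0 in the type embedding table

#: Δt is fed to the recurrence in years (months / 12). Raw month counts up
#: to 59 sit far outside the unit scale of the embeddings and saturate the
#: GRU gates at initialization, which measurably stalls training.
DELTA_T_SCALE = 1.0 / 12.0


@dataclass
class ModelConfig:
    """Hyperparameters of the network and its training procedure.

    Defaults follow the published training scheme (Adam with learning rate
    0.001 and betas (0.9, 0.999), 256-case mini-batches, 10 epochs,
    ensembles of 10); ``embedding_dim`` is a desk-scale choice since the
    original tuned value is unpublished.
    """

    embedding_dim: int = 16
    gru_layers: int = 3
    bidirectional: bool = True
    dropout: float = 0.10
    learning_rate: float = 0.001
    adam_betas: tuple[float, float] = (0.9, 0.999)
    batch_cases: int = 256
    epochs: int = 10
    ensemble_size: int = 10
    max_sequence_length: int = 500
    seed: int = 0
    predictor_set: str = "full"

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")


@dataclass
class Batch:
    """Padded integer sequences plus covariates for a set of persons."""

    tokens: np.ndarray   # (B, L) int, 0 = padding
    types: np.ndarray    # (B, L) int, 0 = padding
    delta: np.ndarray    # (B, L) float months
    mask: np.ndarray     # (B, L) float 0/1
    cov: np.ndarray      # (B, p)

    @property
    def size(self) -> int:
        return self.tokens.shape[0]


def pad_batch(histories: list, covariates: np.ndarray,
              max_sequence_length: int = 500) -> Batch:
    """Right-pad encoded histories into one batch.

    Sequences longer than ``max_sequence_length`` keep their most recent
    events (with Δt of the first kept event reset to 0). At least one
    (fully masked) column is always present so a batch of empty histories
    is processable.
    """
    clipped = []
    for h in histories:
        tok, typ, dlt = h.token_idx, h.type_idx, h.delta_t
        if len(tok) > max_sequence_length:
            tok = tok[-max_sequence_length:]
            typ = typ[-max_sequence_length:]
            dlt = dlt[-max_sequence_length:].copy()
            dlt[0] = 0
        clipped.append((tok, typ, dlt))
    B = len(clipped)
    L = max(1, max(len(t[0]) for t in clipped))
    tokens = np.zeros((B, L), dtype=np.int64)
    types = np.zeros((B, L), dtype=np.int64)
    delta = np.zeros((B, L), dtype=float)
    mask = np.zeros((B, L), dtype=float)
    for i, (tok, typ, dlt) in enumerate(clipped):
        n = len(tok)
        tokens[i, :n] = tok
        types[i, :n] = typ
        delta[i, :n] = dlt
        mask[i, :n] = 1.0
    return Batch(tokens=tokens, types=types, delta=delta, mask=mask,
                 cov=np.asarray(covariates, dtype=float))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


@dataclass
class _GruCache:
    r: np.ndarray
    z: np.ndarray
    n: np.ndarray
    hn: np.ndarray      # U_n h_prev + b_un, pre r-gating
    h_prev: np.ndarray
    x: np.ndarray
    order: list


class RiskNetwork:
    """One ensemble member: parameters plus forward/backward machinery."""

    def __init__(self, config: ModelConfig, vocab_size: int,
                 n_covariates: int, rng: np.random.Generator):
        self.config = config
        self.vocab_size = vocab_size
        self.n_covariates = n_covariates
        e = config.embedding_dim
        self.hidden = e + 1          # per direction
        self.n_dir = 2 if config.bidirectional else 1
        self.out_width = self.n_dir * self.hidden
        self.head_width = self.out_width + n_covariates
        self.params: dict[str, np.ndarray] = {}
        p = self.params
        p["E_code"] = rng.normal(0.0, 1.0 / np.sqrt(e),
                                 size=(vocab_size + 1, e))
        p["E_type"] = rng.normal(0.0, 1.0 / np.sqrt(e),
                                 size=(N_CODE_TYPES + 1, e))
        H = self.hidden
        k = 1.0 / np.sqrt(H)
        for layer in range(config.gru_layers):
            din = self.hidden if layer == 0 else self.out_width
            for d in range(self.n_dir):
                p[f"W{layer}{d}"] = rng.uniform(-k, k, size=(din, 3 * H))
                p[f"U{layer}{d}"] = rng.uniform(-k, k, size=(H, 3 * H))
                p[f"bW{layer}{d}"] = np.zeros(3 * H)
                p[f"bU{layer}{d}"] = np.zeros(3 * H)
        p["q"] = rng.uniform(-k, k, size=self.out_width)
        kh = 1.0 / np.sqrt(self.head_width)
        p["W1"] = rng.uniform(-kh, kh,
                              size=(self.head_width, self.head_width))
        p["b1"] = np.zeros(self.head_width)
        p["w2"] = rng.uniform(-kh, kh, size=self.head_width)
        p["b2"] = np.zeros(1)

    def zero_like_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    # -- forward -----------------------------------------------------------
    def _gru_direction(self, X: np.ndarray, mask: np.ndarray, layer: int,
                       d: int) -> tuple[np.ndarray, _GruCache]:
        p = self.params
        W, U = p[f"W{layer}{d}"], p[f"U{layer}{d}"]
        bW, bU = p[f"bW{layer}{d}"], p[f"bU{layer}{d}"]
        B, L, _ = X.shape
        H = self.hidden
        order = list(range(L - 1, -1, -1)) if d == 1 else list(range(L))
        cache = _GruCache(*(np.zeros((B, L, H)) for _ in range(5)), X, order)
        O = np.zeros((B, L, H))
        h = np.zeros((B, H))
        for t in order:
            m = mask[:, t][:, None]
            xg = X[:, t] @ W + bW
            hg = h @ U + bU
            r = _sigmoid(xg[:, :H] + hg[:, :H])
            z = _sigmoid(xg[:, H:2 * H] + hg[:, H:2 * H])
            hn = hg[:, 2 * H:]
            n = np.tanh(xg[:, 2 * H:] + r * hn)
            hc = (1.0 - z) * n + z * h
            hnew = m * hc + (1.0 - m) * h
            cache.r[:, t], cache.z[:, t], cache.n[:, t] = r, z, n
            cache.hn[:, t], cache.h_prev[:, t] = hn, h
            O[:, t] = hnew
            h = hnew
        return O, cache

    def forward(self, batch: Batch, training: bool = False,
                drop_rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, dict]:
        """Compute f for a batch; the cache supports backward()."""
        p = self.params
        cfg = self.config
        tokens, types, mask = batch.tokens, batch.types, batch.mask
        emb = p["E_code"][tokens] + p["E_type"][types]       # (B, L, e)
        X = np.concatenate(
            [emb, DELTA_T_SCALE * batch.delta[..., None]], axis=2)
        cache: dict = {"batch": batch, "layer_inputs": [],
                       "gru_caches": [], "drop_masks": []}
        for layer in range(cfg.gru_layers):
            cache["layer_inputs"].append(X)
            outs, caches = [], []
            for d in range(self.n_dir):
                O, c = self._gru_direction(X, mask, layer, d)
                outs.append(O)
                caches.append(c)
            cache["gru_caches"].append(caches)
            X = np.concatenate(outs, axis=2)
            if training and cfg.dropout > 0 and layer < cfg.gru_layers - 1:
                dm = (drop_rng.random(X.shape) >= cfg.dropout) \
                    / (1.0 - cfg.dropout)
                X = X * dm
                cache["drop_masks"].append(dm)
            else:
                cache["drop_masks"].append(None)
        O = X                                                # (B, L, 2H)
        scores = np.einsum("bld,d->bl", O, p["q"])
        neg = -1e30 * (1.0 - mask)
        s = scores * mask + neg
        mx = s.max(axis=1, keepdims=True)
        e = np.exp(s - mx) * mask
        denom = e.sum(axis=1, keepdims=True)
        w = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
        context = np.einsum("bl,bld->bd", w, O)
        u = np.concatenate([context, batch.cov], axis=1)
        a1 = u @ p["W1"] + p["b1"]
        h1 = _elu(a1)
        f = h1 @ p["w2"] + p["b2"][0]
        cache.update(O=O, w=w, context=context, u=u, a1=a1, h1=h1)
        return f, cache

    # -- backward ----------------------------------------------------------
    def _gru_direction_backward(self, dO: np.ndarray, mask: np.ndarray,
                                layer: int, d: int, cache: _GruCache,
                                grads: dict) -> np.ndarray:
        p = self.params
        W, U = p[f"W{layer}{d}"], p[f"U{layer}{d}"]
        B, L, H = dO.shape
        dX = np.zeros_like(cache.x)
        dW = grads[f"W{layer}{d}"]
        dU = grads[f"U{layer}{d}"]
        dbW = grads[f"bW{layer}{d}"]
        dbU = grads[f"bU{layer}{d}"]
        dh = np.zeros((B, H))
        for t in reversed(cache.order):
            m = mask[:, t][:, None]
            dh = dh + dO[:, t]
            r, z, n = cache.r[:, t], cache.z[:, t], cache.n[:, t]
            hn, hp = cache.hn[:, t], cache.h_prev[:, t]
            dhc = dh * m
            dz = dhc * (hp - n)
            dn = dhc * (1.0 - z)
            dhprev = dhc * z + dh * (1.0 - m)
            dan = dn * (1.0 - n * n)
            dr = dan * hn
            dhn = dan * r
            dar = dr * r * (1.0 - r)
            daz = dz * z * (1.0 - z)
            dxg = np.concatenate([dar, daz, dan], axis=1)
            dhg = np.concatenate([dar, daz, dhn], axis=1)
            dW += cache.x[:, t].T @ dxg
            dbW += dxg.sum(axis=0)
            dU += hp.T @ dhg
            dbU += dhg.sum(axis=0)
            dX[:, t] = dxg @ W.T
            dh = dhg @ U.T + dhprev
        return dX

    def backward(self, cache: dict, df: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate d(loss)/d(f) to parameter gradients."""
        p = self.params
        grads = self.zero_like_grads()
        batch: Batch = cache["batch"]
        mask = batch.mask
        h1, a1, u = cache["h1"], cache["a1"], cache["u"]
        dh1 = df[:, None] * p["w2"][None, :]
        grads["w2"] += h1.T @ df
        grads["b2"][0] += df.sum()
        da1 = dh1 * np.where(a1 > 0, 1.0, _elu(a1) + 1.0)
        grads["W1"] += u.T @ da1
        grads["b1"] += da1.sum(axis=0)
        du = da1 @ p["W1"].T
        dcontext = du[:, :self.out_width]
        O, w = cache["O"], cache["w"]
        dO = w[..., None] * dcontext[:, None, :]
        dw = np.einsum("bd,bld->bl", dcontext, O)
        ds = w * (dw - (w * dw).sum(axis=1, keepdims=True))
        grads["q"] += np.einsum("bl,bld->d", ds, O)
        dO += ds[..., None] * p["q"][None, None, :]
        for layer in reversed(range(self.config.gru_layers)):
            dm = cache["drop_masks"][layer]
            if dm is not None:
                dO = dO * dm
            caches = cache["gru_caches"][layer]
            H = self.hidden
            dX = np.zeros_like(cache["layer_inputs"][layer])
            for d in range(self.n_dir):
                dX += self._gru_direction_backward(
                    dO[..., d * H:(d + 1) * H], mask, layer, d,
                    caches[d], grads)
            dO = dX
        demb = dO[..., :-1]   # Δt column is data, not a parameter
        np.add.at(grads["E_code"], batch.tokens, demb)
        np.add.at(grads["E_type"], batch.types, demb)
        return grads


def pair_logistic_loss(f_cases: np.ndarray, f_controls: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """Sampled-risk-set partial likelihood loss over matched pairs.

    Each case-control pair contributes ``log(1 + exp(-(f_case -
    f_control)))`` — the negative log Cox partial likelihood of a sampled
    risk set of size two. Returns (mean loss, dloss/df_cases,
    dloss/df_controls).
    """
    f_cases = np.asarray(f_cases, dtype=float)
    f_controls = np.asarray(f_controls, dtype=float)
    if f_cases.shape != f_controls.shape:
        raise ValueError("case and control score lists differ in length")
    diff = f_cases - f_controls
    loss = float(np.mean(np.logaddexp(0.0, -diff)))
    dd = -_sigmoid(-diff) / diff.size
    return loss, dd, -dd


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            self.params[k] -= (self.lr * (self.m[k] / b1t)
                               / (np.sqrt(self.v[k] / b2t) + self.eps))
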