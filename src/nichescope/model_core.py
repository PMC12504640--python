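"""The neighborhood transformer: encode, pool, decode, and the ZINB likelihood.

Each cell becomes a token by concatenating a two-layer GELU perceptron over
its log1p expression with a learned cell-type embedding.  A neighborhood's
tokens plus a learned register token pass through pre-norm self-attention
layers restricted to that neighborhood, and attention pooling (a learned
multi-head query) collapses them into one d-vector — the neighborhood
representation.  A shallow decoder then refines the pair (neighborhood
vector, masked-cell type embedding) and linear heads emit the parameters of
a zero-inflated negative binomial model of the masked reference cell's raw
transcript counts.

The reference cell's own token is never part of the encoder input, so the
representation describes context only.  There is no positional input:
two references with the same neighbor multiset get identical embeddings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import special

from . import _tensor as T
from ._tensor import Tensor
from .neighborhoods import NeighborhoodBatch

__all__ = ["ModelConfig", "ZINBParams", "CellTransformer", "zinb_nll"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults target gene-panel-scale data: embedding dimension 384 split
    evenly between expression and type tokens, 4 encoder and 4 decoder
    layers, 8 heads, biases in the Q/K/V projections (they stabilize
    training) and nowhere else.  High-gene-count data benefits from a
    deeper encoder (10 layers).
    """

    n_cell_types: int
    n_genes: int
    embed_dim: int = 384
    expr_token_dim: int = 192
    type_token_dim: int = 192
    n_encoder_layers: int = 4
    n_decoder_layers: int = 4
    n_heads: int = 8
    qkv_bias: bool = True
    mlp_ratio: int = 4
    use_type_encoder: bool = True
    use_type_decoder: bool = True
    likelihood: str = "zinb"  # "zinb" or "nb" (zero inflation pinned to 0)

    def __post_init__(self):
        if self.expr_token_dim + self.type_token_dim != self.embed_dim:
            raise ValueError("expr_token_dim + type_token_dim must equal embed_dim")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.likelihood not in ("zinb", "nb"):
            raise ValueError("likelihood must be 'zinb' or 'nb'")

    @classmethod
    def small(cls, n_cell_types: int, n_genes: int, **kw) -> "ModelConfig":
        """Reduced CPU-friendly configuration (d=64, 2+2 layers, 4 heads)."""
        defaults = dict(
            embed_dim=64,
            expr_token_dim=32,
            type_token_dim=32,
            n_encoder_layers=2,
            n_decoder_layers=2,
            n_heads=4,
        )
        defaults.update(kw)
        return cls(n_cell_types=n_cell_types, n_genes=n_genes, **defaults)


@dataclass
class ZINBParams:
    """Decoder output for one masked cell.

    ``mean`` is a probability simplex over genes (the expression profile);
    the per-cell positive ``scale`` plays the role of a library-size factor,
    so the modeled count mean is ``scale * mean``.  ``dispersion`` is the
    per-gene inverse-overdispersion theta of the negative binomial, and
    ``zero_inflation_logit`` parameterizes the extra point mass at zero.
    """

    mean: np.ndarray
    dispersion: np.ndarray
    zero_inflation_logit: np.ndarray
    scale: float

    def __post_init__(self):
        if not (np.all(self.mean > 0) and np.all(self.dispersion > 0) and self.scale > 0):
            raise ValueError("mean, dispersion and scale must be strictly positive")
        if not (
            np.all(np.isfinite(self.mean))
            and np.all(np.isfinite(self.dispersion))
            and np.isfinite(self.scale)
        ):
            raise ValueError("ZINB parameters must be finite")

    @property
    def mu(self) -> np.ndarray:
        return self.scale * self.mean


def zinb_nll(params: ZINBParams, observed: np.ndarray) -> float:
    """Mean-over-genes negative log-likelihood of one observed count vector.

    Stable at y=0 and for extreme logits; with the zero-inflation logit at
    -inf (pi = 0) it reduces exactly to the plain negative binomial NLL.
    """
    y = np.asarray(observed, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("observed counts must be non-negative integers")
    mu, theta = params.mu, params.dispersion
    zeta = np.broadcast_to(np.asarray(params.zero_inflation_logit, float), y.shape)
    log_nb = (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )
    sp = np.logaddexp(0.0, zeta)  # softplus(zeta); 0 when zeta = -inf
    ll = np.where(y == 0, np.logaddexp(zeta, log_nb) - sp, log_nb - sp)
    return float(-np.mean(ll))


def _init(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return rng.normal(0.0, std, size=shape)


class CellTransformer:
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d, h = cfg.embed_dim, cfg.mlp_ratio * cfg.embed_dim
        ed, td, g, C = cfg.expr_token_dim, cfg.type_token_dim, cfg.n_genes, cfg.n_cell_types
        p: dict[str, np.ndarray] = {}

        p["expr_mlp1_w"] = _init(rng, (g, ed))
        p["expr_mlp1_b"] = np.zeros(ed)
        p["expr_mlp2_w"] = _init(rng, (ed, ed))
        p["expr_mlp2_b"] = np.zeros(ed)
        n_enc_types = C if cfg.use_type_encoder else 1
        p["type_embed"] = _init(rng, (n_enc_types, td))
        p["register"] = _init(rng, (1, d))
        for i in range(cfg.n_encoder_layers):
            self._init_block(p, rng, f"enc{i}", d, h, cfg.qkv_bias)
        p["pool_ln_g"] = np.ones(d)
        p["pool_ln_b"] = np.zeros(d)
        p["pool_query"] = _init(rng, (1, d))
        for name in ("pool_k", "pool_v"):
            p[f"{name}_w"] = _init(rng, (d, d))
            if cfg.qkv_bias:
                p[f"{name}_b"] = np.zeros(d)
        p["pool_o_w"] = _init(rng, (d, d))
        n_dec_types = C if cfg.use_type_decoder else 1
        p["dec_type_embed"] = _init(rng, (n_dec_types, d))
        for i in range(cfg.n_decoder_layers):
            self._init_block(p, rng, f"dec{i}", d, h, cfg.qkv_bias)
        p["dec_ln_g"] = np.ones(d)
        p["dec_ln_b"] = np.zeros(d)
        for name, width in (("mean", g), ("disp", g), ("zi", g), ("scale", 1)):
            p[f"head_{name}_w"] = _init(rng, (d, width))
            p[f"head_{name}_b"] = np.zeros(width)
        # sparse-zeros prior: start near pi ~ 5% rather than 50%
        p["head_zi_b"] += -3.0
        self.params = {k: Tensor(v, requires_grad=True, name=k) for k, v in p.items()}

    @staticmethod
    def _init_block(p, rng, prefix, d, hidden, qkv_bias):
        p[f"{prefix}_ln1_g"] = np.ones(d)
        p[f"{prefix}_ln1_b"] = np.zeros(d)
        for name in ("q", "k", "v"):
            p[f"{prefix}_{name}_w"] = _init(rng, (d, d))
            if qkv_bias:
                p[f"{prefix}_{name}_b"] = np.zeros(d)
        p[f"{prefix}_o_w"] = _init(rng, (d, d))
        p[f"{prefix}_ln2_g"] = np.ones(d)
        p[f"{prefix}_ln2_b"] = np.zeros(d)
        p[f"{prefix}_mlp1_w"] = _init(rng, (d, hidden))
        p[f"{prefix}_mlp2_w"] = _init(rng, (hidden, d))

    # -- introspection ---------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.params.values()))

    # -- token encoding --------------------------------------------------
    def _tokens_t(self, expr: np.ndarray, types: np.ndarray) -> Tensor:
        """(N, d) cell tokens: concat(expr MLP, type embedding)."""
        cfg, p = self.cfg, self.params
        expr = np.asarray(expr, dtype=float)
        types = np.asarray(types, dtype=np.int64)
        if expr.ndim != 2 or expr.shape[1] != cfg.n_genes:
            raise ValueError(f"expected {cfg.n_genes} gene columns, got {expr.shape}")
        if types.size and (types.min() < 1 or types.max() > cfg.n_cell_types):
            raise ValueError("unknown cell type id")
        x = T.matmul(Tensor(expr), p["expr_mlp1_w"]) + p["expr_mlp1_b"]
        x = T.gelu(x)
        x = T.matmul(x, p["expr_mlp2_w"]) + p["expr_mlp2_b"]
        idx = (types - 1) if cfg.use_type_encoder else np.zeros(len(types), dtype=np.int64)
        te = T.take(p["type_embed"], idx)
        return T.concat([x, te], axis=1)

    def encode_cell_tokens(self, expr: np.ndarray, types: np.ndarray) -> np.ndarray:
        with T.no_grad():
            return self._tokens_t(expr, types).data

    # -- encoder + pooling ----------------------------------------------
    def _attention_block(self, x: Tensor, prefix: str) -> Tensor:
        """One pre-norm self-attention + MLP residual block on an (S, d)
        token sequence.  Every neighborhood is processed with its exact
        sequence length (no padding), so its output depends only on its own
        tokens — permutation of the caller's neighbor order (canonicalized
        at batch assembly) and batch composition cannot change it, bit for
        bit."""
        cfg, p = self.cfg, self.params
        nh, d = cfg.n_heads, cfg.embed_dim
        dh = d // nh
        S = x.shape[0]
        xn = T.layer_norm(x, p[f"{prefix}_ln1_g"], p[f"{prefix}_ln1_b"])

        def proj(name):
            y = T.matmul(xn, p[f"{prefix}_{name}_w"])
            if cfg.qkv_bias:
                y = y + p[f"{prefix}_{name}_b"]
            return T.swapaxes(T.reshape(y, (S, nh, dh)), 0, 1)  # (nh, S, dh)

        q, k, v = proj("q"), proj("k"), proj("v")
        scores = T.matmul(q, T.swapaxes(k, -1, -2)) * (1.0 / np.sqrt(dh))
        att = T.softmax(scores, axis=-1)
        out = T.reshape(T.swapaxes(T.matmul(att, v), 0, 1), (S, d))
        x = x + T.matmul(out, p[f"{prefix}_o_w"])
        xn2 = T.layer_norm(x, p[f"{prefix}_ln2_g"], p[f"{prefix}_ln2_b"])
        y = T.gelu(T.matmul(xn2, p[f"{prefix}_mlp1_w"]))
        return x + T.matmul(y, p[f"{prefix}_mlp2_w"])

    def _pool_one(self, seq: Tensor) -> Tensor:
        """Encoder stack + attention pooling for one (S, d) neighborhood
        sequence (register token at row 0); returns (1, d)."""
        cfg, p = self.cfg, self.params
        nh, d = cfg.n_heads, cfg.embed_dim
        dh = d // nh
        x = seq
        for i in range(cfg.n_encoder_layers):
            x = self._attention_block(x, f"enc{i}")
        xf = T.layer_norm(x, p["pool_ln_g"], p["pool_ln_b"])
        S = xf.shape[0]

        def kv(name):
            y = T.matmul(xf, p[f"pool_{name}_w"])
            if cfg.qkv_bias:
                y = y + p[f"pool_{name}_b"]
            return T.swapaxes(T.reshape(y, (S, nh, dh)), 0, 1)

        k, v = kv("k"), kv("v")
        q = T.reshape(p["pool_query"], (nh, 1, dh))
        scores = T.matmul(q, T.swapaxes(k, -1, -2)) * (1.0 / np.sqrt(dh))
        att = T.softmax(scores, axis=-1)
        pooled = T.reshape(T.swapaxes(T.matmul(att, v), 0, 1), (1, d))
        return T.matmul(pooled, p["pool_o_w"])

    def _pool_t(self, tokens: Tensor, batch: NeighborhoodBatch) -> Tensor:
        """(B, 1, d) neighborhood representations (one graph per
        neighborhood; a zero-neighbor reference pools its register token
        alone)."""
        p = self.params
        d = self.cfg.embed_dim
        rows = []
        for b in range(batch.n_neighborhoods):
            ids = batch.token_index[b][batch.valid[b]]
            ids = np.sort(ids[ids >= 0])  # canonical order: exact permutation invariance
            if len(ids):
                seq = T.concat([p["register"], T.take(tokens, ids)], axis=0)
            else:
                seq = p["register"]
            rows.append(T.reshape(self._pool_one(seq), (1, 1, d)))
        return rows[0] if len(rows) == 1 else T.concat(rows, axis=0)

    def encode_and_pool(self, batch: NeighborhoodBatch, tokens: np.ndarray) -> np.ndarray:
        """One pooled d-vector per reference neighborhood (evaluation mode)."""
        with T.no_grad():
            return self._pool_t(Tensor(tokens), batch).data[:, 0, :]

    # -- decoder ---------------------------------------------------------
    def _decode_t(self, nbhd: Tensor, ref_types: np.ndarray) -> dict[str, Tensor]:
        cfg, p = self.cfg, self.params
        ref_types = np.asarray(ref_types, dtype=np.int64)
        if ref_types.min() < 1 or ref_types.max() > cfg.n_cell_types:
            raise ValueError("unknown cell type id")
        B = nbhd.shape[0]
        d = cfg.embed_dim
        idx = (ref_types - 1) if cfg.use_type_decoder else np.zeros(B, dtype=np.int64)
        raw = {"mean": [], "disp": [], "zi": [], "scale": []}
        for b in range(B):  # per-reference pair keeps the decode exact per item
            mask_tok = T.take(p["dec_type_embed"], idx[b : b + 1])  # (1, d)
            x = T.concat([T.reshape(T.take(nbhd, b), (1, d)), mask_tok], axis=0)
            for i in range(cfg.n_decoder_layers):
                x = self._attention_block(x, f"dec{i}")
            x = T.layer_norm(x, p["dec_ln_g"], p["dec_ln_b"])
            h = T.take(x, slice(1, 2))  # masked-cell token, (1, d)
            for name in raw:
                raw[name].append(T.matmul(h, p[f"head_{name}_w"]) + p[f"head_{name}_b"])
        cat = {k: (v[0] if B == 1 else T.concat(v, axis=0)) for k, v in raw.items()}
        return {
            "mean_logits": cat["mean"],  # (B, g)
            "dispersion": T.softplus(cat["disp"]) + 1e-4,
            "zero_inflation_logit": cat["zi"],
            # log-link: multiplicative gradients let the library-size factor
            # cover orders of magnitude in a few optimizer steps
            "scale": T.exp(cat["scale"]),  # (B, 1)
        }

    def decode_masked_cell(self, nbhd_vec: np.ndarray, ref_type: int) -> ZINBParams:
        with T.no_grad():
            out = self._decode_t(
                Tensor(np.asarray(nbhd_vec, float).reshape(1, 1, -1)),
                np.array([ref_type]),
            )
            probs = T.softmax(out["mean_logits"], axis=-1).data[0]
        return ZINBParams(
            mean=probs,
            dispersion=out["dispersion"].data[0],
            zero_inflation_logit=out["zero_inflation_logit"].data[0],
            scale=float(out["scale"].data[0, 0]),
        )

    # -- likelihood ------------------------------------------------------
    def _nll_t(self, heads: dict[str, Tensor], counts: np.ndarray) -> Tensor:
        """Mean (over cells and genes) ZINB negative log-likelihood Tensor."""
        B, g = counts.shape
        y = counts.astype(float)
        probs = T.softmax(T.reshape(heads["mean_logits"], (B, g)), axis=-1)
        mu = probs * T.reshape(heads["scale"], (B, 1))
        theta = T.reshape(heads["dispersion"], (B, g))
        log_nb = (
            T.lgamma(theta + y)
            - T.lgamma(theta)
            - special.gammaln(y + 1.0)
            + theta * (T.log(theta) - T.log(theta + mu))
            + y * (T.log(mu) - T.log(theta + mu))
        )
        if self.cfg.likelihood == "nb":
            ll = log_nb
        else:
            zeta = T.reshape(heads["zero_inflation_logit"], (B, g))
            zero = (y == 0).astype(float)
            ll = zero * (T.logaddexp(zeta, log_nb) - T.softplus(zeta)) + (1.0 - zero) * (
                log_nb - T.softplus(zeta)
            )
        return -ll.mean()

    def loss(self, batch: NeighborhoodBatch, expr: np.ndarray, types: np.ndarray, counts: np.ndarray) -> Tensor:
        """Masked-cell NLL for one batch (differentiable)."""
        tokens = self._tokens_t(expr, types)
        pooled = self._pool_t(tokens, batch)
        heads = self._decode_t(pooled, batch.reference_type)
        return self._nll_t(heads, counts[batch.reference_index])

    def evaluate_nll(self, batch: NeighborhoodBatch, expr, types, counts) -> float:
        with T.no_grad():
            return float(self.loss(batch, expr, types, counts).data)

    def predict_mu(self, batch: NeighborhoodBatch, tokens: np.ndarray) -> np.ndarray:
        """Predicted mean counts (B, g) for the masked reference cells."""
        with T.no_grad():
            pooled = self._pool_t(Tensor(tokens), batch)
            heads = self._decode_t(pooled, batch.reference_type)
            B = batch.n_neighborhoods
            probs = T.softmax(T.reshape(heads["mean_logits"], (B, self.cfg.n_genes)), axis=-1)
            return probs.data * heads["scale"].data.reshape(B, 1)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(path, __config__=json.dumps(asdict(self.cfg)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CellTransformer":
        with np.load(Path(path), allow_pickle=False) as f:
            cfg = ModelConfig(**json.loads(str(f["__config__"])))
            model = cls(cfg, seed=0)
            for k, t in model.params.items():
                arr = f[k]
                if arr.shape != t.data.shape:
                    raise ValueError(f"checkpoint shape mismatch for {k}")
                t.data = arr.astype(np.float64)
        return model
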