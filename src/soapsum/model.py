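"""Dual-encoder pointer-generator network for assessment generation.

The architecture reads the Subjective+Objective narrative X with one
bidirectional LSTM and the Header (chief complaint) T with a second one.
An LSTM decoder generates the Assessment word by word.  At each step it
first attends over the header states Z to form a patient-information
context z*, then uses (s_i, z*) — the attention-over-attention — to
attend over the narrative states H and fetch a source context h*.  A
sigmoid gate p_gen mixes a vocabulary softmax with the source attention
to form the final distribution over the extended vocabulary, letting the
decoder copy out-of-vocabulary tokens (names, dates) directly from the
source.  A coverage vector — the running sum of past source attentions —
can feed back into the attention logits to discourage repetition.

The three published baselines are ablations of the same parameterization:

========================  ====  ======  ========
model                     copy  header  coverage
========================  ====  ======  ========
``seq2seq``               off   off     off
``pg``                    on    off     off
``pg-coverage``           on    off     on
``n2mag``                 on    on      off
``n2mag-coverage``        on    on      on
========================  ====  ======  ========

All math runs on the reverse-mode tape in :mod:`soapsum._autodiff`;
gradients are therefore analytic and are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .notes_io import EncodedExample, Vocabulary

__all__ = [
    "ModelConfig",
    "StepDistribution",
    "AssessmentModel",
    "MODEL_FLAGS",
    "config_for_model",
    "init_parameters",
    "add_coverage_parameters",
    "parameter_count",
    "make_batch",
    "encode_source",
    "encode_header",
    "init_decoder_state",
    "header_attention",
    "source_attention",
    "copy_gate",
    "vocab_distribution",
    "final_distribution",
    "decoder_step",
    "save_checkpoint",
    "load_checkpoint",
]

# flag triples (use_copy, use_header_encoder, use_coverage) per model name
MODEL_FLAGS = {
    "seq2seq": (False, False, False),
    "pg": (True, False, False),
    "pg-coverage": (True, False, True),
    "n2mag": (True, True, False),
    "n2mag-coverage": (True, True, True),
}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_dim`` is the per-direction encoder size; encoder states are
    its concatenation (2·hidden) and the decoder state is reduced back
    to ``hidden_dim`` by a learned linear map.  ``attn_dim`` is the width
    of the additive-attention hidden layer (defaults to 2·hidden).
    """

    vocab_size: int
    embed_dim: int = 128
    hidden_dim: int = 200
    use_header_encoder: bool = True
    use_copy: bool = True
    use_coverage: bool = False
    input_feeding: bool = False
    max_source_len: int = 500
    max_header_len: int = 100
    max_decode_len: int = 60
    attn_dim: int | None = None
    init_seed: int = 0

    def __post_init__(self):
        if self.attn_dim is None:
            self.attn_dim = 2 * self.hidden_dim
        if self.vocab_size < 4:
            raise ValueError("vocab_size must include the four special ids")
        flags = (self.use_copy, self.use_header_encoder, self.use_coverage)
        if flags not in MODEL_FLAGS.values():
            raise ValueError(
                f"unsupported flag combination copy={flags[0]} "
                f"header={flags[1]} coverage={flags[2]}"
            )

    @property
    def enc_dim(self) -> int:
        return 2 * self.hidden_dim

    @property
    def dec_dim(self) -> int:
        return self.hidden_dim


def config_for_model(name: str, vocab_size: int, **overrides) -> ModelConfig:
    """Build the configuration for one of the five published setups."""
    try:
        use_copy, use_header, use_cov = MODEL_FLAGS[name]
    except KeyError:
        raise ValueError(
            f"unknown model name {name!r}; expected one of {sorted(MODEL_FLAGS)}"
        ) from None
    return ModelConfig(
        vocab_size=vocab_size,
        use_copy=use_copy,
        use_header_encoder=use_header,
        use_coverage=use_cov,
        **overrides,
    )


# ---------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------

def _parameter_shapes(config: ModelConfig) -> dict[str, tuple[int, ...]]:
    d, H, A, V = config.embed_dim, config.hidden_dim, config.attn_dim, config.vocab_size
    E = config.enc_dim
    dec_in = d + (E if config.input_feeding else 0)
    shapes: dict[str, tuple[int, ...]] = {
        "embedding": (V, d),
        "src_fwd_W": (d + H, 4 * H),
        "src_fwd_b": (4 * H,),
        "src_bwd_W": (d + H, 4 * H),
        "src_bwd_b": (4 * H,),
        "reduce_h_W": (E, H),
        "reduce_h_b": (H,),
        "reduce_c_W": (E, H),
        "reduce_c_b": (H,),
        "dec_W": (dec_in + H, 4 * H),
        "dec_b": (4 * H,),
        "att_src_Wh": (E, A),
        "att_src_Ws": (H, A),
        "att_src_b": (A,),
        "att_src_v": (A, 1),
        "out_W1": ((H + 2 * E if config.use_header_encoder else H + E), H),
        "out_b1": (H,),
        "out_W2": (H, V),
        "out_b2": (V,),
    }
    if config.use_header_encoder:
        shapes.update(
            {
                "hdr_fwd_W": (d + H, 4 * H),
                "hdr_fwd_b": (4 * H,),
                "hdr_bwd_W": (d + H, 4 * H),
                "hdr_bwd_b": (4 * H,),
                "att_hdr_Wz": (E, A),
                "att_hdr_Ws": (H, A),
                "att_hdr_b": (A,),
                "att_hdr_v": (A, 1),
                "att_src_Wz": (E, A),
            }
        )
    if config.use_copy:
        shapes.update(
            {
                "pgen_Wh": (E, 1),
                "pgen_Ws": (H, 1),
                "pgen_Wy": (d, 1),
                "pgen_b": (1,),
            }
        )
    if config.use_coverage:
        shapes["att_src_wc"] = (1, A)
    return shapes


def parameter_count(config: ModelConfig) -> int:
    """Closed-form total number of scalar parameters."""
    return sum(int(np.prod(s)) for s in _parameter_shapes(config).values())


def init_parameters(config: ModelConfig) -> dict[str, Tensor]:
    """Random initialization: uniform(−0.1, 0.1) for weights/projections,
    normal(0, 1e-4) for embeddings, zeros for the coverage weight (so a
    coverage fine-tune starts exactly at the pretrained model's output).
    """
    rng = np.random.default_rng(config.init_seed)
    params: dict[str, Tensor] = {}
    for name, shape in _parameter_shapes(config).items():
        if name == "embedding":
            data = rng.normal(0.0, 1e-4, size=shape)
        elif name == "att_src_wc":
            data = np.zeros(shape)
        else:
            data = rng.uniform(-0.1, 0.1, size=shape)
        params[name] = Tensor(data, requires_grad=True)
    return params


def add_coverage_parameters(params: dict[str, Tensor], config: ModelConfig) -> None:
    """Extend a pretrained parameter set with the coverage weight.

    The new weight starts at zero, so the extended model initially
    reproduces the pretrained attention exactly.
    """
    if not config.use_coverage:
        raise ValueError("config does not enable coverage")
    if "att_src_wc" not in params:
        params["att_src_wc"] = Tensor(np.zeros((1, config.attn_dim)), requires_grad=True)


# ---------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------

@dataclass
class Batch:
    """Padded id arrays for a batch of encoded examples."""

    src_ids: np.ndarray          # (B, n) vocabulary ids, PAD-padded
    src_ext_ids: np.ndarray      # (B, n) extended ids
    src_mask: np.ndarray         # (B, n) 1.0 on real tokens
    hdr_ids: np.ndarray          # (B, m)
    hdr_mask: np.ndarray         # (B, m)
    dec_in_ids: np.ndarray       # (B, l) BEGIN + shifted gold, UNK-mapped
    target_ids: np.ndarray       # (B, l) gold extended ids
    target_mask: np.ndarray      # (B, l)
    max_oov: int
    examples: list[EncodedExample] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.src_ids.shape[0]


def _pad(rows: list[list[int]], pad_value: int) -> tuple[np.ndarray, np.ndarray]:
    width = max(len(r) for r in rows)
    out = np.full((len(rows), width), pad_value, dtype=np.int64)
    mask = np.zeros((len(rows), width))
    for i, r in enumerate(rows):
        out[i, : len(r)] = r
        mask[i, : len(r)] = 1.0
    return out, mask


def make_batch(examples: Sequence[EncodedExample], vocab: Vocabulary) -> Batch:
    """Pad a group of examples into rectangular id arrays."""
    V, pad, unk, begin = vocab.size, vocab.pad_id, vocab.unk_id, vocab.begin_id
    src_ids, src_mask = _pad([ex.source_ids for ex in examples], pad)
    src_ext, _ = _pad([ex.source_ext_ids for ex in examples], pad)
    hdr_rows = [ex.header_ids if ex.header_ids else [pad] for ex in examples]
    hdr_ids, hdr_mask = _pad(hdr_rows, pad)
    tgt_rows = [ex.target_ids for ex in examples]
    target_ids, target_mask = _pad(tgt_rows, pad)
    dec_rows = [[begin] + [t if t < V else unk for t in row[:-1]] for row in tgt_rows]
    dec_in, _ = _pad(dec_rows, pad)
    return Batch(
        src_ids=src_ids,
        src_ext_ids=src_ext,
        src_mask=src_mask,
        hdr_ids=hdr_ids,
        hdr_mask=hdr_mask,
        dec_in_ids=dec_in,
        target_ids=target_ids,
        target_mask=target_mask,
        max_oov=max(ex.n_oov for ex in examples),
        examples=list(examples),
    )


# ---------------------------------------------------------------------
# recurrent encoders
# ---------------------------------------------------------------------

def _lstm_step(W: Tensor, b: Tensor, x: Tensor, h: Tensor, c: Tensor, mask: Tensor):
    """One masked LSTM step; padded positions carry state through."""
    Hdim = h.shape[1]
    z = ad.matmul(ad.concat([x, h], axis=1), W) + b
    i = ad.sigmoid(ad.narrow(z, 1, 0, Hdim))
    f = ad.sigmoid(ad.narrow(z, 1, Hdim, Hdim))
    g = ad.tanh(ad.narrow(z, 1, 2 * Hdim, Hdim))
    o = ad.sigmoid(ad.narrow(z, 1, 3 * Hdim, Hdim))
    c_new = f * c + i * g
    h_new = o * ad.tanh(c_new)
    keep = Tensor(1.0) - mask
    return mask * h_new + keep * h, mask * c_new + keep * c


def _run_lstm(W, b, embeds, masks, Hdim, reverse=False):
    """Run an LSTM over per-step embeddings; returns per-step h and finals."""
    B = embeds[0].shape[0]
    h = Tensor(np.zeros((B, Hdim)))
    c = Tensor(np.zeros((B, Hdim)))
    order = range(len(embeds) - 1, -1, -1) if reverse else range(len(embeds))
    states: list[Tensor | None] = [None] * len(embeds)
    for t in order:
        h, c = _lstm_step(W, b, embeds[t], h, c, masks[t])
        states[t] = h
    return states, h, c


def _embed_steps(params, ids: np.ndarray) -> list[Tensor]:
    return [ad.gather_rows(params["embedding"], ids[:, t]) for t in range(ids.shape[1])]


def _mask_steps(mask: np.ndarray) -> list[Tensor]:
    return [Tensor(mask[:, t : t + 1]) for t in range(mask.shape[1])]


@dataclass
class EncoderStates:
    """Per-token encoder states and the finals used to start the decoder."""

    H: Tensor                    # (B, n, 2·hidden) source states
    Z: Tensor | None             # (B, m, 2·hidden) header states
    final_h: Tensor              # (B, 2·hidden) concat of fwd-last / bwd-first
    final_c: Tensor              # (B, 2·hidden)
    src_mask: np.ndarray
    hdr_mask: np.ndarray | None
    H_proj: Tensor | None = None  # cached att_src_Wh · H
    Z_proj: Tensor | None = None  # cached att_hdr_Wz · Z


def encode_source(params, src_ids: np.ndarray, src_mask: np.ndarray, config: ModelConfig):
    """Bidirectional LSTM over the narrative; one 2·hidden state per token."""
    if src_ids.shape[1] == 0:
        raise ValueError("empty source")
    embeds = _embed_steps(params, src_ids)
    masks = _mask_steps(src_mask)
    Hdim = config.hidden_dim
    fwd, h_f, c_f = _run_lstm(params["src_fwd_W"], params["src_fwd_b"], embeds, masks, Hdim)
    bwd, h_b, c_b = _run_lstm(params["src_bwd_W"], params["src_bwd_b"], embeds, masks, Hdim, reverse=True)
    states = [ad.concat([f, bk], axis=1) for f, bk in zip(fwd, bwd)]
    H = ad.stack(states, axis=1)
    return H, ad.concat([h_f, h_b], axis=1), ad.concat([c_f, c_b], axis=1)


def encode_header(params, hdr_ids: np.ndarray, hdr_mask: np.ndarray, config: ModelConfig):
    """Second bidirectional LSTM over the header / chief complaint."""
    if hdr_ids.shape[1] == 0:
        raise ValueError("empty header")
    embeds = _embed_steps(params, hdr_ids)
    masks = _mask_steps(hdr_mask)
    Hdim = config.hidden_dim
    fwd, _, _ = _run_lstm(params["hdr_fwd_W"], params["hdr_fwd_b"], embeds, masks, Hdim)
    bwd, _, _ = _run_lstm(params["hdr_bwd_W"], params["hdr_bwd_b"], embeds, masks, Hdim, reverse=True)
    return ad.stack([ad.concat([f, bk], axis=1) for f, bk in zip(fwd, bwd)], axis=1)


def init_decoder_state(final_h: Tensor, final_c: Tensor, params) -> tuple[Tensor, Tensor]:
    """Linear reduction of the concatenated bidirectional finals."""
    s_h = ad.matmul(final_h, params["reduce_h_W"]) + params["reduce_h_b"]
    s_c = ad.matmul(final_c, params["reduce_c_W"]) + params["reduce_c_b"]
    return s_h, s_c


# ---------------------------------------------------------------------
# attention stages
# ---------------------------------------------------------------------

def header_attention(s: Tensor, Z: Tensor, Z_proj: Tensor, hdr_mask: np.ndarray, params):
    """Attention over header states: α_i = softmax_j vᵀ tanh(W_Z z_j + W_S s_i + b_z),
    z* = Σ_k α_ik z_k."""
    B, m, A = Z_proj.shape
    query = ad.matmul(s, params["att_hdr_Ws"]) + params["att_hdr_b"]
    pre = Z_proj + ad.reshape(query, (B, 1, A))
    scores = ad.reshape(ad.matmul(ad.tanh(pre), params["att_hdr_v"]), (B, m))
    scores = scores + Tensor((hdr_mask - 1.0) * 1e9)
    alpha = ad.softmax(scores, axis=-1)
    z_star = ad.sum_(ad.reshape(alpha, (B, m, 1)) * Z, axis=1)
    return alpha, z_star


def source_attention(
    s: Tensor,
    z_star: Tensor | None,
    H: Tensor,
    H_proj: Tensor,
    src_mask: np.ndarray,
    params,
    coverage: Tensor | None = None,
):
    """Attention over narrative states, steered by the header context.

    Logits are vᵀ tanh(W_h h_j + W_s s_i [+ W_z z*_i] [+ w_c c_ij] + b);
    the z* term is present only for the dual-encoder models and the
    coverage term only when a coverage vector is supplied.
    """
    B, n, A = H_proj.shape
    query = ad.matmul(s, params["att_src_Ws"]) + params["att_src_b"]
    if z_star is not None:
        query = query + ad.matmul(z_star, params["att_src_Wz"])
    pre = H_proj + ad.reshape(query, (B, 1, A))
    if coverage is not None:
        pre = pre + ad.matmul(ad.reshape(coverage, (B, n, 1)), params["att_src_wc"])
    scores = ad.reshape(ad.matmul(ad.tanh(pre), params["att_src_v"]), (B, n))
    scores = scores + Tensor((src_mask - 1.0) * 1e9)
    beta = ad.softmax(scores, axis=-1)
    h_star = ad.sum_(ad.reshape(beta, (B, n, 1)) * H, axis=1)
    return beta, h_star


def copy_gate(h_star: Tensor, s: Tensor, y_prev: Tensor, params) -> Tensor:
    """p_gen = σ(W'_h* h* + W'_S s + W'_y y_prev + b'): the probability of
    generating from the fixed vocabulary rather than copying."""
    if "pgen_Wh" not in params:
        raise ValueError("copy gate called but the copy mechanism is disabled")
    z = (
        ad.matmul(h_star, params["pgen_Wh"])
        + ad.matmul(s, params["pgen_Ws"])
        + ad.matmul(y_prev, params["pgen_Wy"])
        + params["pgen_b"]
    )
    return ad.sigmoid(z)  # (B, 1)


def vocab_distribution(s: Tensor, h_star: Tensor, params, z_star: Tensor | None = None) -> Tensor:
    """Two-layer affine readout followed by a softmax over V.

    The readout sees [s; h*] — and, for the dual-encoder models, the
    header context z* as well, so the chief complaint conditions word
    choice directly in addition to steering the source attention.
    """
    parts = [s, h_star] if z_star is None else [s, h_star, z_star]
    feat = ad.matmul(ad.concat(parts, axis=1), params["out_W1"]) + params["out_b1"]
    logits = ad.matmul(feat, params["out_W2"]) + params["out_b2"]
    return ad.softmax(logits, axis=-1)


def final_distribution(
    p_gen: Tensor,
    p_voc: Tensor,
    beta: Tensor,
    src_ext_ids: np.ndarray,
    n_oov: int,
) -> Tensor:
    """Mix generation and copying over the extended vocabulary:
    p(w) = p_gen·p_voc(w) + (1−p_gen)·Σ_j 1(w_j=w)·β_j.

    Copy mass is scatter-added by extended id, so repeated source tokens
    accumulate onto a single id.
    """
    B, V = p_voc.shape
    size = V + n_oov
    if src_ext_ids.max(initial=0) >= size:
        raise ValueError("extended id out of range for the extended vocabulary")
    gen = p_gen * p_voc
    if n_oov > 0:
        gen = ad.concat([gen, Tensor(np.zeros((B, n_oov)))], axis=1)
    copy = ad.scatter_add((Tensor(1.0) - p_gen) * beta, src_ext_ids, size)
    return gen + copy


# ---------------------------------------------------------------------
# one decoder step and the full teacher-forced pass
# ---------------------------------------------------------------------

@dataclass
class StepDistribution:
    """Everything the decoder produced at one step (tape tensors)."""

    header_attention: Tensor | None
    header_context: Tensor | None
    source_attention: Tensor
    source_context: Tensor
    p_gen: Tensor | None
    p_vocab: Tensor
    p_final: Tensor
    coverage: Tensor | None


def decoder_step(
    params,
    config: ModelConfig,
    prev_ids: np.ndarray,
    state: tuple[Tensor, Tensor],
    enc: EncoderStates,
    src_ext_ids: np.ndarray,
    n_oov: int,
    coverage: Tensor | None = None,
    prev_context: Tensor | None = None,
):
    """Advance the decoder one step on the previous word's embedding.

    Extended ids (≥ |V|) have no embedding row and are mapped to UNK by
    the caller.  Returns the step distribution, the new LSTM state, and
    the new source context (used only when input feeding is enabled).
    """
    y_prev = ad.gather_rows(params["embedding"], prev_ids)
    x = y_prev
    if config.input_feeding and prev_context is not None:
        x = ad.concat([y_prev, prev_context], axis=1)
    B = prev_ids.shape[0]
    ones = Tensor(np.ones((B, 1)))
    h, c = _lstm_step(params["dec_W"], params["dec_b"], x, state[0], state[1], ones)
    s = h

    alpha = z_star = None
    if config.use_header_encoder:
        alpha, z_star = header_attention(s, enc.Z, enc.Z_proj, enc.hdr_mask, params)

    cov_in = coverage if config.use_coverage else None
    beta, h_star = source_attention(s, z_star, enc.H, enc.H_proj, enc.src_mask, params, cov_in)

    if config.use_copy:
        p_gen = copy_gate(h_star, s, y_prev, params)
        p_voc = vocab_distribution(s, h_star, params, z_star)
        p_final = final_distribution(p_gen, p_voc, beta, src_ext_ids, n_oov)
    else:
        p_gen = None
        p_voc = vocab_distribution(s, h_star, params, z_star)
        p_final = p_voc

    dist = StepDistribution(
        header_attention=alpha,
        header_context=z_star,
        source_attention=beta,
        source_context=h_star,
        p_gen=p_gen,
        p_vocab=p_voc,
        p_final=p_final,
        coverage=coverage,
    )
    return dist, (h, c), h_star


# ---------------------------------------------------------------------
# model wrapper
# ---------------------------------------------------------------------

class AssessmentModel:
    """Configuration + parameters with encode/decode entry points."""

    def __init__(self, config: ModelConfig, params: dict[str, Tensor] | None = None):
        self.config = config
        self.params = params if params is not None else init_parameters(config)

    # -- encoding ------------------------------------------------------
    def encode(self, batch: Batch) -> EncoderStates:
        cfg, p = self.config, self.params
        H, final_h, final_c = encode_source(p, batch.src_ids, batch.src_mask, cfg)
        Z = Z_proj = None
        hdr_mask = None
        if cfg.use_header_encoder:
            Z = encode_header(p, batch.hdr_ids, batch.hdr_mask, cfg)
            Z_proj = ad.matmul(Z, p["att_hdr_Wz"])
            hdr_mask = batch.hdr_mask
        return EncoderStates(
            H=H,
            Z=Z,
            final_h=final_h,
            final_c=final_c,
            src_mask=batch.src_mask,
            hdr_mask=hdr_mask,
            H_proj=ad.matmul(H, p["att_src_Wh"]),
            Z_proj=Z_proj,
        )

    def initial_state(self, enc: EncoderStates) -> tuple[Tensor, Tensor]:
        return init_decoder_state(enc.final_h, enc.final_c, self.params)

    def initial_coverage(self, batch_size: int, n: int) -> Tensor:
        return Tensor(np.zeros((batch_size, n)))

    # -- teacher-forced forward ---------------------------------------
    def forward(self, batch: Batch) -> list[StepDistribution]:
        """Run the decoder over the gold prefix (teacher forcing)."""
        cfg = self.config
        enc = self.encode(batch)
        state = self.initial_state(enc)
        B, n = batch.src_mask.shape
        coverage = self.initial_coverage(B, n) if cfg.use_coverage else None
        n_oov = batch.max_oov if cfg.use_copy else 0
        context = None
        steps: list[StepDistribution] = []
        for t in range(batch.dec_in_ids.shape[1]):
            dist, state, context = decoder_step(
                self.params,
                cfg,
                batch.dec_in_ids[:, t],
                state,
                enc,
                batch.src_ext_ids,
                n_oov,
                coverage=coverage,
                prev_context=context,
            )
            steps.append(dist)
            if cfg.use_coverage:
                coverage = coverage + dist.source_attention
        return steps

    # -- bookkeeping ---------------------------------------------------
    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def copy(self) -> "AssessmentModel":
        params = {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.params.items()}
        return AssessmentModel(self.config, params)


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def vocabulary_hash(vocab: Vocabulary) -> str:
    h = hashlib.sha256("\n".join(vocab.id_to_token).encode()).hexdigest()
    return h[:16]


def save_checkpoint(path, model: AssessmentModel, vocab: Vocabulary, extra: dict | None = None):
    """Serialize config + parameters + vocabulary hash to an .npz file."""
    meta = {
        "config": asdict(model.config),
        "vocab_hash": vocabulary_hash(vocab),
        "extra": extra or {},
    }
    arrays = {k: v.data for k, v in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, vocab: Vocabulary | None = None) -> tuple[AssessmentModel, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        params = {
            k: Tensor(npz[k].copy(), requires_grad=True) for k in npz.files if k != "__meta__"
        }
    config = ModelConfig(**meta["config"])
    if vocab is not None and vocabulary_hash(vocab) != meta["vocab_hash"]:
        raise ValueError("checkpoint was trained with a different vocabulary")
    return AssessmentModel(config, params), meta
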