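"""Beam-search generation of assessments with OOV restoration.

Decoding expands hypotheses over the extended vocabulary, so the model
can emit per-example OOV tokens (copied names, dates) directly.  The end
symbol is suppressed until a minimum length is reached; finished
hypotheses are ranked by length-normalized log-probability, which avoids
the degenerate preference for the shortest legal output.  Coverage, when
the model uses it, is updated during decoding exactly as in training; it
does not add any decode-time score penalty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .model import AssessmentModel, EncoderStates, decoder_step, make_batch
from .notes_io import EncodedExample, Vocabulary, render_ids

__all__ = ["Hypothesis", "DecodeResult", "beam_search", "greedy_decode", "export_attention_trace"]


@dataclass
class Hypothesis:
    """A partial decode: extended-id prefix plus carried decoder state."""

    token_ids: list[int]                 # starts at BEGIN
    log_prob: float
    state_h: np.ndarray
    state_c: np.ndarray
    coverage: np.ndarray | None
    finished: bool = False
    attentions: list[tuple[np.ndarray | None, np.ndarray]] = field(default_factory=list)

    @property
    def n_generated(self) -> int:
        return len(self.token_ids) - 1

    def score(self) -> float:
        """Length-normalized cumulative log-probability."""
        return self.log_prob / max(self.n_generated, 1)


@dataclass
class DecodeResult:
    tokens: list[str]                    # generated tokens, BEGIN/END stripped
    text: str
    hypothesis: Hypothesis
    example: EncodedExample


def _tile(t: Tensor, k: int) -> Tensor:
    return Tensor(np.repeat(t.data, k, axis=0))


def _tile_enc(enc: EncoderStates, k: int) -> EncoderStates:
    return EncoderStates(
        H=_tile(enc.H, k),
        Z=_tile(enc.Z, k) if enc.Z is not None else None,
        final_h=_tile(enc.final_h, k),
        final_c=_tile(enc.final_c, k),
        src_mask=np.repeat(enc.src_mask, k, axis=0),
        hdr_mask=np.repeat(enc.hdr_mask, k, axis=0) if enc.hdr_mask is not None else None,
        H_proj=_tile(enc.H_proj, k),
        Z_proj=_tile(enc.Z_proj, k) if enc.Z_proj is not None else None,
    )


def beam_search(
    model: AssessmentModel,
    example: EncodedExample,
    vocab: Vocabulary,
    beam_size: int = 10,
    min_len: int = 15,
    max_len: int = 60,
) -> DecodeResult:
    """Generate one assessment with beam search.

    At every step each live hypothesis is expanded over the extended
    vocabulary and the best ``beam_size`` prefixes by cumulative
    log-probability survive.  The end symbol is masked while fewer than
    ``min_len`` tokens have been generated.  The returned hypothesis is
    the finished one with the best length-normalized score; if nothing
    finishes within ``max_len`` steps the best unfinished hypothesis is
    returned with a warning.
    """
    cfg = model.config
    batch = make_batch([example], vocab)
    enc1 = model.encode(batch)
    s_h, s_c = model.initial_state(enc1)
    n = batch.src_mask.shape[1]
    n_oov = example.n_oov if cfg.use_copy else 0
    V_ext = vocab.size + n_oov

    init_cov = np.zeros(n) if cfg.use_coverage else None
    beam = [
        Hypothesis(
            token_ids=[vocab.begin_id],
            log_prob=0.0,
            state_h=s_h.data[0].copy(),
            state_c=s_c.data[0].copy(),
            coverage=init_cov,
        )
    ]
    finished: list[Hypothesis] = []
    blocked = [vocab.pad_id, vocab.begin_id]

    for step in range(max_len):
        k = len(beam)
        enc = _tile_enc(enc1, k)
        prev = np.array([h.token_ids[-1] for h in beam])
        prev = np.where(prev >= vocab.size, vocab.unk_id, prev)
        state = (
            Tensor(np.stack([h.state_h for h in beam])),
            Tensor(np.stack([h.state_c for h in beam])),
        )
        coverage = (
            Tensor(np.stack([h.coverage for h in beam])) if cfg.use_coverage else None
        )
        dist, (new_h, new_c), _ = decoder_step(
            model.params,
            cfg,
            prev,
            state,
            enc,
            np.repeat(batch.src_ext_ids, k, axis=0),
            n_oov,
            coverage=coverage,
        )
        logp = np.log(np.maximum(dist.p_final.data, 1e-300))
        logp[:, blocked] = -np.inf
        if step < min_len:
            logp[:, vocab.end_id] = -np.inf

        alpha = dist.header_attention.data if dist.header_attention is not None else None
        beta = dist.source_attention.data

        candidates: list[tuple[float, int, int]] = []  # (score, beam idx, token)
        per_hyp = min(2 * beam_size, V_ext)
        for b, hyp in enumerate(beam):
            top = np.argpartition(-logp[b], per_hyp - 1)[:per_hyp]
            for tok in top:
                if np.isfinite(logp[b, tok]):
                    candidates.append((hyp.log_prob + logp[b, tok], b, int(tok)))
        candidates.sort(key=lambda x: -x[0])

        new_beam: list[Hypothesis] = []
        for score, b, tok in candidates:
            if tok != vocab.end_id and len(new_beam) >= beam_size:
                continue
            parent = beam[b]
            cov = None
            if cfg.use_coverage:
                cov = parent.coverage + beta[b]
            child = Hypothesis(
                token_ids=parent.token_ids + [tok],
                log_prob=score,
                state_h=new_h.data[b].copy(),
                state_c=new_c.data[b].copy(),
                coverage=cov,
                attentions=parent.attentions
                + [(alpha[b].copy() if alpha is not None else None, beta[b].copy())],
            )
            if tok == vocab.end_id:
                child.finished = True
                finished.append(child)
            elif len(new_beam) < beam_size:
                new_beam.append(child)
        beam = new_beam
        if not beam or len(finished) >= beam_size:
            break

    if finished:
        best = max(finished, key=lambda h: h.score())
    else:
        warnings.warn("no hypothesis finished within max_len; returning best unfinished")
        for h in beam:
            h.finished = True  # at max length
        best = max(beam, key=lambda h: h.score())

    out_ids = [t for t in best.token_ids[1:] if t != vocab.end_id]
    tokens = render_ids(out_ids, vocab, example.oov_tokens)
    return DecodeResult(tokens=tokens, text=" ".join(tokens), hypothesis=best, example=example)


def greedy_decode(model, example, vocab, min_len: int = 15, max_len: int = 60) -> DecodeResult:
    """Stepwise argmax decoding (identical to beam search with beam 1)."""
    return beam_search(model, example, vocab, beam_size=1, min_len=min_len, max_len=max_len)


def export_attention_trace(result: DecodeResult, vocab: Vocabulary) -> list[dict]:
    """One record per generated token with both attention distributions,
    aligned to the header and source token strings."""
    ex = result.example
    hyp = result.hypothesis
    out_ids = hyp.token_ids[1:]
    records = []
    for step, (tok_id, (alpha, beta)) in enumerate(zip(out_ids, hyp.attentions)):
        tok = render_ids([tok_id], vocab, ex.oov_tokens)[0]
        rec = {
            "step": step,
            "token": tok,
            "source_tokens": ex.source_tokens,
            "source_attention": [float(x) for x in beta[: len(ex.source_tokens)]],
        }
        if alpha is not None:
            rec["header_tokens"] = ex.header_tokens
            rec["header_attention"] = [float(x) for x in alpha[: len(ex.header_tokens)]]
        records.append(rec)
    return records


def save_attention_trace(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
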