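import numpy as np
import pytest

from soapsum import (
    ModelConfig,
    Note,
    SynthConfig,
    build_vocabulary,
    encode_example,
    generate_corpus,
)
from soapsum.model import AssessmentModel, make_batch


@pytest.fixture(scope="session")
def tiny_notes():
    """A handful of hand-written notes with digit-bearing OOV tokens."""
    return [
        Note(
            header_text="reason for visit: follow up of finger fracture .",
            subjective_text="the patient smith82 feels well . swelling of the finger persists .",
            objective_text="the scar is well healed . alignment acceptable .",
            assessment_text="healing fracture of the finger for patient smith82 .",
            plan_text="continue therapy .",
        ),
        Note(
            header_text="reason for visit: wrist sprain evaluation .",
            subjective_text="patient lopez91 reports pain on 03/04/2016 . motion limited .",
            objective_text="tenderness over the wrist . films reviewed .",
            assessment_text="improving sprain of the wrist for patient lopez91 .",
        ),
        Note(
            header_text="reason for visit: knee pain .",
            subjective_text="the knee is swollen . patient walks with support .",
            objective_text="effusion noted . radiographs unremarkable .",
            assessment_text="knee effusion , likely overuse .",
        ),
    ]


@pytest.fixture(scope="session")
def tiny_vocab(tiny_notes):
    return build_vocabulary(tiny_notes, max_size=500)


@pytest.fixture(scope="session")
def tiny_examples(tiny_notes, tiny_vocab):
    return [encode_example(n, tiny_vocab, 40, 20, 15) for n in tiny_notes]


@pytest.fixture(scope="session")
def tiny_model_setup(tiny_vocab, tiny_examples):
    """A small dual-encoder model with copy and coverage, plus a batch."""
    config = ModelConfig(
        vocab_size=tiny_vocab.size,
        embed_dim=6,
        hidden_dim=5,
        attn_dim=7,
        use_copy=True,
        use_header_encoder=True,
        use_coverage=True,
        max_source_len=40,
        max_header_len=20,
        max_decode_len=15,
        init_seed=42,
    )
    model = AssessmentModel(config)
    batch = make_batch(tiny_examples, tiny_vocab)
    return model, batch


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus with vocabulary, shared across tests."""
    config = SynthConfig(
        n_conditions=4,
        entity_pool_size=60,
        split_sizes=(60, 12, 12),
        source_len_range=(25, 40),
        templates_per_condition=1,
        noise_rate=0.02,
        seed=7,
    )
    splits, manifest = generate_corpus(config)
    vocab = build_vocabulary(splits["train"], max_size=2000)
    return config, splits, manifest, vocab
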