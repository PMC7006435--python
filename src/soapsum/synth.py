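"""Seeded generator of synthetic SOAP-like notes.

Real clinical corpora are private; this generator emits notes whose
statistical structure exercises each model mechanism at desk scale:

* **Header-dependent content selection.**  Each note has one true
  condition — a (problem, body site) pair — whose findings are
  interleaved with the findings of distractor conditions that share
  either the problem or the site.  The narrative alone is therefore
  ambiguous about which combination the assessment should describe; only
  the header's chief complaint names the true condition.  This is the
  signal the attention-over-attention mechanism can use and a
  source-only model cannot.

* **Copy necessity.**  Every note carries a surrogate patient entity
  (a surname with digits appended, e.g. ``rivera93``).  Digit-bearing
  tokens are excluded from the vocabulary by construction, so emitting
  the entity in the assessment requires copying it from the source.

* **Repetitive sources.**  Filler sentences repeat across the
  narrative, giving the coverage mechanism something to discourage.

Assessments are deterministic functions of (condition, entity), so the
generation task is learnable; token noise is applied to the narrative
only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .notes_io import Note

__all__ = ["SynthConfig", "Condition", "conditions_for", "generate_note", "generate_corpus"]

_PROBLEMS = [
    "metacarpal fracture",
    "ligament sprain",
    "soft tissue infection",
    "tendon inflammation",
    "joint degeneration",
]

_SITES = [
    "right small finger",
    "left wrist",
    "right ankle",
    "left knee",
    "right shoulder",
    "left hip",
    "right elbow",
    "lumbar spine",
]

_SURNAMES = [
    "rivera", "okafor", "lindqvist", "tanaka", "moreau", "castillo",
    "novak", "haddad", "schmidt", "oconnell", "petrov", "yamamoto",
    "fernandez", "kowalski", "demir", "johansson", "nakamura", "silva",
    "dubois", "hansen",
]

_FINDING_TEMPLATES = [
    "tenderness noted over the {site} .",
    "swelling of the {site} persists on examination .",
    "imaging of the {site} was reviewed today .",
    "symptoms consistent with {problem} were discussed .",
    "limited range of motion at the {site} .",
    "the {site} appears well aligned on films .",
    "prior treatment of the {problem} was reviewed .",
]

_FILLER_SENTENCES = [
    "vital signs were reviewed and recorded today .",
    "the patient tolerated the examination well .",
    "medication list was reviewed with the patient .",
    "no new complaints were reported at this visit .",
    "follow up instructions were provided in detail .",
]

_ASSESSMENT_TEMPLATES = [
    "healing {problem} of the {site} for patient {entity} .",
    "patient {entity} shows improving {problem} of the {site} .",
]


@dataclass(frozen=True)
class Condition:
    """A diagnosable condition: a clinical problem at a body site."""

    index: int
    problem: str
    site: str

    @property
    def chief_complaint(self) -> str:
        return f"evaluation of {self.problem} of the {self.site}"


def _grid_dims(n_conditions: int) -> tuple[int, int]:
    """Factor K into a problems × sites rectangle with both sides ≥ 2.

    A complete rectangle lets every condition (p, s) be confused with
    (p', s), (p, s') and (p', s') — the symmetric square that makes the
    narrative genuinely ambiguous.  The divisor pair closest to square
    is used; a K with no such factorization (a prime) is rejected.
    """
    best = None
    for n_p in range(2, int(np.sqrt(n_conditions)) + 1):
        if n_conditions % n_p == 0 and n_conditions // n_p >= 2:
            best = (n_p, n_conditions // n_p)
    if best is None:
        raise ValueError(
            f"n_conditions={n_conditions} has no problems × sites factorization "
            "with both sides >= 2; choose a composite K (e.g. 4, 8, 12, 20)"
        )
    if best[0] > len(_PROBLEMS) or best[1] > len(_SITES):
        raise ValueError(f"n_conditions={n_conditions} exceeds the {len(_PROBLEMS)}×{len(_SITES)} phrase grid")
    return best


def conditions_for(n_conditions: int) -> list[Condition]:
    """A complete problems × sites rectangle of K conditions."""
    if n_conditions < 4:
        raise ValueError("need at least 4 conditions (a 2×2 grid)")
    n_p, n_s = _grid_dims(n_conditions)
    grid = list(product(_PROBLEMS[:n_p], _SITES[:n_s]))
    return [Condition(i, p, s) for i, (p, s) in enumerate(grid)]


@dataclass
class SynthConfig:
    """Generator settings.

    Defaults are desk-scale: sources of 40–90 tokens instead of the
    500-token clinical narratives, 20 conditions, and a 2000/200/200
    split.  ``n_distractors`` ≥ 1 makes the source ambiguous;
    ``noise_rate`` is the per-token probability of dropout/swap noise in
    the narrative.
    """

    n_conditions: int = 20
    findings_per_condition: int = 3
    n_distractors: int = 3
    entity_pool_size: int = 50
    source_len_range: tuple[int, int] = (40, 90)
    templates_per_condition: int = 2
    noise_rate: float = 0.02
    split_sizes: tuple[int, int, int] = (2000, 200, 200)
    seed: int = 0

    def __post_init__(self):
        _grid_dims(self.n_conditions)  # validates K early
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if not 1 <= self.templates_per_condition <= len(_ASSESSMENT_TEMPLATES):
            raise ValueError(f"templates_per_condition must be in [1, {len(_ASSESSMENT_TEMPLATES)}]")

    def entity_pool(self) -> list[str]:
        """Digit-bearing surrogate identifiers, guaranteed OOV."""
        pool = []
        i = 0
        while len(pool) < self.entity_pool_size:
            pool.append(f"{_SURNAMES[i % len(_SURNAMES)]}{10 + i}")
            i += 1
        return pool

    def capacity(self) -> int:
        """Distinct (condition, entity, template) combinations."""
        return self.n_conditions * self.entity_pool_size * self.templates_per_condition


def _apply_noise(tokens: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate <= 0:
        return tokens
    out: list[str] = []
    i = 0
    while i < len(tokens):
        r = rng.random()
        if r < rate / 2:
            i += 1  # dropout
            continue
        if r < rate and i + 1 < len(tokens):
            out.extend([tokens[i + 1], tokens[i]])  # adjacent swap
            i += 2
            continue
        out.append(tokens[i])
        i += 1
    return out if out else tokens[:1]


def _sample_distractors(
    cond: Condition,
    conditions: list[Condition],
    n_distractors: int,
    rng: np.random.Generator,
) -> list[Condition]:
    """Distractor conditions that leave the narrative ambiguous.

    With an alternative problem p' and site s', three distractors form
    the full confusion square {(p', s), (p, s'), (p', s')}: every
    problem/site phrase then occurs equally often in the source, so no
    frequency heuristic reveals the true condition.  With two
    distractors one half of the square is drawn at random, leaving two
    equally likely hypotheses; one distractor shares nothing.  Beyond
    three, extra conditions are drawn at random.
    """
    if n_distractors <= 0:
        return []
    by_pair = {(c.problem, c.site): c for c in conditions}
    problems = sorted({c.problem for c in conditions})
    sites = sorted({c.site for c in conditions})
    p_alt = [p for p in problems if p != cond.problem]
    s_alt = [s for s in sites if s != cond.site]
    p2 = p_alt[int(rng.integers(len(p_alt)))]
    s2 = s_alt[int(rng.integers(len(s_alt)))]
    square = [by_pair[(p2, cond.site)], by_pair[(cond.problem, s2)], by_pair[(p2, s2)]]
    if n_distractors == 1:
        return [by_pair[(p2, s2)]]
    if n_distractors == 2:
        keep = int(rng.integers(2))  # drop one shared-component distractor
        return [square[keep], square[2]]
    out = list(square)
    rest = [c for c in conditions if c.index != cond.index and c not in out]
    extra = min(n_distractors - 3, len(rest))
    if extra > 0:
        out += [rest[i] for i in rng.choice(len(rest), size=extra, replace=False)]
    return out


def _assessment_for(cond: Condition, entity: str, entity_idx: int, config: SynthConfig) -> str:
    tpl_idx = (cond.index + entity_idx) % config.templates_per_condition
    return _ASSESSMENT_TEMPLATES[tpl_idx].format(problem=cond.problem, site=cond.site, entity=entity)


def generate_note(config: SynthConfig, rng: np.random.Generator) -> Note:
    """Draw one synthetic note.

    The true condition and entity are drawn uniformly; distractor
    conditions are sampled among those sharing the problem or the site
    with the true condition, so only the header disambiguates the
    assessment.
    """
    conditions = conditions_for(config.n_conditions)
    pool = config.entity_pool()
    cond = conditions[int(rng.integers(len(conditions)))]
    entity_idx = int(rng.integers(len(pool)))
    entity = pool[entity_idx]

    distractors = _sample_distractors(cond, conditions, config.n_distractors, rng)

    header = f"reason for visit: {cond.chief_complaint} . patient {entity} ."

    # every condition (true or distractor) contributes exactly one
    # problem-mentioning finding and the same number of site-mentioning
    # findings, so mention frequencies never reveal which one is true;
    # template choice varies per condition for phrasing diversity
    n_find = max(2, min(config.findings_per_condition, len(_FINDING_TEMPLATES)))
    problem_tpl = [i for i, t in enumerate(_FINDING_TEMPLATES) if "{problem}" in t]
    site_tpl = [i for i, t in enumerate(_FINDING_TEMPLATES) if "{site}" in t]
    sentences = [f"the patient {entity} returns for follow up ."]
    for c in [cond] + distractors:
        picks = [int(rng.choice(problem_tpl))]
        n_site = min(n_find - 1, len(site_tpl))
        picks += [site_tpl[i] for i in rng.choice(len(site_tpl), size=n_site, replace=False)]
        for i in picks:
            sentences.append(_FINDING_TEMPLATES[i].format(problem=c.problem, site=c.site))
    order = rng.permutation(len(sentences) - 1) + 1
    sentences = [sentences[0]] + [sentences[i] for i in order]

    lo, hi = config.source_len_range
    target_len = int(rng.integers(lo, hi + 1))
    body = " ".join(sentences)
    while len(body.split()) < target_len:
        body += " " + _FILLER_SENTENCES[int(rng.integers(len(_FILLER_SENTENCES)))]

    tokens = body.split()
    tokens = _apply_noise(tokens, config.noise_rate, rng)
    # keep the entity recoverable: noise must not delete every copy of it
    if entity not in tokens:
        tokens = [tokens[0], "patient", entity] + tokens[1:]
    mid = len(tokens) // 2

    return Note(
        header_text=header,
        subjective_text=" ".join(tokens[:mid]),
        objective_text=" ".join(tokens[mid:]),
        assessment_text=_assessment_for(cond, entity, entity_idx, config),
        plan_text="continue current management and follow up as scheduled .",
    )


def generate_corpus(config: SynthConfig):
    """Generate disjoint train/dev/test splits plus a manifest.

    Returns ``(splits, manifest)`` where ``splits`` maps split name to a
    list of notes and the manifest records per-split seeds, note-id
    ranges and condition/entity frequencies.
    """
    total = sum(config.split_sizes)
    if total > config.capacity():
        raise ValueError(
            f"requested {total} notes exceeds template capacity {config.capacity()}"
        )
    names = ("train", "dev", "test")
    splits: dict[str, list[Note]] = {}
    manifest: dict = {"seed": config.seed, "splits": {}, "condition_counts": {}, "entity_counts": {}}
    next_id = 0
    cond_counts: dict[str, int] = {}
    ent_counts: dict[str, int] = {}
    conditions = conditions_for(config.n_conditions)
    for name, size, offset in zip(names, config.split_sizes, (0, 1, 2)):
        split_seed = config.seed * 3 + offset
        rng = np.random.default_rng(split_seed)
        notes = [generate_note(config, rng) for _ in range(size)]
        splits[name] = notes
        manifest["splits"][name] = {
            "size": size,
            "seed": split_seed,
            "note_ids": [next_id + i for i in range(size)],
        }
        next_id += size
        for note in notes:
            for cond in conditions:
                if cond.problem in note.assessment_text and cond.site in note.assessment_text:
                    cond_counts[f"{cond.problem}/{cond.site}"] = cond_counts.get(f"{cond.problem}/{cond.site}", 0) + 1
                    break
            ent = note.header_text.split()[-2]
            ent_counts[ent] = ent_counts.get(ent, 0) + 1
    manifest["condition_counts"] = cond_counts
    manifest["entity_counts"] = ent_counts
    return splits, manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
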