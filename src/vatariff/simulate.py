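"""Gold-standard-structured synthetic VA data with controllable separability.

The generator emulates the structure the tariff method assumes: each
cause has signature items its deaths endorse with high probability
``p_sig`` while all other items are background noise at ``p_bg``.  Three
item groups are produced: per-cause signature symptom items (non-HCE
questions), shared background symptom items, and per-cause HCE-dependent
items (chronic-illness / health-service questions) so the with- and
without-HCE conditions differ.  With probability ``p_drop`` a record is
an informant-knowledge dropout: its whole response vector is zeroed and
the narrative blanked, emulating real interviews with too little
information to support any cause (these should become indeterminate, not
be attracted to a cause).  Narratives emit per-cause vocabulary words at
a configurable rate so the text-mining pipeline has signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .data import CauseList, Dataset, Item, ItemDictionary, VARecord

#: plain clinical words assigned to causes round-robin for narratives
DEFAULT_VOCABULARY = (
    "fever", "cough", "vomiting", "injuries", "burning", "drowning",
    "rash", "bleeding", "swelling", "jaundice", "headache", "seizure",
    "diarrhea", "pain", "chest", "breathless", "pregnant", "accident",
    "snakebite", "poison", "cancer", "stroke", "sugar", "liver",
    "kidney", "heart", "lung", "malaria", "measles", "tetanus",
)


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    ``p_sig``/``p_bg`` are the endorsement probabilities of a cause's own
    signature items and of everything else; ``p_drop`` is the probability
    a record is an all-negative informant dropout.
    """

    module: str = "adult"
    n_causes: int = 5
    signature_items: int = 8  # per cause
    background_items: int = 10  # shared
    hce_items: int = 2  # per cause, HCE-dependent signature questions
    p_sig: float = 0.9
    p_bg: float = 0.05
    p_drop: float = 0.05
    n_per_cause: int = 200
    tokens_per_cause: int = 2
    p_token: float = 0.5  # own-cause narrative word rate
    p_token_bg: float = 0.02  # other-cause narrative word rate
    sites: tuple[str, ...] = ("site_a", "site_b")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_sig", "p_bg", "p_drop", "p_token", "p_token_bg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_causes < 2:
            raise ValueError("need at least 2 causes")
        if self.n_per_cause < 1:
            raise ValueError("need at least 1 record per cause")

    @property
    def cause_ids(self) -> tuple[str, ...]:
        return tuple(f"cause_{i + 1:02d}" for i in range(self.n_causes))


def _build_dictionary(spec: GeneratorSpec) -> tuple[ItemDictionary, dict[str, list[str]]]:
    items: list[Item] = []
    signature_of: dict[str, list[str]] = {}
    for c in spec.cause_ids:
        sig_ids = [f"sig_{c}_{k + 1:02d}" for k in range(spec.signature_items)]
        hce_ids = [f"hce_{c}_{k + 1:02d}" for k in range(spec.hce_items)]
        signature_of[c] = sig_ids + hce_ids
        items += [
            Item(i, f"symptom of {c}", "question", False, spec.module)
            for i in sig_ids
        ]
        items += [
            Item(i, f"health-service history of {c}", "question", True, spec.module)
            for i in hce_ids
        ]
    items += [
        Item(f"bg_{k + 1:02d}", "background symptom", "question", False, spec.module)
        for k in range(spec.background_items)
    ]
    return ItemDictionary(items), signature_of


def _vocab_of(spec: GeneratorSpec) -> dict[str, list[str]]:
    vocab = {}
    words = list(DEFAULT_VOCABULARY)
    need = spec.n_causes * spec.tokens_per_cause
    while len(words) < need:
        words += [w + "x" for w in words]  # degenerate fallback for huge N
    for i, c in enumerate(spec.cause_ids):
        vocab[c] = words[i * spec.tokens_per_cause:(i + 1) * spec.tokens_per_cause]
    return vocab


def _draw_age(rng: np.random.Generator, module: str) -> float:
    if module == "adult":
        return float(rng.uniform(20, 85))
    if module == "child":
        return float(rng.uniform(1, 12))
    return float(rng.uniform(0, 28) / 365.0)


def generate(spec: GeneratorSpec) -> Dataset:
    """Generate a balanced gold-standard dataset per the spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    dictionary, signature_of = _build_dictionary(spec)
    causes = CauseList(
        module=spec.module,
        cause_ids=spec.cause_ids,
        labels={c: c.replace("_", " ") for c in spec.cause_ids},
    )
    vocab = _vocab_of(spec)
    all_items = dictionary.item_ids(spec.module)
    records: list[VARecord] = []
    counter = 0
    for c in spec.cause_ids:
        sig = set(signature_of[c])
        for _ in range(spec.n_per_cause):
            counter += 1
            rid = f"d{counter:05d}"
            sex = "male" if rng.random() < 0.5 else "female"
            age = _draw_age(rng, spec.module)
            site = spec.sites[int(rng.integers(len(spec.sites)))]
            if rng.random() < spec.p_drop:
                responses: dict[str, int] = {}
                narrative = None
            else:
                responses = {
                    it: 1
                    for it in all_items
                    if rng.random() < (spec.p_sig if it in sig else spec.p_bg)
                }
                words = []
                for cc in spec.cause_ids:
                    rate = spec.p_token if cc == c else spec.p_token_bg
                    words += [w for w in vocab[cc] if rng.random() < rate]
                narrative = " ".join(words) or None
            records.append(
                VARecord(
                    id=rid, module=spec.module, sex=sex, age=age, site=site,
                    responses=responses, narrative=narrative, gold_standard=c,
                )
            )
    return Dataset(records, dictionary, causes)


def truth_report(dataset: Dataset) -> tuple[pd.Series, pd.Series]:
    """Exact ground-truth CSMF and per-record labels of a generated dataset."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    labels = pd.Series(dataset.gold_standards(), index=dataset.ids, name="gs_cause")
    if labels.isna().any():
        raise ValueError("dataset has records without gold-standard causes")
    csmf = labels.value_counts(normalize=True).reindex(
        list(dataset.causes), fill_value=0.0
    )
    csmf.name = "csmf"
    return csmf, labels
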