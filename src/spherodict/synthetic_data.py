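"""Synthetic triage-visit generator with planted topic structure.

Real ED admission notes are short (two to three sentences), mention one to a
few presenting problems, and come with a single-choice structured chief
complaint that reflects the note imperfectly.  This module emulates exactly
that, with full ground truth, so the tagging and modelling layers can be
validated end to end:

* each visit draws one or more latent symptom topics (the multi-topic rate
  targets the regime where roughly a third of visits carry at least two);
* its note mixes words from the true topics' vocabularies with background
  words; the first tokens always mention every true topic, as a triage note
  names each presenting problem;
* the chief-complaint code names a true topic with probability
  ``chief_complaint_fidelity``, is an unrelated code otherwise, and with
  probability ``unspecified_rate`` is an uninformative "diverse" code;
* outcomes follow a linear probability model over true topic indicators,
  the true chief-complaint cluster and covariates, then Bernoulli draws.

Vocabularies are abstract word stems (``traumaw3``), not clinical German, so
tests carry no language dependency; :func:`make_fixture_suite` additionally
writes a small German-flavoured demo with a chest-pain style combination
rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dictionary_builder import TopicDictionary, save_dictionaries
from .embedding import EmbeddingModel
from .tagger import ClusterMap

UNSPECIFIED_CODE = "diverse"

TEAMS = ("internal", "surgery", "neurology", "psychiatry")
TEAM_PROBS = (0.55, 0.30, 0.10, 0.05)
SHIFTS = ("early", "late", "night")
SHIFT_PROBS = (0.41, 0.44, 0.15)


@dataclass(frozen=True)
class TopicSpec:
    """One latent topic: its name, private vocabulary and relative prevalence."""

    name: str
    vocabulary: tuple[str, ...]
    prevalence: float


@dataclass(frozen=True)
class OutcomeSpec:
    """LPM coefficients generating one binary outcome.

    ``p_i = clip(alpha + beta.X_i + gamma.Z*_i + delta.W*_i, 0, 1)`` with
    true topic indicators Z* and the true chief-complaint cluster indicator
    W*; ``Y_i ~ Bernoulli(p_i)``.
    """

    name: str
    alpha: float
    beta: dict[str, float] = field(default_factory=dict)
    gamma: dict[str, float] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class GeneratorConfig:
    n_visits: int = 2000
    topics: tuple[TopicSpec, ...] = ()
    background_vocabulary: tuple[str, ...] = ()
    note_tokens_min: int = 8
    note_tokens_max: int = 24
    multi_topic_rate: float = 0.33
    topic_token_share: float = 0.5
    chief_complaint_fidelity: float = 0.8
    unspecified_rate: float = 0.115
    outcomes: tuple[OutcomeSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.multi_topic_rate <= 1:
            raise ValueError("multi_topic_rate must lie in [0, 1]")
        for t in self.topics:
            if not 0 <= t.prevalence:
                raise ValueError(f"prevalence of {t.name} must be >= 0")
        vocabs = [set(t.vocabulary) for t in self.topics]
        bg = set(self.background_vocabulary)
        for t, v in zip(self.topics, vocabs):
            if v & bg:
                raise ValueError(
                    f"topic {t.name} vocabulary overlaps the background vocabulary"
                )

    def topic_names(self) -> list[str]:
        return [t.name for t in self.topics]

    def ls_code(self, topic: str) -> str:
        return f"ls_{topic}"

    def cluster_map(self) -> ClusterMap:
        """Identity map: each topic is its own cluster; LS codes join it."""
        mapping = {}
        for t in self.topics:
            mapping[t.name] = t.name
            mapping[self.ls_code(t.name)] = t.name
        return ClusterMap(mapping=mapping, excluded={UNSPECIFIED_CODE})


def _suffix(k: int) -> str:
    """Letter-only suffix (a, b, ..., z, aa, ab, ...): survives tokenization,
    which strips digits."""
    s = ""
    k += 1
    while k:
        k, r = divmod(k - 1, 26)
        s = chr(97 + r) + s
    return s


def _default_topic(name: str, n_words: int, prevalence: float) -> TopicSpec:
    return TopicSpec(
        name=name,
        vocabulary=tuple(f"{name}{_suffix(k)}" for k in range(n_words)),
        prevalence=prevalence,
    )


def default_config(n_visits: int = 2000, seed: int = 0) -> GeneratorConfig:
    """Study-shaped defaults: 8 topics with trauma dominant, modest topic
    effects on hospitalization and acuity, and a fifth of notes left without
    informative structure via background words."""
    topics = (
        _default_topic("trauma", 10, 0.32),
        _default_topic("cardio", 10, 0.10),
        _default_topic("gastro", 10, 0.08),
        _default_topic("respir", 10, 0.08),
        _default_topic("neuro", 10, 0.09),
        _default_topic("infect", 10, 0.07),
        _default_topic("psych", 10, 0.05),
        _default_topic("uro", 10, 0.06),
    )
    background = tuple(f"bg{_suffix(k)}" for k in range(40))
    outcomes = (
        OutcomeSpec(
            name="inpatient",
            alpha=0.10,
            beta={"age": 0.002, "ems": 0.15},
            gamma={
                "trauma": -0.04,
                "cardio": -0.02,
                "gastro": 0.07,
                "respir": 0.06,
                "neuro": -0.03,
                "infect": 0.12,
                "psych": -0.05,
                "uro": -0.015,
            },
            delta={
                "trauma": 0.01,
                "cardio": -0.03,
                "gastro": 0.08,
                "respir": 0.10,
                "neuro": -0.04,
                "infect": 0.11,
                "psych": -0.05,
                "uro": -0.03,
            },
        ),
        OutcomeSpec(
            name="low_esi",
            alpha=0.40,
            beta={"age": 0.002, "ems": 0.20},
            gamma={
                "trauma": -0.13,
                "cardio": 0.05,
                "gastro": 0.09,
                "respir": 0.10,
                "neuro": -0.015,
                "infect": 0.08,
                "psych": 0.06,
                "uro": 0.055,
            },
            delta={
                "trauma": -0.01,
                "cardio": 0.10,
                "gastro": 0.12,
                "respir": 0.09,
                "neuro": -0.04,
                "infect": 0.05,
                "psych": 0.05,
                "uro": 0.08,
            },
        ),
    )
    return GeneratorConfig(
        n_visits=n_visits,
        topics=topics,
        background_vocabulary=background,
        outcomes=outcomes,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation


def _draw_topic_sets(config: GeneratorConfig, rng: np.random.Generator) -> list[list[int]]:
    """Per-visit distinct topic indices via weighted Gumbel top-k."""
    n, T = config.n_visits, len(config.topics)
    weights = np.array([t.prevalence for t in config.topics], dtype=float)
    weights = weights / weights.sum()
    multi = rng.random(n) < config.multi_topic_rate
    # among multi-topic visits: mostly 2, occasionally 3 presenting problems
    k = np.ones(n, dtype=int)
    k[multi] = np.where(rng.random(multi.sum()) < 0.75, 2, 3)
    k = np.minimum(k, T)
    gumbel = rng.gumbel(size=(n, T)) + np.log(weights)
    order = np.argsort(-gumbel, axis=1)
    return [sorted(order[i, : k[i]].tolist()) for i in range(n)]


def _make_notes(
    config: GeneratorConfig,
    topic_sets: list[list[int]],
    rng: np.random.Generator,
) -> list[str]:
    vocabs = [t.vocabulary for t in config.topics]
    sizes = np.array([len(v) for v in vocabs])
    bg = config.background_vocabulary
    n = config.n_visits
    k = np.array([len(ts) for ts in topic_sets])
    lengths = rng.integers(config.note_tokens_min, config.note_tokens_max + 1, size=n)
    lengths = np.maximum(lengths, k)

    # mandatory tokens: the note names each presenting problem at least once
    flat_topics = np.concatenate([np.asarray(ts, dtype=int) for ts in topic_sets])
    mand_word = np.floor(rng.random(flat_topics.size) * sizes[flat_topics]).astype(int)

    # filler tokens, drawn in one flat batch across all visits
    filler = lengths - k
    total = int(filler.sum())
    visit_of = np.repeat(np.arange(n), filler)
    use_topic = np.ones(total, dtype=bool)
    if bg and config.topic_token_share < 1:
        use_topic = rng.random(total) < config.topic_token_share
    pos = np.floor(rng.random(total) * k[visit_of]).astype(int)
    offsets = np.concatenate([[0], np.cumsum(k)])
    fill_topic = flat_topics[offsets[visit_of] + pos]
    fill_word = np.floor(rng.random(total) * sizes[fill_topic]).astype(int)
    bg_word = rng.integers(0, max(1, len(bg)), size=total)

    notes = []
    mstart = fstart = 0
    for i in range(n):
        toks = [
            vocabs[flat_topics[mstart + j]][mand_word[mstart + j]]
            for j in range(k[i])
        ]
        mstart += int(k[i])
        for j in range(fstart, fstart + int(filler[i])):
            if use_topic[j]:
                toks.append(vocabs[fill_topic[j]][fill_word[j]])
            else:
                toks.append(bg[bg_word[j]])
        fstart += int(filler[i])
        rng.shuffle(toks)
        notes.append(" ".join(toks))
    return notes


def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_visits
    shift = rng.choice(len(SHIFTS), size=n, p=SHIFT_PROBS)
    return pd.DataFrame(
        {
            "age": np.round(rng.uniform(18, 90, size=n), 1),
            "female": (rng.random(n) < 0.46).astype(int),
            "ems": (rng.random(n) < 0.17).astype(int),
            "police": (rng.random(n) < 0.004).astype(int),
            "accident": (rng.random(n) < 0.32).astype(int),
            "ed_census": rng.poisson(20, size=n),
            "night": (shift == 2).astype(int),
            "late": (shift == 1).astype(int),
            "early": (shift == 0).astype(int),
            "team": rng.choice(TEAMS, size=n, p=TEAM_PROBS),
        }
    )


def _draw_chief_complaints(
    config: GeneratorConfig, topic_sets: list[list[int]], rng: np.random.Generator
) -> tuple[list[str], list[str | None]]:
    names = config.topic_names()
    codes, clusters = [], []
    for tset in topic_sets:
        if rng.random() < config.unspecified_rate:
            codes.append(UNSPECIFIED_CODE)
            clusters.append(None)
            continue
        if rng.random() < config.chief_complaint_fidelity:
            t = names[tset[rng.integers(len(tset))]]
        else:
            others = [nm for j, nm in enumerate(names) if j not in tset]
            t = others[rng.integers(len(others))] if others else names[tset[0]]
        codes.append(config.ls_code(t))
        clusters.append(t)
    return codes, clusters


def generate_outcomes(
    visits: pd.DataFrame,
    truth: pd.DataFrame,
    spec: OutcomeSpec,
    topic_names: list[str],
    seed: int,
    clip_warn_tol: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one binary outcome from the generating LPM.

    Returns ``(y, p)`` where ``p`` is the clipped generating probability.
    Emits a warning with a count if more than ``clip_warn_tol`` of the
    probabilities needed clipping.
    """
    n = len(visits)
    p = np.full(n, spec.alpha, dtype=float)
    for cov, b in spec.beta.items():
        p += b * visits[cov].to_numpy(dtype=float)
    for t, g in spec.gamma.items():
        p += g * truth[f"true_{t}"].to_numpy(dtype=float)
    for t, d in spec.delta.items():
        p += d * (truth["true_ls_cluster"] == t).to_numpy(dtype=float)
    clipped = (p < 0) | (p > 1)
    if clipped.mean() > clip_warn_tol:
        import warnings

        warnings.warn(
            f"{int(clipped.sum())} generating probabilities for {spec.name!r} "
            "fell outside [0, 1] and were clipped",
            stacklevel=2,
        )
    p = np.clip(p, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < p).astype(int)
    return y, p


def generate_corpus(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a visit table and its ground truth.

    Returns ``(visits, truth)``: the visit table in the canonical schema the
    ingestion layer reads, and a truth table with one boolean
    ``true_<topic>`` column per topic, the true chief-complaint cluster
    (None for unspecified codes) and the generating probability of each
    outcome.  Fully reproducible from ``config`` + ``seed``.
    """
    if not config.topics:
        raise ValueError("config defines no topics")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    topic_sets = _draw_topic_sets(config, rng)
    notes = _make_notes(config, topic_sets, rng)
    cov = _draw_covariates(config, rng)
    codes, ls_clusters = _draw_chief_complaints(config, topic_sets, rng)

    names = config.topic_names()
    visits = pd.DataFrame({"visit_id": [f"v{i:06d}" for i in range(config.n_visits)]})
    visits["text"] = notes
    visits["chief_complaint"] = codes
    visits = pd.concat([visits, cov], axis=1)
    base = pd.Timestamp("2020-01-01")
    visits["timestamp"] = [
        (base + pd.Timedelta(minutes=int(m))).isoformat()
        for m in rng.integers(0, 525600, size=config.n_visits)
    ]

    truth = pd.DataFrame({"visit_id": visits["visit_id"]})
    for j, nm in enumerate(names):
        truth[f"true_{nm}"] = [int(j in ts) for ts in topic_sets]
    truth["true_topics"] = ["|".join(names[j] for j in ts) for ts in topic_sets]
    truth["true_ls_cluster"] = ls_clusters

    for k, spec in enumerate(config.outcomes):
        y, p = generate_outcomes(
            visits, truth, spec, names, seed=seed + 1000 + k
        )
        visits[f"y_{spec.name}"] = y
        truth[f"p_{spec.name}"] = p

    visits["text_missing"] = visits["text"].str.strip() == ""
    return visits, truth


# ---------------------------------------------------------------------------
# companions for testing dictionaries and embeddings


def oracle_dictionaries(
    config: GeneratorConfig, words_per_topic: int | None = None
) -> list[TopicDictionary]:
    """Topic dictionaries built from the generating vocabularies.

    With ``words_per_topic=None`` each dictionary holds the topic's full
    vocabulary (the oracle tagger); a smaller number yields deliberately
    incomplete "initial" dictionaries for enhancement experiments.
    """
    dicts = []
    for t in config.topics:
        words = t.vocabulary[: words_per_topic or len(t.vocabulary)]
        dicts.append(TopicDictionary.from_seeds(t.name, words))
    return dicts


def planted_embedding(
    config: GeneratorConfig,
    dim: int = 16,
    noise: float = 0.25,
    seed: int = 0,
    freq: int = 50,
) -> EmbeddingModel:
    """Embedding with the generator's semantics planted geometrically.

    Words of one topic scatter around a common random unit direction with
    isotropic ``noise``; background words get independent directions.  This
    is the geometry CBOW training converges to on such a corpus, available
    without the training cost — used to exercise neighbour queries and
    spherical enhancement at scale.
    """
    rng = np.random.default_rng(seed)
    vectors: dict[str, np.ndarray] = {}
    for t in config.topics:
        center = rng.normal(size=dim)
        center /= np.linalg.norm(center)
        for w in t.vocabulary:
            vectors[w] = center + noise * rng.normal(size=dim)
    for w in config.background_vocabulary:
        v = rng.normal(size=dim)
        vectors[w] = v / np.linalg.norm(v)
    freqs = {w: freq for w in vectors}
    return EmbeddingModel.from_vectors(vectors, freqs, planted=True, seed=seed)


# ---------------------------------------------------------------------------
# fixture suite

FIXTURE_SEED = 424242


def make_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the small deterministic fixture set used by tests and docs.

    200 visits over 4 topics, oracle and truncated dictionaries, the cluster
    map, a selection file, and a German-flavoured demo dictionary whose
    chest-pain topic uses a combination rule ``(schmerz|druck) AND
    (brust|thorax)``.  Repeated invocations produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_cfg = default_config(n_visits=200)
    topics = base_cfg.topics[:4]
    names = {t.name for t in topics}
    outcomes = tuple(
        replace(
            o,
            gamma={k: v for k, v in o.gamma.items() if k in names},
            delta={k: v for k, v in o.delta.items() if k in names},
        )
        for o in base_cfg.outcomes
    )
    cfg = replace(base_cfg, topics=topics, outcomes=outcomes, seed=FIXTURE_SEED)
    visits, truth = generate_corpus(cfg)

    # plant a combination-rule visit: German-style chest-pain phrasing,
    # triggered through different or-group members in different visits
    visits.loc[0, "text"] = "druck auf thorax seit heute"
    visits.loc[1, "text"] = "schmerz in der brust akut"
    visits.loc[0:1, "text_missing"] = False

    paths = {}
    paths["visits"] = out / "visits.csv"
    visits.to_csv(paths["visits"], index=False)
    paths["truth"] = out / "truth.csv"
    truth.to_csv(paths["truth"], index=False)

    dicts = oracle_dictionaries(cfg)
    demo = TopicDictionary.from_seeds("chest_pain", ["angina"])
    demo.add_combination(["schmerz", "druck"], ["brust", "thorax"])
    paths["dictionaries"] = out / "dictionaries.json"
    save_dictionaries(dicts + [demo], paths["dictionaries"])
    paths["dictionaries_initial"] = out / "dictionaries_initial.json"
    save_dictionaries(oracle_dictionaries(cfg, words_per_topic=5), paths["dictionaries_initial"])

    cmap = cfg.cluster_map()
    cmap.mapping["chest_pain"] = "cardio"
    paths["cluster_map"] = out / "cluster_map.json"
    cmap.save(paths["cluster_map"])

    trauma_vocab = topics[0].vocabulary
    paths["selection"] = out / "selection.txt"
    paths["selection"].write_text(
        "# reviewer-approved candidates for topic 'trauma'\n"
        + "\n".join(trauma_vocab[5:7])
        + "\n"
    )

    # generation-time sanity: every topic tags at least one visit, and the
    # combination rule fires via different or-group members
    from .tagger import tag_visits

    tags = tag_visits(visits, dicts + [demo])
    assert (tags.sum(axis=0) > 0).all(), "fixture must exercise every topic"
    assert tags.loc[["v000000", "v000001"], "chest_pain"].sum() == 2
    return paths
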