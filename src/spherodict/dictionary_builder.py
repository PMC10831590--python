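"""Topic dictionaries: seed keywords, embedding-assisted candidate suggestion,
and spherical dictionary enhancement.

A topic dictionary is a set of keyword rules.  Most rules are single words;
a *combination rule* is an AND of OR-groups, e.g. ``(pain|pressure) AND
(chest|thorax)`` for a chest-pain topic.  Every single-word keyword carries a
provenance tag:

``seed``
    chosen by the researcher to initialise the topic;
``manual``
    picked by the researcher from the embedding's nearest-neighbour
    suggestions;
``spherical``
    added automatically by spherical enhancement.

Spherical enhancement treats the topic's keywords as points in embedding
space.  The largest pairwise cosine distance among them, ``d_max``, is the
radius of a ball around each keyword; a candidate word (drawn from the
keywords' nearest neighbours) joins the topic iff it lies inside *every*
ball, i.e. its distance to each existing keyword is at most ``d_max`` — the
intersection of the balls.  A topic with fewer than two embedded keywords
defines no radius and is skipped with an explicit report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from .embedding import DEFAULT_MIN_FREQ, DEFAULT_N_NEIGHBORS, EmbeddingModel

SCHEMA_VERSION = 1

PROVENANCES = ("seed", "manual", "spherical")


@dataclass(frozen=True)
class KeywordRule:
    """AND-of-OR keyword rule: matches a token set iff every group intersects it.

    ``or_groups`` is a tuple of frozensets.  A single-keyword rule is one
    group of one word.
    """

    or_groups: tuple[frozenset[str], ...]

    def __post_init__(self):
        if not self.or_groups or any(not g for g in self.or_groups):
            raise ValueError("a rule needs at least one non-empty or-group")

    @classmethod
    def single(cls, word: str) -> "KeywordRule":
        return cls((frozenset([word]),))

    @classmethod
    def combination(cls, *groups: Iterable[str]) -> "KeywordRule":
        return cls(tuple(frozenset(g) for g in groups))

    @property
    def is_single(self) -> bool:
        return len(self.or_groups) == 1 and len(next(iter(self.or_groups))) == 1

    @property
    def single_word(self) -> str | None:
        return next(iter(self.or_groups[0])) if self.is_single else None

    def matches(self, tokens: set[str] | frozenset[str]) -> bool:
        return all(not g.isdisjoint(tokens) for g in self.or_groups)

    def to_json(self) -> list[list[str]]:
        return [sorted(g) for g in self.or_groups]


@dataclass
class TopicDictionary:
    """Named topic with keyword rules and per-keyword provenance.

    ``modulating`` marks severity-style topics (acute / chronic / severe /
    nonsevere) that are tagged alongside, but kept outside, the symptom
    clusters.
    """

    topic: str
    rules: list[KeywordRule] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)
    modulating: bool = False

    @classmethod
    def from_seeds(
        cls, topic: str, seeds: Iterable[str], modulating: bool = False
    ) -> "TopicDictionary":
        d = cls(topic=topic, modulating=modulating)
        for w in seeds:
            d.add_keyword(w, "seed")
        return d

    def single_words(self) -> list[str]:
        """All single-word keywords, in insertion order."""
        return [r.single_word for r in self.rules if r.is_single]

    def all_words(self) -> set[str]:
        """Every word appearing anywhere in the dictionary's rules."""
        return {w for r in self.rules for g in r.or_groups for w in g}

    def add_keyword(self, word: str, provenance: str) -> None:
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        if word in self.single_words():
            return  # no duplicate single-word rules
        self.rules.append(KeywordRule.single(word))
        self.provenance[word] = provenance

    def add_combination(self, *groups: Iterable[str]) -> None:
        self.rules.append(KeywordRule.combination(*groups))

    def copy(self) -> "TopicDictionary":
        return TopicDictionary(
            self.topic, list(self.rules), dict(self.provenance), self.modulating
        )

    def to_json(self) -> dict:
        return {
            "topic": self.topic,
            "modulating": self.modulating,
            "rules": [r.to_json() for r in self.rules],
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_json(cls, obj: dict, lax: bool = False) -> "TopicDictionary":
        known = {"topic", "modulating", "rules", "provenance"}
        unknown = set(obj) - known
        if unknown and not lax:
            raise ValueError(f"unknown dictionary fields: {sorted(unknown)}")
        rules = [
            KeywordRule(tuple(frozenset(g) for g in groups)) for groups in obj["rules"]
        ]
        return cls(
            topic=obj["topic"],
            rules=rules,
            provenance=dict(obj.get("provenance", {})),
            modulating=bool(obj.get("modulating", False)),
        )


@dataclass
class EnhancementReport:
    """Outcome of spherical enhancement for one topic."""

    topic: str
    d_max: float | None
    candidates_examined: int
    words_added: list[str]
    skipped: str | None = None

    def to_json(self) -> dict:
        return {
            "topic": self.topic,
            "d_max": self.d_max,
            "candidates_examined": self.candidates_examined,
            "words_added": list(self.words_added),
            "skipped": self.skipped,
        }


# ---------------------------------------------------------------------------
# candidate suggestion + manual selection


def suggest_candidates(
    seeds: Iterable[str],
    model: EmbeddingModel,
    n: int = DEFAULT_N_NEIGHBORS,
    min_freq: int = DEFAULT_MIN_FREQ,
) -> list[tuple[str, float]]:
    """Nearest-neighbour candidate list for a seed word set, for human review.

    The whole seed list is the query (centroid ranking); seeds are excluded
    and candidates must clear the corpus-frequency floor.
    """
    return model.nearest_neighbors(list(seeds), n=n, min_freq=min_freq)


def apply_selection(
    candidates: Sequence[tuple[str, float]],
    selection: Iterable[str],
    topic: TopicDictionary,
) -> TopicDictionary:
    """Append reviewer-selected candidate words as ``manual`` keywords.

    Idempotent: selecting the same words twice leaves the dictionary
    unchanged.  Selecting a word that was never a candidate is an error
    (it would silently bypass the suggestion audit trail).
    """
    candidate_words = {w for w, _ in candidates}
    selection = list(selection)
    bad = sorted(set(selection) - candidate_words)
    if bad:
        raise ValueError(f"selected words are not candidates: {bad}")
    out = topic.copy()
    for w in selection:
        if w not in out.provenance:  # keep original provenance on re-selection
            out.add_keyword(w, "manual")
    return out


# ---------------------------------------------------------------------------
# spherical enhancement


def max_pairwise_distance(
    keywords: Iterable[str], model: EmbeddingModel
) -> float | None:
    """Largest cosine distance over all unordered keyword pairs.

    Returns None when fewer than two keywords are embedded (no radius is
    defined — the degenerate-topic signal consumed by
    :func:`spherical_enhance`).
    """
    embedded = [w for w in dict.fromkeys(keywords) if w in model]
    if len(embedded) < 2:
        return None
    return max(
        model.cosine_distance(a, b) for a, b in combinations(embedded, 2)
    )


def spherical_enhance(
    topic: TopicDictionary,
    model: EmbeddingModel,
    n_closest: int = DEFAULT_N_NEIGHBORS,
    min_freq: int = DEFAULT_MIN_FREQ,
    seeds_only: bool = False,
) -> tuple[TopicDictionary, EnhancementReport]:
    """Automatically grow a topic dictionary inside the keyword sphere.

    Let K be the topic's embedded single-word keywords and ``d_max`` their
    largest pairwise cosine distance.  Candidates are the union of the
    ``n_closest`` neighbours of each keyword (excluding words already in the
    topic, and words below ``min_freq`` occurrences).  A candidate is added,
    with provenance ``spherical``, iff its distance to *every* k in K is at
    most ``d_max`` — the intersection of the balls of radius ``d_max``
    centred on the keywords.  The boundary is closed (``<= d_max``) so
    floating-point noise cannot exclude a word exactly as far as the widest
    keyword pair.

    ``seeds_only=True`` restricts the sphere geometry to seed-provenance
    keywords; by default all current single-word keywords (seed + manual)
    shape the sphere.  Combination rules never contribute to the geometry —
    their semantics are conjunctive, not lexical proximity.

    Topics with fewer than two embedded keywords are returned unchanged with
    ``report.skipped`` set: one point defines no radius, and guessing one
    would be arbitrary.
    """
    words = topic.single_words()
    if seeds_only:
        words = [w for w in words if topic.provenance.get(w) == "seed"]
    anchors = [w for w in words if w in model]
    if len(anchors) < 2:
        report = EnhancementReport(
            topic=topic.topic,
            d_max=None,
            candidates_examined=0,
            words_added=[],
            skipped="degenerate: fewer than 2 embedded keywords",
        )
        return topic.copy(), report

    d_max = max(
        model.cosine_distance(a, b) for a, b in combinations(anchors, 2)
    )

    existing = topic.all_words()
    pool: list[str] = []
    seen: set[str] = set()
    for k in anchors:
        for w, _ in model.nearest_neighbors(k, n=n_closest, min_freq=min_freq):
            if w not in existing and w not in seen:
                seen.add(w)
                pool.append(w)

    enhanced = topic.copy()
    added = []
    for w in pool:
        if all(model.cosine_distance(w, k) <= d_max for k in anchors):
            enhanced.add_keyword(w, "spherical")
            added.append(w)

    report = EnhancementReport(
        topic=topic.topic,
        d_max=d_max,
        candidates_examined=len(pool),
        words_added=added,
    )
    return enhanced, report


def enhance_all(
    dicts: Sequence[TopicDictionary],
    model: EmbeddingModel,
    n_closest: int = DEFAULT_N_NEIGHBORS,
    min_freq: int = DEFAULT_MIN_FREQ,
    seeds_only: bool = False,
) -> tuple[list[TopicDictionary], list[EnhancementReport]]:
    """Spherically enhance each topic independently.

    Topics do not interact: a word may be added to several topics, matching
    the multi-label tagging downstream.  Per-topic errors are recorded in the
    report (``skipped``) rather than aborting the batch.
    """
    out_dicts, reports = [], []
    for d in dicts:
        try:
            enhanced, report = spherical_enhance(
                d, model, n_closest=n_closest, min_freq=min_freq, seeds_only=seeds_only
            )
        except Exception as exc:  # keep going; surface the failure in the report
            enhanced = d.copy()
            report = EnhancementReport(
                topic=d.topic,
                d_max=None,
                candidates_examined=0,
                words_added=[],
                skipped=f"error: {exc}",
            )
        out_dicts.append(enhanced)
        reports.append(report)
    return out_dicts, reports


# ---------------------------------------------------------------------------
# persistence


def save_dictionaries(dicts: Sequence[TopicDictionary], path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "topics": [d.to_json() for d in dicts],
    }
    Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False))


def load_dictionaries(path: str | Path, lax: bool = False) -> list[TopicDictionary]:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION and not lax:
        raise ValueError(f"unsupported dictionary schema version: {version}")
    names = [t["topic"] for t in payload["topics"]]
    if len(names) != len(set(names)):
        raise ValueError("duplicate topic names in dictionary file")
    return [TopicDictionary.from_json(t, lax=lax) for t in payload["topics"]]


def load_selection(path: str | Path) -> list[str]:
    """Read a selection file: one word per line, ``#`` comments ignored."""
    words = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.append(line)
    return words
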