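"""Rule-based visit tagging and cluster aggregation.

Tag matrices are plain :class:`pandas.DataFrame` objects: visit ids as
index, label names as columns, values in {0, 1}.  Two DataFrame ``attrs``
carry bookkeeping: ``level`` ("topic" or "cluster") and ``source`` ("nlp"
for dictionary tags from free text, "ls" for the structured lead-symptom /
chief-complaint codes).

NLP tagging is multi-label: a note mentioning both a wound and chest pain
gets both topics.  The chief complaint is a single-choice drop-down, so its
cluster matrix is one-hot at most; codes in the map's excluded set (e.g. a
"Diverse" bucket) yield an all-zero row flagged ``unspecified``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import tokenize
from .dictionary_builder import KeywordRule, TopicDictionary


@dataclass
class ClusterMap:
    """Label -> cluster assignment with an explicit excluded set.

    Used both for aggregating NLP topics into symptom clusters and for
    mapping structured chief-complaint codes into the same clusters, so the
    two sources become comparable.
    """

    mapping: dict[str, str]
    excluded: set[str] = field(default_factory=set)

    def cluster_of(self, label: str) -> str | None:
        if label in self.excluded:
            return None
        return self.mapping.get(label)

    @property
    def clusters(self) -> list[str]:
        seen = dict.fromkeys(self.mapping.values())
        return list(seen)

    def to_json(self) -> dict:
        obj: dict = dict(self.mapping)
        obj["excluded"] = sorted(self.excluded)
        return obj

    @classmethod
    def from_json(cls, obj: Mapping) -> "ClusterMap":
        excluded = set(obj.get("excluded", []))
        mapping = {k: v for k, v in obj.items() if k != "excluded"}
        return cls(mapping=mapping, excluded=excluded)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2, ensure_ascii=False))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterMap":
        return cls.from_json(json.loads(Path(path).read_text()))


def match_rule(rule: KeywordRule, tokens: set[str] | frozenset[str]) -> int:
    """1 iff every or-group of the rule intersects the token set.

    Token-level exact match: ``thorax`` matches the token ``thorax`` but not
    the compound ``thoraxschmerz``.
    """
    return int(rule.matches(tokens))


def tag_visits(
    visits: pd.DataFrame, dicts: Sequence[TopicDictionary]
) -> pd.DataFrame:
    """Tag each visit with every topic whose dictionary matches its note.

    Multi-label by design; a visit matching nothing keeps an all-zero row
    ("no tag").  Deterministic: tagging depends only on the token set.

    Returns a topic-level NLP tag matrix (visits x topics).
    """
    if not dicts:
        raise ValueError("empty dictionary set: nothing to tag with")
    names = [d.topic for d in dicts]
    if len(names) != len(set(names)):
        raise ValueError("duplicate topic names in dictionary set")

    token_sets = [frozenset(tokenize(t)) for t in visits["text"]]
    data = np.zeros((len(visits), len(dicts)), dtype=np.int8)
    for j, d in enumerate(dicts):
        for i, toks in enumerate(token_sets):
            if any(r.matches(toks) for r in d.rules):
                data[i, j] = 1
    out = pd.DataFrame(data, index=pd.Index(visits["visit_id"], name="visit_id"), columns=names)
    out.attrs["level"] = "topic"
    out.attrs["source"] = "nlp"
    out.attrs["modulating"] = [d.topic for d in dicts if d.modulating]
    return out


def aggregate_clusters(tags: pd.DataFrame, cmap: ClusterMap) -> pd.DataFrame:
    """OR-reduce topic indicators into cluster indicators.

    Every topic column must appear in the map or its excluded set.
    Modulating (severity) topics are excluded from clusters but carried
    through as their own columns, so downstream models can still control
    for severity.
    """
    modulating = set(tags.attrs.get("modulating", []))
    unmapped = [
        t
        for t in tags.columns
        if t not in cmap.mapping and t not in cmap.excluded and t not in modulating
    ]
    if unmapped:
        raise ValueError(f"topics missing from cluster map: {unmapped}")

    out = pd.DataFrame(0, index=tags.index, columns=cmap.clusters, dtype=np.int8)
    for topic in tags.columns:
        cluster = cmap.cluster_of(topic)
        if cluster is None or topic in modulating:
            continue
        out[cluster] = np.maximum(out[cluster], tags[topic].to_numpy())
    for topic in sorted(modulating & set(tags.columns)):
        out[topic] = tags[topic].to_numpy()
    out.attrs["level"] = "cluster"
    out.attrs["source"] = tags.attrs.get("source", "nlp")
    out.attrs["modulating"] = sorted(modulating & set(tags.columns))
    return out


def map_chief_complaints(visits: pd.DataFrame, cmap: ClusterMap) -> pd.DataFrame:
    """One-hot cluster matrix from the structured chief-complaint codes.

    The drop-down is single-choice, so each visit activates at most one
    cluster.  Codes in the excluded set (not-otherwise-specified buckets)
    and missing codes yield all-zero rows; the matrix records which in a
    boolean ``attrs["unspecified"]`` series.
    """
    if "chief_complaint" not in visits.columns:
        raise ValueError("visit table has no 'chief_complaint' column")
    codes = visits["chief_complaint"]
    known = set(cmap.mapping) | cmap.excluded
    unknown = sorted(
        {c for c in codes.dropna().astype(str) if c and c not in known}
    )
    if unknown:
        raise ValueError(f"chief-complaint codes missing from cluster map: {unknown}")

    out = pd.DataFrame(
        0,
        index=pd.Index(visits["visit_id"], name="visit_id"),
        columns=cmap.clusters,
        dtype=np.int8,
    )
    unspecified = np.zeros(len(visits), dtype=bool)
    for i, code in enumerate(codes):
        if pd.isna(code) or not str(code):
            unspecified[i] = True
            continue
        cluster = cmap.cluster_of(str(code))
        if cluster is None:
            unspecified[i] = True
        else:
            out.iloc[i, out.columns.get_loc(cluster)] = 1
    out.attrs["level"] = "cluster"
    out.attrs["source"] = "ls"
    out.attrs["unspecified"] = pd.Series(unspecified, index=out.index)
    return out


def no_tag_mask(tags: pd.DataFrame, symptom_only: bool = True) -> pd.Series:
    """True for visits with no active indicator.

    With ``symptom_only`` (default) modulating severity columns are ignored:
    a note tagged only "acute" still counts as carrying no symptom topic.
    """
    cols = list(tags.columns)
    if symptom_only:
        modulating = set(tags.attrs.get("modulating", []))
        cols = [c for c in cols if c not in modulating]
    return tags[cols].sum(axis=1) == 0


def write_tags_long(tags: pd.DataFrame, path: str | Path) -> None:
    """Long-form writer: visit_id, label, level, source, value (ones only)."""
    level = tags.attrs.get("level", "topic")
    source = tags.attrs.get("source", "nlp")
    long = tags.reset_index().melt(
        id_vars="visit_id", var_name="label", value_name="value"
    )
    long = long[long["value"] == 1]
    long.insert(2, "level", level)
    long.insert(3, "source", source)
    long.to_csv(path, index=False)


def write_tags_wide(tags: pd.DataFrame, path: str | Path) -> None:
    """Wide binary-matrix writer (visits x labels)."""
    tags.to_csv(path)
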