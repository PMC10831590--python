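"""Seeded validation studies over the synthetic generator.

These are the package's standing experiments: each builds its inputs from
the synthetic generator (or random geometries), runs the pipeline, and
returns summary numbers.  They back the test suite and the reproduction
script, and are equally usable interactively to probe how the method behaves
as conditions change.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import combinations

import numpy as np
import pandas as pd

from .dictionary_builder import TopicDictionary, enhance_all, spherical_enhance
from .evaluation import fit_lpm, nesting_check
from .synthetic_data import (
    OutcomeSpec,
    default_config,
    generate_corpus,
    oracle_dictionaries,
    planted_embedding,
)
from .tagger import no_tag_mask, tag_visits

from .embedding import EmbeddingModel


# ---------------------------------------------------------------------------
# spherical enhancement vs exhaustive scan


def _brute_force_additions(topic, model, min_freq):
    anchors = [w for w in topic.single_words() if w in model]
    if len(anchors) < 2:
        return set()
    d_max = max(model.cosine_distance(a, b) for a, b in combinations(anchors, 2))
    existing = topic.all_words()
    return {
        w
        for w in model.words
        if w not in existing
        and model.freqs.get(w, 0) >= min_freq
        and all(model.cosine_distance(w, k) <= d_max for k in anchors)
    }


def spherical_oracle_study(
    n_models: int = 50, max_words: int = 200, seed: int = 0
) -> dict:
    """Compare spherical enhancement against an exhaustive vocabulary scan.

    Draws ``n_models`` random embeddings (up to ``max_words`` words each),
    enhances a topic seeded with the first few words using
    ``n_closest = |vocabulary|``, and checks (a) set equality with the
    brute-force scan and (b) the sphere certificate
    ``dist(w, k) <= d_max`` for every added word and keyword.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    certified = total_added = 0
    for m_idx in range(n_models):
        n_words = int(rng.integers(50, max_words + 1))
        dim = int(rng.integers(4, 16))
        words = [f"w{i:03d}" for i in range(n_words)]
        mat = rng.normal(size=(n_words, dim))
        freqs = {w: int(f) for w, f in zip(words, rng.integers(1, 200, size=n_words))}
        model = EmbeddingModel(words, mat, freqs)
        k = int(rng.integers(2, 6))
        topic = TopicDictionary.from_seeds("t", words[:k])
        enhanced, report = spherical_enhance(
            topic, model, n_closest=n_words, min_freq=10
        )
        added = set(report.words_added)
        if added == _brute_force_additions(topic, model, min_freq=10):
            agree += 1
        total_added += len(added)
        certified += sum(
            all(
                model.cosine_distance(w, anchor) <= report.d_max + 1e-12
                for anchor in topic.single_words()
            )
            for w in added
        )
    return {
        "n_models": n_models,
        "oracle_agreement_rate": agree / n_models,
        "certificate_rate": certified / total_added if total_added else 1.0,
        "total_words_added": total_added,
    }


# ---------------------------------------------------------------------------
# no-tag monotonicity under enhancement


def no_tag_monotonicity_study(
    n_corpora: int = 20, n_visits: int = 1000, seed: int = 0
) -> dict:
    """Tag synthetic corpora with initial vs spherically enhanced dictionaries.

    Initial dictionaries hold a truncated slice of each topic's vocabulary;
    enhancement against a planted embedding recovers further topic words.
    Because enhanced dictionaries are supersets, the set of untagged visits
    can only shrink; the study measures how often that holds and by how much
    the no-tag share falls.
    """
    ok = 0
    drops = []
    for r in range(n_corpora):
        s = seed + r
        cfg = default_config(n_visits=n_visits, seed=s)
        visits, _ = generate_corpus(cfg)
        initial = oracle_dictionaries(cfg, words_per_topic=4)
        model = planted_embedding(cfg, dim=16, noise=0.25, seed=s)
        enhanced, _ = enhance_all(initial, model, n_closest=len(model.words), min_freq=1)
        t0 = tag_visits(visits, initial)
        t1 = tag_visits(visits, enhanced)
        no0 = set(no_tag_mask(t0)[no_tag_mask(t0)].index)
        no1 = set(no_tag_mask(t1)[no_tag_mask(t1)].index)
        if no1 <= no0:
            ok += 1
        drops.append((len(no0) - len(no1)) / n_visits)
    return {
        "n_corpora": n_corpora,
        "monotone_rate": ok / n_corpora,
        "mean_no_tag_drop": float(np.mean(drops)),
    }


# ---------------------------------------------------------------------------
# LPM parameter recovery


def _recovery_outcome(model_id: int) -> OutcomeSpec:
    """Generating coefficients for the recovery study, sized so that no
    probability needs clipping (clipping would bias the recovery target)."""
    base = default_config().outcomes[0]  # inpatient-shaped effect pattern
    spec = OutcomeSpec(
        name="inpatient",
        alpha=0.2,
        beta={"age": 0.001, "ems": 0.1},
        gamma=dict(base.gamma),
        delta=dict(base.delta),
    )
    if model_id == 1:
        spec = replace(spec, delta={})
    elif model_id == 2:
        spec = replace(spec, gamma={})
    return spec


def _truth_vector(columns, spec: OutcomeSpec) -> np.ndarray:
    vals = []
    for c in columns:
        if c == "const":
            vals.append(spec.alpha)
        elif c.startswith("nlp:"):
            vals.append(spec.gamma.get(c[4:], 0.0))
        elif c.startswith("ls:"):
            vals.append(spec.delta.get(c[3:], 0.0))
        else:
            vals.append(spec.beta.get(c, 0.0))
    return np.array(vals)


def _oracle_matrices(cfg, visits, truth):
    names = cfg.topic_names()
    z = truth[[f"true_{t}" for t in names]].copy()
    z.columns = names
    z.index = pd.Index(visits["visit_id"], name="visit_id")
    w = (
        pd.get_dummies(truth["true_ls_cluster"])
        .reindex(columns=names, fill_value=0)
        .astype(int)
    )
    w.index = z.index
    return z, w


def recovery_study(
    n_visits: int = 50_000, n_replicates: int = 20, seed: int = 0
) -> dict:
    """Fit the three nested LPMs on data generated under each one.

    Per replicate, three corpora are generated — outcomes driven by NLP
    topics only (model 1), by the chief-complaint cluster only (model 2),
    and by both (model 3) — and the matching model is fitted on the *true*
    indicator matrices.  A coefficient counts as recovered when the estimate
    lies within 3 standard errors of its generating value.  The nesting
    property (model 3's R² dominating models 1 and 2 on a common corpus) is
    checked on every replicate.
    """
    hits = total = 0
    nesting_ok = 0
    for r in range(n_replicates):
        s = seed + 7919 * (r + 1)  # distinct, stays far below 2**31
        for model_id in (1, 2, 3):
            spec = _recovery_outcome(model_id)
            cfg = replace(
                default_config(n_visits=n_visits),
                outcomes=(spec,),
                seed=s + model_id,
            )
            visits, truth = generate_corpus(cfg)
            z, w = _oracle_matrices(cfg, visits, truth)
            res = fit_lpm(
                visits,
                z if model_id in (1, 3) else None,
                w if model_id in (2, 3) else None,
                "inpatient",
                model_id=model_id,
            )
            true_vec = _truth_vector(res.params.index, spec)
            hit = np.abs(res.params.to_numpy() - true_vec) <= 3 * res.bse.to_numpy()
            hits += int(hit.sum())
            total += hit.size
            if model_id == 3:
                m1 = fit_lpm(visits, z, None, "inpatient", model_id=1)
                m2 = fit_lpm(visits, None, w, "inpatient", model_id=2)
                if nesting_check((m1, m2, res)):
                    nesting_ok += 1
    return {
        "n_visits": n_visits,
        "n_replicates": n_replicates,
        "n_coefficients": total,
        "coverage_3se": hits / total,
        "nesting_rate": nesting_ok / n_replicates,
    }


# ---------------------------------------------------------------------------
# prediction sanity


def prediction_sanity_study(seed: int = 0) -> dict:
    """Three closed-form checks of the prediction pipeline.

    A separable outcome must reach AUC 1; labels independent of all features
    must sit at AUC 0.5; and an all-positive predictor on a 30%-prevalence
    sample must score F1 = 2*0.3/1.3 = 0.4615.
    """
    from sklearn.metrics import f1_score

    from .evaluation import predict_evaluate

    rng = np.random.default_rng(seed)

    def visits_frame(y, age):
        df = pd.DataFrame({"visit_id": [str(i) for i in range(len(y))]})
        df["age"] = age
        df["y_inpatient"] = y
        return df

    age = np.repeat([0.0, 1.0], 200)
    sep = predict_evaluate(
        visits_frame((age > 0.5).astype(int), age), None, None, "inpatient", seed=seed
    )

    n = 10_000
    perm = predict_evaluate(
        visits_frame((rng.random(n) < 0.5).astype(int), rng.uniform(0, 1, n)),
        None,
        None,
        "inpatient",
        seed=seed,
    )

    y = np.zeros(1000, dtype=int)
    y[:300] = 1
    f1_all_pos = float(f1_score(y, np.ones_like(y)))

    return {
        "separable_auc": sep.auc,
        "permuted_auc": perm.auc,
        "f1_all_positive_30pct": f1_all_pos,
    }
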