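"""Evaluation protocols: cross-modal retrieval, zero-shot image-to-image
classification, linear probing, and exact binomial confidence intervals.

Retrieval ranks the matched candidate for every query under descending
cosine similarity (ties broken deterministically by candidate index) and
summarizes top-k accuracy with Clopper-Pearson 95% intervals.  Zero-shot
classification embeds one labelled reference image per class and scores
queries by softmax over reference cosine similarities, after removing
reference images and same-molecule/same-plate neighbours from the query
pool so plate effects cannot masquerade as recognition.  Linear probing
fits one logistic regression per task on frozen penultimate features with
the L2 strength selected on validation AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax as _softmax
from scipy.stats import beta as _beta
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score

from .records import EmbeddingMatrix, ImageRecord

__all__ = [
    "RetrievalReport", "ProbeResult", "rank_matched", "topk_accuracy",
    "clopper_pearson_ci", "retrieval_eval", "build_reference_set",
    "zeroshot_classify", "linear_probe", "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = tuple(10.0 ** k for k in range(-6, 7))
DEFAULT_TOPK = (1, 5, 10)


@dataclass
class RetrievalReport:
    direction: str                       # structure_retrieval | image_retrieval
    n_candidates: int
    ranks: np.ndarray                    # per-query rank of the matched item
    topk: dict[int, float] = field(default_factory=dict)      # percent
    topk_ci: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        ks = sorted(self.topk)
        for a, b in zip(ks, ks[1:]):
            if self.topk[a] > self.topk[b] + 1e-9:
                raise ValueError("top-k accuracy must be monotone in k")


@dataclass
class ProbeResult:
    task: str
    chosen_lambda: float
    auc: float
    f1: float
    exceeds: dict[float, bool] = field(default_factory=dict)
    skipped: bool = False
    reason: str = ""


def rank_matched(query_embs: EmbeddingMatrix, candidate_embs: EmbeddingMatrix,
                 pairing: dict[str, str]) -> np.ndarray:
    """Rank (1-based) of each query's matched candidate under descending
    cosine similarity; ties broken by candidate index."""
    cand_index = {cid: i for i, cid in enumerate(candidate_embs.ids)}
    matched = []
    for qid in query_embs.ids:
        if qid not in pairing or pairing[qid] not in cand_index:
            raise KeyError(f"pairing missing for query {qid!r}")
        matched.append(cand_index[pairing[qid]])
    sims = query_embs.vectors @ candidate_embs.vectors.T
    ranks = np.empty(len(matched), dtype=np.int64)
    for i, m in enumerate(matched):
        s = sims[i]
        # stable ordering: higher similarity first, index breaks ties
        better = np.count_nonzero(s > s[m])
        tied_before = np.count_nonzero((s == s[m]) & (np.arange(s.size) < m))
        ranks[i] = 1 + better + tied_before
    return ranks


def topk_accuracy(ranks: np.ndarray, k: int) -> float:
    """100 * fraction of queries whose matched item ranks in the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranks = np.asarray(ranks)
    if ranks.size == 0 or (ranks < 1).any():
        raise ValueError("ranks must be 1-based and nonempty")
    return 100.0 * float(np.mean(ranks <= k))


def clopper_pearson_ci(successes: int, n: int,
                       level: float = 0.95) -> tuple[float, float]:
    """Exact binomial 95% CI (beta-quantile form), returned in percent."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be within [0, n]")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else \
        _beta.ppf(alpha / 2.0, successes, n - successes + 1)
    upper = 1.0 if successes == n else \
        _beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes)
    return 100.0 * lower, 100.0 * upper


def _report(direction: str, ranks: np.ndarray, n_candidates: int,
            ks=DEFAULT_TOPK) -> RetrievalReport:
    n = ranks.size
    topk, cis = {}, {}
    for k in ks:
        hits = int(np.count_nonzero(ranks <= k))
        topk[k] = 100.0 * hits / n
        cis[k] = clopper_pearson_ci(hits, n)
    return RetrievalReport(direction, n_candidates, ranks, topk, cis)


def retrieval_eval(image_embs: EmbeddingMatrix, struct_embs: EmbeddingMatrix,
                   pairing: dict[str, str], subsample: int | None = None,
                   seed: int = 0, ks=DEFAULT_TOPK
                   ) -> tuple[RetrievalReport, RetrievalReport]:
    """Cross-modal retrieval in both directions.

    ``pairing`` maps image id -> molecule id.  With ``subsample`` = m, each
    query instead ranks its match among m randomly drawn un-matched
    candidates plus the match (the 1-vs-m protocol).
    """
    if len(struct_embs) < 2 or len(image_embs) < 2:
        raise ValueError("need at least 2 candidates")
    inverse = {v: k for k, v in pairing.items()}
    if len(inverse) != len(pairing):
        raise ValueError("pairing must be a bijection for retrieval_eval")

    def one_direction(queries, candidates, mapping, direction):
        if subsample is None:
            ranks = rank_matched(queries, candidates, mapping)
            return _report(direction, ranks, len(candidates), ks)
        rng = np.random.default_rng(seed)
        cand_index = {cid: i for i, cid in enumerate(candidates.ids)}
        ranks = []
        for qi, qid in enumerate(queries.ids):
            m = cand_index[mapping[qid]]
            others = np.array([i for i in range(len(candidates)) if i != m])
            chosen = rng.choice(others, size=min(subsample, others.size),
                                replace=False)
            pool = np.concatenate([[m], chosen])
            sims = queries.vectors[qi] @ candidates.vectors[pool].T
            better = np.count_nonzero(sims > sims[0])
            ranks.append(1 + better)
        return _report(direction, np.asarray(ranks), subsample + 1, ks)

    structure = one_direction(image_embs, struct_embs, pairing,
                              "structure_retrieval")
    image = one_direction(struct_embs, image_embs, inverse,
                          "image_retrieval")
    return structure, image


def build_reference_set(image_records: list[ImageRecord],
                        class_key: str = "molecule_id",
                        class_of=None, seed: int = 0
                        ) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """One randomly chosen reference image per class, plus the filtered
    query set.

    ``class_key`` is "molecule_id" or "moa"; for "moa" supply ``class_of``
    mapping molecule_id -> class label.  Queries exclude all reference
    images and any image sharing both molecule and plate with its class's
    reference (plate-effect control).  Classes left with no queries are
    dropped with a warning.
    """
    if class_key == "molecule_id":
        label = lambda r: r.molecule_id
    elif class_key == "moa":
        if class_of is None:
            raise ValueError("class_of mapping required for MoA classes")
        label = lambda r: class_of[r.molecule_id]
    else:
        raise ValueError(f"unknown class key: {class_key}")

    rng = np.random.default_rng(seed)
    by_class: dict[object, list[ImageRecord]] = {}
    for rec in image_records:
        by_class.setdefault(label(rec), []).append(rec)

    references, queries = [], []
    for cls in sorted(by_class, key=str):
        members = by_class[cls]
        ref = members[int(rng.integers(len(members)))]
        remaining = [r for r in members
                     if r.image_id != ref.image_id
                     and not (r.molecule_id == ref.molecule_id
                              and r.plate_id == ref.plate_id)]
        if not remaining:
            warnings.warn(f"class {cls!r} has no queries left after "
                          "plate filtering; dropped", stacklevel=2)
            continue
        references.append(ref)
        queries.extend(remaining)
    return references, queries


def zeroshot_classify(query_embs: EmbeddingMatrix,
                      reference_embs: EmbeddingMatrix,
                      reference_labels: list, true_labels: list,
                      ks=DEFAULT_TOPK) -> tuple[np.ndarray, dict[int, float]]:
    """Zero-shot classification by cosine similarity to one reference
    embedding per class.

    Returns per-query softmax class scores and top-k accuracies (percent).
    Top-k membership is judged on the raw similarity order (softmax is a
    monotone reparametrization reported for score calibration).
    """
    if len(reference_labels) != len(reference_embs):
        raise ValueError("reference labels misaligned with embeddings")
    if len(true_labels) != len(query_embs):
        raise ValueError("true labels misaligned with query embeddings")
    sims = query_embs.vectors @ reference_embs.vectors.T
    scores = _softmax(sims, axis=1)
    ref_labels = np.asarray(reference_labels, dtype=object)
    accs = {}
    order = np.argsort(-sims, axis=1, kind="stable")
    for k in ks:
        kk = min(k, sims.shape[1])
        hits = sum(true in set(ref_labels[order[i, :kk]])
                   for i, true in enumerate(true_labels))
        accs[k] = 100.0 * hits / len(true_labels)
    return scores, accs


def linear_probe(features: np.ndarray, labels: pd.DataFrame,
                 split_of_sample: list[str],
                 lambda_grid=DEFAULT_LAMBDA_GRID,
                 thresholds=(0.9, 0.8, 0.7), max_iter: int = 1000
                 ) -> tuple[list[ProbeResult], dict]:
    """Per-task logistic regression on frozen features.

    ``labels`` is a samples x tasks frame with NaN for missing entries,
    row-aligned with ``features`` and ``split_of_sample`` (train/valid/
    test).  For each task the L2 strength is chosen on validation AUC from
    ``lambda_grid``; test AUC and F1 (at probability 0.5) are reported,
    with summary counts of tasks exceeding the AUC thresholds.  Tasks with
    a single class in any split are skipped and recorded.
    """
    features = np.asarray(features, dtype=np.float64)
    split = np.asarray(split_of_sample)
    if features.shape[0] != len(labels) or features.shape[0] != split.size:
        raise ValueError("features, labels and splits must be row-aligned")
    masks = {s: split == s for s in ("train", "valid", "test")}
    # standardize by training-row statistics (solver conditioning; mirrors
    # the feature-table preprocessing convention)
    mu = features[masks["train"]].mean(axis=0)
    sd = features[masks["train"]].std(axis=0)
    sd[sd == 0] = 1.0
    features = (features - mu) / sd
    results: list[ProbeResult] = []
    for task in labels.columns:
        y = labels[task].to_numpy(dtype=float)
        observed = ~np.isnan(y)
        parts = {}
        degenerate = None
        for s, m in masks.items():
            sel = m & observed
            if sel.sum() == 0 or len(np.unique(y[sel])) < 2:
                degenerate = s
                break
            parts[s] = sel
        if degenerate is not None:
            results.append(ProbeResult(task, np.nan, np.nan, np.nan,
                                       skipped=True,
                                       reason=f"single class in {degenerate}"))
            continue
        best = (None, -np.inf)
        for lam in lambda_grid:
            clf = LogisticRegression(C=1.0 / lam, max_iter=max_iter)
            clf.fit(features[parts["train"]], y[parts["train"]])
            val_auc = roc_auc_score(
                y[parts["valid"]],
                clf.predict_proba(features[parts["valid"]])[:, 1])
            if val_auc > best[1]:
                best = (lam, val_auc)
        lam = best[0]
        clf = LogisticRegression(C=1.0 / lam, max_iter=max_iter)
        clf.fit(features[parts["train"]], y[parts["train"]])
        prob = clf.predict_proba(features[parts["test"]])[:, 1]
        auc = roc_auc_score(y[parts["test"]], prob)
        f1 = f1_score(y[parts["test"]], (prob >= 0.5).astype(int))
        results.append(ProbeResult(
            task, lam, float(auc), float(f1),
            exceeds={t: bool(auc > t) for t in thresholds}))
    scored = [r for r in results if not r.skipped]
    summary = {
        "n_tasks": len(results),
        "n_scored": len(scored),
        "n_skipped": len(results) - len(scored),
        "mean_auc": float(np.mean([r.auc for r in scored])) if scored else np.nan,
        "mean_f1": float(np.mean([r.f1 for r in scored])) if scored else np.nan,
        "auc_above": {t: sum(r.exceeds[t] for r in scored)
                      for t in thresholds},
    }
    return results, summary
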