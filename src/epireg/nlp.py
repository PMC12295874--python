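"""TF-IDF clustering of gene functional descriptions.

Each gene is a text document (its concatenated functional descriptions).
Documents are tokenized to lowercase unigrams plus adjacent-pair bigrams
(joined with ``_``), stopwords and tokens of length <= 2 dropped.  Term
weights are tf * idf with tf the term count normalized by document length and
idf = ln(N / df) (unsmoothed, so a term present in every document weighs 0 —
that is what makes cluster keywords "unique").  Genes are clustered by
average-linkage agglomeration on 1 - cosine similarity, and each cluster is
characterized by the terms whose mean weight inside the cluster most exceeds
their mean weight outside.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

# Compact English stopword list (function words common in gene annotations).
STOPWORDS = frozenset("""
a about above after again against all am an and any are as at be because been
before being below between both but by can did do does doing down during each
few for from further had has have having he her here hers him his how i if in
into is it its itself just me more most my no nor not now of off on once only
or other our ours out over own same she should so some such than that the
their theirs them then there these they this those through to too under until
up very was we were what when where which while who whom why will with you
your yours via involved may also known
""".split())

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str, bigrams: bool = True) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop stopwords and tokens of
    length <= 2; emit unigrams plus adjacent-pair bigrams joined with '_'.

    Bigrams are formed over the surviving token sequence, so they may bridge
    a removed stopword ("regulation of ion" -> "regulation_ion").
    """
    toks = [t for t in _TOKEN_RE.findall(text.lower())
            if len(t) > 2 and t not in STOPWORDS]
    terms = list(toks)
    if bigrams:
        terms += [f"{a}_{b}" for a, b in zip(toks, toks[1:])]
    return terms


@dataclasses.dataclass
class TFIDFModel:
    """Vocabulary, document frequencies and the document-by-term weights."""

    weights: pd.DataFrame       # documents x terms, tf * idf
    idf: pd.Series
    df_counts: pd.Series

    @property
    def vocabulary(self) -> list[str]:
        return list(self.weights.columns)


def tfidf(corpus: dict[str, str], bigrams: bool = True,
          smooth: bool = False) -> TFIDFModel:
    """Fit the TF-IDF model: tf = count / document length, idf = ln(N/df)
    (``smooth`` adds one to df and N, keeping idf finite but never zero)."""
    if not corpus:
        raise ValueError("empty corpus")
    docs = {g: tokenize(t, bigrams=bigrams) for g, t in corpus.items()}
    empty = [g for g, toks in docs.items() if not toks]
    if empty:
        raise ValueError(f"documents empty after tokenization: {empty[:5]}")
    vocab = sorted({t for toks in docs.values() for t in toks})
    index = {t: j for j, t in enumerate(vocab)}
    n_docs = len(docs)
    if n_docs == 1:
        warnings.warn("single-document corpus: all idf are 0 and clustering "
                      "is undefined")
    tf = np.zeros((n_docs, len(vocab)))
    genes = list(docs)
    for i, g in enumerate(genes):
        toks = docs[g]
        for t in toks:
            tf[i, index[t]] += 1
        tf[i] /= len(toks)
    df_counts = (tf > 0).sum(axis=0)
    if smooth:
        idf = np.log((1 + n_docs) / (1 + df_counts)) + 1.0
    else:
        idf = np.log(n_docs / df_counts)
    weights = pd.DataFrame(tf * idf[None, :], index=genes, columns=vocab)
    zero_rows = weights.index[(weights.to_numpy() == 0).all(axis=1)]
    if len(zero_rows):
        warnings.warn(f"documents with all-zero weights: {list(zero_rows)[:5]}")
    return TFIDFModel(weights=weights, idf=pd.Series(idf, index=vocab),
                      df_counts=pd.Series(df_counts, index=vocab))


def cosine_matrix(weights: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity; zero rows give 0 off and on the diagonal."""
    x = weights.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    sim = (x / safe[:, None]) @ (x / safe[:, None]).T
    sim = np.clip(sim, 0.0, 1.0)
    return pd.DataFrame(sim, index=weights.index, columns=weights.index)


def cluster(similarity: pd.DataFrame, k: int) -> pd.Series:
    """Cut an average-linkage tree on distance 1 - cosine into k clusters.

    Returns integer labels 1..k indexed by gene.  Deterministic: scipy's
    linkage on the condensed distance matrix has a fixed merge order, ties
    resolved by condensed-index order.
    """
    n = len(similarity)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == n:
        return pd.Series(range(1, n + 1), index=similarity.index)
    dist = 1.0 - similarity.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=similarity.index)


def cluster_keywords(model: TFIDFModel, assignments: pd.Series,
                     top_n: int = 10) -> dict[int, list[str]]:
    """Per-cluster keywords ranked by (mean weight inside) - (mean weight
    outside); only positive-score terms qualify."""
    out: dict[int, list[str]] = {}
    w = model.weights
    for c in sorted(assignments.unique()):
        inside = w.loc[assignments[assignments == c].index]
        outside = w.loc[assignments[assignments != c].index]
        score = inside.mean(axis=0)
        if len(outside):
            score = score - outside.mean(axis=0)
        score = score[score > 0].sort_values(ascending=False)
        out[int(c)] = list(score.head(top_n).index)
    return out


def cluster_table(model: TFIDFModel, assignments: pd.Series,
                  top_n: int = 10) -> pd.DataFrame:
    """Summary table: cluster ID, size, top words (cf. the keyword tables
    produced for gene-description clusterings)."""
    kw = cluster_keywords(model, assignments, top_n=top_n)
    rows = [{"cluster": c, "size": int((assignments == c).sum()),
             "top_words": ", ".join(words)} for c, words in kw.items()]
    return pd.DataFrame(rows)


def suggest_k(similarity: pd.DataFrame, k_range: Sequence[int] = range(2, 9)
              ) -> int:
    """Silhouette-based suggestion for the cluster count."""
    from sklearn.metrics import silhouette_score

    dist = 1.0 - similarity.to_numpy()
    np.fill_diagonal(dist, 0.0)
    best_k, best_s = 2, -np.inf
    for k in k_range:
        if k >= len(similarity):
            break
        labels = cluster(similarity, k)
        s = silhouette_score(np.maximum(dist, 0), labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    return best_k
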