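"""Sample clustering, label-association diagnostics and candidate reports.

Samples are compared by Pearson correlation of log2(normalized count + 1)
profiles, clustered by average-linkage agglomeration on 1 - r, and scored
for how strongly the correlation structure tracks the batch, treatment or
timepoint labels (mean within-label minus mean between-label correlation
with a seeded permutation p-value).  Candidate species are ranked from the
differential-expression table by p-value then absolute fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotate_quantify import CountMatrix


def correlation_matrix(m: CountMatrix | pd.DataFrame,
                       pseudocount: float = 1.0,
                       rna_class: str | None = None) -> pd.DataFrame:
    """Sample x sample Pearson correlation of log2(x + pseudocount).

    Zero-variance samples yield missing correlations (reported as NaN).
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    if rna_class is not None and isinstance(m, CountMatrix):
        counts = m.subset_class(rna_class).counts
    if counts.shape[1] < 2 or counts.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 species")
    logx = np.log2(counts + pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(logx.values.T)
    out = pd.DataFrame(corr, index=counts.columns, columns=counts.columns)
    np.fill_diagonal(out.values, 1.0)
    return out


@dataclass
class Dendrogram:
    linkage: np.ndarray        # scipy linkage matrix (average linkage)
    labels: list[str]

    def newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return (f"({walk(node.left)}:{node.dist - node.left.dist:.6g},"
                    f"{walk(node.right)}:{node.dist - node.right.dist:.6g})")

        return walk(root) + ";"

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def build_dendrogram(corr: pd.DataFrame) -> Dendrogram:
    """Average-linkage clustering on distance 1 - r.

    Requires a complete correlation matrix; ties between merges are broken
    deterministically by the (smallest-index) pair ordering of scipy's
    implementation.
    """
    if corr.isna().any().any():
        raise ValueError("correlation matrix has missing entries")
    d = 1.0 - corr.values
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(Z, list(corr.columns))


def average_linkage_bruteforce(corr: pd.DataFrame) -> list[tuple]:
    """Exhaustive average-linkage merges ((members_a, members_b, height));
    independent oracle for build_dendrogram."""
    labels = list(corr.columns)
    d = {(a, b): 1.0 - corr.loc[a, b] for a in labels for b in labels if a != b}
    clusters: list[tuple[str, ...]] = [(l,) for l in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = np.mean([d[(a, b)] for a in clusters[i]
                             for b in clusters[j]])
                key = (h, clusters[i], clusters[j])
                if best is None or key < best:
                    best = key
        h, ca, cb = best
        merges.append((ca, cb, h))
        clusters = [c for c in clusters if c not in (ca, cb)] + [ca + cb]
    return merges


@dataclass
class LabelAssociation:
    score: float          # mean within-label r minus mean between-label r
    p_value: float
    n_permutations: int


def label_association(corr: pd.DataFrame, labels: pd.Series,
                      n_permutations: int = 10_000,
                      seed: int = 0) -> LabelAssociation:
    """Association between correlation structure and a sample label.

    Labels with a single sample contribute no within-label pairs and are
    excluded from the within-label mean (with a warning).  The permutation
    p-value shuffles labels ``n_permutations`` times with the given seed;
    set ``n_permutations=0`` to skip it.
    """
    samples = list(corr.columns)
    lab = labels.reindex(samples)
    if lab.nunique() < 2:
        raise ValueError("need >= 2 distinct labels")
    singletons = [l for l, c in lab.value_counts().items() if c == 1]
    if singletons:
        warnings.warn(f"labels with a single sample excluded from "
                      f"within-label mean: {singletons}")
    r = corr.values
    iu = np.triu_indices(len(samples), k=1)
    rv = r[iu]

    def score_of(lv: np.ndarray) -> float:
        same = lv[iu[0]] == lv[iu[1]]
        if not same.any() or same.all():
            return 0.0
        return float(rv[same].mean() - rv[~same].mean())

    lv = lab.values
    obs = score_of(lv)
    if n_permutations <= 0:
        return LabelAssociation(obs, np.nan, 0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if score_of(rng.permutation(lv)) >= obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return LabelAssociation(obs, p, n_permutations)


def select_candidates(de: pd.DataFrame, max_candidates: int = 12,
                      p_threshold: float = 0.05) -> pd.DataFrame:
    """Rank species with p < threshold by p ascending, then |log2fc|
    descending, then species id; truncate to ``max_candidates`` and report
    the direction of change in the treated group."""
    if de.empty:
        return pd.DataFrame(columns=["p_value", "log2fc", "direction"])
    sel = de[de["p_value"] < p_threshold].copy()
    sel["_abs_fc"] = sel["log2fc"].abs()
    sel["_sid"] = sel.index  # deterministic final tie-break on species id
    sel = sel.sort_values(["p_value", "_abs_fc", "_sid"],
                          ascending=[True, False, True], kind="stable")
    sel = sel.drop(columns=["_abs_fc", "_sid"]).head(max_candidates)
    sel["direction"] = np.where(sel["log2fc"] > 0, "up", "down")
    return sel
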