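"""Quantifying allele-vs-species clustering.

The hallmark of trans-species polymorphism is that sequences cluster by
allelic lineage rather than by species: allele clades contain several
species, and the species labels are intermingled across the tree.  Two
complementary quantifications are provided:

* a parsimony permutation test: the Fitch parsimony score of the
  species labels on the tree is compared with the score distribution
  under label permutation.  A species-monophyletic tree attains the
  minimum possible score (number of species - 1); a score close to the
  permutation mean means species labels are as intermingled as random
  labels.  The "intermixing index"
  (observed - min) / (E[null] - min) is 0 for species monophyly and
  ~1 for full intermixing.  The emitted p-value is P(null <= observed):
  SMALL p means species cluster MORE than random (no trans-species
  signal); a trans-species data set has p near 1 and index near 1.

* DAPC (PCA followed by linear discriminant analysis on the retained
  components): on trans-species data, groups defined by allelic cluster
  separate cleanly while groups defined by species overlap, so the
  reassignment accuracy for allele-defined groups exceeds that for
  species-defined groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .seqio import Alignment
from .trees import fitch_score

__all__ = [
    "TranspeciesResult",
    "DAPCModel",
    "transpecies_test",
    "clade_species_sharing",
    "genotype_matrix",
    "dapc_fit",
]


@dataclass
class TranspeciesResult:
    observed_score: int
    min_possible: int
    null_scores: np.ndarray
    p_value: float              # P(null <= observed); small = species-clustered
    intermixing_index: float    # 0 = species-monophyletic, ~1 = fully intermixed
    index_ci: tuple[float, float]
    per_clade: pd.DataFrame
    stratified: bool


def _permute_within_strata(labels, strata, rng):
    labels = np.asarray(labels, dtype=object)
    out = labels.copy()
    for s in set(strata):
        idx = np.flatnonzero(np.asarray(strata, dtype=object) == s)
        out[idx] = rng.permutation(labels[idx])
    return out


def per_clade_table(tree: dendropy.Tree, species: dict[str, str]) -> pd.DataFrame:
    rows = []
    for k, nd in enumerate(tree.preorder_internal_node_iter()):
        leaves = [l.taxon.label for l in nd.leaf_iter()]
        if len(leaves) < 2:
            continue
        sp = sorted({species[l] for l in leaves})
        rows.append(
            {
                "clade": k,
                "n_leaves": len(leaves),
                "n_species": len(sp),
                "species": ",".join(sp),
            }
        )
    return pd.DataFrame(rows)


def transpecies_test(
    tree: dendropy.Tree,
    species: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
    clusters: dict[str, str] | None = None,
) -> TranspeciesResult:
    """Species-label parsimony permutation test.

    ``species`` maps leaf labels to species codes.  When ``clusters``
    is given (leaf -> paralog/cluster label) the permutation is
    stratified within clusters, so paralog structure itself does not
    masquerade as allelic trans-species signal; otherwise labels are
    shuffled across all leaves.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a usable null")
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    missing = [l for l in leaves if l not in species]
    if missing:
        raise ValueError(f"no species label for leaves {missing[:5]}")
    labels = [species[l] for l in leaves]
    n_species = len(set(labels))
    if n_species < 2:
        raise ValueError("need >=2 species")

    # with clusters, score each cluster's subtree and sum, so paralog
    # clades do not register as species intermixing on their own
    if clusters is not None:
        subtrees = []
        for cl in sorted(set(clusters[l] for l in leaves)):
            members = [l for l in leaves if clusters[l] == cl]
            if len(members) < 2:
                continue
            sub = tree.extract_tree_with_taxa_labels(members)
            sub_leaves = sorted(l.taxon.label for l in sub.leaf_node_iter())
            subtrees.append((sub, sub_leaves))
    else:
        subtrees = [(tree, leaves)]

    def total_score(label_of: dict[str, str]) -> tuple[int, int]:
        score = minimum = 0
        for sub, sub_leaves in subtrees:
            states = {l: label_of[l] for l in sub_leaves}
            s, _ = fitch_score(sub, states)
            score += s
            minimum += len(set(states.values())) - 1
        return score, minimum

    label_of = dict(zip(leaves, labels))
    observed, min_possible = total_score(label_of)

    strata = (
        [clusters[l] for l in leaves] if clusters is not None else [0] * len(leaves)
    )
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = _permute_within_strata(labels, strata, rng)
        null[b], _ = total_score(dict(zip(leaves, perm)))

    p_value = (1 + int((null <= observed).sum())) / (n_perm + 1)
    denom = null.mean() - min_possible
    if denom <= 0:
        index = 0.0 if observed == min_possible else float("nan")
        ci = (index, index)
    else:
        index = (observed - min_possible) / denom
        boots = np.empty(200)
        for b in range(200):
            resamp = rng.choice(null, size=null.size, replace=True)
            d = resamp.mean() - min_possible
            boots[b] = (observed - min_possible) / d if d > 0 else np.nan
        boots = boots[np.isfinite(boots)]
        ci = (
            (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
            if boots.size
            else (float("nan"), float("nan"))
        )

    return TranspeciesResult(
        observed_score=int(observed),
        min_possible=int(min_possible),
        null_scores=null,
        p_value=float(p_value),
        intermixing_index=float(index),
        index_ci=ci,
        per_clade=per_clade_table(tree, species),
        stratified=clusters is not None,
    )


def clade_species_sharing(
    clusters: dict[str, str], species: dict[str, str]
) -> pd.DataFrame:
    """Per cluster: number of distinct species; >=2 flags the cluster as
    trans-species."""
    rows = []
    for cl in sorted(set(clusters.values())):
        members = [cid for cid, c in clusters.items() if c == cl]
        sp = sorted({species[m] for m in members if m in species})
        rows.append(
            {
                "cluster": cl,
                "n_members": len(members),
                "n_species": len(sp),
                "species": ",".join(sp),
                "trans_species": len(sp) >= 2,
            }
        )
    return pd.DataFrame(rows)


def genotype_matrix(aln: Alignment, maf_min: int = 1, scale: bool = False):
    """Records x one-hot-allele indicator matrix over polymorphic sites.

    A site is retained when its second-most-frequent non-gap state
    occurs in >= ``maf_min`` sequences.  One indicator column per
    (site, allele); gaps give an all-zero block for that site.  Columns
    are mean-centered (and unit-scaled with ``scale=True``).

    Returns ``(X, feature_names, record_ids)``.
    """
    arr = aln.to_array()
    n, L = arr.shape
    feats = []
    cols = []
    for c in range(L):
        col = arr[:, c]
        vals, counts = np.unique(col[~np.isin(col, ("-", "N"))], return_counts=True)
        if len(vals) < 2:
            continue
        if sorted(counts)[-2] < maf_min:
            continue
        for v in vals:
            feats.append(f"{c + 1}{v}")
            cols.append((col == v).astype(float))
    if not cols:
        raise ValueError("no polymorphic sites pass the MAF filter")
    X = np.column_stack(cols)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    return X, feats, aln.ids


@dataclass
class DAPCModel:
    n_pca: int
    n_da: int
    groups: list[str]
    record_ids: list[str]
    pc_scores: np.ndarray          # records x n_pca
    da_coords: np.ndarray          # records x n_da
    posterior: np.ndarray          # records x n_groups
    assignments: list[str]
    accuracy: float                # fraction reassigned to their own group
    pca_eigenvalues: np.ndarray
    da_eigenvalues: np.ndarray
    group_order: list[str] = field(default_factory=list)


def dapc_fit(
    X: np.ndarray,
    groups: list[str],
    n_pca: int = 10,
    n_da: int = 3,
    record_ids: list[str] | None = None,
) -> DAPCModel:
    """Discriminant analysis of principal components.

    PCA by eigen-decomposition of the centered matrix, then LDA on the
    retained PC scores.  ``n_da`` is clamped to (groups - 1) with a
    warning.  The reproduction profile of the cathelicidin analysis
    retains 10 PCs and 3 discriminant functions.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if len(groups) != n:
        raise ValueError("groups length does not match matrix rows")
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValueError("need >=2 groups")
    rank = min(n - 1, X.shape[1])
    if n_pca > rank:
        warnings.warn(f"n_pca={n_pca} exceeds rank {rank}; clamped", stacklevel=2)
        n_pca = rank
    max_da = len(uniq) - 1
    if n_da > max_da:
        warnings.warn(f"n_da={n_da} exceeds groups-1={max_da}; clamped", stacklevel=2)
        n_da = max_da

    pca = PCA(n_components=n_pca, svd_solver="full")
    scores = pca.fit_transform(X)
    n_da = min(n_da, min(n_pca, max_da))
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    coords = lda.fit_transform(scores, groups)
    posterior = lda.predict_proba(scores)
    pred = list(lda.predict(scores))
    acc = float(np.mean([p == g for p, g in zip(pred, groups)]))
    ev = getattr(lda, "explained_variance_ratio_", np.array([]))
    return DAPCModel(
        n_pca=n_pca,
        n_da=n_da,
        groups=list(groups),
        record_ids=list(record_ids) if record_ids is not None else [],
        pc_scores=scores,
        da_coords=coords,
        posterior=posterior,
        assignments=pred,
        accuracy=acc,
        pca_eigenvalues=pca.explained_variance_,
        da_eigenvalues=np.asarray(ev),
        group_order=list(lda.classes_),
    )
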