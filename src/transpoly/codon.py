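"""Counting-based per-codon selection test (SLAC-style).

For each codon column of a coding alignment the test
(1) reconstructs ancestral codons on a supplied tree by Fitch
    parsimony over the 61 sense codons (deterministic tie-break:
    first codon in lexicographic order),
(2) counts observed synonymous (s) and non-synonymous (n) changes per
    branch by Nei-Gojobori pathway counting, averaging over all
    orderings of the differing positions and excluding pathways through
    stop codons, and
(3) compares the observed split (n, s) to the expected non-synonymous
    fraction EN/(EN+ES) with one-tailed binomial probabilities, where
    ES/EN are the synonymous/non-synonymous site counts averaged over
    the codons at all nodes (observed and reconstructed, weighted
    equally).

dN = n/EN, dS = s/ES; positive dN - dS with small p_pos suggests
diversifying selection at that codon, negative with small p_neg
purifying selection.  Codons containing a gap in any sequence are
excluded region-wide before the scan so every retained codon is scored
on the full sequence set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import special

import dendropy

from .seqio import Alignment
from .trees import fitch_score

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonSiteResult",
    "ng_codon_sites",
    "pathway_counts",
    "slac_site_test",
    "region_scan",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


def translate(codon: str) -> str:
    return _AA[codon]


@dataclass(frozen=True)
class CodonSiteResult:
    codon_index: int       # 1-based within the analyzed region
    ES: float              # expected synonymous sites (tree-averaged)
    EN: float              # expected non-synonymous sites
    s_obs: float           # observed synonymous changes (all branches)
    n_obs: float
    dS: float
    dN: float
    dn_minus_ds: float
    p_pos: float           # P(X >= n_obs): evidence for diversifying selection
    p_neg: float           # P(X <= n_obs): evidence for purifying selection
    excluded: bool = False
    note: str = ""


def _neighbors(codon: str):
    for pos in range(3):
        for b in _BASES:
            if b != codon[pos]:
                yield codon[:pos] + b + codon[pos + 1:]


def ng_codon_sites(codon: str) -> tuple[float, float]:
    """Nei-Gojobori synonymous/non-synonymous site counts for one codon.

    Each of the 9 single-nucleotide neighbors is classified; neighbors
    that are stop codons are excluded from the denominator.  Returns
    ``(ES, EN)`` with ES + EN <= 3.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r}")
    aa = _AA[codon]
    syn = nonsyn = 0
    for nb in _neighbors(codon):
        if nb in STOP_CODONS:
            continue
        if _AA[nb] == aa:
            syn += 1
        else:
            nonsyn += 1
    return 3 * syn / 9, 3 * nonsyn / 9


def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/non-synonymous step counts over all mutational
    pathways between two codons.

    Pathways passing through a stop codon are excluded; if every
    pathway is illegal the average is taken over all pathways (flagged
    by returning the counts anyway — s + n still equals the Hamming
    distance).
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c in STOP_CODONS or len(c) != 3 or any(x not in _BASES for x in c):
            raise ValueError(f"invalid or stop codon {c!r}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    legal, all_paths = [], []
    for order in itertools.permutations(diff):
        cur = a
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
            steps.append((cur, nxt))
            cur = nxt
        counts = None
        if ok:
            s = sum(1 for x, y in steps if _AA[x] == _AA[y])
            legal.append((s, len(steps) - s))
        else:
            # count steps not involving stops for the fallback
            s = sum(
                1
                for x, y in steps
                if x not in STOP_CODONS and y not in STOP_CODONS and _AA[x] == _AA[y]
            )
            all_paths.append((s, len(steps) - s))
    pool = legal if legal else all_paths
    s = float(np.mean([p[0] for p in pool]))
    n = float(np.mean([p[1] for p in pool]))
    return s, n


def _binomial_tails(n_obs: float, total: float, p: float):
    """One-tailed binomial probabilities including the point mass,
    generalized to the fractional counts pathway-averaging produces via
    the regularized incomplete beta function."""
    if total <= 0:
        return 1.0, 1.0
    k = float(n_obs)
    N = float(total)
    # P(X >= k) = I_p(k, N - k + 1); P(X <= k) = 1 - I_p(k + 1, N - k)
    p_pos = 1.0 if k <= 0 else float(special.betainc(k, N - k + 1, p))
    p_neg = 1.0 if k >= N else float(1.0 - special.betainc(k + 1, N - k, p))
    return min(p_pos, 1.0), min(p_neg, 1.0)


def _leaf_codons(aln: Alignment, codon_cols) -> dict[str, str]:
    out = {}
    for rec in aln.records:
        out[rec.id] = "".join(rec.sequence[c] for c in codon_cols)
    return out


def slac_site_test(
    aln: Alignment, tree: dendropy.Tree, codon_cols, codon_index: int = 1
) -> CodonSiteResult:
    """Run the counting test at one codon (three alignment columns).

    The tree's leaf labels must match the alignment record ids.  Codons
    with gaps/N or stop codons in any sequence are reported as
    excluded.
    """
    leaf_codons = _leaf_codons(aln, codon_cols)
    tree_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if tree_leaves != set(leaf_codons):
        raise ValueError("tree leaf labels do not match alignment record ids")

    bad = {
        cid: cod
        for cid, cod in leaf_codons.items()
        if any(ch not in _BASES for ch in cod) or cod in STOP_CODONS
    }
    if bad:
        return CodonSiteResult(
            codon_index=codon_index, ES=np.nan, EN=np.nan, s_obs=np.nan,
            n_obs=np.nan, dS=np.nan, dN=np.nan, dn_minus_ds=np.nan,
            p_pos=np.nan, p_neg=np.nan, excluded=True,
            note=f"gap/ambiguous/stop codon in {len(bad)} record(s)",
        )

    # Fitch parsimony over codon states; min() of the candidate set is
    # the first codon in lexicographic order (fixed codon ordering)
    _, assignment = fitch_score(tree, leaf_codons)

    node_codon: dict[int, str] = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            node_codon[id(nd)] = leaf_codons[nd.taxon.label]
        else:
            node_codon[id(nd)] = assignment[id(nd)]

    s_obs = n_obs = 0.0
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        s, n = pathway_counts(node_codon[id(nd.parent_node)], node_codon[id(nd)])
        s_obs += s
        n_obs += n

    site_counts = [ng_codon_sites(c) for c in node_codon.values()]
    ES = float(np.mean([c[0] for c in site_counts]))
    EN = float(np.mean([c[1] for c in site_counts]))

    dS = s_obs / ES if ES > 0 else (0.0 if s_obs == 0 else np.inf)
    dN = n_obs / EN if EN > 0 else (0.0 if n_obs == 0 else np.inf)
    total = s_obs + n_obs
    p_pos, p_neg = _binomial_tails(n_obs, total, EN / (EN + ES))
    return CodonSiteResult(
        codon_index=codon_index, ES=ES, EN=EN, s_obs=s_obs, n_obs=n_obs,
        dS=dS, dN=dN, dn_minus_ds=dN - dS, p_pos=p_pos, p_neg=p_neg,
    )


def region_codons(aln: Alignment, region_cols) -> list[tuple[int, ...]]:
    """Split region columns into codon triples and exclude, region-wide,
    every codon containing a gap/N or stop in any sequence.

    The region length must be divisible by 3 (reading frame starts at
    the first region column).  Returns the retained triples in order;
    downstream numbering (codon 1, 2, ...) refers to this list.
    """
    cols = sorted(region_cols)
    if len(cols) % 3 != 0:
        raise ValueError(
            f"region length {len(cols)} is not divisible by 3; cannot set a reading frame"
        )
    triples = [tuple(cols[i: i + 3]) for i in range(0, len(cols), 3)]
    kept = []
    for tri in triples:
        ok = True
        for rec in aln.records:
            cod = "".join(rec.sequence[c] for c in tri)
            if any(ch not in _BASES for ch in cod) or cod in STOP_CODONS:
                ok = False
                break
        if ok:
            kept.append(tri)
    return kept


def region_scan(
    aln: Alignment, tree: dendropy.Tree, region_cols, alpha: float = 0.05,
    report_alpha: float = 0.2,
) -> pd.DataFrame:
    """Counting test over every analyzable codon of a region.

    Codon 1 is the first codon after region-wide exclusion of
    gap-containing codons.  Flags are set at p < ``alpha`` (0.05) and
    the looser reporting threshold p < ``report_alpha`` (0.2).
    """
    triples = region_codons(aln, region_cols)
    rows = []
    for i, tri in enumerate(triples, start=1):
        res = slac_site_test(aln, tree, tri, codon_index=i)
        d = res.__dict__.copy()
        d["pos_significant"] = bool(res.p_pos < alpha) if np.isfinite(res.p_pos) else False
        d["neg_significant"] = bool(res.p_neg < alpha) if np.isfinite(res.p_neg) else False
        d["pos_reported"] = bool(res.p_pos < report_alpha) if np.isfinite(res.p_pos) else False
        d["neg_reported"] = bool(res.p_neg < report_alpha) if np.isfinite(res.p_neg) else False
        rows.append(d)
    return pd.DataFrame(rows)
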