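"""Pairwise linkage disequilibrium D' with count-based MAF filtering.

The clone sequences are haploid haplotypes, so gametic frequencies are
observed directly.  Minor-allele-frequency filtering is by count (e.g.
2 of 22 haplotypes, or 3 of 36), mirroring how LD heatmaps of
high-frequency polymorphic sites are usually specified for small clone
libraries.

For two biallelic sites with major alleles A, B at frequencies p_A,
p_B and gamete frequency p_AB:

    D  = p_AB - p_A * p_B
    D' = D / Dmax,   Dmax = min(p_A (1-p_B), (1-p_A) p_B)        if D > 0
                     Dmax = min(p_A p_B, (1-p_A)(1-p_B))         if D < 0
    D' = 0 when D = 0.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import Alignment

__all__ = ["LDResult", "biallelic_sites", "dprime_pair", "ld_matrix"]

_MISSING = ("-", "N")


@dataclass(frozen=True)
class LDResult:
    site_i: int        # 1-based alignment columns
    site_j: int
    p_A: float         # major-allele frequency at site i
    p_B: float         # major-allele frequency at site j
    D: float
    D_prime: float
    n_haplotypes: int


def biallelic_sites(aln: Alignment, maf_min: int = 1) -> list[int]:
    """0-based columns with exactly two non-gap states, minor count >=
    ``maf_min``; columns containing any gap or N are excluded."""
    if maf_min < 1:
        raise ValueError("maf_min must be >= 1")
    arr = aln.to_array()
    out = []
    for c in range(arr.shape[1]):
        col = arr[:, c]
        if np.isin(col, _MISSING).any():
            continue
        counts = Counter(col.tolist())
        if len(counts) != 2:
            continue
        minor = min(counts.values())
        if minor >= maf_min:
            out.append(c)
    return out


def _pair_haplotypes(arr: np.ndarray, a: int, b: int) -> list[tuple[str, str]]:
    """Two-site haplotypes, dropping sequences with a gap/N at either
    site (pairwise deletion)."""
    haps = []
    for row in arr:
        x, y = row[a], row[b]
        if x in _MISSING or y in _MISSING:
            continue
        haps.append((x, y))
    return haps


def _major_allele(values) -> str:
    counts = Counter(values)
    # deterministic: highest count, alphabetical tie-break
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def dprime_pair(haplotypes: list[tuple[str, str]], site_i=0, site_j=0) -> LDResult:
    """D and D' from two-site haplotypes (both sites must be biallelic)."""
    if not haplotypes:
        raise ValueError("no haplotypes")
    xs = [h[0] for h in haplotypes]
    ys = [h[1] for h in haplotypes]
    if len(set(xs)) != 2 or len(set(ys)) != 2:
        raise ValueError("both sites must be biallelic over the haplotype set")
    A = _major_allele(xs)
    B = _major_allele(ys)
    n = len(haplotypes)
    p_A = xs.count(A) / n
    p_B = ys.count(B) / n
    p_AB = sum(1 for x, y in haplotypes if x == A and y == B) / n
    D = p_AB - p_A * p_B
    if abs(D) < 1e-15:
        dprime = 0.0
    elif D > 0:
        dmax = min(p_A * (1 - p_B), (1 - p_A) * p_B)
        dprime = D / dmax
    else:
        dmax = min(p_A * p_B, (1 - p_A) * (1 - p_B))
        dprime = D / dmax
    return LDResult(
        site_i=site_i,
        site_j=site_j,
        p_A=p_A,
        p_B=p_B,
        D=D,
        D_prime=float(np.clip(dprime, -1.0, 1.0)),
        n_haplotypes=n,
    )


def ld_matrix(aln: Alignment, maf_min: int = 1) -> pd.DataFrame:
    """All-pairs D' over retained biallelic sites.

    Long-format frame (site_i, site_j, p_A, p_B, D, D_prime, n) with
    1-based columns, ordered by alignment position (upper triangle).
    """
    sites = biallelic_sites(aln, maf_min)
    if len(sites) < 2:
        warnings.warn("fewer than 2 sites pass the MAF filter; empty LD matrix",
                      stacklevel=2)
        return pd.DataFrame(
            columns=["site_i", "site_j", "p_A", "p_B", "D", "D_prime", "n_haplotypes"]
        )
    arr = aln.to_array()
    rows = []
    for a, b in itertools.combinations(sites, 2):
        haps = _pair_haplotypes(arr, a, b)
        try:
            res = dprime_pair(haps, site_i=a + 1, site_j=b + 1)
        except ValueError:
            continue  # monomorphic after pairwise deletion
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def ld_square(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format LD frame into a heatmap-ready square matrix."""
    if df.empty:
        return pd.DataFrame()
    sites = sorted(set(df["site_i"]) | set(df["site_j"]))
    mat = pd.DataFrame(np.nan, index=sites, columns=sites)
    for _, r in df.iterrows():
        mat.loc[r["site_i"], r["site_j"]] = r["D_prime"]
    return mat
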