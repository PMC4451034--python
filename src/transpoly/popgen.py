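"""Nucleotide diversity, Watterson's theta, Tajima's D and the
four-gamete test, per region and in sliding windows.

Window defaults (100 bp, 25 bp step) match the sliding-window profiles
used for the cathelicidin clusters.  Gap handling is complete deletion
per window: any column containing a gap or N in any included sequence
is dropped, and the number of retained columns is reported as
``n_sites_used``.  Per-site values are totals divided by
``n_sites_used``; windows with fewer than 10 usable columns are flagged
low-confidence.  |D| > 2 is flagged as significant, the working
threshold for the balancing/purifying-selection peaks in exon 4.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ld import biallelic_sites, _pair_haplotypes
from .seqio import Alignment

__all__ = [
    "SiteStats",
    "WindowStat",
    "site_stats",
    "tajimas_D",
    "watterson_theta",
    "sliding_windows",
    "windows_to_frame",
    "four_gamete_pairs",
]

LOW_CONFIDENCE_SITES = 10
SIGNIFICANT_ABS_D = 2.0


@dataclass(frozen=True)
class SiteStats:
    S: int                # segregating sites among retained columns
    pi_total: float       # mean pairwise differences (total over columns)
    n: int                # number of sequences
    n_sites_used: int     # gap-free columns retained


@dataclass(frozen=True)
class WindowStat:
    start: int            # alignment columns, 0-based half-open
    end: int
    n_sites_used: int
    S: int
    pi: float             # per site
    theta_w: float        # per site
    tajima_D: float       # nan when undefined (S == 0)
    low_confidence: bool
    significant: bool     # |D| > 2


def _usable_columns(arr: np.ndarray, columns=None) -> np.ndarray:
    L = arr.shape[1]
    mask = np.zeros(L, dtype=bool)
    if columns is None:
        mask[:] = True
    else:
        cols = np.asarray(sorted(columns), dtype=int)
        if len(cols) and (cols[0] < 0 or cols[-1] >= L):
            raise ValueError("columns outside alignment")
        mask[cols] = True
    gap_free = ~np.isin(arr, ("-", "N")).any(axis=0)
    return mask & gap_free


def site_stats(aln: Alignment, columns=None) -> SiteStats:
    """Segregating sites and total pairwise diversity over ``columns``.

    Columns containing any gap/N are excluded (complete deletion).
    ``pi_total`` is the average over all sequence pairs of the number of
    differing retained columns.
    """
    if aln.n < 2:
        raise ValueError("need >=2 sequences")
    arr = aln.to_array()
    keep = _usable_columns(arr, columns)
    sub = arr[:, keep]
    n, m = sub.shape
    S = int(sum(len(set(sub[:, c])) > 1 for c in range(m)))
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int((sub[i] != sub[j]).sum())
            npairs += 1
    pi_total = total / npairs
    return SiteStats(S=S, pi_total=pi_total, n=n, n_sites_used=m)


def _tajima_coefficients(n: int):
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_D(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from totals; ``nan`` when undefined (S == 0)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if S == 0:
        return float("nan")
    a1, e1, e2 = _tajima_coefficients(n)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_total - S / a1) / np.sqrt(var)


def watterson_theta(S: int, n: int, n_sites_used: int) -> float:
    """Watterson's theta per site: S / (a1 * sites)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if n_sites_used == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    return S / (a1 * n_sites_used)


def _window_stat(aln: Alignment, start: int, end: int) -> WindowStat:
    st = site_stats(aln, columns=range(start, end))
    m = st.n_sites_used
    pi = st.pi_total / m if m else float("nan")
    th = watterson_theta(st.S, st.n, m) if m else float("nan")
    D = tajimas_D(st.S, st.pi_total, st.n)
    return WindowStat(
        start=start,
        end=end,
        n_sites_used=m,
        S=st.S,
        pi=pi,
        theta_w=th,
        tajima_D=D,
        low_confidence=m < LOW_CONFIDENCE_SITES,
        significant=bool(np.isfinite(D) and abs(D) > SIGNIFICANT_ABS_D),
    )


def sliding_windows(
    aln: Alignment,
    window: int = 100,
    step: int = 25,
    keep_tail: bool = False,
    columns=None,
) -> list[WindowStat]:
    """Window statistics over the alignment (or a column subset).

    Windows start at 0, step, 2*step, ...; a trailing short window is
    emitted only with ``keep_tail``.  A window longer than the
    alignment yields one full-length window with a warning.

    ``columns``: optional subset of alignment columns (e.g. one gene
    region); windows are then taken along the subset in order.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    if columns is not None:
        aln = aln.take_columns(columns)
    L = aln.length
    if window > L:
        warnings.warn(
            f"window {window} exceeds alignment length {L}; using one full-length window",
            stacklevel=2,
        )
        return [_window_stat(aln, 0, L)]
    out = []
    start = 0
    while start + window <= L:
        out.append(_window_stat(aln, start, start + window))
        start += step
    if keep_tail and start < L:
        out.append(_window_stat(aln, start, L))
    return out


def windows_to_frame(stats: list[WindowStat]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in stats])
    if not df.empty:
        # user-facing coordinates are 1-based inclusive
        df.insert(0, "start_1based", df.pop("start") + 1)
        df.insert(1, "end_1based", df.pop("end"))
    return df


def four_gamete_pairs(aln: Alignment, maf_min: int = 1) -> list[tuple[int, int]]:
    """Pairs of biallelic sites (0-based columns) showing all four
    haplotype combinations — evidence of recombination or recurrent
    mutation."""
    sites = biallelic_sites(aln, maf_min)
    arr = aln.to_array()
    out = []
    for a, b in itertools.combinations(sites, 2):
        haps = _pair_haplotypes(arr, a, b)
        if len(set(haps)) == 4:
            out.append((a, b))
    return out
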