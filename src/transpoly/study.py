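"""Published sampling design of the cod cathelicidin clone-library study.

The study cloned and Sanger-sequenced a cathelicidin amplicon from 27
individuals — 19 Atlantic cod (Gmo) plus two each of Polar cod (Bsa),
Greenland cod (Gog), Pacific cod (Gma) and Walleye pollock (Gch) — with
(mostly) three PCR clones per individual and more for individuals whose
clones showed several fragment sizes.  This module encodes that design
table verbatim: per individual the barcode, origin, number of clones
sequenced and number of distinct forms/alleles found.

Note the published table is internally inconsistent: its per-row clone
counts sum to 99, while its totals row and the running text state 97
clones.  Both numbers are exposed; the forms column sums to 43,
matching the 43 representative sequences that were analyzed and
deposited (GenBank KJ831349-KJ831391).
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = [
    "SAMPLING_DESIGN",
    "PUBLISHED_TOTAL_CLONES",
    "PUBLISHED_TOTAL_INDIVIDUALS",
    "CLONE_COUNT_COLUMN",
    "design_frame",
    "accession_range_size",
    "DEPOSITED_ACCESSIONS",
]

# (barcode, species, locality, clones sequenced, forms/alleles found)
SAMPLING_DESIGN: tuple[tuple[str, str, str, int, int], ...] = (
    ("105746", "Gmo", "Gre", 3, 2),
    ("104931", "Gmo", "Gre", 3, 2),
    ("140254", "Gmo", "Bar", 3, 1),
    ("140272", "Gmo", "Bar", 8, 3),
    ("118507", "Gmo", "Ice", 12, 3),
    ("125968", "Gmo", "Ice", 3, 2),
    ("118214", "Gmo", "Ice", 3, 1),
    ("117795", "Gmo", "Ice", 3, 1),
    ("117757", "Gmo", "Ice", 3, 1),
    ("140179", "Gmo", "Cel", 3, 2),
    ("140176", "Gmo", "Cel", 3, 1),
    ("140219", "Gmo", "Bal", 3, 1),
    ("140233", "Gmo", "Bal", 3, 1),
    ("152921", "Gmo", "Nor", 3, 1),
    ("152924", "Gmo", "Nor", 3, 1),
    ("115574", "Gmo", "Far", 2, 2),
    ("114718", "Gmo", "Far", 6, 2),
    ("200093", "Gmo", "Can", 6, 2),
    ("200079", "Gmo", "Can", 3, 2),
    ("103659", "Bsa", "Gre", 3, 1),
    ("104725", "Bsa", "Gre", 2, 1),
    ("103852", "Gog", "Gre", 3, 1),
    ("104947", "Gog", "Gre", 3, 1),
    ("152074", "Gma", "Pac", 3, 2),
    ("152050", "Gma", "Pac", 3, 2),
    ("152018", "Gch", "Pac", 3, 1),
    ("152027", "Gch", "Pac", 3, 3),
)

PUBLISHED_TOTAL_CLONES = 97       # totals row / running text
PUBLISHED_TOTAL_INDIVIDUALS = 27

CLONE_COUNT_COLUMN: tuple[int, ...] = tuple(r[3] for r in SAMPLING_DESIGN)

DEPOSITED_ACCESSIONS = ("KJ831349", "KJ831391")  # inclusive GenBank range


def design_frame() -> pd.DataFrame:
    df = pd.DataFrame(
        SAMPLING_DESIGN,
        columns=["barcode", "species", "locality", "n_clones", "n_forms"],
    )
    df["origin"] = df["species"] + "." + df["locality"]
    return df


def accession_range_size(first: str = None, last: str = None) -> int:
    """Number of accessions in an inclusive GenBank range like
    KJ831349-KJ831391 (same alphabetic prefix assumed)."""
    first = first or DEPOSITED_ACCESSIONS[0]
    last = last or DEPOSITED_ACCESSIONS[1]
    pre1 = re.match(r"[A-Za-z]+", first).group(0)
    pre2 = re.match(r"[A-Za-z]+", last).group(0)
    if pre1 != pre2:
        raise ValueError("accession prefixes differ")
    a = int(first[len(pre1):])
    b = int(last[len(pre2):])
    return b - a + 1
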