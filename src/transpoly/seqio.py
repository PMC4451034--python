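"""Sequence and annotation I/O.

Clone libraries are shipped as aligned multi-FASTA where each record id
encodes the sampled individual, clone, species and locality as
``<barcode>-<clone>.<species>.<locality>`` (e.g. ``105746-3.Gmo.Gre``).
A six-digit barcode identifies the individual; the clone number
distinguishes independent PCR clones from that individual.  Some data
sets use ``_`` instead of ``-`` as the clone separator; both are
accepted and the canonical form uses ``-``.

Gene annotations (UTRs, exons, introns) are given on the ungapped
reference sequence in 0-based half-open coordinates and are projected
onto alignment columns so that statistics can be restricted to, say,
exon 4 (the variable antimicrobial peptide) versus exons 1-3 (the
conserved cathelin domain).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CloneRecord",
    "Alignment",
    "GeneAnnotation",
    "CloneLabelError",
    "parse_clone_label",
    "format_clone_label",
    "read_alignment",
    "write_alignment",
    "read_annotation",
    "project_annotation",
]

ALLOWED_CHARS = frozenset("ACGTN-")

_LABEL_RE = re.compile(
    r"^(?P<barcode>\d{6})"
    r"(?:[-_](?P<clone>\d{1,2}|cons))?"
    r"\.(?P<species>[A-Za-z][A-Za-z0-9]*)"
    r"\.(?P<locality>[A-Za-z][A-Za-z0-9]*)$"
)

KNOWN_SPECIES = ("Gmo", "Gma", "Gog", "Gch", "Bsa")
KNOWN_LOCALITIES = ("Ice", "Gre", "Bar", "Cel", "Bal", "Nor", "Far", "Can", "Pac")


class CloneLabelError(ValueError):
    """Raised when a clone label does not follow the naming convention."""


@dataclass(frozen=True)
class CloneRecord:
    """One cloned sequence plus its parsed sample metadata.

    ``barcode``/``species``/``locality`` are ``None`` for records whose
    id does not follow the naming convention; such records still take
    part in all sequence-level computations.
    """

    id: str
    sequence: str
    barcode: str | None = None
    clone_number: int | None = None
    species: str | None = None
    locality: str | None = None
    is_consensus: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.barcode is not None and not re.fullmatch(r"\d{6}", self.barcode):
            raise ValueError(
                f"record {self.id!r}: barcode {self.barcode!r} is not 6 digits"
            )

    @property
    def has_metadata(self) -> bool:
        return self.barcode is not None

    def canonical_id(self) -> str:
        if not self.has_metadata:
            return self.id
        return format_clone_label(
            self.barcode,
            "cons" if self.is_consensus else self.clone_number,
            self.species,
            self.locality,
        )


def parse_clone_label(label: str):
    """Parse ``<barcode>-<clone>.<species>.<locality>`` into its parts.

    Returns ``(barcode, clone_number, species, locality)`` where
    ``clone_number`` is ``None`` for consensus records (clone token
    ``cons``) or labels without a clone token.  Both ``-`` and ``_``
    clone separators are accepted.
    """
    if not label:
        raise CloneLabelError("empty label")
    m = _LABEL_RE.match(label)
    if m is None:
        # best-effort diagnosis of the offending token
        parts = label.split(".")
        if len(parts) != 3:
            raise CloneLabelError(
                f"label {label!r}: expected 3 dot-separated fields "
                f"(<barcode>-<clone>.<species>.<locality>), got {len(parts)}"
            )
        head = parts[0]
        if not re.match(r"^\d{6}([-_]|$)", head):
            raise CloneLabelError(
                f"label {label!r}: token {head!r} does not start with a 6-digit barcode"
            )
        raise CloneLabelError(f"label {label!r}: malformed clone/species/locality token")
    clone_tok = m.group("clone")
    clone = None if clone_tok in (None, "cons") else int(clone_tok)
    return m.group("barcode"), clone, m.group("species"), m.group("locality")


def format_clone_label(barcode, clone, species, locality) -> str:
    """Canonical label with ``-`` separator; ``clone`` may be an int,
    ``"cons"`` or ``None`` (omitted)."""
    mid = "" if clone is None else f"-{clone}"
    return f"{barcode}{mid}.{species}.{locality}"


def _record_from_label(label: str, seq: str) -> CloneRecord:
    try:
        barcode, clone, species, locality = parse_clone_label(label)
    except CloneLabelError:
        return CloneRecord(id=label, sequence=seq)
    return CloneRecord(
        id=label,
        sequence=seq,
        barcode=barcode,
        clone_number=clone,
        species=species,
        locality=locality,
        is_consensus=label.split(".")[0].endswith("cons"),
    )


@dataclass
class Alignment:
    """Ordered gapped sequences of equal length ('-' is the gap char)."""

    records: list[CloneRecord]

    def __post_init__(self):
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            offenders = sorted({r.id: len(r.sequence) for r in self.records}.items())
            raise ValueError(f"ragged alignment: lengths per record {offenders}")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self):
        return len(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def to_array(self) -> np.ndarray:
        """(n, length) array of single characters."""
        return np.array([list(r.sequence) for r in self.records], dtype="U1")

    def subset(self, ids=None, indices=None) -> "Alignment":
        if ids is not None:
            wanted = set(ids)
            recs = [r for r in self.records if r.id in wanted]
        else:
            recs = [self.records[i] for i in indices]
        return Alignment(recs)

    def take_columns(self, columns) -> "Alignment":
        cols = sorted(columns)
        recs = [
            replace(r, sequence="".join(r.sequence[c] for c in cols))
            for r in self.records
        ]
        return Alignment(recs)

    def replace_sequences(self, seqs: dict[str, str]) -> "Alignment":
        recs = [
            replace(r, sequence=seqs.get(r.id, r.sequence)) for r in self.records
        ]
        return Alignment(recs)


def _clean_sequence(raw: str, rec_id: str) -> str:
    seq = str(raw).upper().replace("U", "T")
    bad = set(seq) - ALLOWED_CHARS
    if bad:
        raise ValueError(
            f"record {rec_id!r}: unsupported characters {sorted(bad)} "
            "(only A,C,G,T,N,- are accepted; IUPAC ambiguity codes must be "
            "resolved upstream)"
        )
    return seq


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file.

    Records whose ids follow the clone naming convention get parsed
    metadata; nonconforming ids are kept with null metadata and a
    warning.  Ragged lengths raise with the offending record ids.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(rec.seq), rec.id)
        cr = _record_from_label(rec.id, seq)
        if not cr.has_metadata:
            warnings.warn(
                f"record {rec.id!r} does not follow "
                "<barcode>-<clone>.<species>.<locality>; kept without metadata",
                stacklevel=2,
            )
        records.append(cr)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment(records)


def write_alignment(aln: Alignment, path) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in aln.records]
    SeqIO.write(recs, str(path), "fasta")


REGION_NAMES = (
    "UTR5",
    "exon1",
    "intron1",
    "exon2",
    "intron2",
    "exon3",
    "intron3",
    "exon4",
    "UTR3",
)


@dataclass
class GeneAnnotation:
    """Exon/intron/UTR intervals on an ungapped reference.

    ``regions`` is a list of ``(name, start, end)`` with 0-based
    half-open coordinates, non-overlapping and sorted.
    """

    regions: list[tuple[str, int, int]]
    reference_id: str = ""

    def __post_init__(self):
        prev_end = 0
        for name, start, end in self.regions:
            if not (0 <= start < end):
                raise ValueError(f"region {name}: bad interval [{start}, {end})")
            if start < prev_end:
                raise ValueError(f"region {name}: overlaps/unsorted at {start}")
            prev_end = end

    @property
    def names(self) -> list[str]:
        return [r[0] for r in self.regions]

    @property
    def reference_length(self) -> int:
        return self.regions[-1][2] if self.regions else 0

    def region(self, name: str) -> tuple[int, int]:
        for n, s, e in self.regions:
            if n == name:
                return s, e
        raise KeyError(f"region {name!r} not annotated")

    def exon_names(self) -> list[str]:
        return [n for n in self.names if n.startswith("exon")]


def read_annotation(path) -> GeneAnnotation:
    """Read a BED-like TSV (name, start, end) or a JSON annotation."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        regions = [(r["name"], int(r["start"]), int(r["end"])) for r in data["regions"]]
        return GeneAnnotation(regions, data.get("reference_id", ""))
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            name, start, end = line.split("\t")[:3]
            regions.append((name, int(start), int(end)))
    return GeneAnnotation(regions)


def write_annotation(ann: GeneAnnotation, path) -> None:
    with open(str(path), "w") as fh:
        fh.write("name\tstart\tend\n")
        for name, s, e in ann.regions:
            fh.write(f"{name}\t{s}\t{e}\n")


def reference_column_map(aln: Alignment, ref_row: str) -> np.ndarray:
    """Alignment column of each ungapped reference position (a bijection
    between reference positions and a subset of columns)."""
    ref = aln[ref_row].sequence
    return np.array([i for i, ch in enumerate(ref) if ch != "-"], dtype=int)


def project_annotation(
    ann: GeneAnnotation, aln: Alignment, ref_row: str
) -> dict[str, list[int]]:
    """Map each annotated region to the set of alignment columns it covers.

    Insertion columns relative to the reference are assigned to the
    region of the preceding reference base (leading insertions to the
    first region).  Raises if the ungapped reference does not span the
    annotation.
    """
    colmap = reference_column_map(aln, ref_row)
    ref_len = len(colmap)
    if ref_len < ann.reference_length:
        raise ValueError(
            f"annotation spans {ann.reference_length} bp but ungapped "
            f"reference {ref_row!r} has only {ref_len} bp"
        )
    # region of each reference position (None = unannotated)
    region_of_ref = [None] * ref_len
    for name, s, e in ann.regions:
        for p in range(s, e):
            region_of_ref[p] = name

    out: dict[str, list[int]] = {name: [] for name in ann.names}
    # assign every column: reference columns by their position's region,
    # insertion columns by the preceding reference base's region
    # (leading insertions fall to the first region)
    current_region = ann.names[0] if ann.names else None
    col_to_refpos = {int(c): p for p, c in enumerate(colmap)}
    for col in range(aln.length):
        if col in col_to_refpos:
            current_region = region_of_ref[col_to_refpos[col]]
        if current_region is not None:
            out[current_region].append(col)
    return out
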