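"""PCR-error screening and representative selection for clone libraries.

PCR polymerase errors appear in cloned amplicons mostly as singleton
sites.  The screening rule works within groups of clones from the same
individual that belong to the same cluster (paralog): a column where
exactly one clone of a group differs from the rest is a singleton
candidate, treated as a PCR error and masked to the group-majority
base — UNLESS the same column is also variable among the clones of at
least one other individual in the same cluster, in which case the
variant is retained as a real SNP (recurrence across individuals is
evidence against independent polymerase error).  Groups of size 1
provide no within-individual evidence and are never masked.

After screening, identical corrected sequences within an
individual x cluster group collapse to one representative (a consensus
record when the group has a single form); every distinct corrected
form yields one representative, and a single clone that alone
represents a cluster for its individual is always included.

All candidate decisions are evaluated simultaneously against the
*input* alignment and then applied, which makes the screen idempotent:
a retained singleton always has a variable partner group that is
itself retained.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .seqio import Alignment, CloneRecord, format_clone_label
from .trees import pdistance_matrix

__all__ = [
    "ClusterAssignment",
    "Decision",
    "ScreenReport",
    "assign_clusters",
    "screen_singletons",
    "select_representatives",
    "tabulate_forms",
]


@dataclass
class ClusterAssignment:
    labels: dict[str, str]          # clone id -> cluster label
    method: str                     # "auto" | "user"

    def __getitem__(self, clone_id):
        return self.labels[clone_id]

    def members(self, label):
        return [cid for cid, lab in self.labels.items() if lab == label]

    @property
    def cluster_names(self):
        return sorted(set(self.labels.values()))


@dataclass(frozen=True)
class Decision:
    clone_id: str
    column: int                     # 0-based
    decision: str                   # error_masked | snp_retained | unresolved
    original: str
    replacement: str                # equals original unless masked
    evidence_individuals: tuple[str, ...]  # other individuals variable here


@dataclass
class ScreenReport:
    decisions: list[Decision]
    groups: dict[tuple[str, str], list[str]]   # (barcode, cluster) -> clone ids
    clusters: ClusterAssignment
    forms: dict[tuple[str, str], list[list[str]]] = field(default_factory=dict)
    representatives: list[str] = field(default_factory=list)
    representative_clusters: dict[str, str] = field(default_factory=dict)
    origins: dict[str, str] = field(default_factory=dict)  # barcode -> "Sp.Loc"

    def decisions_frame(self) -> pd.DataFrame:
        rows = [
            {
                "clone": d.clone_id,
                "column_1based": d.column + 1,
                "decision": d.decision,
                "original": d.original,
                "replacement": d.replacement,
                "evidence_individuals": ",".join(d.evidence_individuals),
            }
            for d in self.decisions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "clone", "column_1based", "decision", "original",
                "replacement", "evidence_individuals",
            ],
        )

    @property
    def n_masked(self) -> int:
        return sum(1 for d in self.decisions if d.decision == "error_masked")

    @property
    def n_retained(self) -> int:
        return sum(1 for d in self.decisions if d.decision == "snp_retained")


def assign_clusters(
    aln: Alignment,
    mode: str = "auto",
    threshold: float = 0.10,
    labels: dict[str, str] | None = None,
) -> ClusterAssignment:
    """Cluster clones into paralogs.

    auto: single-linkage clustering on gap-excluded pairwise p-distance,
    cut at ``threshold`` divergence (default 0.10); clusters are named
    C1..Ck in order of first appearance.  user: ``labels`` maps every
    clone id to a label.
    """
    if mode == "user":
        if labels is None:
            raise ValueError("user mode needs a labels mapping")
        missing = [r.id for r in aln.records if r.id not in labels]
        if missing:
            raise ValueError(f"no cluster label for {missing[:5]}")
        return ClusterAssignment({r.id: labels[r.id] for r in aln.records}, "user")
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    if aln.n < 2:
        raise ValueError("need >=2 sequences")
    ids, D = pdistance_matrix(aln, mode="pairwise-deletion")
    Z = linkage(squareform(D, checks=False), method="single")
    flat = fcluster(Z, t=threshold, criterion="distance")
    # rename in order of first appearance
    name_of: dict[int, str] = {}
    out = {}
    for cid, k in zip(ids, flat):
        if k not in name_of:
            name_of[k] = f"C{len(name_of) + 1}"
        out[cid] = name_of[k]
    return ClusterAssignment(out, "auto")


def _group_clones(aln: Alignment, clusters: ClusterAssignment):
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for rec in aln.records:
        if rec.barcode is None:
            raise ValueError(f"clone {rec.id!r} lacks an individual barcode")
        groups[(rec.barcode, clusters[rec.id])].append(rec.id)
    return dict(groups)


def screen_singletons(
    aln: Alignment, clusters: ClusterAssignment
) -> tuple[ScreenReport, Alignment]:
    """Apply the singleton screen; returns the report and the corrected
    alignment (masked singletons replaced by the group-majority base).

    Indel characters count as a fifth state, so a one-clone gap is a
    maskable singleton.
    """
    groups = _group_clones(aln, clusters)
    seqs = {r.id: list(r.sequence) for r in aln.records}
    row_of = {r.id: i for i, r in enumerate(aln.records)}
    arr = aln.to_array()
    L = aln.length
    decisions: list[Decision] = []

    by_cluster: dict[str, list[tuple[str, list[str]]]] = defaultdict(list)
    for (barcode, cluster), members in groups.items():
        by_cluster[cluster].append((barcode, members))

    for cluster, indiv_groups in by_cluster.items():
        def recurs(barcode, col, base):
            """Evidence that a singleton variant is real: the base
            occurs in another individual's clones at this column, or
            another individual's clones are themselves variable here."""
            ev = []
            for b, ms in indiv_groups:
                if b == barcode:
                    continue
                states = {arr[row_of[m], col] for m in ms}
                if base in states or len(states) > 1:
                    ev.append(b)
            return tuple(sorted(ev))

        for barcode, members in indiv_groups:
            if len(members) < 2:
                continue  # no within-individual evidence
            rows = [row_of[m] for m in members]
            sub = arr[rows, :]
            for col in range(L):
                states = Counter(sub[:, col].tolist())
                if len(states) < 2:
                    continue
                if len(members) == 2 and len(states) == 2:
                    # both clones are singletons at this column: test
                    # each variant for recurrence elsewhere
                    (m1, m2) = members
                    b1, b2 = arr[row_of[m1], col], arr[row_of[m2], col]
                    ev1, ev2 = recurs(barcode, col, b1), recurs(barcode, col, b2)
                    if ev1 and ev2:
                        for m, b, ev in ((m1, b1, ev1), (m2, b2, ev2)):
                            decisions.append(
                                Decision(m, col, "snp_retained", b, b, ev)
                            )
                    elif ev1 or ev2:
                        loser, lb, wb = (m2, b2, b1) if ev1 else (m1, b1, b2)
                        winner_ev = ev1 or ev2
                        seqs[loser][col] = wb
                        decisions.append(
                            Decision(loser, col, "error_masked", lb, wb, ())
                        )
                        keeper, kb = (m1, b1) if ev1 else (m2, b2)
                        decisions.append(
                            Decision(keeper, col, "snp_retained", kb, kb, winner_ev)
                        )
                    else:
                        # neither recurs: cluster-wide majority decides;
                        # tie -> mask neither, flag unresolved
                        cl_states = Counter(
                            arr[row_of[m], col]
                            for _, ms in indiv_groups for m in ms
                        )
                        if cl_states[b1] == cl_states[b2]:
                            for m, b in ((m1, b1), (m2, b2)):
                                decisions.append(
                                    Decision(m, col, "unresolved", b, b, ())
                                )
                        else:
                            minority = b1 if cl_states[b1] < cl_states[b2] else b2
                            majority = b2 if minority == b1 else b1
                            loser = m1 if b1 == minority else m2
                            seqs[loser][col] = majority
                            decisions.append(Decision(
                                loser, col, "error_masked", minority, majority, (),
                            ))
                    continue
                # groups of >= 3 clones: singleton = exactly one clone
                # differing from the (uniform) rest
                if len(states) != 2 or states.most_common(1)[0][1] != len(members) - 1:
                    continue
                singleton_base = states.most_common()[-1][0]
                majority = states.most_common(1)[0][0]
                offender = members[
                    int(np.flatnonzero(sub[:, col] == singleton_base)[0])
                ]
                ev = recurs(barcode, col, singleton_base)
                if ev:
                    decisions.append(Decision(
                        offender, col, "snp_retained",
                        singleton_base, singleton_base, ev,
                    ))
                else:
                    seqs[offender][col] = majority
                    decisions.append(Decision(
                        offender, col, "error_masked", singleton_base, majority, (),
                    ))

    corrected = aln.replace_sequences({cid: "".join(s) for cid, s in seqs.items()})
    origins = {
        r.barcode: f"{r.species}.{r.locality}"
        for r in aln.records
        if r.barcode is not None
    }
    report = ScreenReport(
        decisions=decisions, groups=groups, clusters=clusters, origins=origins
    )
    return report, corrected


def select_representatives(
    corrected: Alignment, report: ScreenReport
) -> Alignment:
    """One representative per distinct corrected form per
    individual x cluster group.

    A group whose clones are all identical yields one consensus record
    (id ``<barcode>-cons.<species>.<locality>``); a multi-form group
    yields, per form, the member clone with the lowest clone number
    under its own id; a single clone alone representing a cluster is
    always included.  Fills ``report.forms`` and
    ``report.representatives``.
    """
    reps: list[CloneRecord] = []
    order = {r.id: i for i, r in enumerate(corrected.records)}
    # a consensus id <barcode>-cons.<sp>.<loc> is only unique if the
    # individual has a single collapsible group; otherwise fall back to
    # real clone ids
    collapsible = Counter()
    form_cache: dict[tuple[str, str], list[list[str]]] = {}
    for key in sorted(report.groups, key=lambda k: (k[0], k[1])):
        members = report.groups[key]
        forms: dict[str, list[str]] = {}
        for m in sorted(members, key=lambda m: order[m]):
            forms.setdefault(corrected[m].sequence, []).append(m)
        form_cache[key] = list(forms.values())
        if len(forms) == 1 and len(members) > 1:
            collapsible[key[0]] += 1
    for key in sorted(report.groups, key=lambda k: (k[0], k[1])):
        form_list = form_cache[key]
        report.forms[key] = form_list
        single_form = len(form_list) == 1 and collapsible[key[0]] == 1
        for member_ids in form_list:
            first = corrected[
                min(member_ids, key=lambda m: (corrected[m].clone_number or 0, m))
            ]
            if single_form and len(member_ids) > 1:
                rep = CloneRecord(
                    id=format_clone_label(
                        first.barcode, "cons", first.species, first.locality
                    ),
                    sequence=first.sequence,
                    barcode=first.barcode,
                    clone_number=None,
                    species=first.species,
                    locality=first.locality,
                    is_consensus=True,
                )
            else:
                rep = first
            reps.append(rep)
            report.representative_clusters[rep.id] = key[1]
    report.representatives = [r.id for r in reps]
    return Alignment(reps)


def tabulate_forms(report: ScreenReport) -> pd.DataFrame:
    """Per-individual table: clones sequenced and forms found, plus a
    totals row (number of individuals, total clones, total forms)."""
    per_ind: dict[str, dict] = {}
    for (barcode, cluster), members in sorted(report.groups.items()):
        d = per_ind.setdefault(
            barcode,
            {
                "barcode": barcode,
                "origin": report.origins.get(barcode, ""),
                "n_clones": 0,
                "n_forms": 0,
            },
        )
        d["n_clones"] += len(members)
        d["n_forms"] += len(report.forms.get((barcode, cluster), [members]))
    rows = sorted(per_ind.values(), key=lambda d: d["barcode"])
    df = pd.DataFrame(rows, columns=["barcode", "origin", "n_clones", "n_forms"])
    if df.empty:
        return df
    total = {
        "barcode": "total",
        "origin": f"{len(rows)} individuals",
        "n_clones": int(df["n_clones"].sum()),
        "n_forms": int(df["n_forms"].sum()),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
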