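"""Synthetic clone-library generator with known truth.

The generator emulates the data-producing process behind a multi-gene
clone library under long-term balancing selection:

* G paralogous genes diverge from a common ancestor at a deep
  duplication time (default divergence ~15%).
* Within each paralog, K allelic classes originate ``t_class_origin``
  generations ago.  In the balancing preset that origin predates every
  ingroup speciation, so every ingroup species inherits every class —
  the trans-species architecture.  Each class then evolves neutrally
  down the species tree (Jukes-Cantor, Poisson number of substitutions
  per branch), accumulating species-private divergence within classes.
* The species design follows the published sampling: 19 Atlantic cod
  (Gmo) and two each of Gma, Gog, Gch, plus the outgroup Bsa which
  split before the class origin and therefore carries its own private
  lineage per paralog.
* Default demographic primitives: Ne = 10,000, 5-year generations,
  ingroup splits ~4 mya (8e5 generations), class origin 1.6e6
  generations — well beyond the 20·Ne generations a balanced
  polymorphism must survive to look trans-specific.
* Deletions (intron 3 only by default) model the length variation seen
  between allelic classes.
* Individuals are diploid per paralog: two allele copies drawn from the
  class pool, with per-paralog amplification dropout; each sequenced
  clone copies one allele and receives Poisson(e*L) independent PCR
  errors at uniform positions — the singletons the screening stage must
  remove.

The observed FASTA equals the truth haplotypes plus the recorded
errors, exactly; labels follow ``<barcode>-<clone>.<species>.<locality>``.

``neutral_control`` uses identical machinery but lets allele classes
originate within each species after the splits, so no class spans
species — the null for the trans-species test.

``simulate_codon_alignment`` is a separate, smaller generator for the
codon selection test: codon sequences evolved on a known balanced tree
with a controllable non-synonymous/synonymous rate ratio omega.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from . import study
from .seqio import Alignment, CloneRecord, GeneAnnotation, format_clone_label

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "neutral_control",
    "simulate_codon_alignment",
    "default_annotation",
]

_BASES = np.array(list("ACGT"))

# generations; topology (Bsa,(  (Gma,Gog), (Gch,Gmo) ))
DEFAULT_SPECIES_TREE = (
    "split", 2_400_000,
    "Bsa",
    ("split", 800_000,
        ("split", 200_000, "Gma", "Gog"),
        ("split", 760_000, "Gch", "Gmo")),
)

# (name, start, end) on a 1300-bp reference; exon lengths divisible by 3
DEFAULT_REGIONS = (
    ("UTR5", 0, 50),
    ("exon1", 50, 200),
    ("intron1", 200, 350),
    ("exon2", 350, 500),
    ("intron2", 500, 650),
    ("exon3", 650, 800),
    ("intron3", 800, 1050),
    ("exon4", 1050, 1248),
    ("UTR3", 1248, 1300),
)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulationConfig:
    seed: int
    n_paralogs: int = 3
    n_classes: int = 2
    length: int = 1300
    regions: tuple = DEFAULT_REGIONS
    mu: float = 6.25e-9                 # per site per generation
    ne: int = 10_000
    generation_years: float = 5.0
    t_class_origin: float = 1_600_000   # generations; > ingroup splits
    t_paralog: float = 12_000_000       # paralog divergence time
    t_within_neutral: float = 50_000    # class origin for the neutral control;
                                        # well inside the youngest split (200k)
    species_tree: tuple = DEFAULT_SPECIES_TREE
    individuals: tuple = tuple((b, s, l) for b, s, l, _, _ in study.SAMPLING_DESIGN)
    clone_counts: tuple = study.CLONE_COUNT_COLUMN
    error_rate: float = 1e-3            # PCR errors per site per clone
    dropout: float = 0.4                # per paralog per individual
    indel_prob: float = 0.4             # per (paralog, class) lineage
    indel_length: tuple = (5, 40)       # uniform, intron 3 only
    within_species_theta: bool = True   # per-copy private mutations ~ 2*Ne*mu

    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(list(self.regions), reference_id="simulated")

    def validate(self):
        if self.t_class_origin < 0:
            raise ValueError("t_class_origin must be >= 0")
        for r in (self.mu, self.error_rate, self.dropout, self.indel_prob):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.regions[-1][2] != self.length:
            raise ValueError("annotation does not span the sequence length")


def default_annotation() -> GeneAnnotation:
    return GeneAnnotation(list(DEFAULT_REGIONS), reference_id="simulated")


@dataclass
class SimulatedDataset:
    alignment: Alignment
    annotation: GeneAnnotation
    config: SimulationConfig
    truth_assignments: dict[str, dict]        # clone id -> paralog/class/copy
    truth_errors: dict[str, list[tuple[int, str, str]]]  # clone -> (pos, old, new)
    truth_haplotypes: dict[str, str]          # "paralog|class|species" -> sequence
    metadata: pd.DataFrame

    def paralog_of(self, clone_id: str) -> str:
        return self.truth_assignments[clone_id]["paralog"]

    def write(self, outdir):
        import pathlib

        from .seqio import write_alignment, write_annotation

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, out / "clones.fasta")
        write_annotation(self.annotation, out / "annotation.tsv")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        truth = {
            "assignments": self.truth_assignments,
            "errors": {k: [list(e) for e in v] for k, v in self.truth_errors.items()},
            "haplotypes": self.truth_haplotypes,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


class _Frame:
    """Coding-frame helper: maps sequence positions to codon triples of
    the concatenated exons so mutations can avoid creating stops."""

    def __init__(self, annotation: GeneAnnotation):
        exon_cols = []
        for name, s, e in annotation.regions:
            if name.startswith("exon"):
                exon_cols.extend(range(s, e))
        self.codon_of = {}
        for i in range(0, len(exon_cols) - len(exon_cols) % 3, 3):
            tri = tuple(exon_cols[i: i + 3])
            for c in tri:
                self.codon_of[c] = tri

    def makes_stop(self, seq: list[str], pos: int, base: str) -> bool:
        tri = self.codon_of.get(pos)
        if tri is None:
            return False
        cod = "".join(base if c == pos else seq[c] for c in tri)
        return cod in _STOPS


def _random_sequence(rng, length, frame: _Frame) -> list[str]:
    seq = list(rng.choice(_BASES, size=length))
    # repair any in-frame stop codons
    for tri in {t for t in frame.codon_of.values()}:
        while "".join(seq[c] for c in tri) in _STOPS:
            c = tri[int(rng.integers(3))]
            seq[c] = str(rng.choice(_BASES))
    return seq


def _mutate(rng, seq: list[str], expected: float, frame: _Frame | None) -> list[str]:
    """Jukes-Cantor substitutions: Poisson(expected) events at uniform
    non-gap positions; in coding frame, substitutions creating stop
    codons are redrawn (functional gene assumption)."""
    seq = list(seq)
    sites = [i for i, b in enumerate(seq) if b != "-"]
    if not sites:
        return seq
    n = rng.poisson(expected)
    for _ in range(n):
        pos = sites[int(rng.integers(len(sites)))]
        choices = [b for b in "ACGT" if b != seq[pos]]
        rng.shuffle(choices)
        for b in choices:
            if frame is not None and frame.makes_stop(seq, pos, b):
                continue
            seq[pos] = b
            break
    return seq


def _evolve_down_species_tree(rng, tree, t_top, seq, mu_L, frame):
    """Evolve ``seq`` from time ``t_top`` down to every tip of the
    species (sub)tree; returns {species: sequence}."""
    if isinstance(tree, str):
        return {tree: _mutate(rng, seq, mu_L * t_top, frame)}
    _, t_split, left, right = tree
    trunk = _mutate(rng, seq, mu_L * max(t_top - t_split, 0.0), frame)
    out = {}
    out.update(_evolve_down_species_tree(rng, left, t_split, trunk, mu_L, frame))
    out.update(_evolve_down_species_tree(rng, right, t_split, trunk, mu_L, frame))
    return out


def _subtree_species(tree):
    if isinstance(tree, str):
        return [tree]
    return _subtree_species(tree[2]) + _subtree_species(tree[3])


def _class_haplotypes_balancing(rng, cfg: SimulationConfig, frame: _Frame):
    """{(paralog, class, species): sequence} under the balancing preset."""
    L = cfg.length
    mu_L = cfg.mu * L
    root = _random_sequence(rng, L, frame)
    haps = {}
    _, t_root_split, outgroup, ingroup = cfg.species_tree
    for g in range(cfg.n_paralogs):
        par = f"G{g + 1}"
        # paralog lineage from the duplication down to the species-tree root
        par_seq = _mutate(rng, root, mu_L * (cfg.t_paralog - t_root_split), frame)
        # outgroup split predates the class origin: private lineage
        og_tips = _evolve_down_species_tree(
            rng, outgroup, t_root_split, par_seq, mu_L, frame
        )
        for sp, seq in og_tips.items():
            haps[(par, "K1", sp)] = seq
        # ingroup trunk down to the class origin, then K class lineages
        trunk = _mutate(
            rng, par_seq, mu_L * max(t_root_split - cfg.t_class_origin, 0.0), frame
        )
        for k in range(cfg.n_classes):
            cls = f"K{k + 1}"
            cls_seq = list(trunk)
            cls_seq = _apply_indel(rng, cfg, cls_seq)
            tips = _evolve_down_species_tree(
                rng, ingroup, cfg.t_class_origin, cls_seq, mu_L, frame
            )
            for sp, seq in tips.items():
                haps[(par, cls, sp)] = seq
    return haps


def _class_haplotypes_neutral(rng, cfg: SimulationConfig, frame: _Frame):
    """Classes originate within species after the splits (no sharing)."""
    L = cfg.length
    mu_L = cfg.mu * L
    root = _random_sequence(rng, L, frame)
    haps = {}
    t_root = cfg.species_tree[1]
    for g in range(cfg.n_paralogs):
        par = f"G{g + 1}"
        par_seq = _mutate(rng, root, mu_L * (cfg.t_paralog - t_root), frame)
        # evolve the whole species tree but stop t_within before present
        shallow = _shifted_tips(rng, cfg.species_tree, t_root, par_seq, mu_L,
                                frame, cfg.t_within_neutral)
        for sp, seq in shallow.items():
            for k in range(cfg.n_classes):
                cls_seq = _apply_indel(rng, cfg, list(seq))
                haps[(par, f"K{k + 1}", sp)] = _mutate(
                    rng, cls_seq, mu_L * cfg.t_within_neutral, frame
                )
    return haps


def _shifted_tips(rng, tree, t_top, seq, mu_L, frame, t_stop):
    """Like _evolve_down_species_tree but stops ``t_stop`` generations
    before the present (species-level sequences at that time)."""
    if isinstance(tree, str):
        return {tree: _mutate(rng, seq, mu_L * max(t_top - t_stop, 0.0), frame)}
    _, t_split, left, right = tree
    trunk = _mutate(rng, seq, mu_L * max(t_top - t_split, 0.0), frame)
    out = {}
    out.update(_shifted_tips(rng, left, t_split, trunk, mu_L, frame, t_stop))
    out.update(_shifted_tips(rng, right, t_split, trunk, mu_L, frame, t_stop))
    return out


def _apply_indel(rng, cfg: SimulationConfig, seq: list[str]) -> list[str]:
    if rng.random() >= cfg.indel_prob:
        return seq
    try:
        s, e = cfg.annotation().region("intron3")
    except KeyError:
        return seq
    lo, hi = cfg.indel_length
    ln = int(rng.integers(lo, hi + 1))
    ln = min(ln, e - s)
    start = int(rng.integers(s, e - ln + 1))
    for c in range(start, start + ln):
        seq[c] = "-"
    return seq


def _sample_clones(rng, rng_err, cfg, haps, frame):
    records = []
    assignments = {}
    errors = {}
    meta_rows = []
    paralogs = [f"G{g + 1}" for g in range(cfg.n_paralogs)]
    classes = [f"K{k + 1}" for k in range(cfg.n_classes)]
    counts_pool = np.array(cfg.clone_counts)

    for barcode, species, locality in cfg.individuals:
        amplifiable = [p for p in paralogs if rng.random() >= cfg.dropout]
        if not amplifiable:
            amplifiable = [paralogs[int(rng.integers(len(paralogs)))]]
        # two allele copies per amplifiable paralog
        copies = {}
        for p in amplifiable:
            avail = [c for c in classes if (p, c, species) in haps]
            chosen = [avail[int(rng.integers(len(avail)))] for _ in range(2)]
            copy_seqs = []
            for c in chosen:
                seq = list(haps[(p, c, species)])
                if cfg.within_species_theta:
                    seq = _mutate(rng, seq, cfg.mu * 2 * cfg.ne * cfg.length, frame)
                copy_seqs.append((c, seq))
            copies[p] = copy_seqs
        n_clones = int(counts_pool[int(rng.integers(len(counts_pool)))])
        for clone_no in range(1, n_clones + 1):
            p = amplifiable[int(rng.integers(len(amplifiable)))]
            copy_idx = int(rng.integers(2))
            cls, base_seq = copies[p][copy_idx]
            seq = list(base_seq)
            sites = [i for i, b in enumerate(seq) if b != "-"]
            n_err = rng_err.poisson(cfg.error_rate * len(sites))
            errs = []
            for _ in range(n_err):
                pos = sites[int(rng_err.integers(len(sites)))]
                old = seq[pos]
                new = str(rng_err.choice([b for b in "ACGT" if b != old]))
                seq[pos] = new
                errs.append((pos, old, new))
            cid = format_clone_label(barcode, clone_no, species, locality)
            records.append(
                CloneRecord(
                    id=cid, sequence="".join(seq), barcode=barcode,
                    clone_number=clone_no, species=species, locality=locality,
                )
            )
            assignments[cid] = {
                "paralog": p, "class": cls, "copy": copy_idx,
                "species": species, "individual": barcode,
            }
            errors[cid] = errs
            meta_rows.append(
                {
                    "clone": cid, "barcode": barcode, "species": species,
                    "locality": locality, "paralog": p, "allele_class": cls,
                    "n_errors": len(errs),
                }
            )
    return records, assignments, errors, meta_rows


def _build(cfg: SimulationConfig, haps_fn) -> SimulatedDataset:
    cfg.validate()
    # separate streams: the clone library is identical across error-rate
    # settings, so error-injection effects can be studied in isolation
    rng = np.random.default_rng([cfg.seed, 0])
    rng_err = np.random.default_rng([cfg.seed, 1])
    frame = _Frame(cfg.annotation())
    haps = haps_fn(rng, cfg, frame)
    records, assignments, errors, meta = _sample_clones(rng, rng_err, cfg, haps, frame)
    return SimulatedDataset(
        alignment=Alignment(records),
        annotation=cfg.annotation(),
        config=cfg,
        truth_assignments=assignments,
        truth_errors=errors,
        truth_haplotypes={"|".join(k): "".join(v) for k, v in haps.items()},
        metadata=pd.DataFrame(meta),
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Balancing preset: allele classes older than every ingroup split,
    hence shared across species."""
    if cfg.t_class_origin <= _max_ingroup_split(cfg.species_tree):
        raise ValueError(
            "balancing preset needs t_class_origin above every ingroup split"
        )
    return _build(cfg, _class_haplotypes_balancing)


def neutral_control(cfg: SimulationConfig) -> SimulatedDataset:
    """Null model: allele classes coalesce within species after the
    splits; no trans-species classes."""
    return _build(cfg, _class_haplotypes_neutral)


def _max_ingroup_split(tree) -> float:
    ingroup = tree[3]
    if isinstance(ingroup, str):
        return 0.0
    return ingroup[1]


# ---------------------------------------------------------------------------
# codon-level generator for the selection test


def _balanced_tree(n_taxa: int, branch_length: float):
    """Balanced bifurcating tree with equal branch lengths; labels t1..tn."""
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nd.edge.length = branch_length
        nodes.append(nd)
    while len(nodes) > 2:
        nxt = []
        for i in range(0, len(nodes) - 1, 2):
            parent = dendropy.Node()
            parent.add_child(nodes[i])
            parent.add_child(nodes[i + 1])
            parent.edge.length = branch_length
            nxt.append(parent)
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    for nd in nodes:
        tree.seed_node.add_child(nd)
    tree.is_rooted = False
    return tree, labels


_SENSE = None


def _sense_codons():
    global _SENSE
    if _SENSE is None:
        from .codon import SENSE_CODONS

        _SENSE = SENSE_CODONS
    return _SENSE


def _evolve_codon(rng, codon: str, expected_events: float, omega: float) -> str:
    from .codon import STOP_CODONS, translate

    n = rng.poisson(expected_events)
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_non = min(1.0, omega)
    for _ in range(n):
        pos = int(rng.integers(3))
        new = str(rng.choice([b for b in "ACGT" if b != codon[pos]]))
        cand = codon[:pos] + new + codon[pos + 1:]
        if cand in STOP_CODONS:
            continue
        accept = p_syn if translate(cand) == translate(codon) else p_non
        if rng.random() < accept:
            codon = cand
    return codon


def simulate_codon_alignment(
    n_taxa: int = 64,
    n_codons: int = 200,
    branch_length: float = 0.08,
    omega: float = 1.0,
    selected_fraction: float = 0.0,
    omega_selected: float = 5.0,
    seed: int = 0,
):
    """Codon alignment evolved on a balanced tree with known omega.

    ``branch_length`` is expected substitution events per site per
    branch (before selection thinning).  A ``selected_fraction`` of
    codons evolves with ``omega_selected`` instead of ``omega``.

    Returns ``(alignment, tree, selected_indices)`` — 0-based indices
    of the codons simulated under ``omega_selected``.
    """
    rng = np.random.default_rng(seed)
    tree, labels = _balanced_tree(n_taxa, branch_length)
    sense = _sense_codons()
    root = [sense[int(rng.integers(len(sense)))] for _ in range(n_codons)]
    n_sel = int(round(selected_fraction * n_codons))
    selected = sorted(rng.choice(n_codons, size=n_sel, replace=False).tolist())
    sel_set = set(selected)

    seqs = {}

    def recurse(node, codons):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            ev = 3 * bl
            new = [
                _evolve_codon(
                    rng, c, ev, omega_selected if i in sel_set else omega
                )
                for i, c in enumerate(codons)
            ]
            if child.is_leaf():
                seqs[child.taxon.label] = "".join(new)
            else:
                recurse(child, new)

    recurse(tree.seed_node, root)
    records = [CloneRecord(id=lab, sequence=seqs[lab]) for lab in labels]
    return Alignment(records), tree, selected
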