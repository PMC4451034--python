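"""One-command orchestration of the full analysis graph:

screen -> cluster -> trees -> popgen/LD -> codon selection ->
trans-species/DAPC -> report.

Every stage is a pure function of (inputs, config, seed); re-running
with the same inputs reproduces the outputs byte-identically except for
timestamps in the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass

import numpy as np
import yaml

from . import codon, ld, popgen, screen, seqio, transpecies, trees

log = logging.getLogger("transpoly")


@dataclass
class RunConfig:
    alignment: str
    out_dir: str
    annotation: str | None = None
    annotation_ref: str | None = None     # record id carrying the reference
    tree: str | None = None               # external Newick; default: NJ
    cluster_mode: str = "auto"            # auto | path to TSV
    cluster_threshold: float = 0.10
    window: int = 100
    step: int = 25
    maf_count: int = 2
    n_perm: int = 999
    n_bootstrap: int = 100
    n_pca: int = 10
    n_da: int = 3
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _read_cluster_tsv(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("clone\t"):
                continue
            cid, lab = line.split("\t")[:2]
            out[cid] = lab
    return out


def run_all(cfg: RunConfig) -> dict:
    """Run the whole pipeline; returns a summary dict (also written to
    ``summary.json`` in the output directory)."""
    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_all(cfg, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_all(cfg: RunConfig, out: pathlib.Path) -> dict:
    cfg.to_yaml(out / "config.yaml")
    summary: dict = {"stages": []}

    aln = seqio.read_alignment(cfg.alignment)
    log.info("read %d records of length %d", aln.n, aln.length)

    # --- clustering + screening -------------------------------------
    if cfg.cluster_mode == "auto":
        clusters = screen.assign_clusters(aln, "auto", cfg.cluster_threshold)
    else:
        clusters = screen.assign_clusters(
            aln, "user", labels=_read_cluster_tsv(cfg.cluster_mode)
        )
    report, corrected = screen.screen_singletons(aln, clusters)
    reps = screen.select_representatives(corrected, report)
    seqio.write_alignment(corrected, out / "corrected.fasta")
    seqio.write_alignment(reps, out / "representatives.fasta")
    report.decisions_frame().to_csv(out / "screen_decisions.tsv", sep="\t", index=False)
    screen.tabulate_forms(report).to_csv(out / "forms.tsv", sep="\t", index=False)
    summary["n_clones_in"] = aln.n
    summary["n_representatives"] = reps.n
    summary["n_clusters"] = len(clusters.cluster_names)
    summary["n_masked"] = report.n_masked
    summary["n_retained_snps"] = report.n_retained
    summary["stages"] += ["screen"]
    log.info(
        "clusters=%d masked=%d retained=%d representatives=%d",
        summary["n_clusters"], report.n_masked, report.n_retained, reps.n,
    )

    # --- tree ---------------------------------------------------------
    if cfg.tree:
        tree = trees.read_newick(cfg.tree)
    else:
        tree = trees.bootstrap_support(reps, n_reps=cfg.n_bootstrap, seed=cfg.seed)
    trees.write_newick(tree, out / "representatives.nwk")
    summary["stages"] += ["tree"]

    rep_cluster_map = report.representative_clusters

    # --- per-cluster popgen + LD -------------------------------------
    window_frames = []
    ld_frames = []
    for cl in sorted(set(rep_cluster_map.values())):
        members = [cid for cid, c in rep_cluster_map.items() if c == cl]
        sub = reps.subset(ids=members)
        if sub.n < 2:
            continue
        ws = popgen.sliding_windows(sub, window=cfg.window, step=cfg.step)
        wf = popgen.windows_to_frame(ws)
        wf.insert(0, "cluster", cl)
        window_frames.append(wf)
        lf = ld.ld_matrix(sub, maf_min=cfg.maf_count)
        lf.insert(0, "cluster", cl)
        ld_frames.append(lf)
        fg = popgen.four_gamete_pairs(sub, maf_min=cfg.maf_count)
        summary.setdefault("four_gamete_pairs", {})[cl] = len(fg)
    if window_frames:
        pd_concat(window_frames).to_csv(out / "windows.tsv", sep="\t", index=False)
    if ld_frames:
        pd_concat(ld_frames).to_csv(out / "ld.tsv", sep="\t", index=False)
    summary["stages"] += ["popgen", "ld"]

    # --- trans-species + DAPC ----------------------------------------
    species = {r.id: r.species for r in reps.records if r.species}
    if len(set(species.values())) >= 2 and set(species) == set(reps.ids):
        ts = transpecies.transpecies_test(
            tree, species, n_perm=cfg.n_perm, seed=cfg.seed,
            clusters=rep_cluster_map,
        )
        sharing = transpecies.clade_species_sharing(rep_cluster_map, species)
        sharing.to_csv(out / "cluster_species_sharing.tsv", sep="\t", index=False)
        ts.per_clade.to_csv(out / "clade_species.tsv", sep="\t", index=False)
        summary["transpecies"] = {
            "observed_score": ts.observed_score,
            "min_possible": ts.min_possible,
            "p_species_clustered": ts.p_value,
            "intermixing_index": ts.intermixing_index,
            "index_ci": list(ts.index_ci),
        }
        try:
            X, feats, ids = transpecies.genotype_matrix(reps, maf_min=1)
            alle = transpecies.dapc_fit(
                X, [rep_cluster_map[i] for i in ids],
                n_pca=cfg.n_pca, n_da=cfg.n_da, record_ids=ids,
            )
            spec_groups = [species[i] for i in ids]
            if len(set(spec_groups)) >= 2:
                sp = transpecies.dapc_fit(
                    X, spec_groups, n_pca=cfg.n_pca, n_da=cfg.n_da, record_ids=ids
                )
                summary["dapc"] = {
                    "accuracy_alleles": alle.accuracy,
                    "accuracy_species": sp.accuracy,
                }
                _write_dapc(out / "dapc_alleles.tsv", alle)
                _write_dapc(out / "dapc_species.tsv", sp)
        except ValueError as exc:
            log.warning("DAPC skipped: %s", exc)
        summary["stages"] += ["transpecies", "dapc"]

    # --- codon selection ---------------------------------------------
    if cfg.annotation:
        ann = seqio.read_annotation(cfg.annotation)
        ref = cfg.annotation_ref or reps.records[0].id
        if "exon4" not in ann.names:
            raise ValueError("codon stage requested but annotation lacks exon4")
        projected = seqio.project_annotation(ann, reps, ref)
        for region_name, cols in _codon_regions(ann, projected).items():
            try:
                scan = codon.region_scan(reps, tree, cols)
            except ValueError as exc:
                log.warning("codon scan %s skipped: %s", region_name, exc)
                continue
            scan.to_csv(out / f"codon_{region_name}.tsv", sep="\t", index=False)
            summary.setdefault("codon", {})[region_name] = {
                "n_codons": int(len(scan)),
                "n_pos_reported": int(scan["pos_reported"].sum()) if len(scan) else 0,
                "n_neg_reported": int(scan["neg_reported"].sum()) if len(scan) else 0,
            }
        summary["stages"] += ["codon_selection"]

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    log.info("pipeline complete: %s", ", ".join(summary["stages"]))
    return summary


def _codon_regions(ann, projected) -> dict[str, list[int]]:
    regions = {"exon4": list(projected["exon4"])}
    e123 = []
    for name in ("exon1", "exon2", "exon3"):
        if name in projected:
            e123.extend(projected[name])
    if e123:
        regions["exons123"] = sorted(e123)
    return regions


def _write_dapc(path, model) -> None:
    import pandas as pd

    df = pd.DataFrame(
        model.da_coords,
        columns=[f"LD{i + 1}" for i in range(model.da_coords.shape[1])],
    )
    df.insert(0, "id", model.record_ids)
    df["group"] = model.groups
    df["assigned"] = model.assignments
    for k, g in enumerate(model.group_order):
        df[f"P({g})"] = model.posterior[:, k]
    df.to_csv(path, sep="\t", index=False)


def pd_concat(frames):
    import pandas as pd

    return pd.concat(frames, ignore_index=True)
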