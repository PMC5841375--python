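"""End-to-end pipeline orchestration.

Stage order: QC -> paired-end backbone clustering (with de novo chimera
removal and an optional reference chimera screen) -> orphan single-end
mapping -> clustering of the unmapped remainder -> stitching -> taxonomy
-> non-bacteria and singleton filtering -> tree -> OTU table.

Three comparator modes mirror the method evaluation: ``hybrid`` (the full
procedure), ``paired-only`` (orphans discarded after QC) and ``r1-only``
(reverse reads ignored entirely, all surviving forward reads clustered as
single-end). One global seed drives every stochastic step through derived
per-stage streams, so identical configs are bit-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from . import hybrid, phylotree, taxonomy
from .cluster import Origin, dereplicate, greedy_cluster, reference_chimera_screen
from .qc import QCLog, QCParams, qc_sample
from .seqio import OTUTable, write_fasta, write_otu_table, write_taxonomy

MODES = ("hybrid", "paired-only", "r1-only")


@dataclass
class PipelineParams:
    qc: QCParams = field(default_factory=QCParams)
    radius: float = 0.97
    spacer_len: int = 8
    keep_singletons: bool = False
    chimera_check: bool = True
    chimera_ref: "str | list | None" = None
    word_size: int = 8
    n_bootstrap: int = 100
    conf_threshold: float = 0.8
    kmer_k: int = 6
    fast_identity: bool = True
    seed: int = 0


@dataclass
class RunResult:
    mode: str
    table: OTUTable
    otus: dict                       # otu_id -> OTU (those in the table)
    stitched: dict[str, str]         # otu_id -> stitched representative
    calls: dict                      # otu_id -> TaxonomyCall
    tree: "object | None"            # skbio TreeNode over table OTUs (>= 2)
    counters: dict[str, int]
    qc_logs: dict[str, QCLog]


def run_pipeline(
    samples: "dict | object",
    train_refs: list[tuple[str, str]],
    train_lineages: dict[str, str],
    params: PipelineParams = PipelineParams(),
    mode: str = "hybrid",
) -> RunResult:
    """Run the full pipeline on per-sample read-pair streams.

    ``samples`` is either a mapping sample_id -> iterable of
    (forward Read, reverse Read or None) or a
    :class:`~hybridotu.simulate.SimulatedDataset`. The taxonomy model is
    trained on ``train_refs``/``train_lineages`` (for synthetic studies,
    the generator's reference set doubles as the training set).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if hasattr(samples, "ledger"):  # SimulatedDataset
        dataset = samples
        samples = {sid: dataset.reads(sid) for sid in dataset.sample_ids}

    counters: dict[str, int] = {}
    qc_logs: dict[str, QCLog] = {}
    pair_records = []    # (r1_seq, r2_seq, sample, read) for backbone derep
    orphan_records = []  # (r1_seq, None, sample, read)
    for sid in sorted(samples):
        pair_list = list(samples[sid])
        pairs, orphans, log = qc_sample(
            (r1 for r1, _ in pair_list),
            (r2 for _, r2 in pair_list),
            params.qc,
        )
        qc_logs[sid] = log
        for p in pairs:
            pair_records.append((p.r1.bases, p.r2.bases, sid, p.r1.id))
        for o in orphans:
            orphan_records.append((o.bases, None, sid, o.id))
    counters["input_pairs"] = sum(l.input_pairs for l in qc_logs.values())
    counters["qc_paired"] = len(pair_records)
    counters["qc_orphans"] = len(orphan_records)
    counters["qc_dropped"] = sum(l.dropped for l in qc_logs.values())

    if mode == "r1-only":
        # ignore R2 entirely: every surviving forward read is single-end
        orphan_records = [
            (r1, None, s, rid) for r1, _r2, s, rid in pair_records
        ] + orphan_records
        pair_records = []

    backbone = []
    backbone_assign = []
    discarded_paired = []
    if pair_records:
        units = dereplicate(pair_records)
        backbone, assigns, discarded_paired = greedy_cluster(
            units,
            radius=params.radius,
            chimera_check=params.chimera_check,
            id_prefix="OTU_B",
            origin=Origin.PAIRED_BACKBONE,
            fast_identity=params.fast_identity,
        )
        if params.chimera_ref is not None:
            kept = reference_chimera_screen(backbone, params.chimera_ref)
            kept_ids = {o.otu_id for o in kept}
            counters["ref_chimera_removed"] = len(backbone) - len(kept)
            backbone = kept
            assigns = [a if a in kept_ids else None for a in assigns]
        backbone_assign = list(zip(units, assigns))
    counters["backbone_otus"] = len(backbone)
    counters["denovo_chimera_paired"] = len(discarded_paired)

    mappings = []
    new_otus = []
    new_assign = []
    discarded_single = []
    if orphan_records and mode != "paired-only":
        orphan_units = dereplicate(orphan_records)
        if mode == "hybrid" and backbone:
            mappings, unmapped = hybrid.map_single_reads(
                orphan_units,
                backbone,
                radius=params.radius,
                fast_identity=params.fast_identity,
            )
        else:
            unmapped = orphan_units
        unmapped.sort(key=lambda u: (-u.size, u.sequence_r1))
        new_otus, assigns, discarded_single = hybrid.cluster_unmapped(
            unmapped, radius=params.radius, fast_identity=params.fast_identity
        )
        new_assign = list(zip(unmapped, assigns))
    counters["orphans_mapped"] = len(mappings)
    counters["new_single_otus"] = len(new_otus)
    counters["denovo_chimera_single"] = len(discarded_single)

    all_otus = list(backbone) + list(new_otus)
    stitched = {
        o.otu_id: hybrid.stitch_pair(o.rep_r1, o.rep_r2, params.spacer_len)
        for o in all_otus
    }
    model = taxonomy.train(train_refs, train_lineages, word_size=params.word_size)
    calls = {
        o.otu_id: taxonomy.classify(
            stitched[o.otu_id],
            model,
            n_bootstrap=params.n_bootstrap,
            conf_threshold=params.conf_threshold,
            seed=params.seed,
            seq_id=o.otu_id,
        )
        for o in all_otus
    }
    bacterial, tax_removed = taxonomy.filter_nonbacteria(
        all_otus, calls, conf_threshold=params.conf_threshold
    )
    counters["nonbacteria_removed"] = len(tax_removed)
    bact_ids = {o.otu_id for o in bacterial}

    sample_ids = sorted(samples)
    table, singleton_log = hybrid.build_final_table(
        [o for o in backbone if o.otu_id in bact_ids],
        [o for o in new_otus if o.otu_id in bact_ids],
        backbone_assign + new_assign,
        mappings,
        sample_ids=sample_ids,
        keep_singletons=params.keep_singletons,
    )
    counters["singletons_removed"] = len(singleton_log)
    counters["final_otus"] = len(table.otu_ids)
    counters["reads_in_table"] = table.grand_total()
    for otu_id in table.otu_ids:
        table.otu_metadata[otu_id]["taxonomy"] = calls[otu_id].lineage_string()

    tree = None
    if len(table.otu_ids) >= 2:
        dm = phylotree.kmer_distance_matrix(
            {o: stitched[o] for o in table.otu_ids}, k=params.kmer_k
        )
        tree = phylotree.midpoint_root(phylotree.neighbor_joining(dm))

    return RunResult(
        mode=mode,
        table=table,
        otus={o.otu_id: o for o in all_otus if o.otu_id in set(table.otu_ids)},
        stitched=stitched,
        calls={o: calls[o] for o in table.otu_ids},
        tree=tree,
        counters=counters,
        qc_logs=qc_logs,
    )


def save_result(result: RunResult, outdir: str) -> None:
    """Write otu_table.tsv, otus.fasta, otus_origin.tsv, taxonomy.tsv,
    tree.nwk and a JSON run report under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    write_otu_table(result.table, os.path.join(outdir, "otu_table.tsv"))
    write_fasta(
        [(o, result.stitched[o]) for o in result.table.otu_ids],
        os.path.join(outdir, "otus.fasta"),
    )
    with open(os.path.join(outdir, "otus_origin.tsv"), "w") as fh:
        fh.write("#otu_id\torigin\tabundance\n")
        for o in result.table.otu_ids:
            otu = result.otus[o]
            fh.write(f"{o}\t{otu.origin.value}\t{otu.abundance}\n")
    write_taxonomy(result.calls, os.path.join(outdir, "taxonomy.tsv"))
    if result.tree is not None:
        phylotree.write_newick(result.tree, os.path.join(outdir, "tree.nwk"))
    report = {"mode": result.mode, "counters": result.counters}
    report["qc"] = {
        sid: {
            "input_pairs": log.input_pairs,
            "paired_out": log.paired_out,
            "orphan_out": log.orphan_out,
            "dropped": log.dropped,
        }
        for sid, log in result.qc_logs.items()
    }
    with open(os.path.join(outdir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
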