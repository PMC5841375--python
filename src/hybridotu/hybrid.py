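"""Single-end integration onto the paired-end OTU backbone.

This is the stage that distinguishes the hybrid approach from a
paired-only or forward-read-only analysis: forward reads whose mates
failed QC ("orphans") are mapped against the forward segment of the
backbone centroids; the unmappable remainder is clustered into new
single-end OTUs appended after the backbone. Representatives are stitched
(forward + N spacer + reverse-complemented reverse segment) for taxonomy
assignment, and the final count table drops singleton OTUs as presumed
contaminants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import revcomp
from .cluster import (
    ChimeraVerdict,
    DerepUnit,
    OTU,
    Origin,
    _segment_identity_exact,
    _segment_identity_fast,
    greedy_cluster,
)
from .seqio import OTUTable


@dataclass
class MappingResult:
    read_key: tuple[str, str]  # (sample_id, read_id)
    otu_id: str | None         # None == unmapped
    identity: float | None

    def __post_init__(self) -> None:
        if (self.otu_id is None) != (self.identity is None):
            raise ValueError("identity present iff mapped")


def map_single_reads(
    orphans: list[DerepUnit],
    backbone: list[OTU],
    radius: float = 0.97,
    fast_identity: bool = False,
) -> tuple[list[MappingResult], list[DerepUnit]]:
    """Map orphan forward-read units onto backbone centroids' R1 segments.

    Each dereplicated orphan unit is aligned ends-free against every
    backbone representative's forward segment and joins the best hit at or
    above the radius; exact score ties go to the more abundant OTU, then
    founding order (backbone abundances are held fixed during mapping, so
    the result does not depend on unit order). Units below the radius
    everywhere are returned for fresh clustering. An empty backbone maps
    nothing and is not an error.
    """
    for o in backbone:
        if o.origin is not Origin.PAIRED_BACKBONE:
            raise ValueError("backbone must consist of paired-backbone OTUs")
    min_cover = 0.8  # alignment must span most of the shorter segment
    mapped: list[MappingResult] = []
    unmapped: list[DerepUnit] = []
    for unit in orphans:
        if unit.paired:
            raise ValueError("orphan units must be R1-only")
        best_i = -1
        best_id = -1.0
        for ci, otu in enumerate(backbone):
            if fast_identity:
                m, n = _segment_identity_fast(
                    unit._enc_r1, otu._enc_r1, unit.sequence_r1, otu.rep_r1
                )
            else:
                m, n = _segment_identity_exact(unit.sequence_r1, otu.rep_r1)
            short = min(len(unit.sequence_r1), len(otu.rep_r1))
            ident = m / n if n and n >= min_cover * short else 0.0
            if ident > best_id + 1e-12 or (
                abs(ident - best_id) <= 1e-12
                and best_i >= 0
                and otu.abundance > backbone[best_i].abundance
            ):
                best_id = ident
                best_i = ci
        if best_i >= 0 and best_id >= radius:
            otu_id = backbone[best_i].otu_id
            for key in unit.member_ids:
                mapped.append(MappingResult(key, otu_id, best_id))
        else:
            unmapped.append(unit)
    return mapped, unmapped


def cluster_unmapped(
    unmapped: list[DerepUnit],
    radius: float = 0.97,
    fast_identity: bool = False,
    id_prefix: str = "OTU_S",
) -> tuple[list[OTU], list[str | None], list[tuple[DerepUnit, ChimeraVerdict]]]:
    """Cluster unmapped orphan units into new single-end OTUs.

    Same greedy procedure as the backbone; resulting OTUs are tagged
    SINGLE_END_NEW and numbered after all backbone OTUs so origin is
    recoverable from the id.
    """
    if not unmapped:
        return [], [], []
    return greedy_cluster(
        unmapped,
        radius=radius,
        chimera_check=True,
        id_prefix=id_prefix,
        origin=Origin.SINGLE_END_NEW,
        fast_identity=fast_identity,
    )


def stitch_pair(r1: str, r2: str | None, spacer_len: int = 8) -> str:
    """Join mates for taxonomy: r1 + N-spacer + reverse-complement(r2).

    Single-end input passes through unchanged. The N spacer is neutralized
    downstream by skipping any word/k-mer containing N, so its exact
    length is not load-bearing.
    """
    if not r1:
        raise ValueError("r1 must be nonempty")
    if r2 is None:
        return r1
    if spacer_len < 1:
        raise ValueError("spacer_len must be >= 1 when r2 is present")
    return r1 + "N" * spacer_len + revcomp(r2)


def build_final_table(
    backbone: list[OTU],
    new_otus: list[OTU],
    unit_assignments: list[tuple[DerepUnit, str | None]],
    mappings: list[MappingResult],
    sample_ids: list[str] | None = None,
    keep_singletons: bool = False,
) -> tuple[OTUTable, dict[str, int]]:
    """Assemble the samples x OTUs count table and apply the singleton filter.

    ``unit_assignments`` pairs every clustered unit (backbone and new) with
    its otu_id (None for discarded chimeras); ``mappings`` carries the
    per-read orphan mapping results. OTUs whose total count across all
    samples is 1 are removed unless ``keep_singletons``. Returns the table
    and a log of removed-singleton counts.
    """
    otus = {o.otu_id: o for o in list(backbone) + list(new_otus)}
    counts: dict[str, dict[str, int]] = {}

    def add(sample: str, otu_id: str, n: int = 1) -> None:
        counts.setdefault(sample, {})
        counts[sample][otu_id] = counts[sample].get(otu_id, 0) + n

    for unit, otu_id in unit_assignments:
        if otu_id is None:
            continue
        for sample, _read in unit.member_ids:
            add(sample, otu_id)
    for m in mappings:
        if m.otu_id is not None:
            add(m.read_key[0], m.otu_id)

    if sample_ids is None:
        sample_ids = sorted(counts)
    otu_ids = [o.otu_id for o in backbone] + [o.otu_id for o in new_otus]
    mat = pd.DataFrame(0, index=list(sample_ids), columns=otu_ids, dtype=np.int64)
    for sample, row in counts.items():
        if sample not in mat.index:
            continue
        for otu_id, n in row.items():
            mat.loc[sample, otu_id] = n

    totals = mat.sum(axis=0)
    empty = totals[totals == 0].index
    mat = mat.drop(columns=empty)
    removed: dict[str, int] = {}
    if not keep_singletons:
        singles = mat.columns[mat.sum(axis=0) == 1]
        removed = {o: 1 for o in singles}
        mat = mat.drop(columns=singles)
    meta = {o: {"origin": otus[o].origin.value} for o in mat.columns}
    return OTUTable(mat, meta), removed
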