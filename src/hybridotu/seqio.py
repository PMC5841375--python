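"""Readers and writers for the pipeline's on-disk formats.

FASTQ (4-line, PHRED+33), FASTA, QIIME-classic TSV OTU tables
(``#OTU ID`` header), taxonomy TSVs and TSV sample manifests. Newick
output lives in :mod:`hybridotu.phylotree`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO as _BioSeqIO

PHRED_OFFSET = 33


class MateRole(str, Enum):
    R1 = "R1"
    R2 = "R2"


@dataclass
class Read:
    """A single sequencing read with PHRED-scale qualities.

    ``quals`` is a uint8 numpy array the same length as ``bases``.
    """

    id: str
    bases: str
    quals: np.ndarray
    mate_role: MateRole = MateRole.R1
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be nonempty")
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: length mismatch between bases "
                f"({len(self.bases)}) and qualities ({len(self.quals)})"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadPair:
    r1: Read
    r2: Read

    def __post_init__(self) -> None:
        if self.r1.id != self.r2.id:
            raise ValueError(f"mate id mismatch: {self.r1.id!r} vs {self.r2.id!r}")


@dataclass
class ManifestEntry:
    sample_id: str
    r1_path: str
    r2_path: str | None = None
    group_label: str | None = None
    replicate_id: str | None = None


@dataclass
class SampleManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids in manifest must be unique")
        r1s = [e.r1_path for e in self.entries]
        if len(set(r1s)) != len(r1s):
            raise ValueError("every r1_path in manifest must be distinct")

    def __iter__(self) -> Iterator[ManifestEntry]:
        return iter(self.entries)


def read_manifest(path: str | os.PathLike) -> SampleManifest:
    """Load a TSV manifest: sample_id, r1_path, [r2_path, group, replicate]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = list(df.columns)
    if "sample_id" not in cols or "r1_path" not in cols:
        raise ValueError("manifest needs at least sample_id and r1_path columns")
    entries = []
    for row in df.itertuples(index=False):
        d = dict(zip(cols, row))
        entries.append(
            ManifestEntry(
                sample_id=d["sample_id"],
                r1_path=d["r1_path"],
                r2_path=d.get("r2_path") or None,
                group_label=d.get("group_label") or None,
                replicate_id=d.get("replicate_id") or None,
            )
        )
    return SampleManifest(entries)


def read_fastq(
    path: str | os.PathLike,
    mate_role: MateRole | str = MateRole.R1,
    sample_id: str = "",
) -> Iterator[Read]:
    """Stream 4-line PHRED+33 FASTQ records as :class:`Read` objects.

    Bases are uppercased on read. Malformed records raise ``ValueError``
    naming the offending line; quality characters below ``'!'`` (which
    would imply a negative PHRED score, or PHRED+64 confusion) are a
    hard error.
    """
    mate_role = MateRole(mate_role)
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"{path}: line {lineno}: expected '@' header")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"{path}: truncated record at line {lineno}")
            lineno += 3
            seq = seq.strip().upper()
            qual = qual.strip()
            if not plus.startswith("+"):
                raise ValueError(f"{path}: line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: line {lineno}: length mismatch between sequence "
                    f"({len(seq)}) and quality ({len(qual)})"
                )
            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
            if len(q) and q.min() < PHRED_OFFSET:
                raise ValueError(
                    f"{path}: line {lineno}: quality character below '!' — "
                    "not PHRED+33"
                )
            yield Read(
                id=header[1:].split()[0],
                bases=seq,
                quals=q - PHRED_OFFSET,
                mate_role=mate_role,
                sample_id=sample_id,
            )


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = (r.quals + PHRED_OFFSET).tobytes().decode("ascii")
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in _BioSeqIO.parse(path, "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (id, sequence) records as single-line FASTA, order preserved."""
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dup}")
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


class OTUTable:
    """Samples x OTUs count matrix plus per-OTU metadata.

    Backed by a pandas DataFrame with samples as rows and OTU ids as
    columns; ``otu_metadata`` maps otu_id -> dict with optional keys
    ``origin`` and ``taxonomy``.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        otu_metadata: dict[str, dict] | None = None,
    ) -> None:
        if (counts.values < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if counts.index.duplicated().any() or counts.columns.duplicated().any():
            raise ValueError("duplicate sample or OTU ids")
        self.counts = counts.astype(np.int64)
        self.otu_metadata = otu_metadata or {}
        unknown = set(self.otu_metadata) - set(counts.columns)
        if unknown:
            raise ValueError(f"metadata for unknown OTUs: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def taxonomy_of(self, otu_id: str) -> str | None:
        return self.otu_metadata.get(otu_id, {}).get("taxonomy")

    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return self.counts.equals(other.counts)


def write_otu_table(table: OTUTable, path: str | os.PathLike) -> None:
    """Write a QIIME-classic TSV: rows are OTUs, columns samples.

    A trailing ``taxonomy`` column is emitted when any OTU carries one.
    """
    has_tax = any("taxonomy" in m for m in table.otu_metadata.values())
    with open(path, "w") as fh:
        cols = "\t".join(table.sample_ids)
        fh.write(f"#OTU ID\t{cols}" + ("\ttaxonomy" if has_tax else "") + "\n")
        for otu in table.otu_ids:
            row = "\t".join(str(int(v)) for v in table.counts[otu].values)
            line = f"{otu}\t{row}"
            if has_tax:
                line += "\t" + (table.taxonomy_of(otu) or "")
            fh.write(line + "\n")


def read_otu_table(path: str | os.PathLike) -> OTUTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta: dict[str, dict] = {}
    if "taxonomy" in df.columns:
        for otu, tax in df["taxonomy"].items():
            if isinstance(tax, str) and tax:
                meta[str(otu)] = {"taxonomy": tax}
        df = df.drop(columns=["taxonomy"])
    df.index = df.index.astype(str)
    return OTUTable(df.T.astype(np.int64), meta)


def write_taxonomy(calls: dict[str, "object"], path: str | os.PathLike) -> None:
    """Write otu_id, lineage string, per-rank confidences as TSV.

    ``calls`` maps otu_id -> TaxonomyCall (duck-typed: .lineage_string(),
    .confidence dict).
    """
    with open(path, "w") as fh:
        fh.write("#otu_id\tlineage\tconfidences\n")
        for otu_id in calls:
            call = calls[otu_id]
            confs = ";".join(f"{r}:{c:.2f}" for r, c in call.confidence.items())
            fh.write(f"{otu_id}\t{call.lineage_string()}\t{confs}\n")


def read_lineages(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV of reference id -> semicolon lineage string."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: bad lineage line: {line!r}")
            out[parts[0]] = parts[1]
    return out


def write_lineages(lineages: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rid, lin in lineages.items():
            fh.write(f"{rid}\t{lin}\n")
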