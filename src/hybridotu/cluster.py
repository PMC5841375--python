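"""Dereplication, greedy centroid clustering and chimera detection.

OTUs are picked greedily at a fixed identity radius (97% by default) from
dereplicated units processed in decreasing abundance order, UPARSE-style:
the first unit founds a centroid, later units join the best centroid at or
above the radius, and units below the radius either found new centroids or
are discarded as chimeras. Centroid sequences are never updated after
founding, which makes the procedure deterministic.

Paired units are compared segment-wise (R1 against R1, R2 against R2) with
identities pooled over both segments, so an alignment can never cross the
R1/R2 junction. Chimeras are modelled as two-parent splices with a single
crossover, scanned exhaustively in genome-orientation coordinates
(forward segment followed by the reverse-complemented reverse segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .alignment import align_endsfree, encode, hamming_identity, match_profile, revcomp
from . import seqio


class Origin(str, Enum):
    PAIRED_BACKBONE = "PAIRED_BACKBONE"
    SINGLE_END_NEW = "SINGLE_END_NEW"


@dataclass
class DerepUnit:
    """A unique (R1, R2) sequence with its multiplicity and member reads."""

    sequence_r1: str
    sequence_r2: str | None
    size: int
    member_ids: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.size != len(self.member_ids) or self.size < 1:
            raise ValueError("unit size must equal its member count (>= 1)")
        self._enc_r1 = encode(self.sequence_r1)
        self._enc_r2 = None if self.sequence_r2 is None else encode(self.sequence_r2)

    @property
    def paired(self) -> bool:
        return self.sequence_r2 is not None


@dataclass
class OTU:
    otu_id: str
    rep_r1: str
    rep_r2: str | None
    origin: Origin
    abundance: int
    member_units: list[int] = field(default_factory=list)
    taxonomy: str | None = None

    def __post_init__(self) -> None:
        if self.origin is Origin.PAIRED_BACKBONE and self.rep_r2 is None:
            raise ValueError("paired-backbone OTU requires an R2 segment")
        if self.origin is Origin.SINGLE_END_NEW and self.rep_r2 is not None:
            raise ValueError("single-end OTU must not carry an R2 segment")
        if self.abundance < 1:
            raise ValueError("OTU abundance must be >= 1")
        self._enc_r1 = encode(self.rep_r1)
        self._enc_r2 = None if self.rep_r2 is None else encode(self.rep_r2)


@dataclass
class ChimeraVerdict:
    is_chimera: bool
    parent_a: str | None = None
    parent_b: str | None = None
    crossover: int | None = None
    model_identity: float | None = None


def dereplicate(records) -> list[DerepUnit]:
    """Collapse identical (R1, R2) sequences into abundance-carrying units.

    ``records`` yields (r1_seq, r2_seq_or_None, sample_id, read_id). The
    result is sorted by size descending, ties broken lexicographically by
    sequence, so clustering input order is independent of file order.
    """
    buckets: dict[tuple[str, str | None], list[tuple[str, str]]] = {}
    for r1_seq, r2_seq, sample_id, read_id in records:
        buckets.setdefault((r1_seq, r2_seq), []).append((sample_id, read_id))
    units = [
        DerepUnit(k[0], k[1], len(v), v)
        for k, v in buckets.items()
    ]
    units.sort(key=lambda u: (-u.size, u.sequence_r1, u.sequence_r2 or ""))
    return units


def _segment_identity_exact(a: str, b: str) -> tuple[int, int]:
    res = align_endsfree(a, b)
    return res.matches, res.aligned_columns


def _segment_identity_fast(ea: np.ndarray, eb: np.ndarray, a: str, b: str) -> tuple[int, int]:
    if ea.shape[0] == eb.shape[0]:
        return int(np.count_nonzero(ea == eb)), ea.shape[0]
    return _segment_identity_exact(a, b)


def pair_identity_covered(
    q: DerepUnit | OTU,
    c: DerepUnit | OTU,
    fast: bool = False,
    min_cover: float = 0.8,
) -> float:
    """Pooled identity, zeroed when the alignment covers too little sequence.

    A dovetail ends-free alignment of two *unrelated* sequences can degenerate
    to a short perfect overlap with identity 1; genuine homologs align over
    nearly their full (shorter) length. Radius decisions therefore require the
    aligned columns to cover at least ``min_cover`` of the shorter segment,
    pooled over segments; otherwise the pair is treated as no hit (0.0).
    """
    a1 = q.sequence_r1 if isinstance(q, DerepUnit) else q.rep_r1
    a2 = q.sequence_r2 if isinstance(q, DerepUnit) else q.rep_r2
    b1 = c.sequence_r1 if isinstance(c, DerepUnit) else c.rep_r1
    b2 = c.sequence_r2 if isinstance(c, DerepUnit) else c.rep_r2
    if (a2 is None) != (b2 is None):
        raise ValueError(
            "pair_identity requires both operands paired or both single-end"
        )
    if fast:
        m1, n1 = _segment_identity_fast(q._enc_r1, c._enc_r1, a1, b1)
    else:
        m1, n1 = _segment_identity_exact(a1, b1)
    short = min(len(a1), len(b1))
    m, n = m1, n1
    if a2 is not None:
        if fast:
            m2, n2 = _segment_identity_fast(q._enc_r2, c._enc_r2, a2, b2)
        else:
            m2, n2 = _segment_identity_exact(a2, b2)
        short += min(len(a2), len(b2))
        m += m2
        n += n2
    if n == 0 or n < min_cover * short:
        return 0.0
    return m / n


def pair_identity(q: DerepUnit | OTU, c: DerepUnit | OTU, fast: bool = False) -> float:
    """Pooled segment-wise identity between two units/centroids.

    Both operands must agree on R2 presence. With ``fast=True`` equal-length
    segments are compared gaplessly (exact whenever the optimal alignment
    has no internal gaps, which holds under substitution-only divergence);
    unequal lengths always use the full ends-free DP.
    """
    a1 = q.sequence_r1 if isinstance(q, DerepUnit) else q.rep_r1
    a2 = q.sequence_r2 if isinstance(q, DerepUnit) else q.rep_r2
    b1 = c.sequence_r1 if isinstance(c, DerepUnit) else c.rep_r1
    b2 = c.sequence_r2 if isinstance(c, DerepUnit) else c.rep_r2
    if (a2 is None) != (b2 is None):
        raise ValueError(
            "pair_identity requires both operands paired or both single-end; "
            "cross-type comparison belongs to the hybrid mapping stage"
        )
    if fast:
        m1, n1 = _segment_identity_fast(q._enc_r1, c._enc_r1, a1, b1)
    else:
        m1, n1 = _segment_identity_exact(a1, b1)
    if a2 is None:
        return m1 / n1 if n1 else 0.0
    if fast:
        m2, n2 = _segment_identity_fast(q._enc_r2, c._enc_r2, a2, b2)
    else:
        m2, n2 = _segment_identity_exact(a2, b2)
    total = n1 + n2
    return (m1 + m2) / total if total else 0.0


def _genomic_profile(q, parent_r1: str, parent_r2: str | None) -> np.ndarray:
    """Per-position match profile of q against a parent, genome orientation.

    Forward-segment profile, then the reverse-segment profile reversed so
    the concatenated coordinate runs 5'->3' along the amplicon; a chimeric
    splice is then a prefix/suffix pattern regardless of where the
    crossover fell.
    """
    q_r1 = q.sequence_r1 if isinstance(q, DerepUnit) else q.rep_r1
    q_r2 = q.sequence_r2 if isinstance(q, DerepUnit) else q.rep_r2
    prof1 = match_profile(q_r1, parent_r1)
    if q_r2 is None:
        return prof1
    if parent_r2 is None:
        raise ValueError("paired query profiled against single-end parent")
    prof2 = match_profile(q_r2, parent_r2)[::-1]
    return np.concatenate([prof1, prof2])


def _best_splice(profiles: np.ndarray) -> tuple[int, int, int, int]:
    """Best two-parent splice over candidate match profiles.

    Returns (matches, parent_a_idx, parent_b_idx, crossover); the model at
    crossover x takes parent A over positions [0, x) and parent B over
    [x, L).
    """
    pref = np.concatenate(
        [np.zeros((profiles.shape[0], 1), dtype=np.int64),
         np.cumsum(profiles, axis=1, dtype=np.int64)],
        axis=1,
    )
    tot = pref[:, -1]
    best = (-1, 0, 0, 0)
    for a in range(profiles.shape[0]):
        for b in range(profiles.shape[0]):
            if a == b:
                continue
            gain = pref[a] - pref[b]
            x = int(np.argmax(gain))
            score = int(gain[x] + tot[b])
            if score > best[0]:
                best = (score, a, b, x)
    return best


def detect_chimera(
    q: DerepUnit,
    centroids: list[OTU],
    min_parent_id: float = 0.90,
    model_min_id: float = 0.99,
    margin: float = 0.01,
    max_parents: int = 8,
    identities: list[float] | None = None,
) -> ChimeraVerdict:
    """Two-parent chimera test of a unit that failed the clustering radius.

    Candidate parents are the up-to-``max_parents`` centroids most similar
    to the query, each at identity >= ``min_parent_id``. Every ordered
    parent pair and crossover position is scored; the query is chimeric iff
    the best spliced model reaches ``model_min_id`` identity and beats the
    best single parent by at least ``margin``.
    """
    if identities is None:
        identities = [pair_identity_covered(q, c, fast=True) for c in centroids]
    order = sorted(range(len(centroids)), key=lambda i: -identities[i])
    cand = [i for i in order if identities[i] >= min_parent_id][:max_parents]
    if len(cand) < 2:
        return ChimeraVerdict(False)
    best_single = max(identities[i] for i in cand)
    profiles = np.stack(
        [_genomic_profile(q, centroids[i].rep_r1, centroids[i].rep_r2) for i in cand]
    )
    L = profiles.shape[1]
    matches, ai, bi, x = _best_splice(profiles)
    model_id = matches / L
    if model_id >= model_min_id and model_id - best_single >= margin - 1e-12:
        return ChimeraVerdict(
            True,
            parent_a=centroids[cand[ai]].otu_id,
            parent_b=centroids[cand[bi]].otu_id,
            crossover=x,
            model_identity=model_id,
        )
    return ChimeraVerdict(False)


def greedy_cluster(
    units: list[DerepUnit],
    radius: float = 0.97,
    chimera_check: bool = True,
    id_prefix: str = "OTU_",
    origin: Origin | None = None,
    fast_identity: bool = False,
    check_centroid_separation: bool = True,
) -> tuple[list[OTU], list[str | None], list[tuple[DerepUnit, ChimeraVerdict]]]:
    """Abundance-sorted greedy centroid clustering at the given radius.

    Returns (centroids, assignments, discarded): ``assignments`` is parallel
    to ``units`` and holds the otu_id each unit joined (None for discarded
    chimeras). Ties on best identity go to the more abundant centroid, then
    to founding order. Input must already be sorted by size descending.
    """
    for prev, cur in zip(units, units[1:]):
        if cur.size > prev.size:
            raise ValueError("greedy_cluster input must be sorted by size descending")
    if origin is None:
        origin = (
            Origin.PAIRED_BACKBONE
            if units and units[0].paired
            else Origin.SINGLE_END_NEW
        )
    centroids: list[OTU] = []
    assignments: list[str | None] = [None] * len(units)
    discarded: list[tuple[DerepUnit, ChimeraVerdict]] = []
    for ui, unit in enumerate(units):
        best_i = -1
        best_id = -1.0
        identities = []
        for ci, c in enumerate(centroids):
            ident = pair_identity_covered(unit, c, fast=fast_identity)
            identities.append(ident)
            if ident > best_id + 1e-12 or (
                abs(ident - best_id) <= 1e-12
                and best_i >= 0
                and c.abundance > centroids[best_i].abundance
            ):
                best_id = ident
                best_i = ci
        if best_i >= 0 and best_id >= radius:
            c = centroids[best_i]
            c.abundance += unit.size
            c.member_units.append(ui)
            assignments[ui] = c.otu_id
            continue
        if chimera_check and centroids:
            verdict = detect_chimera(unit, centroids, identities=identities)
            if verdict.is_chimera:
                discarded.append((unit, verdict))
                continue
        otu = OTU(
            otu_id=f"{id_prefix}{len(centroids) + 1}",
            rep_r1=unit.sequence_r1,
            rep_r2=unit.sequence_r2,
            origin=origin,
            abundance=unit.size,
            member_units=[ui],
        )
        assignments[ui] = otu.otu_id
        centroids.append(otu)
    if check_centroid_separation:
        for i in range(len(centroids)):
            for j in range(i + 1, len(centroids)):
                ident = pair_identity_covered(
                    centroids[i], centroids[j], fast=fast_identity
                )
                assert ident < radius, (
                    f"centroids {centroids[i].otu_id} and {centroids[j].otu_id} "
                    f"at identity {ident:.4f} >= radius {radius}"
                )
    assert sum(c.abundance for c in centroids) + sum(
        u.size for u, _ in discarded
    ) == sum(u.size for u in units)
    return centroids, assignments, discarded


def reference_chimera_screen(
    otus: list[OTU],
    ref: "str | list[tuple[str, str]] | None",
    min_parent_id: float = 0.90,
    model_min_id: float = 0.99,
    margin: float = 0.01,
    max_parents: int = 8,
) -> list[OTU]:
    """Drop OTUs that are two-parent splices of user-supplied references.

    ``ref`` may be a FASTA path or a list of (id, sequence); when absent
    the input is returned unchanged. Reference sequences are full-length
    amplicons: each OTU segment is aligned ends-free into the reference,
    the reverse segment in genome orientation.
    """
    if ref is None or ref == "":
        return list(otus)
    refs = seqio.read_fasta(ref) if isinstance(ref, str) else list(ref)
    if not refs:
        return list(otus)
    retained: list[OTU] = []
    for otu in otus:
        genomic_r2 = None if otu.rep_r2 is None else revcomp(otu.rep_r2)
        profs = []
        idents = []
        for _, rseq in refs:
            p1 = match_profile(otu.rep_r1, rseq)
            if genomic_r2 is None:
                prof = p1
            else:
                prof = np.concatenate([p1, match_profile(genomic_r2, rseq)])
            profs.append(prof)
            idents.append(prof.mean())
        order = sorted(range(len(refs)), key=lambda i: -idents[i])
        cand = [i for i in order if idents[i] >= min_parent_id][:max_parents]
        if len(cand) < 2:
            retained.append(otu)
            continue
        best_single = max(idents[i] for i in cand)
        matches, _, _, _ = _best_splice(np.stack([profs[i] for i in cand]))
        model_id = matches / profs[0].shape[0]
        if model_id >= model_min_id and model_id - best_single >= margin - 1e-12:
            continue
        retained.append(otu)
    return retained
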