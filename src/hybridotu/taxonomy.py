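"""Naive-Bayes taxonomy classification with bootstrap confidence.

An 8-mer word model in the style of the classic ribosomal-database
classifier: training counts, per genus, the number of reference sequences
containing each word; classification draws 1/8 of a query's words per
bootstrap replicate and assigns the genus maximizing the summed
log-likelihood, with per-rank confidence equal to the fraction of
replicates agreeing with the full-word-set winner at that rank. Words
containing N are skipped everywhere, which is how the N spacer inside
stitched representatives is neutralized.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import seqio

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIX = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__")))

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def extract_words(seq: str, word_size: int = 8) -> np.ndarray:
    """All overlapping word ids (base-4 encoding); words containing N skipped."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.shape[0] < word_size:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, word_size)
    valid = (win != 255).all(axis=1)
    pw = 4 ** np.arange(word_size - 1, -1, -1, dtype=np.int64)
    return (win[valid].astype(np.int64) @ pw)


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a 'k__X;p__Y;...' string into per-rank labels (prefixes kept)."""
    parts = tuple(p.strip() for p in lineage.split(";") if p.strip())
    if len(parts) != len(RANKS):
        raise ValueError(
            f"lineage must have {len(RANKS)} ranks (kingdom..genus): {lineage!r}"
        )
    return parts


@dataclass
class TaxonomyModel:
    word_size: int
    genus_lineages: list[tuple[str, ...]]   # one full lineage per genus index
    log_cond: np.ndarray                    # (n_genera, 4**word_size) float32
    ranks: tuple[str, ...] = RANKS
    word_totals: np.ndarray | None = None   # per-word reference occurrence counts

    @property
    def n_genera(self) -> int:
        return len(self.genus_lineages)


def train(
    refs: "str | list[tuple[str, str]]",
    lineages: "str | dict[str, str]",
    word_size: int = 8,
) -> TaxonomyModel:
    """Fit the word model: P(w|g) = (n(w,g) + Pr(w)) / (N(g) + 1).

    n(w,g) counts reference sequences of genus g containing word w, N(g)
    the sequences in g, and the word prior Pr(w) is
    (sequences containing w + 0.5) / (total sequences + 1).
    """
    if isinstance(refs, str):
        refs = seqio.read_fasta(refs)
    if isinstance(lineages, str):
        lineages = seqio.read_lineages(lineages)
    seen: set[str] = set()
    V = 4**word_size
    genus_index: dict[tuple[str, ...], int] = {}
    per_seq: list[tuple[int, np.ndarray]] = []
    for rid, seq in refs:
        if rid in seen:
            raise ValueError(f"duplicate reference id: {rid}")
        seen.add(rid)
        if rid not in lineages:
            raise ValueError(f"reference {rid!r} has no lineage row")
        lin = parse_lineage(lineages[rid])
        gi = genus_index.setdefault(lin, len(genus_index))
        words = np.unique(extract_words(seq.upper(), word_size))
        per_seq.append((gi, words))
    G = len(genus_index)
    n_wg = np.zeros((G, V), dtype=np.float32)
    contain = np.zeros(V, dtype=np.float64)
    n_g = np.zeros(G, dtype=np.float64)
    for gi, words in per_seq:
        n_wg[gi, words] += 1
        contain[words] += 1
        n_g[gi] += 1
    S = len(per_seq)
    prior = (contain + 0.5) / (S + 1.0)
    log_cond = np.log(n_wg + prior.astype(np.float32)) - np.log(
        (n_g + 1.0)[:, None]
    ).astype(np.float32)
    genus_lineages = [None] * G
    for lin, gi in genus_index.items():
        genus_lineages[gi] = lin
    return TaxonomyModel(
        word_size=word_size,
        genus_lineages=genus_lineages,
        log_cond=log_cond.astype(np.float32),
        word_totals=contain,
    )


@dataclass
class TaxonomyCall:
    lineage: tuple[str, ...] = ()            # full lineage of the winning genus
    confidence: dict[str, float] = field(default_factory=dict)
    assigned_rank: str | None = None         # deepest rank meeting the threshold

    @property
    def unclassified(self) -> bool:
        return not self.lineage

    def label(self, rank: str) -> str | None:
        if not self.lineage:
            return None
        return self.lineage[RANKS.index(rank)]

    def kingdom_label(self) -> str | None:
        lab = self.label("kingdom")
        return lab.removeprefix("k__") if lab else None

    def lineage_string(self) -> str:
        """Lineage truncated at the assigned rank; 'Unclassified' if none."""
        if not self.lineage or self.assigned_rank is None:
            return "Unclassified"
        depth = RANKS.index(self.assigned_rank) + 1
        return ";".join(self.lineage[:depth])


def _call_rng(seed: int, seq_id: str) -> np.random.Generator:
    # one stream per (seed, id) so per-OTU calls are order-independent
    mix = zlib.crc32(f"{seed}:{seq_id}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(mix)


def classify(
    seq: str,
    model: TaxonomyModel,
    n_bootstrap: int = 100,
    subsample_frac: float = 1 / 8,
    conf_threshold: float = 0.8,
    seed: int = 0,
    seq_id: str = "",
) -> TaxonomyCall:
    """Bootstrap naive-Bayes call for one sequence.

    Returns an UNCLASSIFIED call when the sequence yields no valid words.
    Confidences are monotone non-increasing with depth because agreement
    at a deeper rank implies agreement at every rank above it.
    """
    words = extract_words(seq.upper(), model.word_size)
    if words.shape[0] == 0:
        return TaxonomyCall()
    W = model.log_cond[:, words]                      # (G, n_words)
    point_winner = int(np.argmax(W.sum(axis=1)))
    point_lin = model.genus_lineages[point_winner]
    m = math.ceil(words.shape[0] * subsample_frac)
    rng = _call_rng(seed, seq_id)
    idx = rng.integers(0, words.shape[0], size=(n_bootstrap, m))
    scores = W[:, idx].sum(axis=2)                    # (G, n_bootstrap)
    winners = np.argmax(scores, axis=0)
    lineages = [model.genus_lineages[g] for g in winners]
    confidence: dict[str, float] = {}
    for ri, rank in enumerate(model.ranks):
        agree = sum(1 for lin in lineages if lin[ri] == point_lin[ri])
        confidence[rank] = agree / n_bootstrap
    assigned = None
    for ri, rank in enumerate(model.ranks):
        if confidence[rank] >= conf_threshold:
            assigned = rank
        else:
            break
    return TaxonomyCall(lineage=point_lin, confidence=confidence, assigned_rank=assigned)


def filter_nonbacteria(
    otus: list,
    calls: dict[str, TaxonomyCall],
    conf_threshold: float = 0.8,
) -> tuple[list, list[tuple[str, str]]]:
    """Drop OTUs not confidently classified as Bacteria at kingdom level.

    UNCLASSIFIED-at-kingdom OTUs are removed too (conservative reading:
    presumed contaminants). Returns (retained, removals) where removals are
    (otu_id, reason) pairs.
    """
    retained = []
    removed: list[tuple[str, str]] = []
    for otu in otus:
        call = calls[otu.otu_id]
        if call.unclassified:
            removed.append((otu.otu_id, "unclassified at kingdom"))
        elif call.kingdom_label() != "Bacteria":
            removed.append((otu.otu_id, f"kingdom {call.kingdom_label()}"))
        elif call.confidence.get("kingdom", 0.0) < conf_threshold:
            removed.append((otu.otu_id, "kingdom confidence below threshold"))
        else:
            retained.append(otu)
    return retained, removed
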