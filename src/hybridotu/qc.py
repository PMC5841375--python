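"""Read quality control and pair synchronization.

The QC stage reproduces Trimmomatic-style filtering: hard Q3 clipping of
both read ends, a 4-base Q15 moving-average cut of the 3' end, a
75%-of-original-length floor, and rejection of reads containing ambiguous
bases. Surviving mates are truncated to uniform lengths (250 bp forward,
200 bp reverse by default) so that downstream identity comparisons operate
on fixed coordinates.

A pair whose reverse read fails any step while the forward read survives
becomes an *orphan*: its forward read is carried into the hybrid stage as
a single-end read. Pairs whose forward read fails are dropped outright —
the pipeline is R1-anchored and never uses orphan reverse reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np

from .seqio import Read, ReadPair


@dataclass(frozen=True)
class QCParams:
    hard_end_q: int = 3
    window_size: int = 4
    window_mean_q: float = 15.0
    min_len_frac: float = 0.75
    r1_trunc_len: int = 250
    r2_trunc_len: int = 200
    reject_ambiguous: bool = True

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0 < self.min_len_frac <= 1):
            raise ValueError("min_len_frac must be in (0, 1]")
        if self.r1_trunc_len <= 0 or self.r2_trunc_len <= 0:
            raise ValueError("truncation lengths must be positive")


class QCStatus(Enum):
    PASS = "PASS"
    FAIL_SHORT = "FAIL_SHORT"
    FAIL_AMBIGUOUS = "FAIL_AMBIGUOUS"


@dataclass
class QCOutcome:
    status: QCStatus
    trimmed: Read | None
    original_len: int

    def __post_init__(self) -> None:
        if (self.trimmed is not None) != (self.status is QCStatus.PASS):
            raise ValueError("trimmed read present iff status is PASS")


def trim_read(read: Read, params: QCParams = QCParams()) -> QCOutcome:
    """Quality-trim one read; returns PASS with the trimmed read or a failure.

    Steps, in order: (1) strip 5' bases with quality below the hard cutoff;
    (2) strip 3' bases likewise; (3) scan 5'->3' with a moving window and cut
    immediately before the first window whose mean quality falls below the
    threshold (only positions where a full window fits are evaluated);
    (4) fail unless the trimmed length is at least ``min_len_frac`` of the
    *original* length; (5) fail if any ambiguous base remains.
    """
    L0 = len(read)
    q = read.quals.astype(np.int32)
    ok = q >= params.hard_end_q
    if not ok.any():
        return QCOutcome(QCStatus.FAIL_SHORT, None, L0)
    lo = int(np.argmax(ok))            # first base meeting the hard cutoff
    hi = L0 - int(np.argmax(ok[::-1]))  # one past the last such base
    span = q[lo:hi]
    n = hi - lo
    w = params.window_size
    if n >= w:
        sums = np.convolve(span, np.ones(w, dtype=np.int64), mode="valid")
        bad = sums < params.window_mean_q * w
        if bad.any():
            n = int(np.argmax(bad))  # cut before the first failing window
    trimmed_len = n
    if trimmed_len < params.min_len_frac * L0 or trimmed_len == 0:
        return QCOutcome(QCStatus.FAIL_SHORT, None, L0)
    bases = read.bases[lo : lo + trimmed_len]
    if params.reject_ambiguous and "N" in bases:
        return QCOutcome(QCStatus.FAIL_AMBIGUOUS, None, L0)
    trimmed = replace(read, bases=bases, quals=read.quals[lo : lo + trimmed_len])
    return QCOutcome(QCStatus.PASS, trimmed, L0)


def truncate_to_length(read: Read, L: int) -> Read | None:
    """Cut a read to its first ``L`` bases; ``None`` (reject) if shorter.

    Uniform lengths are required before concatenated-pair clustering.
    """
    if L <= 0:
        raise ValueError("truncation length must be positive")
    if len(read) < L:
        return None
    if len(read) == L:
        return read
    return replace(read, bases=read.bases[:L], quals=read.quals[:L])


@dataclass
class QCLog:
    input_pairs: int = 0
    paired_out: int = 0
    orphan_out: int = 0
    dropped: int = 0
    r1_pass: int = 0
    r2_pass: int = 0
    counters: dict = field(default_factory=dict)

    def check(self) -> None:
        assert self.paired_out + self.orphan_out + self.dropped == self.input_pairs


def _survive(read: Read, params: QCParams, trunc_len: int) -> Read | None:
    out = trim_read(read, params)
    if out.status is not QCStatus.PASS:
        return None
    return truncate_to_length(out.trimmed, trunc_len)


def qc_sample(
    r1_reads: Iterable[Read],
    r2_reads: Iterable[Read | None],
    params: QCParams = QCParams(),
) -> tuple[list[ReadPair], list[Read], QCLog]:
    """QC one sample's mate files into surviving pairs and orphan R1s.

    ``r2_reads`` entries may be ``None`` for pairs whose reverse read is
    already absent (e.g. after controlled R2 removal); those contribute
    orphans directly when the forward read survives. Mate streams must be
    id-synchronized; a mismatch is a hard error.
    """
    pairs: list[ReadPair] = []
    orphans: list[Read] = []
    log = QCLog()
    sentinel = object()
    it2 = iter(r2_reads)
    for r1 in r1_reads:
        r2 = next(it2, sentinel)
        if r2 is sentinel:
            raise ValueError("R2 stream shorter than R1 stream")
        if r2 is not None and r1.id != r2.id:
            raise ValueError(f"mate id mismatch: {r1.id!r} vs {r2.id!r}")
        log.input_pairs += 1
        t1 = _survive(r1, params, params.r1_trunc_len)
        if t1 is None:
            log.dropped += 1
            continue
        log.r1_pass += 1
        t2 = None if r2 is None else _survive(r2, params, params.r2_trunc_len)
        if t2 is None:
            log.orphan_out += 1
            orphans.append(t1)
        else:
            log.r2_pass += 1
            log.paired_out += 1
            pairs.append(ReadPair(t1, t2))
    if next(it2, sentinel) is not sentinel:
        raise ValueError("R2 stream longer than R1 stream")
    log.check()
    return pairs, orphans, log
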