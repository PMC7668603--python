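"""Adapter and quality trimming for small-RNA reads.

Small-RNA libraries are sequenced longer than the insert (50 nt single-end
for a ~22-31 nt mature RNA), so nearly every read runs into the 3' ligation
adapter. This module removes the adapter by error-tolerant semi-global
matching against the read 3' end, trims low-quality tails with the running
sum rule, and applies a length filter that keeps the miRNA/piRNA size range.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

DEFAULT_ADAPTER = "AGATCGGAAGAGC"

_PHRED_OFFSET = 33


@dataclass
class TrimParams:
    """Parameters of the trimming stage.

    ``adapter_seq`` may be ``None`` or empty to disable adapter removal
    (e.g. for libraries already trimmed upstream).
    """

    adapter_seq: str | None = DEFAULT_ADAPTER
    max_error_rate: float = 0.1
    min_overlap: int = 3
    quality_cutoff: int = 20
    min_length: int = 15
    max_length: int = 45

    def __post_init__(self) -> None:
        if not (0 <= self.max_error_rate < 0.5):
            raise ValueError("max_error_rate must be in [0, 0.5)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")


def _adapter_cut(seq: str, adapter: str, max_error_rate: float,
                 min_overlap: int) -> int | None:
    """Best 3' semi-global match of ``adapter`` in ``seq``.

    Returns the cut index (everything from that index on is removed) or
    ``None`` when no acceptable match exists.  Candidate matches either place
    the full adapter inside the read (everything 3' of it is discarded too)
    or overlap the read's 3' end with a prefix of the adapter.  A match is
    acceptable when errors / overlap <= max_error_rate and overlap >=
    min_overlap; among acceptable matches the fewest errors win, then the
    longest overlap, then the earliest cut point.
    """
    L, A = len(seq), len(adapter)
    if L == 0:
        return None
    # Fast path: a leftmost exact full-adapter occurrence is always optimal
    # (zero errors, maximal overlap, earliest such cut).
    j = seq.find(adapter)
    if j != -1:
        return j
    best: tuple[int, int, int] | None = None
    for i in range(max(0, L - min_overlap), -1, -1):
        ov = min(A, L - i)
        if ov < min_overlap:
            continue
        errs = sum(a != b for a, b in zip(seq[i:i + ov], adapter[:ov]))
        if errs <= max_error_rate * ov:
            key = (errs, -ov, i)
            if best is None or key < best:
                best = key
    return best[2] if best else None


def trim_adapter(seq: str, qual: str, params: TrimParams) -> tuple[str, str]:
    """Remove the 3' adapter from one read, iterating to a fixed point.

    Matching is repeated on the trimmed read until no acceptable match
    remains, which makes the operation idempotent.  Qualities are sliced
    in step with the sequence.
    """
    if not params.adapter_seq:
        return seq, qual
    while True:
        cut = _adapter_cut(seq, params.adapter_seq, params.max_error_rate,
                           params.min_overlap)
        if cut is None:
            return seq, qual
        seq, qual = seq[:cut], qual[:cut]


def quality_trim(seq: str, qual: str, quality_cutoff: int) -> tuple[str, str]:
    """Trim the 3' end by the running-sum rule.

    For every suffix start c the partial sum S(c) = sum_{i>=c} (q_i - cutoff)
    is evaluated (the empty suffix scores 0); the read is cut at the c with
    the minimal sum, keeping the read intact on ties.
    """
    if not seq:
        return seq, qual
    cut = len(seq)
    s = 0
    best = 0
    for i in range(len(seq) - 1, -1, -1):
        s += (ord(qual[i]) - _PHRED_OFFSET) - quality_cutoff
        if s < best:
            best = s
            cut = i
    return seq[:cut], qual[:cut]


def length_filter(reads: Iterable[tuple[str, str, str]], min_length: int,
                  max_length: int) -> tuple[list[tuple[str, str, str]], dict]:
    """Keep reads whose length is within [min_length, max_length].

    Returns the passing reads and an attrition report.
    """
    if min_length > max_length:
        raise ValueError("min_length must not exceed max_length")
    kept: list[tuple[str, str, str]] = []
    too_short = too_long = 0
    for rec in reads:
        n = len(rec[1])
        if n < min_length:
            too_short += 1
        elif n > max_length:
            too_long += 1
        else:
            kept.append(rec)
    report = {"input": too_short + too_long + len(kept), "kept": len(kept),
              "too_short": too_short, "too_long": too_long}
    return kept, report


# ---------------------------------------------------------------------------
# batched trimming (vectorised adapter scan for whole libraries)

_BASE_DTYPE = np.uint8


def _encode(seqs: Sequence[str], width: int) -> np.ndarray:
    buf = np.zeros((len(seqs), width), dtype=_BASE_DTYPE)
    for i, s in enumerate(seqs):
        buf[i, :len(s)] = np.frombuffer(s.encode(), dtype=_BASE_DTYPE)
    return buf


def _adapter_cuts_batch(seqs: Sequence[str], adapter: str,
                        max_error_rate: float, min_overlap: int) -> np.ndarray:
    """Vectorised equivalent of :func:`_adapter_cut` over many reads.

    Returns per-read cut indices; ``-1`` means no acceptable match.
    """
    n = len(seqs)
    lengths = np.fromiter((len(s) for s in seqs), count=n, dtype=np.int64)
    lmax = int(lengths.max(initial=0))
    A = len(adapter)
    mat = _encode(seqs, lmax + A)  # padded with 0 == no base
    ad = np.frombuffer(adapter.encode(), dtype=_BASE_DTYPE)
    best_key = np.full(n, np.inf)
    best_cut = np.full(n, -1, dtype=np.int64)
    rows = np.arange(n)
    for i in range(lmax - min_overlap + 1):
        mism = mat[:, i:i + A] != ad
        cum = np.cumsum(mism, axis=1)
        ov = np.minimum(A, lengths - i)
        valid = ov >= min_overlap
        errs = cum[rows, np.maximum(ov, 1) - 1]
        ok = valid & (errs <= max_error_rate * ov)
        # fewest errors, then longest overlap, then earliest cut
        key = errs * 1e6 + (A - ov) * 1e3 + i
        upd = ok & (key < best_key)
        best_key[upd] = key[upd]
        best_cut[upd] = i
    return best_cut


def trim_reads(reads: Sequence[tuple[str, str, str]],
               params: TrimParams) -> tuple[list[tuple[str, str, str]], dict]:
    """Trim a whole library in memory.

    ``reads`` are ``(name, sequence, qualities)`` triples.  Adapter removal
    (batched, iterated to a fixed point), quality trimming and the length
    filter are applied in order; the attrition report counts reads dropped
    at each stage.
    """
    names = [r[0] for r in reads]
    seqs = [r[1] for r in reads]
    quals = [r[2] for r in reads]
    n_adapter_trimmed = 0
    if params.adapter_seq and seqs:
        pending = np.arange(len(seqs))
        touched = np.zeros(len(seqs), dtype=bool)
        while len(pending):
            cuts = _adapter_cuts_batch([seqs[i] for i in pending],
                                       params.adapter_seq,
                                       params.max_error_rate,
                                       params.min_overlap)
            hit = cuts >= 0
            for j, i in enumerate(pending[hit]):
                c = int(cuts[hit][j])
                seqs[i], quals[i] = seqs[i][:c], quals[i][:c]
            touched[pending[hit]] = True
            pending = pending[hit]
        n_adapter_trimmed = int(touched.sum())
    qmin = chr(params.quality_cutoff + _PHRED_OFFSET)
    for i, q in enumerate(quals):
        if q and min(q) < qmin:
            seqs[i], quals[i] = quality_trim(seqs[i], quals[i],
                                             params.quality_cutoff)
    kept, report = length_filter(zip(names, seqs, quals),
                                 params.min_length, params.max_length)
    report["adapter_trimmed"] = n_adapter_trimmed
    return kept, report


# ---------------------------------------------------------------------------
# FASTQ I/O

def read_fastq(path: str) -> list[tuple[str, str, str]]:
    """Read a (optionally gzipped) FASTQ file into (name, seq, qual) triples."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        return [(e.name, e.sequence, e.quality or "") for e in fh]


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str) -> None:
    """Write (name, seq, qual) triples as Phred+33 FASTQ (.gz if so named).

    Gzip streams are written with a zeroed mtime so identical content gives
    identical bytes (seed-reproducibility of simulated libraries).
    """
    path = str(path)
    if path.endswith(".gz"):
        import io

        with open(path, "wb") as raw, \
                gzip.GzipFile("", fileobj=raw, mode="wb", mtime=0) as gz, \
                io.TextIOWrapper(gz) as fh:
            for name, seq, qual in reads:
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    else:
        with open(path, "w") as fh:
            for name, seq, qual in reads:
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def trim_fastq(in_path: str, out_path: str, params: TrimParams,
               report_path: str | None = None) -> dict:
    """File-level trimming: FASTQ in, trimmed FASTQ out, report returned."""
    reads = read_fastq(in_path)
    kept, report = trim_reads(reads, params)
    write_fastq(kept, out_path)
    if report_path:
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
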