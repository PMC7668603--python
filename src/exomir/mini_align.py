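"""Desk-scale ungapped short-read aligner with best-stratum reporting.

Reproduces the reporting contract of a classic mismatch-mode short-read
aligner run as ``-v V -k K --best --strata``: every end-to-end placement of
the read with at most ``V`` substitutions is found (no indels), only the
minimal-mismatch stratum is reported, and at most ``K`` placements are
emitted in a deterministic canonical order.  ``n_placements`` carries the
stratum size before truncation (capped at ``K``), which is the ``n`` used by
downstream 1/n fractional counting of multi-mapped reads.

Candidate generation uses pigeonhole seeding: the read is cut into
``V + 1`` disjoint pieces, at least one of which must match the genome
exactly; exact piece hits come from per-length k-mer tables built lazily
over the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignerParams:
    """Alignment parameters (mismatch budget, report cap, stratum mode)."""

    max_mismatches: int = 1   # -v
    report_cap: int = 100     # -k
    best_strata: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches not in (0, 1, 2, 3):
            raise ValueError("max_mismatches must be in {0,1,2,3}")
        if self.report_cap < 1:
            raise ValueError("report_cap must be >= 1")


@dataclass(frozen=True)
class AlignmentRecord:
    """One placement of one read (0-based half-open genomic interval)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    n_placements: int


class GenomeIndex:
    """Exact k-mer lookup over a small genome, both strands via the query.

    Per-length k-mer position tables are built lazily the first time a piece
    of that length is queried and cached for the life of the index.
    """

    def __init__(self, genome: Mapping[str, str], seed_length: int = 12):
        if not genome:
            raise ValueError("empty genome")
        self.seed_length = seed_length
        self.chroms = sorted(genome)
        self._seqs = {c: genome[c].upper() for c in self.chroms}
        if max(len(s) for s in self._seqs.values()) < seed_length:
            raise ValueError("genome shorter than seed_length")
        self._arrays = {c: np.frombuffer(self._seqs[c].encode(), dtype=np.uint8)
                        for c in self.chroms}
        self._tables: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def _table(self, k: int) -> dict[str, list[tuple[str, int]]]:
        tab = self._tables.get(k)
        if tab is None:
            tab = {}
            for c in self.chroms:
                s = self._seqs[c]
                for i in range(len(s) - k + 1):
                    tab.setdefault(s[i:i + k], []).append((c, i))
            self._tables[k] = tab
        return tab

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Forward-strand positions of an exact k-mer."""
        return self._table(len(kmer)).get(kmer.upper(), [])


def build_index(genome: Mapping[str, str], seed_length: int = 12) -> GenomeIndex:
    return GenomeIndex(genome, seed_length)


_STRAND_ORDER = {"+": 0, "-": 1}


def _placements(seq: str, index: GenomeIndex,
                v: int) -> list[tuple[str, int, str, int]]:
    """All (chrom, start, strand, mismatches) placements with <= v subs."""
    L = len(seq)
    out = []
    seen = set()
    for strand in "+-":
        query = seq.upper() if strand == "+" else revcomp(seq).upper()
        qarr = np.frombuffer(query.encode(), dtype=np.uint8)
        # v+1 disjoint pieces: with <= v mismatches one piece is exact
        bounds = np.linspace(0, L, v + 2).astype(int)
        cands = set()
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            for chrom, pos in index.lookup(query[b0:b1]):
                cands.add((chrom, pos - b0))
        for chrom, start in cands:
            if start < 0 or start + L > index.chrom_length(chrom):
                continue
            mm = int((index._arrays[chrom][start:start + L] != qarr).sum())
            if mm <= v and (chrom, start, strand) not in seen:
                seen.add((chrom, start, strand))
                out.append((chrom, start, strand, mm))
    return out


def align_read(read_id: str, seq: str, index: GenomeIndex,
               params: AlignerParams = AlignerParams()) -> list[AlignmentRecord]:
    """Align one read; empty list when unmapped (including reads shorter
    than the index seed length)."""
    L = len(seq)
    if L < index.seed_length:
        return []
    hits = _placements(seq, index, params.max_mismatches)
    if not hits:
        return []
    if params.best_strata:
        best = min(h[3] for h in hits)
        hits = [h for h in hits if h[3] == best]
    hits.sort(key=lambda h: (h[0], h[1], _STRAND_ORDER[h[2]]))
    n = min(len(hits), params.report_cap)
    return [AlignmentRecord(read_id, c, s, s + L, st, mm, n)
            for c, s, st, mm in hits[:params.report_cap]]


def align_reads(reads: Sequence[tuple[str, str, str]], index: GenomeIndex,
                params: AlignerParams = AlignerParams(),
                ) -> tuple[dict[str, list[AlignmentRecord]], dict]:
    """Align a library; placements are cached per distinct read sequence.

    Returns (read_id -> placements for mapped reads, mapping stats).
    """
    cache: dict[str, list[AlignmentRecord]] = {}
    by_read: dict[str, list[AlignmentRecord]] = {}
    unmapped = 0
    for name, seq, _ in reads:
        tmpl = cache.get(seq)
        if tmpl is None:
            tmpl = align_read("", seq, index, params)
            cache[seq] = tmpl
        if tmpl:
            by_read[name] = [AlignmentRecord(name, r.chrom, r.start, r.end,
                                             r.strand, r.mismatches,
                                             r.n_placements) for r in tmpl]
        else:
            unmapped += 1
    total = len(reads)
    mapped = total - unmapped
    unique = sum(1 for recs in by_read.values() if recs[0].n_placements == 1)
    stats = {"total_reads": total, "mapped_reads": mapped,
             "unmapped_reads": unmapped, "unique_mapped_reads": unique,
             "mapping_rate": mapped / total if total else 0.0}
    return by_read, stats


# ---------------------------------------------------------------------------
# SAM I/O (pysam); multi-placements become secondary records sharing the
# read id, mismatches ride the NM tag and the stratum size the NH tag.

def write_alignments(records_by_read: Mapping[str, Sequence[AlignmentRecord]],
                     path: str, chrom_lengths: Mapping[str, int]) -> None:
    import pysam

    chroms = sorted(chrom_lengths)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms]}
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read_id in records_by_read:
            for i, rec in enumerate(records_by_read[read_id]):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = rec.read_id
                a.reference_id = tid[rec.chrom]
                a.reference_start = rec.start
                a.mapping_quality = 255
                L = rec.end - rec.start
                a.cigartuples = [(0, L)]
                a.query_sequence = "N" * L
                flag = 0x10 if rec.strand == "-" else 0
                if i > 0:
                    flag |= 0x100
                a.flag = flag
                a.set_tag("NM", rec.mismatches)
                a.set_tag("NH", rec.n_placements)
                fh.write(a)


def read_alignments(path: str) -> dict[str, list[AlignmentRecord]]:
    """Parse a SAM/BAM file back into per-read AlignmentRecord lists."""
    import pysam

    by_read: dict[str, list[AlignmentRecord]] = {}
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for i, a in enumerate(fh):
                if a.is_unmapped:
                    continue
                try:
                    rec = AlignmentRecord(
                        a.query_name, a.reference_name, a.reference_start,
                        a.reference_end, "-" if a.is_reverse else "+",
                        int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                        int(a.get_tag("NH")) if a.has_tag("NH") else 0)
                except (TypeError, ValueError) as exc:
                    raise ValueError(f"malformed alignment record "
                                     f"#{i + 1}: {exc}") from exc
                by_read.setdefault(a.query_name, []).append(rec)
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot parse alignment file {path}: {exc}") from exc
    # restore n_placements from record multiplicity when NH was absent
    for read_id, recs in by_read.items():
        if any(r.n_placements <= 0 for r in recs):
            n = len(recs)
            by_read[read_id] = [AlignmentRecord(r.read_id, r.chrom, r.start,
                                                r.end, r.strand, r.mismatches,
                                                n) for r in recs]
        by_read[read_id].sort(key=lambda r: (r.chrom, r.start,
                                             _STRAND_ORDER[r.strand]))
    return by_read


def brute_force_placements(seq: str, genome: Mapping[str, str],
                           v: int) -> list[tuple[str, int, str, int]]:
    """Exhaustive all-offset mismatch scan; reference oracle for align_read."""
    L = len(seq)
    out = []
    for strand in "+-":
        query = (seq if strand == "+" else revcomp(seq)).upper()
        qarr = np.frombuffer(query.encode(), dtype=np.uint8)
        for chrom in sorted(genome):
            g = np.frombuffer(genome[chrom].upper().encode(), dtype=np.uint8)
            if len(g) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(g, L)
            mms = (windows != qarr).sum(axis=1)
            for pos in np.nonzero(mms <= v)[0]:
                out.append((chrom, int(pos), strand, int(mms[pos])))
    out.sort(key=lambda h: (h[0], h[1], _STRAND_ORDER[h[2]]))
    return out
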