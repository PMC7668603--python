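"""Annotation handling, liftover, window assignment and fractional counting.

Mature miRNA/piRNA loci are short, so alignment ends are compared to
annotated ends with small fuzzy windows: an alignment is assigned to a
species when its strand matches and its 5' end falls within [-3, +2] nt of
the annotated 5' end and its 3' end within [-2, +3] nt of the annotated 3'
end (strand-oriented, inclusive).  Reads with n reported placements
contribute 1/n per assigned placement, so multi-mapped reads are spread
fractionally over the species they are compatible with.

piRNA annotations published on an older assembly are remapped with a UCSC
chain file: an interval is lifted only when a sufficient fraction of its
bases maps through a single chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mini_align import AlignmentRecord

CLASSES = ("miRNA", "piRNA", "spikein")


@dataclass(frozen=True)
class SmallRNAAnnotation:
    """A mature small-RNA locus; several loci may share a species_id when a
    species is encoded at multiple (repeat) positions."""

    species_id: str
    rna_class: str  # miRNA | piRNA | spikein
    chrom: str
    start: int      # 0-based
    end: int        # half-open
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.species_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.species_id}: bad strand {self.strand!r}")
        if self.rna_class not in CLASSES:
            raise ValueError(f"{self.species_id}: bad class {self.rna_class}")


@dataclass(frozen=True)
class AssignmentWindows:
    """Inclusive offsets allowed between alignment and annotation ends."""

    start_lo: int = -3
    start_hi: int = 2
    end_lo: int = -2
    end_hi: int = 3

    def __post_init__(self) -> None:
        if not (self.start_lo <= 0 <= self.start_hi):
            raise ValueError("start window must contain 0")
        if not (self.end_lo <= 0 <= self.end_hi):
            raise ValueError("end window must contain 0")


# ---------------------------------------------------------------------------
# BED6 I/O (class is carried in the name column as "species|class")

def write_bed(annotations: Iterable[SmallRNAAnnotation], path: str) -> None:
    with open(str(path), "w") as fh:
        for a in annotations:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t"
                     f"{a.species_id}|{a.rna_class}\t0\t{a.strand}\n")


def read_bed(path: str) -> list[SmallRNAAnnotation]:
    out = []
    with open(str(path)) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: BED6 needs 6 columns")
            name = f[3]
            species, _, cls = name.partition("|")
            out.append(SmallRNAAnnotation(species, cls or "miRNA", f[0],
                                          int(f[1]), int(f[2]), f[5]))
    return out


# ---------------------------------------------------------------------------
# UCSC chain liftover

@dataclass
class Chain:
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]]  # (size, dt, dq); last block dt=dq=0


def parse_chain_file(path: str) -> list[Chain]:
    chains: list[Chain] = []
    cur: Chain | None = None
    with open(str(path)) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                cur = None
                continue
            f = line.split()
            if f[0] == "chain":
                if len(f) < 12:
                    raise ValueError(f"{path}:{ln}: truncated chain header")
                if f[4] != "+":
                    raise ValueError(f"{path}:{ln}: target strand must be +")
                cur = Chain(f[2], int(f[3]), int(f[5]), int(f[6]),
                            f[7], int(f[8]), f[9], int(f[10]), int(f[11]), [])
                chains.append(cur)
            else:
                if cur is None:
                    raise ValueError(f"{path}:{ln}: block outside a chain")
                try:
                    size = int(f[0])
                    dt = int(f[1]) if len(f) > 1 else 0
                    dq = int(f[2]) if len(f) > 2 else 0
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: malformed block") from exc
                cur.blocks.append((size, dt, dq))
    return chains


@dataclass
class LiftoverResult:
    accepted: bool
    interval: tuple[str, int, int, str] | None = None
    mapped_fraction: float = 0.0
    reason: str | None = None


def liftover_interval(interval: tuple[str, int, int, str],
                      chains: Sequence[Chain] | str,
                      min_ratio: float = 0.95) -> LiftoverResult:
    """Remap (chrom, start, end, strand) through chain alignments.

    The chain target side is the source assembly.  The lifted interval spans
    the image of the mappable bases; the interval is rejected when the
    mapped-base fraction falls below ``min_ratio`` or the image is split
    across several chains.
    """
    if isinstance(chains, (str, Path)):
        chains = parse_chain_file(chains)
    chrom, start, end, strand = interval
    length = end - start
    if length <= 0:
        raise ValueError("empty interval")
    best = None
    n_hit = 0
    for chain in chains:
        if chain.t_name != chrom or chain.t_end <= start or chain.t_start >= end:
            continue
        mapped = 0
        q_lo = q_hi = None
        tpos, qpos = chain.t_start, chain.q_start
        for size, dt, dq in chain.blocks:
            lo, hi = max(start, tpos), min(end, tpos + size)
            if lo < hi:
                mapped += hi - lo
                a = qpos + (lo - tpos)
                b = qpos + (hi - tpos)
                q_lo = a if q_lo is None else min(q_lo, a)
                q_hi = b if q_hi is None else max(q_hi, b)
            tpos += size + dt
            qpos += size + dq
        if mapped:
            n_hit += 1
            if best is None or mapped > best[0]:
                best = (mapped, q_lo, q_hi, chain)
    if best is None:
        return LiftoverResult(False, reason="no chain covers interval")
    if n_hit > 1:
        return LiftoverResult(False, reason="split across chains")
    mapped, q_lo, q_hi, chain = best
    frac = mapped / length
    if frac < min_ratio:
        return LiftoverResult(False, mapped_fraction=frac,
                              reason=f"only {mapped}/{length} bases map")
    out_strand = strand
    if chain.q_strand == "-":
        q_lo, q_hi = chain.q_size - q_hi, chain.q_size - q_lo
        out_strand = "-" if strand == "+" else "+"
    return LiftoverResult(True, (chain.q_name, q_lo, q_hi, out_strand), frac)


def liftover_annotations(annotations: Iterable[SmallRNAAnnotation],
                         chains: Sequence[Chain] | str,
                         min_ratio: float = 0.95,
                         ) -> tuple[list[SmallRNAAnnotation], list[tuple]]:
    """Lift a set of loci; returns (lifted, rejected-with-reasons)."""
    if isinstance(chains, (str, Path)):
        chains = parse_chain_file(chains)
    lifted, rejected = [], []
    for a in annotations:
        res = liftover_interval((a.chrom, a.start, a.end, a.strand), chains,
                                min_ratio)
        if res.accepted:
            c, s, e, st = res.interval
            lifted.append(SmallRNAAnnotation(a.species_id, a.rna_class,
                                             c, s, e, st))
        else:
            rejected.append((a.species_id, res.reason))
    return lifted, rejected


# ---------------------------------------------------------------------------
# window assignment

def _offsets(rec: AlignmentRecord,
             ann: SmallRNAAnnotation) -> tuple[int, int]:
    """Strand-oriented (5', 3') end offsets of alignment vs annotation,
    positive pointing downstream in read orientation."""
    if ann.strand == "+":
        return rec.start - ann.start, rec.end - ann.end
    return ann.end - rec.end, ann.start - rec.start


def assign_alignment(rec: AlignmentRecord, ann: SmallRNAAnnotation,
                     w: AssignmentWindows = AssignmentWindows()) -> bool:
    """True iff the placement is compatible with the annotated locus."""
    if rec.chrom != ann.chrom or rec.strand != ann.strand:
        return False
    off5, off3 = _offsets(rec, ann)
    return (w.start_lo <= off5 <= w.start_hi) and (w.end_lo <= off3 <= w.end_hi)


class _AnnotationLookup:
    """O(1) candidate retrieval keyed by the alignment's 5'-anchoring
    genomic coordinate (start for +, end for - placements)."""

    def __init__(self, annotations: Sequence[SmallRNAAnnotation],
                 w: AssignmentWindows):
        self.w = w
        self._by_anchor: dict[tuple[str, str, int],
                              list[SmallRNAAnnotation]] = {}
        for a in annotations:
            for d in range(w.start_lo, w.start_hi + 1):
                anchor = a.start + d if a.strand == "+" else a.end - d
                key = (a.chrom, a.strand, anchor)
                self._by_anchor.setdefault(key, []).append(a)

    def candidates(self, rec: AlignmentRecord) -> list[SmallRNAAnnotation]:
        anchor = rec.start if rec.strand == "+" else rec.end
        return self._by_anchor.get((rec.chrom, rec.strand, anchor), [])


def count_sample(records_by_read: Mapping[str, Sequence[AlignmentRecord]],
                 annotations: Sequence[SmallRNAAnnotation],
                 w: AssignmentWindows = AssignmentWindows(),
                 ) -> tuple[pd.Series, dict]:
    """Fractional species counts for one sample.

    Every (placement, annotation) pair passing the windows adds
    1/n_placements to that species.  A placement compatible with several
    annotations goes to the one with the smallest |5' offset| + |3' offset|;
    exact ties split the placement's mass equally (counted in the stats).
    """
    lookup = _AnnotationLookup(annotations, w)
    species = sorted({a.species_id for a in annotations})
    counts = {s: 0.0 for s in species}
    assigned_mass = 0.0
    ambiguous = 0
    for read_id, recs in records_by_read.items():
        if not recs:
            continue
        n = recs[0].n_placements
        share = 1.0 / n
        for rec in recs:
            matches = []
            for ann in lookup.candidates(rec):
                off5, off3 = _offsets(rec, ann)
                if (w.start_lo <= off5 <= w.start_hi
                        and w.end_lo <= off3 <= w.end_hi):
                    matches.append((abs(off5) + abs(off3), ann))
            if not matches:
                continue
            best = min(m[0] for m in matches)
            tied = [ann for d, ann in matches if d == best]
            if len(tied) > 1:
                ambiguous += 1
            for ann in tied:
                counts[ann.species_id] += share / len(tied)
            assigned_mass += share
    col = pd.Series(counts, dtype=float).reindex(species)
    stats = {"mapped_reads": len(records_by_read),
             "assigned_mass": assigned_mass, "ambiguous_placements": ambiguous}
    return col, stats


def count_sample_bruteforce(records_by_read, annotations,
                            w: AssignmentWindows = AssignmentWindows(),
                            ) -> pd.Series:
    """Exhaustive (placement x annotation) double loop; counting oracle."""
    species = sorted({a.species_id for a in annotations})
    counts = {s: 0.0 for s in species}
    for read_id, recs in records_by_read.items():
        if not recs:
            continue
        share = 1.0 / recs[0].n_placements
        for rec in recs:
            matches = []
            for ann in annotations:
                if assign_alignment(rec, ann, w):
                    off5, off3 = _offsets(rec, ann)
                    matches.append((abs(off5) + abs(off3), ann))
            if not matches:
                continue
            best = min(m[0] for m in matches)
            tied = [ann for d, ann in matches if d == best]
            for ann in tied:
                counts[ann.species_id] += share / len(tied)
    return pd.Series(counts, dtype=float).reindex(species)


def count_spikeins(reads: Sequence[tuple[str, str, str]],
                   spikeins: Mapping[str, str]) -> pd.Series:
    """Exact-sequence spike-in counting (no mismatches allowed)."""
    by_seq: dict[str, str] = {}
    for name, seq in spikeins.items():
        by_seq[seq.upper()] = name
    counts = {name: 0 for name in spikeins}
    for _, seq, _ in reads:
        hit = by_seq.get(seq.upper())
        if hit is not None:
            counts[hit] += 1
    return pd.Series(counts, dtype=float)


# ---------------------------------------------------------------------------
# count matrix

@dataclass
class CountMatrix:
    """Species x sample fractional counts with per-sample totals attached."""

    counts: pd.DataFrame                 # species x samples
    classes: pd.Series                   # species -> miRNA|piRNA
    total_mapped: pd.Series              # per sample
    spikein_counts: pd.Series            # per sample (summed over spike-ins)

    def __post_init__(self) -> None:
        self.classes = self.classes.reindex(self.counts.index)
        self.total_mapped = self.total_mapped.reindex(self.counts.columns)
        self.spikein_counts = self.spikein_counts.reindex(self.counts.columns)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_class(self, rna_class: str) -> "CountMatrix":
        keep = self.classes[self.classes == rna_class].index
        return CountMatrix(self.counts.loc[keep], self.classes.loc[keep],
                           self.total_mapped, self.spikein_counts)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.classes,
                           self.total_mapped[list(samples)],
                           self.spikein_counts[list(samples)])

    def to_tsv(self, path: str, sidecar_path: str | None = None) -> None:
        df = self.counts.copy()
        df.insert(0, "class", self.classes)
        df.to_csv(str(path), sep="\t", index_label="species")
        if sidecar_path:
            meta = {"total_mapped": self.total_mapped.to_dict(),
                    "spikein_counts": self.spikein_counts.to_dict()}
            with open(str(sidecar_path), "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_tsv(cls, path: str, sidecar_path: str) -> "CountMatrix":
        df = pd.read_csv(str(path), sep="\t", index_col="species")
        classes = df.pop("class")
        with open(str(sidecar_path)) as fh:
            meta = json.load(fh)
        return cls(df, classes,
                   pd.Series(meta["total_mapped"], dtype=float),
                   pd.Series(meta["spikein_counts"], dtype=float))


def merge_counts(columns: Mapping[str, pd.Series],
                 sample_sheet: pd.DataFrame,
                 classes: pd.Series,
                 total_mapped: Mapping[str, float],
                 spikein_counts: Mapping[str, float]) -> CountMatrix:
    """Assemble per-sample count columns into a CountMatrix ordered per the
    sample sheet; species missing from a column are zero-filled."""
    samples = list(sample_sheet["sample"])
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in sample sheet")
    missing = [s for s in samples if s not in columns]
    if missing:
        raise ValueError(f"no counts for samples: {missing}")
    species = sorted(set().union(*[set(c.index) for c in columns.values()]))
    mat = pd.DataFrame({s: columns[s].reindex(species).fillna(0.0)
                        for s in samples}, index=species)
    return CountMatrix(mat, classes.reindex(species),
                       pd.Series(dict(total_mapped), dtype=float),
                       pd.Series(dict(spikein_counts), dtype=float))
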