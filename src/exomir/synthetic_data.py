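"""Synthetic exosomal small-RNA sequencing data with known ground truth.

The generator emulates the statistical structure of amniotic-fluid exosome
small-RNA libraries: a piRNA class that numerically dominates miRNA, ~22 nt
miRNA and 26-31 nt piRNA species, multi-mapping caused by repeated genomic
cassettes, 5'/3' end heterogeneity around the annotated mature ends, 3'
adapter read-through on a fixed 50 nt single-end read, sequencing errors,
spike-in RNA mixed at a fixed mass ratio (sample:spike 15:1 by default),
library-depth variation, overdispersed per-species counts with planted
condition fold changes, and a batch ("experiment") effect stronger than the
treatment effect.

Per-sample species counts are drawn as gamma-distributed expression rates
followed by a single multinomial of the configured depth, i.e. a
gamma-Poisson (negative-binomial-like) law conditioned on the exact total,
so every library contains exactly ``depth_per_sample`` reads.  Every emitted
read is recorded in a :class:`TruthTable` together with its source species,
the applied end offsets and the number of exact genomic placements of its
(error-free) sequence, which downstream stages can be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate_quantify import SmallRNAAnnotation, write_bed
from .mini_align import revcomp
from .preprocess import DEFAULT_ADAPTER, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_JITTER: dict[int, float] = {
    0: 0.60, 1: 0.10, -1: 0.10, 2: 0.05, -2: 0.05,
    3: 0.04, -3: 0.04, 4: 0.01, -4: 0.01,
}


def default_planted_fc() -> dict[str, float]:
    """Planted EtOH log2 fold changes: six miRNAs (three up, three down)
    and three piRNAs, echoing the handful of condition-responsive species
    the analysis is meant to recover."""
    fc = {f"mir-{i:03d}": 2.0 for i in (1, 2, 3)}
    fc |= {f"mir-{i:03d}": -2.0 for i in (4, 5, 6)}
    fc |= {"pir-0001": 2.0, "pir-0002": 2.0, "pir-0003": -2.0}
    return fc


@dataclass
class SimulationDesign:
    """Study design and generative parameters of one synthetic experiment.

    ``n_samples_per_group`` counts samples per condition within each
    timepoint; batches are assigned round-robin, so the default of 3 yields
    2 conditions x 2 timepoints x 3 = 12 libraries spread over 2 batches.
    ``spikein_mass_fraction`` is the expected fraction of reads drawn from
    spike-ins (1/16 of the total corresponds to mixing sample RNA with 1/15
    of its amount of spike-in RNA).
    """

    n_samples_per_group: int = 3
    groups: tuple[str, ...] = ("control", "EtOH")
    batches: tuple[str, ...] = ("Exp1", "Exp2")
    timepoints: tuple[str, ...] = ("E16", "E19")
    n_mirna: int = 50
    n_pirna: int = 200
    planted_fc: dict[str, float] = field(default_factory=default_planted_fc)
    dispersion: float = 0.05
    depth_per_sample: int = 200_000
    spikein_mass_fraction: float = 1.0 / 16.0
    jitter_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_JITTER))
    error_rate: float = 0.001
    adapter_seq: str | None = DEFAULT_ADAPTER
    read_length: int = 50
    batch_effect_sd: float = 0.5
    pirna_mass_fraction: float = 0.75
    repeat_fraction: float = 0.2
    n_spikeins: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be > 0")
        if not 0 < self.spikein_mass_fraction < 1:
            raise ValueError("spikein_mass_fraction must be in (0,1)")
        if abs(sum(self.jitter_probs.values()) - 1.0) > 1e-9:
            raise ValueError("jitter_probs must sum to 1")
        if self.dispersion < 0 or self.error_rate < 0:
            raise ValueError("dispersion and error_rate must be >= 0")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")


def sample_sheet(design: SimulationDesign) -> pd.DataFrame:
    """Tab-sheet of samples: condition x timepoint cells, batches assigned
    round-robin within each cell."""
    rows = []
    for tp in design.timepoints:
        for grp in design.groups:
            for i in range(design.n_samples_per_group):
                batch = design.batches[i % len(design.batches)]
                rows.append({"sample": f"{tp}_{grp}_{batch}_s{i + 1}",
                             "condition": grp, "batch": batch,
                             "timepoint": tp})
    return pd.DataFrame(rows)


@dataclass
class TruthTable:
    """Ground truth of one simulated experiment."""

    counts: pd.DataFrame            # emitted genomic reads, species x samples
    expected_counts: pd.DataFrame   # expected reads, species x samples
    spike_counts: pd.Series         # emitted spike-in reads per sample
    reads: dict[str, pd.DataFrame]  # per sample: read_id, species, off5,
                                    # off3, n_placements

    def group_means(self, sheet: pd.DataFrame) -> pd.DataFrame:
        """True mean abundance per condition (averaged expected counts)."""
        out = {}
        for grp, sub in sheet.groupby("condition"):
            out[grp] = self.expected_counts[list(sub["sample"])].mean(axis=1)
        return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# genome / annotations / spike-ins

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


@dataclass
class RepeatFamily:
    name: str
    seq: str
    locations: list[tuple[str, int]]   # (chrom, start) of each pasted copy


def generate_genome(seed: int,
                    chrom_lengths: Sequence[int] = (60_000, 40_000),
                    n_repeat_families: int = 3,
                    repeat_copies: int = 4,
                    cassette_length: int = 40,
                    ) -> tuple[dict[str, str], list[RepeatFamily]]:
    """Random genome with repeated cassettes that create multi-mapping.

    ``n_repeat_families`` distinct ~``cassette_length`` nt sequences are each
    pasted at ``repeat_copies`` non-overlapping locations.  Small RNA species
    later planted inside a cassette therefore occur at every copy.
    """
    if any(l < 1000 for l in chrom_lengths):
        raise ValueError("chromosome lengths must be >= 1000")
    if repeat_copies < 1:
        raise ValueError("repeat_copies must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(len(chrom_lengths))]
    seqs = {c: bytearray(_random_seq(rng, n).encode())
            for c, n in zip(chroms, chrom_lengths)}
    margin = 50
    need = n_repeat_families * repeat_copies * (cassette_length + margin)
    if need > sum(chrom_lengths):
        raise RuntimeError("insufficient genome length to place all "
                           "repeat cassettes without overlap")
    occupied: list[tuple[str, int, int]] = []
    families = []
    weights = np.asarray(chrom_lengths, dtype=float)
    weights /= weights.sum()
    for fi in range(n_repeat_families):
        fam = RepeatFamily(f"rep{fi + 1}", _random_seq(rng, cassette_length), [])
        for _ in range(repeat_copies):
            for _attempt in range(10_000):
                c = chroms[rng.choice(len(chroms), p=weights)]
                start = int(rng.integers(margin,
                                         len(seqs[c]) - cassette_length - margin))
                end = start + cassette_length
                if all(not (oc == c and start - margin < oe
                            and os < end + margin)
                       for oc, os, oe in occupied):
                    break
            else:
                raise RuntimeError("insufficient genome length to place all "
                                   "repeat cassettes without overlap")
            seqs[c][start:end] = fam.seq.encode()
            occupied.append((c, start, end))
            fam.locations.append((c, start))
        families.append(fam)
    return {c: seqs[c].decode() for c in chroms}, families


def plant_annotations(genome: Mapping[str, str], design: SimulationDesign,
                      repeats: Sequence[RepeatFamily] = (),
                      rng: np.random.Generator | None = None,
                      ) -> list[SmallRNAAnnotation]:
    """Plant mature miRNA (20-24 nt) and piRNA (26-31 nt) loci.

    A ``design.repeat_fraction`` share of each class is planted inside
    repeat cassettes (one locus per cassette copy, shared species id), the
    rest at unique genomic positions.  Same-strand loci never overlap.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    chroms = sorted(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    margin = 10
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}
    cassette_iv = [(f, c, s, s + len(f.seq))
                   for f in repeats for c, s in f.locations]
    fam_occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def clash(chrom: str, strand: str, start: int, end: int) -> bool:
        for s, e in occupied.get((chrom, strand), ()):
            if start - margin < e and s < end + margin:
                return True
        return False

    out: list[SmallRNAAnnotation] = []
    fam_cycle = 0
    specs = ([("miRNA", f"mir-{i + 1:03d}", 20, 24)
              for i in range(design.n_mirna)] +
             [("piRNA", f"pir-{i + 1:04d}", 26, 31)
              for i in range(design.n_pirna)])
    for cls, sid, lo, hi in specs:
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        in_repeat = (bool(repeats)
                     and rng.random() < design.repeat_fraction
                     and length <= min(len(f.seq) for f in repeats))
        placed = False
        if in_repeat:
            for _ in range(200):
                fam = repeats[fam_cycle % len(repeats)]
                fam_cycle += 1
                off = int(rng.integers(0, len(fam.seq) - length + 1))
                key = (fam.name, strand)
                if any(off - margin < e and s < off + length + margin
                       for s, e in fam_occupied.get(key, ())):
                    continue
                locs = [(c, s + off, s + off + length)
                        for c, s in fam.locations]
                if any(clash(c, strand, a, b) for c, a, b in locs):
                    continue
                if any(s < margin or e > lengths[c] - margin
                       for c, s, e in locs):
                    continue
                for c, a, b in locs:
                    out.append(SmallRNAAnnotation(sid, cls, c, a, b, strand))
                    occupied.setdefault((c, strand), []).append((a, b))
                fam_occupied.setdefault(key, []).append((off, off + length))
                placed = True
                break
        if not placed:
            for _ in range(10_000):
                c = chroms[rng.choice(len(chroms), p=weights)]
                start = int(rng.integers(margin, lengths[c] - length - margin))
                end = start + length
                # stay clear of cassettes so unique species map uniquely
                if any(cc == c and start - margin < ce and cs < end + margin
                       for _f, cc, cs, ce in cassette_iv):
                    continue
                if clash(c, strand, start, end):
                    continue
                out.append(SmallRNAAnnotation(sid, cls, c, start, end, strand))
                occupied.setdefault((c, strand), []).append((start, end))
                placed = True
                break
            if not placed:
                raise RuntimeError(f"cannot place {sid} without overlap")
    return out


def generate_spikeins(genome: Mapping[str, str], n: int = 8,
                      rng: np.random.Generator | None = None,
                      seed: int = 0) -> dict[str, str]:
    """Synthetic spike-in sequences (21-23 nt) with no exact genome match."""
    if rng is None:
        rng = np.random.default_rng(seed + 7)
    out: dict[str, str] = {}
    i = 0
    while len(out) < n:
        i += 1
        seq = _random_seq(rng, int(rng.integers(21, 24)))
        rc = revcomp(seq)
        if any(seq in g or rc in g for g in genome.values()):
            continue
        out[f"spike-{len(out) + 1:02d}"] = seq
    return out


# ---------------------------------------------------------------------------
# library simulation

def _mature_sequence(genome: Mapping[str, str], ann: SmallRNAAnnotation,
                     off5: int, off3: int) -> str | None:
    """Strand-oriented mature sequence with end offsets applied (positive
    offsets point downstream in read orientation)."""
    if ann.strand == "+":
        a, b = ann.start + off5, ann.end + off3
    else:
        a, b = ann.start - off3, ann.end - off5
    if a < 0 or b > len(genome[ann.chrom]) or a >= b:
        return None
    s = genome[ann.chrom][a:b]
    return s if ann.strand == "+" else revcomp(s)


def _occurrences(haystack: str, needle: str) -> int:
    n = 0
    start = haystack.find(needle)
    while start != -1:
        n += 1
        start = haystack.find(needle, start + 1)
    return n


def _count_placements(genome_seqs: Sequence[str], insert: str) -> int:
    """Exact occurrences of the insert on both strands (overlaps included)."""
    rc = revcomp(insert)
    total = 0
    for g in genome_seqs:
        fwd = _occurrences(g, insert)
        if rc == insert:
            total += 2 * fwd  # a palindrome matches both strands per site
        else:
            total += fwd + _occurrences(g, rc)
    return total


@dataclass
class SimulationResult:
    design: SimulationDesign
    sheet: pd.DataFrame
    reads: dict[str, list[tuple[str, str, str]]]
    truth: TruthTable


@dataclass
class CountSimulation:
    """Count-level simulation output (no reads emitted)."""

    sheet: pd.DataFrame
    counts: pd.DataFrame          # genomic species x samples
    spike_counts: pd.DataFrame    # spike-in x samples
    expected: pd.DataFrame        # expected genomic counts x samples


def _abundance_model(design: SimulationDesign, species: Sequence[str],
                     classes: Mapping[str, str], rng: np.random.Generator,
                     ) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Baseline abundances (piRNA mass dominant), planted fold changes and
    per-(species, batch) log2 shifts."""
    base = pd.Series(np.exp(rng.normal(0.0, 1.0, len(species))),
                     index=list(species))
    cls = pd.Series(dict(classes)).reindex(base.index)
    for rna_class, mass in (("miRNA", 1.0 - design.pirna_mass_fraction),
                            ("piRNA", design.pirna_mass_fraction)):
        idx = cls[cls == rna_class].index
        if len(idx):
            base[idx] *= mass / base[idx].sum()
    fc = pd.Series(design.planted_fc, dtype=float).reindex(
        base.index, fill_value=0.0)
    shifts = pd.DataFrame(
        rng.normal(0.0, design.batch_effect_sd,
                   (len(base), len(design.batches))),
        index=base.index, columns=list(design.batches))
    return base, fc, shifts


def default_species(design: SimulationDesign) -> tuple[list[str],
                                                       dict[str, str]]:
    species = ([f"mir-{i + 1:03d}" for i in range(design.n_mirna)] +
               [f"pir-{i + 1:04d}" for i in range(design.n_pirna)])
    classes = {s: ("miRNA" if s.startswith("mir") else "piRNA")
               for s in species}
    return species, classes


def simulate_counts(design: SimulationDesign,
                    species: Sequence[str] | None = None,
                    classes: Mapping[str, str] | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> CountSimulation:
    """Draw the per-sample count layer only.

    Species rates are Gamma(1/dispersion, mean * dispersion); a single
    multinomial of size ``depth_per_sample`` (spike-ins included at expected
    share ``spikein_mass_fraction``) then yields counts whose per-sample
    total is exact.
    """
    if species is None:
        species, classes = default_species(design)
    species = sorted(species)
    unknown = sorted(set(design.planted_fc) - set(species))
    if unknown:
        raise ValueError(f"planted_fc references unknown species: {unknown}")
    if rng is None:
        rng = np.random.default_rng(design.seed + 2)
    sheet = sample_sheet(design)
    spike_names = [f"spike-{i + 1:02d}" for i in range(design.n_spikeins)]
    base, fc, shifts = _abundance_model(design, species, classes, rng)
    sf = design.spikein_mass_fraction

    counts_tab, spike_tab, expected_tab = {}, {}, {}
    for row in sheet.itertuples(index=False):
        is_etoh = 1.0 if row.condition == design.groups[-1] else 0.0
        w = base * np.power(2.0, fc * is_etoh + shifts[row.batch])
        if design.dispersion > 0:
            shape = 1.0 / design.dispersion
            rates = rng.gamma(shape, w.values / shape)
        else:
            rates = w.values.copy()
        rates = np.maximum(rates, 1e-300)
        spike_total_w = rates.sum() * sf / (1.0 - sf)
        p = np.concatenate([rates,
                            np.full(len(spike_names),
                                    spike_total_w / len(spike_names))])
        p /= p.sum()
        draw = rng.multinomial(design.depth_per_sample, p)
        counts_tab[row.sample] = pd.Series(draw[:len(species)], index=species,
                                           dtype=float)
        spike_tab[row.sample] = pd.Series(draw[len(species):],
                                          index=spike_names, dtype=float)
        expected_tab[row.sample] = pd.Series(
            design.depth_per_sample * p[:len(species)], index=species)
    order = list(sheet["sample"])
    return CountSimulation(sheet, pd.DataFrame(counts_tab)[order],
                           pd.DataFrame(spike_tab)[order],
                           pd.DataFrame(expected_tab)[order])


def simulate_libraries(genome: Mapping[str, str],
                       annotations: Sequence[SmallRNAAnnotation],
                       spikeins: Mapping[str, str],
                       design: SimulationDesign) -> SimulationResult:
    """Simulate per-sample FASTQ libraries plus a full TruthTable."""
    if not annotations:
        raise ValueError("annotations must be non-empty")
    loci: dict[str, list[SmallRNAAnnotation]] = {}
    classes: dict[str, str] = {}
    for a in annotations:
        loci.setdefault(a.species_id, []).append(a)
        classes[a.species_id] = a.rna_class
    species = sorted(loci)
    if len(spikeins) != design.n_spikeins:
        raise ValueError("spikeins must match design.n_spikeins")

    rng = np.random.default_rng(design.seed + 2)
    spike_names = sorted(spikeins)
    cs = simulate_counts(design, species, classes, rng=rng)
    sheet = cs.sheet

    offs = np.array(sorted(design.jitter_probs))
    offp = np.array([design.jitter_probs[o] for o in offs], dtype=float)
    offp /= offp.sum()
    genome_seqs = [genome[c].upper() for c in sorted(genome)]
    adapter = design.adapter_seq or ""

    reads_out: dict[str, list[tuple[str, str, str]]] = {}
    truth_reads: dict[str, pd.DataFrame] = {}
    seq_cache: dict[tuple[str, int, int], tuple[str | None, int]] = {}

    for row in sheet.itertuples(index=False):
        sp_counts = cs.counts[row.sample].values
        spike_draw = cs.spike_counts[row.sample].reindex(spike_names).values

        lib: list[tuple[str, str, str]] = []
        recs: list[tuple[str, str, int, int, int]] = []
        serial = 0
        for si, sid in enumerate(species):
            c = int(sp_counts[si])
            if c == 0:
                continue
            d5 = rng.choice(offs, size=c, p=offp)
            d3 = rng.choice(offs, size=c, p=offp)
            pairs, inv = np.unique(np.stack([d5, d3], axis=1), axis=0,
                                   return_inverse=True)
            for pi, (o5, o3) in enumerate(pairs):
                idx = np.nonzero(inv == pi)[0]
                key = (sid, int(o5), int(o3))
                if key not in seq_cache:
                    ins = _mature_sequence(genome, loci[sid][0],
                                           int(o5), int(o3))
                    npl = _count_placements(genome_seqs, ins) if ins else 0
                    seq_cache[key] = (ins, npl)
                ins, npl = seq_cache[key]
                if ins is None:
                    continue
                n_err = rng.binomial(len(ins), design.error_rate,
                                     size=len(idx))
                for k in range(len(idx)):
                    serial += 1
                    seq = ins
                    if n_err[k]:
                        barr = bytearray(seq.encode())
                        pos = rng.choice(len(barr), size=n_err[k],
                                         replace=False)
                        for pnt in pos:
                            cur = barr[pnt]
                            alt = [b for b in b"ACGT" if b != cur]
                            barr[pnt] = alt[int(rng.integers(3))]
                        seq = barr.decode()
                    rid = f"{row.sample}.r{serial}"
                    lib.append((rid, _finish_read(seq, adapter,
                                                  design.read_length),
                                None))
                    recs.append((rid, sid, int(o5), int(o3), npl))
        for sj, sname in enumerate(spike_names):
            ins = spikeins[sname]
            c = int(spike_draw[sj])
            n_err = rng.binomial(len(ins), design.error_rate, size=c)
            for k in range(c):
                serial += 1
                seq = ins
                if n_err[k]:
                    barr = bytearray(seq.encode())
                    pos = rng.choice(len(barr), size=n_err[k], replace=False)
                    for pnt in pos:
                        cur = barr[pnt]
                        alt = [b for b in b"ACGT" if b != cur]
                        barr[pnt] = alt[int(rng.integers(3))]
                    seq = barr.decode()
                rid = f"{row.sample}.r{serial}"
                lib.append((rid, _finish_read(seq, adapter,
                                              design.read_length), None))
                recs.append((rid, sname, 0, 0, 0))
        lib = [(rid, s, "I" * len(s)) for rid, s, _ in lib]
        order = rng.permutation(len(lib))
        reads_out[row.sample] = [lib[i] for i in order]
        truth_reads[row.sample] = pd.DataFrame(
            recs, columns=["read_id", "species", "offset5", "offset3",
                           "n_placements"])

    truth = TruthTable(cs.counts, cs.expected,
                       cs.spike_counts.sum(axis=0),
                       truth_reads)
    return SimulationResult(design, sheet, reads_out, truth)


def _finish_read(insert: str, adapter: str, read_length: int) -> str:
    """Insert + adapter read-through, truncated/padded to the read length."""
    if not adapter:
        return insert
    read = insert + adapter
    while len(read) < read_length:
        read += adapter
    return read[:read_length]


# ---------------------------------------------------------------------------
# on-disk artifact layout

def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seqs[name]), id=name, description="")
            for name in seqs]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_simulation(result: SimulationResult, genome: Mapping[str, str],
                     spikeins: Mapping[str, str],
                     annotations: Sequence[SmallRNAAnnotation],
                     outdir: str) -> dict[str, str]:
    """Write the full simulated experiment to disk; returns the path map."""
    out = Path(outdir)
    (out / "fastq").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    write_fasta(genome, out / "genome.fa")
    write_fasta(spikeins, out / "spikeins.fa")
    write_bed(annotations, out / "annotations.bed")
    result.sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    result.truth.counts.to_csv(out / "truth" / "counts.tsv", sep="\t",
                               index_label="species")
    for sample, reads in result.reads.items():
        write_fastq(reads, out / "fastq" / f"{sample}.fastq.gz")
        result.truth.reads[sample].to_csv(
            out / "truth" / f"reads_{sample}.tsv", sep="\t", index=False)
    return {"genome": str(out / "genome.fa"),
            "spikeins": str(out / "spikeins.fa"),
            "annotations": str(out / "annotations.bed"),
            "sample_sheet": str(out / "sample_sheet.tsv"),
            "fastq_dir": str(out / "fastq")}


def simulate_experiment(design: SimulationDesign,
                        genome_seed: int | None = None,
                        chrom_lengths: Sequence[int] = (60_000, 40_000),
                        n_repeat_families: int = 30,
                        repeat_copies: int = 4,
                        ) -> tuple[dict[str, str], list[SmallRNAAnnotation],
                                   dict[str, str], SimulationResult]:
    """Convenience wrapper: genome -> annotations -> spike-ins -> libraries."""
    gseed = design.seed if genome_seed is None else genome_seed
    genome, repeats = generate_genome(gseed, chrom_lengths,
                                      n_repeat_families, repeat_copies)
    annotations = plant_annotations(genome, design, repeats)
    spikeins = generate_spikeins(genome, design.n_spikeins,
                                 seed=design.seed)
    result = simulate_libraries(genome, annotations, spikeins, design)
    return genome, annotations, spikeins, result
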