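"""Sequence/interval I/O and dataset-construction rules.

Implements the preprocessing pipeline for circRNA binding-site fragments:
reading FASTA/BED, retaining fragments of 51-99 nt, extending peaks to a
fixed 100 nt centered on the peak midpoint, removing redundant sites,
generating dinucleotide-composition-matched shuffled negatives, and the
pair-coupled 4:1 train/test split with a validation hold-out.

Coordinates are BED dialect throughout: 0-based, half-open. Sequences are
kept in the RNA alphabet {A,U,C,G}; DNA input is mapped T->U on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from circrbp._rng import substream

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("AUCG")
_VALID_INPUT = frozenset("ACGTUacgtu")

POSITIVE = "positive"
NEGATIVE = "negative"

#: suffix appended to a positive's id to name its shuffled negative partner
SHUFFLE_SUFFIX = "_shuf"


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SequenceRecord:
    """One binding-site fragment: id, RNA sequence, optional interval and label."""

    id: str
    seq: str
    interval: Optional[GenomicInterval] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: characters outside A/U/C/G: {sorted(bad)}")
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"record {self.id!r}: unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions with the seed that produced them."""

    train: list[SequenceRecord]
    validation: list[SequenceRecord]
    test: list[SequenceRecord]
    seed: int

    def all_records(self) -> list[SequenceRecord]:
        return self.train + self.validation + self.test


def _to_rna(s: str) -> str:
    return s.upper().replace("T", "U")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (T->U, uppercased).

    Records containing characters outside {A,C,G,T,U} (e.g. N) are rejected
    with a logged warning. A ``label=positive|negative`` token in the FASTA
    description is picked up into the record label.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: expected FASTA header line, got {line.strip()!r}")
            break
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        raw = str(entry.seq)
        if set(raw) - _VALID_INPUT:
            logger.warning("rejecting record %s: ambiguous/invalid characters", entry.id)
            continue
        label = None
        for token in entry.description.split():
            if token.startswith("label="):
                label = token.removeprefix("label=")
        records.append(SequenceRecord(id=entry.id, seq=_to_rna(raw), label=label))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (80-column wrap); the label travels in the description."""
    bio = []
    for r in records:
        desc = f"label={r.label}" if r.label is not None else ""
        bio.append(_BioRecord(Seq(r.seq), id=r.id, description=desc))
    SeqIO.write(bio, str(path), "fasta")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read BED6 (or BED3) intervals; returns (interval, name) pairs."""
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >=3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "+"
            if strand == ".":
                strand = "+"
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def filter_by_length(
    records: list[SequenceRecord], min_len: int = 51, max_len: int = 99
) -> list[SequenceRecord]:
    """Retain records with min_len <= length <= max_len (defaults: 51-99 nt).

    Fragments shorter than ~50 nt carry too little signal to discriminate,
    and longer ones are handled by peak-centered extension to a fixed width,
    so the pipeline keeps the 51-99 nt range by default.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in records if min_len <= len(r) <= max_len]


def extend_to_fixed_length(
    interval: GenomicInterval,
    genome: Mapping[str, str],
    target_len: int = 100,
    name: Optional[str] = None,
) -> Optional[SequenceRecord]:
    """Extend a peak interval to exactly target_len nt centered on its midpoint.

    center = floor((start+end)/2); window = [center - target_len//2,
    center - target_len//2 + target_len). Minus-strand windows are
    reverse-complemented before the T->U mapping. Windows running past either
    chromosome end are dropped (returns None) rather than clamped, so every
    emitted record has the exact fixed length the model input requires.
    """
    if len(interval) > target_len:
        raise ValueError(f"interval length {len(interval)} exceeds target {target_len}")
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome")
    chrom_seq = genome[interval.chrom]
    center = (interval.start + interval.end) // 2
    new_start = center - target_len // 2
    new_end = new_start + target_len
    if new_start < 0 or new_end > len(chrom_seq):
        logger.info(
            "dropping interval %s:%d-%d: extended window [%d,%d) exceeds chromosome bounds",
            interval.chrom, interval.start, interval.end, new_start, new_end,
        )
        return None
    raw = chrom_seq[new_start:new_end]
    if interval.strand == "-":
        raw = str(Seq(raw).reverse_complement())
    rec_id = name if name is not None else f"{interval.chrom}:{new_start}-{new_end}({interval.strand})"
    return SequenceRecord(
        id=rec_id,
        seq=_to_rna(raw),
        interval=GenomicInterval(interval.chrom, new_start, new_end, interval.strand),
    )


def deduplicate(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Drop redundant sites, keeping first occurrences.

    A record is redundant if its (chrom, start, end, strand) tuple — or, when
    no interval is attached, its exact sequence string — was seen before.
    """
    seen: set = set()
    out = []
    for r in records:
        key = (
            (r.interval.chrom, r.interval.start, r.interval.end, r.interval.strand)
            if r.interval is not None
            else ("seq", r.seq)
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact multiset of overlapping dinucleotides.

    Altschul-Erickson scheme: the sequence is an Eulerian path on the
    dinucleotide transition multigraph; a random Eulerian path with the same
    edge multiset is drawn by fixing, for every vertex other than the final
    character, a randomly chosen "last exit" edge such that the last-exit
    edges form a tree into the final vertex, shuffling all remaining edges,
    and walking the graph. First/last characters and all mono- and
    dinucleotide counts are conserved exactly.
    """
    if len(seq) < 2:
        logger.warning("dinucleotide_shuffle: sequence shorter than 2 nt returned unchanged")
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # vertices with out-edges, excluding the terminal vertex
    inner = [v for v in edges if v != last]
    while True:
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in inner}
        # every inner vertex must reach `last` by following last exits
        ok = True
        for v in inner:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    pools: dict[str, list[str]] = {}
    for v, outs in edges.items():
        outs = list(outs)
        if v in last_exit:
            outs.remove(last_exit[v])
        perm = rng.permutation(len(outs))
        shuffled = [outs[i] for i in perm]
        if v in last_exit:
            shuffled.append(last_exit[v])
        pools[v] = shuffled
    # walk the Eulerian path
    out = [seq[0]]
    nxt = {v: 0 for v in pools}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        step = pools[cur][nxt[cur]]
        nxt[cur] += 1
        out.append(step)
        cur = step
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    """Count overlapping dinucleotides (16-dim count vector as a dict)."""
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


def make_negatives(positives: list[SequenceRecord], seed: int) -> list[SequenceRecord]:
    """One dinucleotide-shuffled negative per positive, ids suffixed '_shuf'."""
    for r in positives:
        if r.label != POSITIVE:
            raise ValueError(f"record {r.id!r} is not labeled positive")
    rng = substream(seed, "shuffle")
    out = []
    for r in positives:
        out.append(
            SequenceRecord(
                id=r.id + SHUFFLE_SUFFIX,
                seq=dinucleotide_shuffle(r.seq, rng),
                label=NEGATIVE,
            )
        )
    return out


def _pair_key(record_id: str) -> str:
    return record_id.removesuffix(SHUFFLE_SUFFIX)


def split_dataset(
    records: list[SequenceRecord],
    test_fraction: float = 0.2,
    validation_fraction_of_train: float = 0.1,
    seed: int = 0,
) -> DatasetSplit:
    """Randomly split into train/validation/test, keeping shuffle pairs together.

    A positive and its shuffled negative share a base id and are always
    assigned to the same partition, preventing composition leakage between
    partitions. Fractions are applied at the pair level; unpaired records are
    split separately per label so class balance holds within each partition.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to populate all partitions")
    if any(r.label is None for r in records):
        raise ValueError("all records must carry labels")
    groups: dict[str, list[SequenceRecord]] = {}
    for r in records:
        groups.setdefault(_pair_key(r.id), []).append(r)
    units = sorted(groups.keys())
    rng = substream(seed, "split")

    # stratify: paired units first, then singletons per label
    paired = [u for u in units if len(groups[u]) > 1]
    single_pos = [u for u in units if len(groups[u]) == 1 and groups[u][0].label == POSITIVE]
    single_neg = [u for u in units if len(groups[u]) == 1 and groups[u][0].label == NEGATIVE]

    train: list[SequenceRecord] = []
    val: list[SequenceRecord] = []
    test: list[SequenceRecord] = []
    for stratum in (paired, single_pos, single_neg):
        if not stratum:
            continue
        order = [stratum[i] for i in rng.permutation(len(stratum))]
        n_test = round(len(order) * test_fraction)
        n_val = round((len(order) - n_test) * validation_fraction_of_train)
        for u in order[:n_test]:
            test.extend(groups[u])
        for u in order[n_test : n_test + n_val]:
            val.extend(groups[u])
        for u in order[n_test + n_val :]:
            train.extend(groups[u])
    return DatasetSplit(train=train, validation=val, test=test, seed=seed)
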