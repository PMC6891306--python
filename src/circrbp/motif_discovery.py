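"""Convert learnt convolution kernels into sequence motifs.

Each trained kernel acts as a motif scanner: scanning a sequence records the
position and value of the maximum of the kernel's ReLU feature map. The
h-length subsequences under sufficiently strong maxima are stacked into a
position frequency matrix per kernel, which is exported in MEME minimal
motif format (RNA alphabet, ACGU) for downstream motif-comparison tools.

A local ungapped PFM aligner (`compare_pfm`) is provided to verify recovery
of a known planted motif on synthetic data; it is a stand-in for external
motif-alignment webservices, not a reimplementation of their statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from circrbp.cnn_model import TrainedModel, _branch_forward
from circrbp.encoding import encode_unlabeled
from circrbp.sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

#: alphabet order of PFM rows and MEME columns
PFM_ALPHABET = "ACGU"
_PFM_ROW = {c: i for i, c in enumerate(PFM_ALPHABET)}


@dataclass
class MotifHit:
    """Best scanning position of one kernel on one sequence."""

    kernel_id: int
    record_id: str
    position: int      # 0-based start of the h-window
    activation: float  # max of the kernel's feature map (>= 0 after ReLU)


@dataclass
class PFM:
    """Position frequency matrix over rows A, C, G, U.

    `counts` holds (pseudocount-smoothed) symbol tallies; `probs` is the
    column-stochastic normalization; `nsites` the number of contributing
    subsequences.
    """

    counts: np.ndarray  # (4, w)
    probs: np.ndarray   # (4, w), columns sum to 1
    nsites: int
    kernel_id: int = -1
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.counts.shape[0] != 4 or self.probs.shape != self.counts.shape:
            raise ValueError("PFM matrices must be 4 x width and congruent")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PFM probability columns must sum to 1")
        if not self.name:
            self.name = f"KER_{self.kernel_id}" if self.kernel_id >= 0 else "MOTIF"

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(PFM_ALPHABET[i] for i in self.probs.argmax(axis=0))


def scan_kernel(
    model: TrainedModel, kernel_id: int, records: Sequence[SequenceRecord]
) -> list[MotifHit]:
    """Scan records with one kernel: per record the feature-map argmax and max.

    Ties resolve to the leftmost position. kernel_id indexes kernels globally
    across branches (see TrainedModel.kernel).
    """
    w, b, h = model.kernel(kernel_id)  # raises on out-of-range id
    X, ids = encode_unlabeled(records)
    pooled, argmax, _ = _branch_forward(X, w[None, :, :], np.array([b]))
    # numpy argmax already returns the first maximal index
    return [
        MotifHit(kernel_id=kernel_id, record_id=ids[n], position=int(argmax[n, 0]), activation=float(pooled[n, 0]))
        for n in range(len(ids))
    ]


def build_pfm(
    hits: Sequence[MotifHit],
    records: Mapping[str, SequenceRecord],
    h: int,
    min_activation_fraction: float = 0.5,
    pseudocount: float = 0.25,
) -> PFM:
    """Aggregate one kernel's hits into a PFM.

    Keeps hits with activation >= min_activation_fraction x (the kernel's
    maximum activation over the scanned set) and > 0, stacks the h-length
    subsequences at the hit positions, tallies symbols per column, adds a
    uniform pseudocount, and column-normalizes.
    """
    if not hits:
        raise ValueError("kernel inactive: no hits supplied")
    kernel_ids = {hit.kernel_id for hit in hits}
    if len(kernel_ids) != 1:
        raise ValueError(f"hits from multiple kernels: {sorted(kernel_ids)}")
    top = max(hit.activation for hit in hits)
    kept = [hit for hit in hits if hit.activation > 0 and hit.activation >= min_activation_fraction * top]
    if not kept:
        raise ValueError("kernel inactive: no hits above activation threshold")
    counts = np.full((4, h), float(pseudocount))
    for hit in kept:
        sub = records[hit.record_id].seq[hit.position : hit.position + h]
        if len(sub) != h:
            raise ValueError(f"hit at {hit.position} on {hit.record_id!r} truncates the window")
        for j, c in enumerate(sub):
            counts[_PFM_ROW[c], j] += 1.0
    probs = counts / counts.sum(axis=0, keepdims=True)
    return PFM(counts=counts, probs=probs, nsites=len(kept), kernel_id=kernel_ids.pop())


def discover_motifs(
    model: TrainedModel,
    records: Sequence[SequenceRecord],
    kernel_sizes: Optional[Sequence[int]] = None,
    min_activation_fraction: float = 0.5,
    pseudocount: float = 0.25,
) -> list[PFM]:
    """Scan all kernels (optionally restricted to given sizes) and build PFMs.

    Inactive kernels (never firing above threshold) are skipped with a log
    line. Typically `records` holds positive-labeled sequences only, since
    motifs characterize the bound class.
    """
    by_id = {r.id: r for r in records}
    wanted = set(kernel_sizes) if kernel_sizes is not None else set(model.config.kernel_sizes)
    pfms: list[PFM] = []
    for kid in range(model.n_kernels):
        _, _, h = model.kernel(kid)
        if h not in wanted:
            continue
        hits = scan_kernel(model, kid, records)
        try:
            pfms.append(
                build_pfm(hits, by_id, h, min_activation_fraction=min_activation_fraction, pseudocount=pseudocount)
            )
        except ValueError:
            logger.info("kernel %d inactive, skipped", kid)
    return pfms


def write_meme(pfms: Sequence[PFM], background: Sequence[float], path: str | Path) -> None:
    """Write PFMs in MEME minimal motif format (RNA alphabet ACGU).

    `background` gives mononucleotide frequencies in A, C, G, U order; the
    strand line is omitted (RNA is single-stranded).
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or not np.isclose(background.sum(), 1.0, atol=1e-6):
        raise ValueError("background must be a 4-vector of frequencies summing to 1")
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{c} {background[i]:.6f}" for i, c in enumerate(PFM_ALPHABET)) + "\n\n"
        )
        for pfm in pfms:
            fh.write(f"MOTIF {pfm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pfm.width} nsites= {pfm.nsites} E= 0\n"
            )
            for j in range(pfm.width):
                fh.write(" " + " ".join(f"{pfm.probs[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PFM]:
    """Parse a MEME minimal motif file into PFMs (probs as printed)."""
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip().startswith("MEME version") for line in lines[:5]):
        raise ValueError(f"{path}: missing 'MEME version' line")
    pfms: list[PFM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{i + 1}: MOTIF line without identifier")
            name = parts[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise ValueError(f"{path}:{i + 1}: motif {name!r} has no probability matrix")
                i += 1
            if i == len(lines):
                raise ValueError(f"{path}: motif {name!r} has no probability matrix")
            header = lines[i].strip()
            width = None
            nsites = 0
            tokens = header.replace(":", " ").split()
            for j, tok in enumerate(tokens):
                if tok == "w=" and j + 1 < len(tokens):
                    width = int(tokens[j + 1])
                if tok == "nsites=" and j + 1 < len(tokens):
                    nsites = int(float(tokens[j + 1]))
            if width is None:
                raise ValueError(f"{path}:{i + 1}: matrix header lacks 'w='")
            rows = []
            i += 1
            for _ in range(width):
                if i >= len(lines) or not lines[i].strip():
                    raise ValueError(f"{path}:{i + 1}: truncated probability matrix for {name!r}")
                vals = [float(x) for x in lines[i].split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}:{i + 1}: expected 4 probabilities, got {len(vals)}")
                rows.append(vals)
                i += 1
            probs = np.array(rows).T  # file rows are positions -> transpose to 4 x w
            probs = probs / probs.sum(axis=0, keepdims=True)  # absorb printed rounding
            kid = int(name.split("_")[1]) if name.startswith("KER_") and name.split("_")[1].isdigit() else -1
            pfms.append(PFM(counts=probs * max(nsites, 1), probs=probs, nsites=nsites, kernel_id=kid, name=name))
        else:
            i += 1
    return pfms


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r of two 4-vectors; zero-variance columns contribute 0."""
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def compare_pfm(a: PFM, b: PFM, min_overlap: int = 4) -> tuple[int, float]:
    """Best ungapped alignment of two PFMs by mean per-column Pearson correlation.

    Returns (offset, score) where `offset` is the column of `b` aligned with
    column 0 of `a` (so a motif embedded at column 2 of a wider PFM scores
    1.0 at offset 2). Ties prefer the smallest |offset|, then the smaller
    offset. Score lies in [-1, 1].
    """
    wa, wb = a.width, b.width
    if wa < min_overlap or wb < min_overlap:
        raise ValueError(f"PFM widths {wa},{wb} below minimum overlap {min_overlap}")
    best: Optional[tuple[float, int]] = None
    # offset o: a's column i aligns with b's column i + o
    for o in range(-(wa - min_overlap), wb - min_overlap + 1):
        lo = max(0, -o)
        hi = min(wa, wb - o)
        if hi - lo < min_overlap:
            continue
        score = float(
            np.mean([_column_corr(a.probs[:, i], b.probs[:, i + o]) for i in range(lo, hi)])
        )
        key = (score, -abs(o), -o)
        if best is None or key > (best[0], -abs(best[1]), -best[1]):
            best = (score, o)
    if best is None:
        raise ValueError("no alignment with sufficient overlap")
    return best[1], best[0]


def empirical_background(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Mononucleotide frequencies of a record set, in A, C, G, U order."""
    counts = np.zeros(4)
    for r in records:
        for c in r.seq:
            counts[_PFM_ROW[c]] += 1
    if counts.sum() == 0:
        raise ValueError("no sequence content")
    return counts / counts.sum()
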