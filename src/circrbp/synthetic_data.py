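"""Planted-motif benchmark generator.

Emulates the statistical structure of an RBP binding-site dataset: positive
fragments are drawn from a first-order (dinucleotide) Markov background
with one instance of a protein-binding motif — a string sampled from a PWM
— planted at a uniform random position; negatives are dinucleotide-
composition-matched shuffles of the positives, exactly as in the real
dataset-construction pipeline. Ground truth (planted positions and the PWM)
is retained so motif-recovery and discrimination benchmarks have an oracle.

The default planted motif is the 8-mer UAGGUAGG (the DAZAP1-like consensus)
sharpened to 0.85 per consensus base, in 100-nt fragments, with a mildly
skewed background transition matrix so dinucleotide shuffling is
non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from circrbp._rng import substream
from circrbp.sequence_io import POSITIVE, SequenceRecord, make_negatives

#: alphabet order for background/PWM matrices (matches PFM row order)
SYNTH_ALPHABET = "ACGU"
_IDX = {c: i for i, c in enumerate(SYNTH_ALPHABET)}

DEFAULT_MOTIF = "UAGGUAGG"
DEFAULT_SHARPNESS = 0.85


def pwm_from_consensus(consensus: str, sharpness: float = DEFAULT_SHARPNESS) -> np.ndarray:
    """Column-stochastic 4xw PWM putting `sharpness` mass on each consensus base."""
    if not (0.25 <= sharpness <= 1.0):
        raise ValueError("sharpness must be in [0.25, 1]")
    w = len(consensus)
    pwm = np.full((4, w), (1.0 - sharpness) / 3.0)
    for j, c in enumerate(consensus):
        pwm[_IDX[c], j] = sharpness
    return pwm


def _default_transition() -> np.ndarray:
    # rows mildly skewed (0.3/0.3/0.2/0.2 rolled per row) so the dinucleotide
    # composition carries signal and shuffling negatives is non-trivial
    base = np.array([0.3, 0.3, 0.2, 0.2])
    return np.stack([np.roll(base, i) for i in range(4)])


@dataclass
class SyntheticConfig:
    """Parameters of the planted-motif generator."""

    n_pairs: int = 2000
    length: int = 100
    background_transition: np.ndarray = field(default_factory=_default_transition)
    background_initial: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    motif_pwm: np.ndarray = field(default_factory=lambda: pwm_from_consensus(DEFAULT_MOTIF))
    plant_probability: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.background_transition, dtype=float)
        init = np.asarray(self.background_initial, dtype=float)
        pwm = np.asarray(self.motif_pwm, dtype=float)
        if t.shape != (4, 4) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("background transition rows must be 4x4 and sum to 1")
        if init.shape != (4,) or not np.isclose(init.sum(), 1.0, atol=1e-9):
            raise ValueError("background initial distribution must be a stochastic 4-vector")
        if pwm.shape[0] != 4 or not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if pwm.shape[1] > self.length:
            raise ValueError("PWM wider than fragment length")
        if not (0.0 <= self.plant_probability <= 1.0):
            raise ValueError("plant_probability must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted positions per positive id (None if unplanted) and the PWM."""

    positions: dict[str, Optional[int]]
    planted: dict[str, Optional[str]]
    pwm: np.ndarray


def sample_background(config: SyntheticConfig, rng: np.random.Generator) -> str:
    """One fragment from the first-order Markov background."""
    config.validate()
    t = np.asarray(config.background_transition, dtype=float)
    out = [rng.choice(4, p=np.asarray(config.background_initial, dtype=float))]
    for _ in range(config.length - 1):
        out.append(rng.choice(4, p=t[out[-1]]))
    return "".join(SYNTH_ALPHABET[i] for i in out)


def plant_motif(seq: str, pwm: np.ndarray, rng: np.random.Generator) -> tuple[str, int]:
    """Sample a string from the PWM and overwrite seq at a uniform valid offset.

    The instance never straddles the fragment edge; returns the new sequence
    and the 0-based planting position.
    """
    pwm = np.asarray(pwm, dtype=float)
    w = pwm.shape[1]
    if w > len(seq):
        raise ValueError("PWM wider than sequence")
    instance = "".join(SYNTH_ALPHABET[rng.choice(4, p=pwm[:, j])] for j in range(w))
    pos = int(rng.integers(0, len(seq) - w + 1))
    return seq[:pos] + instance + seq[pos + w :], pos


def generate_dataset(config: SyntheticConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """n_pairs positives (motif planted with plant_probability) + shuffled negatives.

    Negatives reuse the dataset-construction shuffle, so every negative
    matches its paired positive's dinucleotide composition exactly. Output
    is a pure function of config.seed.
    """
    config.validate()
    rng = substream(config.seed, "synthetic")
    positives: list[SequenceRecord] = []
    positions: dict[str, Optional[int]] = {}
    planted: dict[str, Optional[str]] = {}
    width = np.asarray(config.motif_pwm).shape[1]
    for n in range(config.n_pairs):
        seq = sample_background(config, rng)
        rec_id = f"pos_{n:05d}"
        if rng.random() < config.plant_probability:
            seq, pos = plant_motif(seq, config.motif_pwm, rng)
            positions[rec_id] = pos
            planted[rec_id] = seq[pos : pos + width]
        else:
            positions[rec_id] = None
            planted[rec_id] = None
        positives.append(SequenceRecord(id=rec_id, seq=seq, label=POSITIVE))
    negatives = make_negatives(positives, seed=config.seed)
    records = positives + negatives
    truth = GroundTruth(positions=positions, planted=planted, pwm=np.asarray(config.motif_pwm, dtype=float))
    return records, truth
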