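"""Seeded synthetic long-read generator.

Emulates nanopore sequencing of a pool of linearized plasmid molecules with
variable repeat copy number plus background molecules (the endogenous
2-micron plasmid, rDNA- and mtDNA-derived fragments dominate real plasmid
preps). Each read carries substitution/insertion/deletion errors and may be
clipped at either end, the two artefacts the anchor-based selection strategy
is designed to defeat. A truth table records, per read, the origin molecule,
true copy number, strand and clip lengths, so downstream stages can be scored
exactly.

Reproducibility: one master seed; the RNG stream for read ``i`` is derived
from ``(seed, i)`` with ``numpy.random.SeedSequence`` spawn keys, so read i is
identical for any total read count >= i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmer import revcomp
from .plasmid import ConfigurationError, PlasmidMap, build_template

__all__ = [
    "ErrorModel",
    "ClipModel",
    "BackgroundMolecule",
    "MixtureSpec",
    "SimRead",
    "SimBatch",
    "mutate",
    "simulate_sample",
    "TARGET_LABEL",
]

TARGET_LABEL = "target"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {0: "A", 1: "C", 2: "G", 3: "T"}
_ENC = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution/insertion/deletion rates and a flat Phred value.

    Defaults are a crude stand-in for current nanopore chemistry with
    high-accuracy basecalling (~2.5% total error, deletion-leaning); they are
    not calibrated to any particular run and are meant to be overridden.
    """

    sub_rate: float = 0.01
    ins_rate: float = 0.005
    del_rate: float = 0.01
    qual_mean: int = 20

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 0.5:
                raise ConfigurationError("error rates must lie in [0, 0.5)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1:
            raise ConfigurationError("total error rate must be < 1")

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass(frozen=True)
class ClipModel:
    """End-truncation model: each read end is clipped with probability
    ``clip_prob`` by a geometric length of the given mean."""

    clip_prob: float = 0.0
    clip_len_mean: float = 300.0

    def __post_init__(self) -> None:
        if not 0 <= self.clip_prob <= 1:
            raise ConfigurationError("clip_prob must be in [0, 1]")
        if self.clip_len_mean < 0:
            raise ConfigurationError("clip_len_mean must be >= 0")


@dataclass(frozen=True)
class BackgroundMolecule:
    label: str
    seq: str
    circular: bool = False


@dataclass
class MixtureSpec:
    """Composition of the molecule pool.

    ``proportions`` maps repeat copy number to its frequency among target
    molecules (must sum to 1); ``background_fraction`` is the probability a
    read derives from the background pool instead.
    """

    proportions: dict[int, float]
    background_fraction: float = 0.0
    background_pool: list[BackgroundMolecule] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"copy-number proportions sum to {total}, not 1")
        if any(k < 0 for k in self.proportions):
            raise ConfigurationError("copy numbers must be >= 0")
        if not 0 <= self.background_fraction <= 1:
            raise ConfigurationError("background_fraction must be in [0, 1]")
        if self.background_fraction > 0 and not self.background_pool:
            raise ConfigurationError(
                "background_fraction > 0 requires a non-empty background pool"
            )

    def without_linear_background(self) -> "MixtureSpec":
        """Pool after exonuclease V (RecBCD) treatment: linear background
        molecules are degraded, circular ones survive. Models the second
        purification protocol compositionally."""
        pool = [m for m in self.background_pool if m.circular]
        frac = self.background_fraction if pool else 0.0
        return MixtureSpec(dict(self.proportions), frac, pool)


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    quality: str


@dataclass
class SimBatch:
    """Simulated reads plus their truth table (indexed by read_id)."""

    reads: list[SimRead]
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [r.read_id for r in self.reads]
        if len(set(ids)) != len(ids) or set(ids) != set(self.truth.index):
            raise ValueError("read ids must appear exactly once in reads and truth")

    def __len__(self) -> int:
        return len(self.reads)


def _mutate_codes(codes: np.ndarray, model: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    n = codes.size
    if n == 0:
        return codes
    out = codes.copy()
    u = rng.random(n)
    keep = u >= model.del_rate
    sub = (u >= model.del_rate) & (u < model.del_rate + model.sub_rate)
    if sub.any():
        # substitute with one of the three other bases, uniformly
        out[sub] = (out[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    ins = rng.random(n + 1) < model.ins_rate
    n_ins = int(ins.sum())
    if n_ins == 0:
        return out[keep]
    ins_pos = np.nonzero(ins)[0]
    ins_bases = rng.integers(0, 4, size=n_ins).astype(codes.dtype)
    kept_pos = np.nonzero(keep)[0]
    # insertions sort before the base at the same position
    keys = np.concatenate([2 * kept_pos + 1, 2 * ins_pos])
    vals = np.concatenate([out[keep], ins_bases])
    order = np.argsort(keys, kind="stable")
    return vals[order]


def mutate(seq: str, model: ErrorModel, rng_seed: int | np.random.Generator) -> str:
    """Apply the error model to one sequence; deterministic for a fixed seed."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if not seq:
        return ""
    codes = _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    return _BASES[_mutate_codes(codes, model, rng)].tobytes().decode("ascii")


def _read_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def _geometric_clip(rng: np.random.Generator, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1.0)) - 1)


def simulate_sample(
    pmap: PlasmidMap,
    mix: MixtureSpec,
    err: ErrorModel,
    clip: ClipModel,
    n_reads: int,
    rng_seed: int,
    read_prefix: str = "read",
) -> SimBatch:
    """Draw ``n_reads`` reads from the molecule pool.

    Target reads are full linearized templates of their drawn copy number;
    circular background molecules are opened at a uniform random position
    (mimicking random linearization/fragmentation), linear ones enter whole.
    Strand is uniform; clipping is applied to the oriented template before
    errors, as truncated capture precedes the error process.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    copies = sorted(mix.proportions)
    cum = np.cumsum([mix.proportions[c] for c in copies])
    templates = {c: build_template(pmap, c).full_seq for c in copies}
    qual_char = chr(min(err.qual_mean, 93) + 33)

    reads: list[SimRead] = []
    truth_rows = []
    width = max(6, len(str(n_reads)))
    for i in range(n_reads):
        rng = _read_rng(rng_seed, i)
        if mix.background_fraction > 0 and rng.random() < mix.background_fraction:
            mol = mix.background_pool[int(rng.integers(len(mix.background_pool)))]
            if mol.circular:
                cut = int(rng.integers(len(mol.seq)))
                seq = mol.seq[cut:] + mol.seq[:cut]
            else:
                seq = mol.seq
            origin, copy = mol.label, None
        else:
            c = copies[int(np.searchsorted(cum, rng.random(), side="right"))]
            seq = templates[c]
            origin, copy = TARGET_LABEL, c
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            seq = revcomp(seq)
        left_clip = right_clip = 0
        if clip.clip_prob > 0:
            if rng.random() < clip.clip_prob:
                left_clip = _geometric_clip(rng, clip.clip_len_mean)
            if rng.random() < clip.clip_prob:
                right_clip = _geometric_clip(rng, clip.clip_len_mean)
            if left_clip + right_clip >= len(seq):
                # degenerate double-clip: keep at least one base
                left_clip = min(left_clip, len(seq) - 1)
                right_clip = len(seq) - 1 - left_clip
        if left_clip or right_clip:
            seq = seq[left_clip: len(seq) - right_clip]
        seq = mutate(seq, err, rng)
        rid = f"{read_prefix}_{i:0{width}d}"
        reads.append(SimRead(rid, seq, qual_char * len(seq)))
        truth_rows.append(
            {
                "read_id": rid,
                "origin": origin,
                "copy_number": copy,
                "strand": strand,
                "left_clip": left_clip,
                "right_clip": right_clip,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("read_id")
    return SimBatch(reads, truth)
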