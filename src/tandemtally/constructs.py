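"""Synthetic stand-in sequences for the carrier construct and background pool.

No public sequence is available for the actual construct (a URA3-marked
centromeric plasmid carrying two tandem copies of a ~2 kb CUP1 repeat unit),
so the package ships deterministic synthetic surrogates with the same
architecture and scale: a ~5.8 kb vector backbone with a unique PmlI site, a
2 kb repeat unit free of that site, and background molecules mimicking the
2-micron plasmid (circular, BsoBI/SphI-cuttable, PmlI-free) and rDNA/mtDNA
fragments (linear). Real constructs are supplied as FASTA via the CLI/config.

All sequences are generated from fixed internal seeds and are identical on
every call.
"""

from __future__ import annotations

import numpy as np

from .plasmid import DEFAULT_ENZYMES, PlasmidMap, RestrictionEnzyme, build_template, find_sites
from .simulate import BackgroundMolecule

__all__ = [
    "random_dna",
    "scrub_sites",
    "default_plasmid_map",
    "small_plasmid_map",
    "default_background_pool",
    "DEFAULT_MIXTURE_PROPORTIONS",
]

#: Copy-number mixture observed in the assay this package models: ~7.32% of
#: molecules contracted to one unit and ~0.36% expanded to three; used as the
#: simulator's default truth for a yeast-passaged two-unit array.
DEFAULT_MIXTURE_PROPORTIONS: dict[int, float] = {1: 0.0732, 2: 0.9232, 3: 0.0036}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def scrub_sites(seq: str, enzyme: RestrictionEnzyme, circular: bool = False) -> str:
    """Destroy every occurrence of the recognition site by toggling its
    middle base (A<->C); deterministic and re-checked until clean."""
    s = list(seq)
    for _ in range(10):
        sites = find_sites("".join(s), enzyme, circular=circular)
        if not sites:
            break
        for pos in sites:
            mid = (pos + len(enzyme.recognition) // 2) % len(s)
            s[mid] = "C" if s[mid] != "C" else "A"
    return "".join(s)


def _clean_random_dna(rng: np.random.Generator, n: int,
                      avoid: list[RestrictionEnzyme], circular: bool = False) -> str:
    seq = random_dna(rng, n)
    for enz in avoid:
        seq = scrub_sites(seq, enz, circular=circular)
    return seq


def default_plasmid_map(vector_len: int = 5800, unit_len: int = 2000) -> PlasmidMap:
    """The default synthetic construct: unique PmlI site in the vector,
    PmlI-free 2 kb repeat unit, array inserted opposite the cut site."""
    return _make_map(seed=715, vector_len=vector_len, unit_len=unit_len)


def small_plasmid_map() -> PlasmidMap:
    """A miniature construct (1.4 kb vector, 250 bp unit) with the same
    architecture; used where exhaustive quadratic-time cross-checks must stay
    cheap."""
    return _make_map(seed=941, vector_len=1400, unit_len=250)


def _make_map(seed: int, vector_len: int, unit_len: int) -> PlasmidMap:
    rng = np.random.default_rng(seed)
    pml = DEFAULT_ENZYMES["PmlI"]
    avoid = [pml]
    vector = _clean_random_dna(rng, vector_len, avoid, circular=True)
    # place the unique linearization site roughly opposite the array insert
    site_pos = vector_len // 2
    vector = vector[:site_pos] + pml.recognition + vector[site_pos + len(pml.recognition):]
    unit = _clean_random_dna(rng, unit_len, avoid)
    pmap = PlasmidMap(vector, 0, unit, pml)
    # junction safety: no site may arise where units meet each other or the vector
    for k in range(0, 7):
        build_template(pmap, k)  # raises ConfigurationError on any extra site
    return pmap


def default_background_pool() -> list[BackgroundMolecule]:
    """Background surrogates: a circular 2-micron-like plasmid (PmlI-free,
    carrying BsoBI and SphI sites) and linear rDNA-/mtDNA-like fragments."""
    rng = np.random.default_rng(4052)
    pml = DEFAULT_ENZYMES["PmlI"]
    sph = DEFAULT_ENZYMES["SphI"]
    bso = DEFAULT_ENZYMES["BsoBI"]

    two_micron = _clean_random_dna(rng, 6300, [pml], circular=True)
    # guarantee at least one site for each 2-micron-cutting enzyme
    two_micron = (
        two_micron[:1000] + bso.recognition
        + two_micron[1000 + len(bso.recognition): 4000] + sph.recognition
        + two_micron[4000 + len(sph.recognition):]
    )
    rdna = _clean_random_dna(rng, 9100, [pml])
    mtdna = _clean_random_dna(rng, 7500, [pml])
    return [
        BackgroundMolecule("2micron_like", two_micron, circular=True),
        BackgroundMolecule("rDNA_like", rdna, circular=False),
        BackgroundMolecule("mtDNA_like", mtdna, circular=False),
    ]
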