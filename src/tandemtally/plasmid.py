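"""Carrier-plasmid model: restriction sites, in-silico digestion, linearization.

The construct of interest is a centromeric (YCp-type) plasmid carrying a
tandem array of a ~2 kb repeat unit. Cutting the circle at a unique
restriction site turns every molecule into one linear template in which the
array is bracketed by two defined vector arms; those arms are what the read
classifier later anchors on.

Coordinates are 0-based, half-open throughout; positions on circular
sequences are reported modulo the sequence length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._kmer import revcomp

__all__ = [
    "ConfigurationError",
    "RestrictionEnzyme",
    "PlasmidMap",
    "LinearTemplate",
    "DigestResult",
    "DEFAULT_ENZYMES",
    "find_sites",
    "digest_circular",
    "build_template",
]


class ConfigurationError(ValueError):
    """Invalid enzyme, construct, or parameter configuration."""


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def _iupac_regex(recognition: str) -> re.Pattern:
    parts = []
    for ch in recognition.upper():
        if ch not in _IUPAC:
            raise ConfigurationError(f"invalid IUPAC code {ch!r} in recognition site")
        bases = _IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease defined by its recognition site.

    ``cut_offset`` is the 0-based position of the top-strand cut within (or at
    the end of) the recognition site. When omitted it defaults to the
    blunt-cut midpoint, which is correct for PmlI (CAC^GTG).
    """

    name: str
    recognition: str
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ConfigurationError("empty recognition sequence")
        _iupac_regex(self.recognition)  # validates characters
        if self.cut_offset is not None and not (
            0 <= self.cut_offset <= len(self.recognition)
        ):
            raise ConfigurationError(
                f"cut_offset {self.cut_offset} outside recognition site "
                f"of length {len(self.recognition)}"
            )

    @property
    def cut(self) -> int:
        return len(self.recognition) // 2 if self.cut_offset is None else self.cut_offset


#: Enzymes used by the linearization protocols: PmlI opens the test plasmid;
#: BsoBI + SphI linearize the endogenous 2-micron plasmid so exonuclease can
#: remove it. Overridable via config.
DEFAULT_ENZYMES: dict[str, RestrictionEnzyme] = {
    "PmlI": RestrictionEnzyme("PmlI", "CACGTG", 3),
    "SphI": RestrictionEnzyme("SphI", "GCATGC", 5),
    "BsoBI": RestrictionEnzyme("BsoBI", "CYCGRG", 1),
}


def find_sites(seq: str, enzyme: RestrictionEnzyme, circular: bool = False) -> list[int]:
    """0-based start positions of the recognition site, sorted ascending.

    For circular sequences, sites spanning the origin are found by scanning
    the sequence extended with its first ``len(recognition) - 1`` bases and
    reported modulo the sequence length.
    """
    if not seq:
        raise ValueError("empty sequence")
    pattern = _iupac_regex(enzyme.recognition)
    search_space = seq.upper()
    n = len(seq)
    if circular and len(enzyme.recognition) > 1:
        search_space += search_space[: len(enzyme.recognition) - 1]
    sites = sorted({m.start() % n for m in pattern.finditer(search_space) if m.start() < n})
    return sites


@dataclass
class DigestResult:
    """Fragments from a circular digest; empty with ``remains_circular`` set
    when no enzyme cuts."""

    fragments: list[str]
    remains_circular: bool

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)


def digest_circular(seq: str, enzymes: list[RestrictionEnzyme]) -> DigestResult:
    """Digest a circular molecule with one or more enzymes.

    With k >= 1 cut positions the result is exactly k fragments whose
    concatenation, starting from the first cut, is a rotation of the input.
    """
    n = len(seq)
    cuts = sorted(
        {
            (site + enz.cut) % n
            for enz in enzymes
            for site in find_sites(seq, enz, circular=True)
        }
    )
    if not cuts:
        return DigestResult([], remains_circular=True)
    doubled = seq + seq
    frags = []
    for i, start in enumerate(cuts):
        end = cuts[(i + 1) % len(cuts)]
        if end <= start:
            end += n
        frags.append(doubled[start:end])
    return DigestResult(frags, remains_circular=False)


@dataclass
class PlasmidMap:
    """The carrier construct: circular vector backbone plus the repeat unit.

    ``array_insert_pos`` locates the array on the vector circle (units are
    inserted head-to-tail at that position). The linearization enzyme must cut
    the vector exactly once and the repeat unit never, so every template has
    well-defined vector arms around the array.
    """

    vector_seq: str
    array_insert_pos: int
    repeat_unit_seq: str
    linearization_enzyme: RestrictionEnzyme = field(
        default_factory=lambda: DEFAULT_ENZYMES["PmlI"]
    )

    def __post_init__(self) -> None:
        for label, s in (("vector", self.vector_seq), ("repeat unit", self.repeat_unit_seq)):
            if not s or set(s.upper()) - set("ACGTN"):
                raise ConfigurationError(f"{label} sequence must be non-empty ACGT(N)")
        if not 0 <= self.array_insert_pos <= len(self.vector_seq):
            raise ConfigurationError("array_insert_pos outside vector")
        vec_sites = find_sites(self.vector_seq, self.linearization_enzyme, circular=True)
        if len(vec_sites) != 1:
            raise ConfigurationError(
                f"linearization enzyme {self.linearization_enzyme.name} has "
                f"{len(vec_sites)} sites in the vector (need exactly 1)"
            )
        if find_sites(self.repeat_unit_seq, self.linearization_enzyme, circular=False):
            raise ConfigurationError(
                "linearization enzyme cuts inside the repeat unit"
            )

    @property
    def unit_length(self) -> int:
        return len(self.repeat_unit_seq)


@dataclass
class LinearTemplate:
    """One linearized molecule: left vector arm, k repeat units, right arm."""

    left_flank: str
    right_flank: str
    copy_number: int
    repeat_unit_seq: str

    @property
    def full_seq(self) -> str:
        return self.left_flank + self.repeat_unit_seq * self.copy_number + self.right_flank

    def __len__(self) -> int:
        return (
            len(self.left_flank)
            + self.copy_number * len(self.repeat_unit_seq)
            + len(self.right_flank)
        )


def build_template(pmap: PlasmidMap, copy_number: int) -> LinearTemplate:
    """Assemble the circle with ``copy_number`` units and open it at the
    unique linearization cut.

    The flank lengths depend only on the vector and cut position, never on the
    copy number — which is what lets one anchor pair serve every array length.
    """
    if copy_number < 0:
        raise ValueError("copy_number must be >= 0")
    ins = pmap.array_insert_pos
    circle = (
        pmap.vector_seq[:ins]
        + pmap.repeat_unit_seq * copy_number
        + pmap.vector_seq[ins:]
    )
    sites = find_sites(circle, pmap.linearization_enzyme, circular=True)
    if len(sites) != 1:
        raise ConfigurationError(
            f"assembled circle has {len(sites)} linearization sites (need 1); "
            "check for sites created at insert junctions"
        )
    cut = (sites[0] + pmap.linearization_enzyme.cut) % len(circle)
    array_len = copy_number * pmap.unit_length
    # rotate so the molecule starts at the cut; array occupies [ins, ins+array_len)
    rotated = circle[cut:] + circle[:cut]
    arr_start_rot = (ins - cut) % len(circle)
    left = rotated[:arr_start_rot]
    right = rotated[arr_start_rot + array_len:]
    tmpl = LinearTemplate(left, right, copy_number, pmap.repeat_unit_seq)
    assert len(tmpl) == len(circle)
    return tmpl


def reverse_complement(seq: str) -> str:
    return revcomp(seq)
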