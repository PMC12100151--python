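"""End-to-end read processing: classify, count, summarize.

Thin orchestration over the selection and counting modules so the CLI, the
tests, and library users share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .count import CopyCall, UnitParams, count_copies, scan_units
from .plasmid import PlasmidMap
from .select import AnchorParams, ReadClass, SelectionSummary, arm_sequences, classify_read, summarize_selection
from .stats import SampleSummary, copy_distribution

__all__ = ["ProfileResult", "profile_reads"]


@dataclass
class ProfileResult:
    classes: list[ReadClass]
    calls: dict[str, CopyCall]          # target reads only
    selection: SelectionSummary

    def distribution(self, sample_id: str, group: str = "",
                     include_partial: bool = False) -> SampleSummary:
        return copy_distribution(
            sample_id, list(self.calls.values()), group=group,
            include_partial=include_partial,
        )


def profile_reads(
    reads: list[tuple[str, str]],
    pmap: PlasmidMap,
    anchor_params: AnchorParams | None = None,
    unit_params: UnitParams | None = None,
) -> ProfileResult:
    """Classify every (read_id, sequence) pair and count units on targets."""
    anchor_params = anchor_params or AnchorParams()
    unit_params = unit_params or UnitParams()
    arms = arm_sequences(pmap, anchor_params)
    classes: list[ReadClass] = []
    calls: dict[str, CopyCall] = {}
    for read_id, seq in reads:
        rc = classify_read(read_id, seq, pmap, anchor_params, arms=arms)
        classes.append(rc)
        if rc.call == "target":
            hits = scan_units(
                seq, rc.inter_anchor_interval, pmap.repeat_unit_seq,
                unit_params, strand=rc.left_hit.strand,
            )
            calls[read_id] = count_copies(read_id, hits)
    return ProfileResult(classes, calls, summarize_selection(classes))
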