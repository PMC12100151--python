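"""Replicate-level statistics: copy-number distributions, group comparisons,
and the enrichment-mass arithmetic.

The unit of analysis is the per-replicate percentage (e.g. percent one-copy
reads in each biological replicate); groups are compared with Welch's
unequal-variance t-test, a robust default at the 2-6 replicates typical of
these experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .count import CopyCall

__all__ = [
    "SampleSummary",
    "GroupComparison",
    "EnrichmentEstimate",
    "copy_distribution",
    "welch_t",
    "estimate_target_mass",
    "yield_reduction",
    "render_report",
]


@dataclass
class SampleSummary:
    """Copy-number distribution of one replicate."""

    sample_id: str
    group: str
    n_target_reads: int
    proportions: dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")

    def pct(self, copy_number: int) -> float:
        return 100.0 * self.proportions.get(copy_number, 0.0)

    @property
    def pct_one_copy(self) -> float:
        return self.pct(1)

    @property
    def pct_two_copy(self) -> float:
        return self.pct(2)

    @property
    def pct_three_copy(self) -> float:
        return self.pct(3)


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float


@dataclass
class EnrichmentEstimate:
    """Mass of target molecules in a prep: total DNA mass times the target
    read fraction (valid when target and background molecules have similar
    lengths)."""

    total_mass_ng: float
    target_fraction: float
    target_mass_ng: float = field(init=False)

    def __post_init__(self) -> None:
        if self.total_mass_ng < 0 or self.target_fraction < 0:
            raise ValueError("mass and fraction must be non-negative")
        if self.target_fraction > 1:
            raise ValueError("target_fraction cannot exceed 1")
        self.target_mass_ng = self.total_mass_ng * self.target_fraction

    @property
    def display(self) -> str:
        """Mass truncated (not rounded) to 3 decimals, as reported."""
        return f"{math.floor(self.target_mass_ng * 1000) / 1000:.3f}"


def copy_distribution(
    sample_id: str,
    calls: list[CopyCall],
    group: str = "",
    include_partial: bool = False,
) -> SampleSummary:
    """Empirical copy-number proportions over a replicate's target reads.

    Reads flagged ``has_partial`` are excluded unless ``include_partial``;
    the exclusion is conservative (a broken unit should not silently count
    as a shorter array).
    """
    used = [c for c in calls if include_partial or c.qc == "clean"]
    if not used:
        raise ValueError("no usable copy calls")
    counts: dict[int, int] = {}
    for c in used:
        counts[c.copy_number] = counts.get(c.copy_number, 0) + 1
    n = len(used)
    props = {k: v / n for k, v in sorted(counts.items())}
    return SampleSummary(sample_id, group, n, props)


def welch_t(
    values_a: list[float],
    values_b: list[float],
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    Convention: if both groups have zero variance and equal means the test is
    degenerate and reports t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = a.mean(), b.mean()
    se2 = va / a.size + vb / b.size
    if se2 == 0:
        t = 0.0 if ma == mb else math.copysign(math.inf, ma - mb)
        p = 1.0 if ma == mb else 0.0
        df = float(a.size + b.size - 2)
    else:
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        )
        p = float(2 * sps.t.sf(abs(t), df))
    return GroupComparison(
        group_a, group_b, float(ma), float(mb),
        float(math.sqrt(va)), float(math.sqrt(vb)),
        float(t), float(df), float(p),
    )


def estimate_target_mass(total_mass_ng: float, target_fraction: float) -> EnrichmentEstimate:
    """Target-plasmid mass = total purified mass x target read fraction."""
    return EnrichmentEstimate(total_mass_ng, target_fraction)


def yield_reduction(mass_ref_ng: float, mass_alt_ng: float) -> float:
    """Percent yield lost by the alternative protocol relative to the
    reference: 100 * (1 - alt / ref)."""
    if mass_ref_ng <= 0:
        raise ValueError("reference mass must be > 0")
    return 100.0 * (1.0 - mass_alt_ng / mass_ref_ng)


def group_stats(summaries: list[SampleSummary], copy_number: int = 1) -> pd.DataFrame:
    """Mean +/- SD of the percentage of a given copy class, per group."""
    rows = [
        {"group": s.group, "sample_id": s.sample_id, "pct": s.pct(copy_number)}
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    return df.groupby("group")["pct"].agg(["mean", "std", "count"]).reset_index()


def render_report(
    summaries: list[SampleSummary],
    out_dir,
    comparisons: list[GroupComparison] | None = None,
    selection=None,
    enrichment: list[EnrichmentEstimate] | None = None,
    header_lines: list[str] | None = None,
) -> dict:
    """Write the distribution table (TSV), a JSON summary, and a plain-text
    report; returns the JSON-ready dict."""
    if not summaries:
        raise ValueError("no sample summaries to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_copies = sorted({k for s in summaries for k in s.proportions})
    rows = []
    for s in summaries:
        row = {"sample_id": s.sample_id, "group": s.group, "n_target_reads": s.n_target_reads}
        for k in all_copies:
            row[f"pct_{k}_copy"] = s.pct(k)
        rows.append(row)
    table = pd.DataFrame(rows)
    tsv_path = out_dir / "copy_distribution.tsv"
    with tsv_path.open("w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)

    payload: dict = {
        "samples": [
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "n_target_reads": s.n_target_reads,
                "proportions": {str(k): v for k, v in s.proportions.items()},
            }
            for s in summaries
        ]
    }
    if comparisons:
        payload["comparisons"] = [vars(c) for c in comparisons]
    if selection is not None:
        payload["selection"] = (
            selection.as_dict() if hasattr(selection, "as_dict") else selection
        )
    if enrichment:
        payload["enrichment"] = [
            {
                "total_mass_ng": e.total_mass_ng,
                "target_fraction": e.target_fraction,
                "target_mass_ng": e.target_mass_ng,
                "display": e.display,
            }
            for e in enrichment
        ]
    with (out_dir / "report.json").open("w") as fh:
        json.dump(payload, fh, indent=2)

    lines = ["Copy-number distribution report", "=" * 32, ""]
    for s in summaries:
        dist = ", ".join(f"{k}: {s.pct(k):.2f}%" for k in all_copies)
        lines.append(f"{s.sample_id} [{s.group}] n={s.n_target_reads}  {dist}")
    if comparisons:
        lines.append("")
        for c in comparisons:
            lines.append(
                f"{c.group_a} vs {c.group_b}: mean {c.mean_a:.2f} vs {c.mean_b:.2f}, "
                f"t = {c.t:.3f}, df = {c.df:.2f}, p = {c.p:.3g}"
            )
    if enrichment:
        lines.append("")
        for e in enrichment:
            lines.append(
                f"target mass: {e.total_mass_ng} ng x {e.target_fraction} = {e.display} ng"
            )
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return payload


def plot_distribution(summaries: list[SampleSummary], path) -> None:
    """Bar plot of per-sample copy-number percentages (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    all_copies = sorted({k for s in summaries for k in s.proportions})
    x = np.arange(len(summaries))
    width = 0.8 / max(1, len(all_copies))
    fig, ax = plt.subplots(figsize=(1.5 + len(summaries), 4))
    for j, k in enumerate(all_copies):
        ax.bar(x + j * width, [s.pct(k) for s in summaries], width, label=f"{k} copies")
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([s.sample_id for s in summaries], rotation=45, ha="right")
    ax.set_ylabel("% of target reads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
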