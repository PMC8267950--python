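"""Per-nucleus ploidy annotation, gain/loss patterns and sample summaries.

Each nucleus is assigned an integer ploidy anchored on the centromere
reference probes, with amplified gene probes excluded from the average
so they do not bias it.  Gains and losses are then scored per gene
relative to that nucleus's own ploidy, which makes the calls robust to
whole-genome duplication: a uniformly tetraploid nucleus is neutral at
every locus.

Sample-level summaries aggregate these annotations into the average
ploidy (diploid below 2.2, aneuploid at or above), the instability
index I = N*100/n (N distinct signal patterns among n nuclei), per-gene
copy-number-alteration (CNA) calls at the 15%/85% fraction thresholds,
and amplification flags (mean signal count exceeding twice the sample
ploidy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import NucleusRecord, aggregate_patterns, validate_sample
from .panel import ProbePanel

ANEUPLOID_CUTOFF = 2.2
CNA_MINOR_FRACTION = 0.15
CNA_MAJOR_FRACTION = 0.85
AMPLIFICATION_MULTIPLIER = 2

GainLossState = Literal["gain", "loss", "neutral"]


def round_half_up_ratio(numerator: int, denominator: int) -> int:
    """Round numerator/denominator to the nearest integer, halves up.

    Exact integer arithmetic; avoids binary-float banker's rounding.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (2 * numerator + denominator) // (2 * denominator)


def round_half_up_1dp(numerator: int, denominator: int) -> float:
    """Round numerator/denominator to one decimal place, halves up."""
    return round_half_up_ratio(10 * numerator, denominator) / 10.0


@dataclass(frozen=True)
class PloidyAnnotation:
    """Integer ploidy assigned to one nucleus.

    ``excluded_probes`` lists gene probes left out of the average
    because their count exceeded twice the centromere-anchored
    candidate ploidy (i.e. looked amplified).
    """

    nucleus_ploidy: int
    excluded_probes: tuple[str, ...] = ()
    method_note: str = ""


@dataclass(frozen=True)
class GainLossPattern:
    """Per-gene trichotomy (gain/loss/neutral) relative to nucleus ploidy."""

    states: tuple[GainLossState, ...]

    @property
    def n_aberrant(self) -> int:
        return sum(1 for s in self.states if s != "neutral")

    def label(self, gene_names: Sequence[str]) -> str:
        """Compact label like ``"MYC+,DBC2-,CDH1-"`` (panel order, gains first)."""
        gains = [g for g, s in zip(gene_names, self.states) if s == "gain"]
        losses = [g for g, s in zip(gene_names, self.states) if s == "loss"]
        parts = [f"{g}+" for g in gains] + [f"{g}-" for g in losses]
        return ",".join(parts) if parts else "neutral"


@dataclass(frozen=True)
class CnaCall:
    """Sample-level CNA call for one gene probe.

    ``call`` is ``none``, ``gain_minor``, ``gain_major``, ``loss_minor``
    or ``loss_major``; the fractions are the proportion of nuclei with a
    gain (resp. loss) of the gene relative to their own ploidy.
    """

    call: str
    gain_fraction: float
    loss_fraction: float

    @property
    def fraction(self) -> float:
        """Fraction of nuclei carrying the called direction (0 if none)."""
        if self.call.startswith("gain"):
            return self.gain_fraction
        if self.call.startswith("loss"):
            return self.loss_fraction
        return 0.0


@dataclass
class SampleSummary:
    n_nuclei: int
    n_patterns: int
    instability_index: float
    average_ploidy: float
    ploidy_class: Literal["diploid", "aneuploid"]
    modal_ploidy: int
    cna_calls: dict[str, CnaCall]
    amplified_genes: set[str]
    major_clone: tuple[int, ...] = ()
    major_clone_fraction: float = 0.0
    warnings: list[str] = field(default_factory=list)


def annotate_ploidy(
    counts: Sequence[int],
    panel: ProbePanel,
    include_centromeres_in_mean: bool = True,
) -> PloidyAnnotation:
    """Assign an integer ploidy to one nucleus.

    The candidate ploidy is the median of the centromere counts (or of
    the gene counts when the panel has no centromere probes).  Gene
    probes counting more than twice the candidate are treated as
    amplified and excluded.  The final ploidy is the round-half-up mean
    of the centromere counts pooled with the retained gene counts.
    """
    counts = list(counts)
    if len(counts) != len(panel):
        raise ValueError(
            f"counts length {len(counts)} does not match panel size {len(panel)}"
        )
    cent_idx = panel.centromere_indices
    gene_idx = panel.gene_indices
    cent_counts = [counts[i] for i in cent_idx]
    gene_counts = [counts[i] for i in gene_idx]

    anchor = cent_counts if cent_counts else gene_counts
    candidate = float(np.median(anchor))
    retained = [
        (panel.probes[i].name, counts[i])
        for i in gene_idx
        if counts[i] <= 2 * candidate
    ]
    excluded = tuple(
        panel.probes[i].name for i in gene_idx if counts[i] > 2 * candidate
    )

    pool = [c for _, c in retained]
    if include_centromeres_in_mean:
        pool = cent_counts + pool
    note = ""
    if not pool:
        # every usable probe excluded: fall back to the centromere anchor
        if cent_counts:
            pool = cent_counts
            note = "all gene probes amplified; centromere median used"
        else:
            raise ValueError("no usable probes for ploidy annotation")
    ploidy = round_half_up_ratio(sum(pool), len(pool))
    if ploidy < 1:
        ploidy = 1
        note = (note + "; " if note else "") + "ploidy floored at 1"
    if excluded and not note:
        note = f"excluded amplified probes: {', '.join(excluded)}"
    return PloidyAnnotation(ploidy, excluded, note)


def gain_loss_pattern(
    counts: Sequence[int], ploidy: int, panel: ProbePanel
) -> GainLossPattern:
    """Score each gene probe against the nucleus ploidy."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    states: list[GainLossState] = []
    for i in panel.gene_indices:
        c = counts[i]
        states.append("gain" if c > ploidy else "loss" if c < ploidy else "neutral")
    return GainLossPattern(tuple(states))


def _call_cna(
    gain_fraction: float,
    loss_fraction: float,
    minor: float = CNA_MINOR_FRACTION,
    major: float = CNA_MAJOR_FRACTION,
) -> str:
    """One call per gene; when both directions reach the 15% floor the
    more frequent one wins (ties go to the gain)."""
    gain_ok = gain_fraction >= minor
    loss_ok = loss_fraction >= minor
    if not gain_ok and not loss_ok:
        return "none"
    if gain_ok and (not loss_ok or gain_fraction >= loss_fraction):
        return "gain_major" if gain_fraction >= major else "gain_minor"
    return "loss_major" if loss_fraction >= major else "loss_minor"


def amplification_flags(
    records: list[NucleusRecord],
    panel: ProbePanel,
    sample_ploidy: int,
    multiplier: float = AMPLIFICATION_MULTIPLIER,
) -> set[str]:
    """Genes whose mean signal count strictly exceeds ``multiplier`` times
    the assigned sample ploidy."""
    if sample_ploidy < 1:
        raise ValueError("sample_ploidy must be >= 1")
    mat = np.array([r.counts for r in records], dtype=float)
    flagged = set()
    for i in panel.gene_indices:
        if mat[:, i].mean() > multiplier * sample_ploidy:
            flagged.add(panel.probes[i].name)
    return flagged


def sample_summary(
    records: list[NucleusRecord],
    panel: ProbePanel,
    *,
    aneuploid_cutoff: float = ANEUPLOID_CUTOFF,
    cna_minor: float = CNA_MINOR_FRACTION,
    cna_major: float = CNA_MAJOR_FRACTION,
    pattern_universe: Literal["all", "genes"] = "all",
    include_centromeres_in_mean: bool = True,
    min_nuclei: int = 250,
) -> SampleSummary:
    """Full per-sample summary of a nucleus table.

    ``pattern_universe`` selects whether the instability index counts
    distinct patterns over the full probe vector (default) or over the
    gene probes only.
    """
    if not records:
        raise ValueError("sample_summary: empty input")
    n = len(records)
    report = validate_sample(records, min_nuclei=min_nuclei)

    # distinct signal patterns and the major clone
    patterns = aggregate_patterns(records)
    if pattern_universe == "genes":
        idx = panel.gene_indices
        reduced: dict[tuple[int, ...], int] = {}
        for p in patterns:
            key = tuple(p.counts[i] for i in idx)
            reduced[key] = reduced.get(key, 0) + p.multiplicity
        n_patterns = len(reduced)
        major_vec, major_mult = min(
            reduced.items(), key=lambda kv: (-kv[1], kv[0])
        )
    else:
        n_patterns = len(patterns)
        major_vec, major_mult = patterns[0].counts, patterns[0].multiplicity

    instability = n_patterns * 100.0 / n

    # per-nucleus ploidy and gain/loss fractions
    annotations = [
        annotate_ploidy(r.counts, panel, include_centromeres_in_mean)
        for r in records
    ]
    ploidies = [a.nucleus_ploidy for a in annotations]
    average_ploidy = round_half_up_1dp(sum(ploidies), n)
    ploidy_class = "aneuploid" if average_ploidy >= aneuploid_cutoff else "diploid"
    values, counts_ = np.unique(ploidies, return_counts=True)
    modal_ploidy = int(values[np.argmax(counts_)])

    gene_idx = panel.gene_indices
    gains = np.zeros(len(gene_idx), dtype=np.int64)
    losses = np.zeros(len(gene_idx), dtype=np.int64)
    for r, a in zip(records, annotations):
        for j, i in enumerate(gene_idx):
            if r.counts[i] > a.nucleus_ploidy:
                gains[j] += 1
            elif r.counts[i] < a.nucleus_ploidy:
                losses[j] += 1

    cna_calls = {}
    for j, i in enumerate(gene_idx):
        gf, lf = gains[j] / n, losses[j] / n
        cna_calls[panel.probes[i].name] = CnaCall(
            _call_cna(gf, lf, cna_minor, cna_major), gf, lf
        )

    amplified = amplification_flags(records, panel, modal_ploidy)

    return SampleSummary(
        n_nuclei=n,
        n_patterns=n_patterns,
        instability_index=instability,
        average_ploidy=average_ploidy,
        ploidy_class=ploidy_class,
        modal_ploidy=modal_ploidy,
        cna_calls=cna_calls,
        amplified_genes=amplified,
        major_clone=tuple(major_vec),
        major_clone_fraction=major_mult / n,
        warnings=list(report.messages),
    )
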