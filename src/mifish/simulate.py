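"""Synthetic data generators emulating the statistical structure of
single-cell miFISH experiments.

``simulate_sample`` emits a per-nucleus signal table with a known
clonal composition: a clone tree grown from a founder state by
single-probe copy-number events, clone frequencies drawn from a
Dirichlet with a forced dominant clone, per-probe miscount noise, and
centromere reference probes tracking the founder ploidy.  Three founder
scenarios cover the ploidy spectrum: ``diploid`` (all probes at 2),
``wgd_tetraploid`` (whole-genome doubled founder, all probes at 4) and
``hypodiploid`` (a founder that has lost one copy of several loci,
including both centromeres).

``simulate_variant_table`` and ``simulate_histogram`` produce variant
records with pre-known filter verdicts and DNA-content histograms with
a known ploidy class, for end-to-end testing of the filter cascade and
the cytometry classifier.

All generators are deterministic given the seed (numpy Generator,
PCG64 stream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cytometry import DNAHistogram
from .io import NucleusRecord
from .panel import DEFAULT_PANEL, ProbePanel
from .variants import ALL_CRITERIA, VariantRecord

FOUNDERS = ("diploid", "wgd_tetraploid", "hypodiploid")
MAJOR_CLONE_FLOOR = 0.3


@dataclass
class SimulationConfig:
    """Parameters of one synthetic miFISH sample.

    Defaults mirror a typical enumerated sample: 250 nuclei, a dominant
    clone with a few minor subclones, and a 2% per-probe miscount rate
    (symmetric +/-1 enumeration error).
    """

    seed: int = 0
    n_nuclei: int = 250
    founder: str = "diploid"
    n_clones: int = 3
    clone_frequencies: tuple[float, ...] | None = None
    events_per_clone: int = 2
    miscount_rate: float = 0.02
    centromere_tracks_ploidy: bool = True

    def __post_init__(self):
        if self.founder not in FOUNDERS:
            raise ValueError(f"founder must be one of {FOUNDERS}")
        if self.n_nuclei < 1 or self.n_clones < 1:
            raise ValueError("n_nuclei and n_clones must be positive")
        if not 0 <= self.miscount_rate <= 0.2:
            raise ValueError("miscount_rate must lie in [0, 0.2]")
        if self.clone_frequencies is not None:
            freqs = np.asarray(self.clone_frequencies, dtype=float)
            if len(freqs) != self.n_clones:
                raise ValueError("clone_frequencies length must equal n_clones")
            if np.any(freqs <= 0) or abs(freqs.sum() - 1.0) > 1e-9:
                raise ValueError("clone_frequencies must be a positive simplex")


@dataclass
class GroundTruth:
    """What the generator actually planted in a simulated sample."""

    founder_ploidy: int
    ploidy_class: str  # diploid | aneuploid, per the 2.2 cutoff
    clone_patterns: list[tuple[int, ...]]  # full panel vectors, noise-free
    clone_frequencies: list[float]
    clone_parents: list[int | None]  # clone tree (index of parent clone)
    assignments: list[int]  # clone index per nucleus
    cna_truth: dict[str, tuple[float, float]] = field(default_factory=dict)
    # gene -> (gain fraction, loss fraction) over the clone mixture

    @property
    def major_clone(self) -> int:
        return int(np.argmax(self.clone_frequencies))


def _founder_state(config: SimulationConfig, panel: ProbePanel, rng):
    """(gene counts, ploidy) of the founder clone."""
    n_genes = len(panel.gene_indices)
    if config.founder == "diploid":
        return [2] * n_genes, 2
    if config.founder == "wgd_tetraploid":
        return [4] * n_genes, 4
    # hypodiploid: both centromeres and over half of the gene loci at
    # one copy; the remaining loci stay disomic
    genes = [1 if rng.random() < 0.6 else 2 for _ in range(n_genes)]
    if 1 not in genes:
        genes[int(rng.integers(n_genes))] = 1
    return genes, 1


def _draw_frequencies(n_clones: int, rng) -> np.ndarray:
    """Symmetric Dirichlet(1) with a forced dominant clone >= 0.3."""
    for _ in range(200):
        freqs = rng.dirichlet(np.ones(n_clones))
        if freqs.max() >= MAJOR_CLONE_FLOOR:
            return freqs
    freqs = rng.dirichlet(np.ones(n_clones))
    freqs *= (1 - MAJOR_CLONE_FLOOR)
    freqs[int(np.argmax(freqs))] += MAJOR_CLONE_FLOOR
    return freqs / freqs.sum()


def simulate_sample(
    config: SimulationConfig, panel: ProbePanel = DEFAULT_PANEL
) -> tuple[list[NucleusRecord], GroundTruth]:
    """Generate one synthetic sample and its ground truth.

    The clone tree is grown from the founder by ``events_per_clone``
    single-probe +/-1 events per new clone (fully lost loci stay lost);
    clone frequencies are sorted descending onto the tree order, so the
    founder clone is the dominant one.  Nuclei draw their clone i.i.d.
    from the clone frequencies; each probe then miscounts by +/-1 with
    probability ``miscount_rate`` (floored at zero).
    """
    rng = np.random.default_rng(config.seed)
    gene_idx = panel.gene_indices
    cent_idx = panel.centromere_indices

    founder_genes, founder_ploidy = _founder_state(config, panel, rng)

    # grow the clone tree
    clone_genes = [list(founder_genes)]
    parents: list[int | None] = [None]
    for _ in range(config.n_clones - 1):
        for _attempt in range(100):
            parent = int(rng.integers(len(clone_genes)))
            pattern = list(clone_genes[parent])
            for _e in range(config.events_per_clone):
                g = int(rng.integers(len(pattern)))
                step = 1 if rng.random() < 0.5 else -1
                if pattern[g] == 0:  # absorbing zero: cannot regain
                    continue
                pattern[g] = max(0, pattern[g] + step)
            if pattern not in clone_genes:
                clone_genes.append(pattern)
                parents.append(parent)
                break
        else:
            raise RuntimeError("could not grow a distinct clone")

    if config.clone_frequencies is not None:
        freqs = np.asarray(config.clone_frequencies, dtype=float)
    else:
        freqs = np.sort(_draw_frequencies(config.n_clones, rng))[::-1]

    # assemble full panel vectors (centromeres track the founder ploidy)
    cent_count = founder_ploidy if config.centromere_tracks_ploidy else 2
    clone_patterns = []
    for genes in clone_genes:
        vec = [0] * len(panel)
        for j, i in enumerate(gene_idx):
            vec[i] = genes[j]
        for i in cent_idx:
            vec[i] = cent_count
        clone_patterns.append(tuple(vec))

    assignments = rng.choice(config.n_clones, size=config.n_nuclei, p=freqs)
    records = []
    for k, clone in enumerate(assignments):
        counts = list(clone_patterns[clone])
        for i in range(len(counts)):
            if rng.random() < config.miscount_rate:
                counts[i] = max(0, counts[i] + (1 if rng.random() < 0.5 else -1))
        records.append(NucleusRecord(str(k + 1), tuple(counts)))

    cna_truth = {}
    for j, i in enumerate(gene_idx):
        gain = sum(
            f for genes, f in zip(clone_genes, freqs) if genes[j] > founder_ploidy
        )
        loss = sum(
            f for genes, f in zip(clone_genes, freqs) if genes[j] < founder_ploidy
        )
        cna_truth[panel.probes[i].name] = (float(gain), float(loss))

    truth = GroundTruth(
        founder_ploidy=founder_ploidy,
        ploidy_class="aneuploid" if founder_ploidy >= 2.2 else "diploid",
        clone_patterns=clone_patterns,
        clone_frequencies=[float(f) for f in freqs],
        clone_parents=parents,
        assignments=[int(a) for a in assignments],
        cna_truth=cna_truth,
    )
    return records, truth


# ---------------------------------------------------------------------------
# variant-table generator
# ---------------------------------------------------------------------------

_CLEAN = dict(
    caller_pass=True,
    alt_fraction=0.35,
    total_depth=100,
    alt_depth=35,
    qual=100.0,
    mapq=60.0,
    dbnsfp_impact="high",
    is_common_snp=False,
    af_exac=0.0,
    af_esp_global=0.0,
    maf_ea=0.0,
    cosmic_case_count=150,
)

# per-criterion overrides that make an otherwise clean record fail
# exactly that criterion
_VIOLATIONS = {
    1: dict(caller_pass=False),
    2: dict(alt_fraction=0.04, alt_depth=4),
    3: dict(total_depth=5, alt_depth=2, alt_fraction=0.4),
    4: dict(qual=20.0),
    5: dict(dbnsfp_impact="low"),
    6: dict(is_common_snp=True),
    7: dict(af_exac=0.01),
    8: dict(mapq=35.0),  # COSMIC-recurrent branch, below the 40 tier
    9: dict(mapq=50.0, cosmic_case_count=3),  # other-gene branch, below 55
    10: dict(cosmic_case_count=50),  # emitted in multi-sample groups
    11: dict(cosmic_case_count=0, dbnsfp_impact="moderate"),
}


def simulate_variant_table(
    n_records: int, pass_fraction: float, seed: int
) -> tuple[list[VariantRecord], list[tuple[bool, tuple[int, ...]]]]:
    """Variant records engineered so a known subset passes the filters.

    Exactly ``round(n_records * pass_fraction)`` records pass; the
    remainder each violate a single criterion, cycling through all
    eleven, so every rule is exercised once the table is large enough.
    Criterion-10 violators are emitted as groups sharing one variant
    key across different samples.  Returns (records, expected) with
    ``expected[i] = (passes, failed_criteria)``.
    """
    if not 0 <= pass_fraction <= 1:
        raise ValueError("pass_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pass = int(round(n_records * pass_fraction))
    genes_pool = ["TP53", "PIK3CA", "GATA3", "BRCA2", "ESR1", "AKT1"]

    specs: list[tuple[int | None, int]] = []  # (criterion or None, position)
    for i in range(n_records):
        crit = None if i < n_pass else ALL_CRITERIA[(i - n_pass) % 11]
        specs.append((crit, 10_000 + i))
    order = rng.permutation(n_records)

    # criterion-10 records must share a variant key with another record;
    # pair them up, odd one joins the first pair (or a clean-criterion
    # record whose high COSMIC count is immune to the rule)
    c10 = [i for i, (c, _) in enumerate(specs) if c == 10]
    shared_pos: dict[int, int] = {}
    for a, b in zip(c10[0::2], c10[1::2]):
        shared_pos[b] = specs[a][1]
    if len(c10) % 2 == 1:
        lone = c10[-1]
        if len(c10) > 1:
            shared_pos[lone] = specs[c10[0]][1]
        else:
            partners = [
                i for i, (c, _) in enumerate(specs) if c in (1, 2, 3, 4, 5, 6, 7)
            ]
            if partners:
                shared_pos[partners[0]] = specs[lone][1]

    records, expected = [], []
    for i in range(n_records):
        crit, pos = specs[i]
        pos = shared_pos.get(i, pos)
        overrides = dict(_VIOLATIONS[crit]) if crit is not None else {}
        gene = genes_pool[int(rng.integers(len(genes_pool)))]
        if crit == 9:
            gene = "BRCA2"  # must not sit on a hotspot gene
        if crit == 8:
            gene = "TP53"
        fieldsvals = {**_CLEAN, **overrides}
        records.append(
            VariantRecord(
                sample_id=f"S{int(order[i]) % 20 + 1:02d}_{i}",
                gene=gene,
                chrom="chr17",
                pos=pos,
                ref="C",
                alt="T",
                **fieldsvals,
            )
        )
        expected.append((crit is None, (crit,) if crit is not None else ()))
    return records, expected


# ---------------------------------------------------------------------------
# DNA-histogram generator
# ---------------------------------------------------------------------------

def simulate_histogram(
    ploidy_class: str,
    n_cells: int = 5000,
    seed: int = 0,
    aneuploid_stem: float | None = None,
    bin_width: float = 0.05,
) -> DNAHistogram:
    """Synthetic Feulgen DNA histogram with a known ploidy class.

    Diploid: a dominant 2c stem line, a small 4c (G2/M) population and
    a uniform debris floor kept below 5c.  Aneuploid: an additional
    stem line outside the 2c/4c windows (drawn in [2.6, 3.6] c unless
    given) plus a heavy tail above 5c.
    """
    if ploidy_class not in ("diploid", "aneuploid"):
        raise ValueError("ploidy_class must be 'diploid' or 'aneuploid'")
    if n_cells < 100:
        raise ValueError("n_cells must be >= 100")
    rng = np.random.default_rng(seed)
    if ploidy_class == "diploid":
        weights = [0.82, 0.10, 0.08]
        draws = [
            rng.normal(2.0, 0.12, size=n_cells),
            rng.normal(4.0, 0.15, size=n_cells),
            rng.uniform(0.5, 4.5, size=n_cells),
        ]
    else:
        stem = (
            float(aneuploid_stem)
            if aneuploid_stem is not None
            else float(rng.uniform(2.6, 3.6))
        )
        weights = [0.25, 0.45, 0.14, 0.08, 0.08]
        draws = [
            rng.normal(2.0, 0.12, size=n_cells),  # stromal diploid cells
            rng.normal(stem, 0.15, size=n_cells),
            rng.normal(2 * stem, 0.25, size=n_cells),  # G2/M of the stem
            rng.uniform(5.1, 8.0, size=n_cells),  # exceeding events
            rng.uniform(0.5, 4.5, size=n_cells),
        ]
    component = rng.choice(len(weights), size=n_cells, p=weights)
    values = np.choose(component, draws)
    values = np.clip(values, 0.05, None)
    edges = np.arange(0.0, values.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    keep = counts > 0
    return DNAHistogram(
        tuple(float(c) for c in centers[keep]),
        tuple(int(c) for c in counts[keep]),
    )
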