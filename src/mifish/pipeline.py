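"""End-to-end orchestration: signal tables in, summary artifacts out.

``run_pipeline`` runs every analysis stage on one or more samples and
writes TSV/DOT/GraphML artifacts into a run directory, together with
the resolved configuration (for provenance) and a log.  Any stage
failure aborts the run with the failing stage named.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clonal import sample_summary
from .clone_graph import build_clone_graph
from .exclusivity import pairwise_permutation_test, results_to_frame
from .io import read_signal_table, validate_sample
from .panel import DEFAULT_PANEL, ProbePanel
from .phylogeny import build_tree_from_records

logger = logging.getLogger("mifish")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Thresholds default to the values the analysis was calibrated with:
    CNA calls at >= 15% of nuclei (major at >= 85%), aneuploidy at an
    average ploidy of 2.2, amplification above twice the sample ploidy.
    """

    signals: dict[str, str] = field(default_factory=dict)  # sample -> TSV path
    panel_path: str | None = None
    events_path: str | None = None  # optional samples x events 0/1 TSV
    out_dir: str = "mifish_run"
    cna_minor: float = 0.15
    cna_major: float = 0.85
    aneuploid_cutoff: float = 2.2
    amplification_multiplier: float = 2.0
    allow_wgd: bool = True
    absorbing_zero: bool = True
    centromeres_in_ploidy: bool = True
    pattern_universe: str = "all"
    n_perm: int = 10_000
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)


def _load_panel(config: RunConfig) -> ProbePanel:
    if config.panel_path:
        return ProbePanel.read(config.panel_path)
    return DEFAULT_PANEL


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage for every sample; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config_text = yaml.safe_dump(asdict(config), sort_keys=True)
        (out / "run_config.yaml").write_text(config_text)
        digest = hashlib.sha256(config_text.encode()).hexdigest()[:12]
        logger.info("mifish %s, config hash %s", __version__, digest)

        try:
            panel = _load_panel(config)
        except Exception as exc:
            raise PipelineError("panel", str(exc)) from exc

        summary_rows, cna_rows = [], []
        for sample, path in sorted(config.signals.items()):
            try:
                records = read_signal_table(path, panel)
            except Exception as exc:
                raise PipelineError("io", f"sample {sample}: {exc}") from exc
            report = validate_sample(records)
            for msg in report.messages:
                logger.warning("sample %s: %s", sample, msg)
            try:
                summ = sample_summary(
                    records,
                    panel,
                    aneuploid_cutoff=config.aneuploid_cutoff,
                    cna_minor=config.cna_minor,
                    cna_major=config.cna_major,
                    pattern_universe=config.pattern_universe,
                    include_centromeres_in_mean=config.centromeres_in_ploidy,
                )
            except Exception as exc:
                raise PipelineError("clonal", f"sample {sample}: {exc}") from exc
            summary_rows.append(
                {
                    "sample": sample,
                    "n_nuclei": summ.n_nuclei,
                    "n_patterns": summ.n_patterns,
                    "instability_index": round(summ.instability_index, 4),
                    "average_ploidy": summ.average_ploidy,
                    "ploidy_class": summ.ploidy_class,
                    "modal_ploidy": summ.modal_ploidy,
                    "major_clone": "-".join(map(str, summ.major_clone)),
                    "major_clone_fraction": round(summ.major_clone_fraction, 4),
                    "amplified_genes": ",".join(sorted(summ.amplified_genes)),
                    "warnings": "; ".join(summ.warnings),
                }
            )
            for gene, call in summ.cna_calls.items():
                cna_rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "call": call.call,
                        "gain_fraction": round(call.gain_fraction, 4),
                        "loss_fraction": round(call.loss_fraction, 4),
                    }
                )
            try:
                graph = build_clone_graph(
                    records, panel, config.centromeres_in_ploidy
                )
                graph.write_dot(out / f"{sample}.clones.dot")
                graph.write_graphml(out / f"{sample}.clones.graphml")
            except Exception as exc:
                raise PipelineError("clone_graph", f"sample {sample}: {exc}") from exc
            try:
                tree = build_tree_from_records(
                    records, panel, config.allow_wgd, config.absorbing_zero
                )
                tree.write_dot(out / f"{sample}.tree.dot")
                tree.write_graphml(out / f"{sample}.tree.graphml")
                summary_rows[-1]["tree_depth"] = tree.tree_depth
                summary_rows[-1]["tree_total_events"] = tree.total_events
            except Exception as exc:
                raise PipelineError("phylogeny", f"sample {sample}: {exc}") from exc

        if summary_rows:
            pd.DataFrame(summary_rows).to_csv(
                out / "sample_summary.tsv", sep="\t", index=False
            )
            pd.DataFrame(cna_rows).to_csv(
                out / "cna_calls.tsv", sep="\t", index=False
            )

        if config.events_path:
            try:
                events = pd.read_csv(config.events_path, sep="\t", index_col=0)
                results, excluded = pairwise_permutation_test(
                    events, n_perm=config.n_perm, seed=config.seed
                )
                results_to_frame(results).to_csv(
                    out / "pair_tests.tsv", sep="\t", index=False
                )
                for e in excluded:
                    logger.warning("event %s excluded (constant column)", e)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("exclusivity", str(exc)) from exc

        logger.info("run complete: %d sample(s)", len(summary_rows))
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
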