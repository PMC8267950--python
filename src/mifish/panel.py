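"""Probe panel definitions for multiplex interphase FISH (miFISH).

A panel is an ordered set of locus-specific probes.  Gene probes target
breast-cancer-associated loci; centromere probes serve as ploidy
references.  The default panel is the ten-probe breast panel: eight gene
probes plus centromere probes for chromosomes 4 and 10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

VALID_ROLES = ("gene", "centromere")
VALID_GENE_CLASSES = ("oncogene", "tumor_suppressor", "none")


@dataclass(frozen=True)
class Probe:
    """A single FISH probe.

    Parameters
    ----------
    name : str
        Probe name (gene symbol or centromere id), unique within a panel.
    locus : str
        Cytoband of the target locus, e.g. ``"8q24.21"``.
    role : str
        ``"gene"`` for locus-specific gene probes, ``"centromere"`` for
        ploidy-reference centromere probes.
    gene_class : str
        ``"oncogene"``, ``"tumor_suppressor"`` or ``"none"`` (always
        ``"none"`` for centromere probes).
    """

    name: str
    locus: str
    role: str = "gene"
    gene_class: str = "none"

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"probe {self.name!r}: invalid role {self.role!r}")
        if self.gene_class not in VALID_GENE_CLASSES:
            raise ValueError(
                f"probe {self.name!r}: invalid gene_class {self.gene_class!r}"
            )
        if self.role == "centromere" and self.gene_class != "none":
            raise ValueError(
                f"centromere probe {self.name!r} cannot carry a gene_class"
            )


class ProbePanel:
    """Ordered probe set with gene/centromere roles.

    The probe order defines the column order of signal tables and the
    coordinate order of copy-number vectors throughout the package.
    """

    def __init__(self, probes: Iterable[Probe]):
        self.probes: tuple[Probe, ...] = tuple(probes)
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            raise ValueError("probe names must be unique")
        if not any(p.role == "gene" for p in self.probes):
            raise ValueError("panel must contain at least one gene probe")

    # -- basic container behaviour ------------------------------------
    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbePanel) and self.probes == other.probes

    def __repr__(self) -> str:
        return f"ProbePanel({[p.name for p in self.probes]})"

    # -- derived views -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [p.name for p in self.probes]

    @property
    def gene_probes(self) -> list[Probe]:
        return [p for p in self.probes if p.role == "gene"]

    @property
    def gene_names(self) -> list[str]:
        return [p.name for p in self.gene_probes]

    @property
    def gene_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.probes) if p.role == "gene"]

    @property
    def centromere_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.probes) if p.role == "centromere"]

    def index_of(self, name: str) -> int:
        for i, p in enumerate(self.probes):
            if p.name == name:
                return i
        raise KeyError(name)

    # -- serialisation ---------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {
                "name": p.name,
                "locus": p.locus,
                "role": p.role,
                "gene_class": p.gene_class,
            }
            for p in self.probes
        ]

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "ProbePanel":
        return cls(
            Probe(
                name=str(r["name"]),
                locus=str(r.get("locus", "")),
                role=str(r.get("role", "gene")),
                gene_class=str(r.get("gene_class", "none")),
            )
            for r in records
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        records = self.to_records()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(records, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(records, sort_keys=False))

    @classmethod
    def read(cls, path: str | Path) -> "ProbePanel":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            records = json.loads(text)
        else:
            records = yaml.safe_load(text)
        if not isinstance(records, list):
            raise ValueError(f"panel file {path} must contain a list of probes")
        return cls.from_records(records)


def default_panel() -> ProbePanel:
    """The ten-probe breast miFISH panel.

    Eight gene probes (five oncogenes, three tumor suppressors) plus the
    centromere probes CCP4 and CCP10 used as ploidy references.
    """
    return ProbePanel(
        [
            Probe("COX2", "1q31.1", "gene", "oncogene"),
            Probe("DBC2", "8p21.3", "gene", "tumor_suppressor"),
            Probe("MYC", "8q24.21", "gene", "oncogene"),
            Probe("CCND1", "11q13.3", "gene", "oncogene"),
            Probe("CDH1", "16q22.1", "gene", "tumor_suppressor"),
            Probe("TP53", "17p13.1", "gene", "tumor_suppressor"),
            Probe("HER2", "17q12", "gene", "oncogene"),
            Probe("ZNF217", "20q13.2", "gene", "oncogene"),
            Probe("CCP4", "4p11.1-q11.1", "centromere"),
            Probe("CCP10", "10p11.1-q11.1", "centromere"),
        ]
    )


DEFAULT_PANEL = default_panel()
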