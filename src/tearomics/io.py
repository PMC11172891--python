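"""Tabular I/O, YAML configuration, and run-report provenance.

All tabular files are UTF-8 TSV with "." decimals.  Protein tables are wide
(protein_id, peptide_count, contaminant, one intensity column per sample;
empty cell = missing); abundance tables are profiler-style (lineage rows,
sample columns, percent scale); metadata is one row per sample.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import DEResultTable, ProteinGroupTable, SampleAnnotation, TaxonAbundanceTable
from .microbiome import GroupComparisonResult, RANK_PREFIXES
from .proteome import FilterConfig, ImputationConfig, SignificanceCurveConfig
from .simulate import MicrobiomeSimConfig, ProteomeSimConfig

__all__ = [
    "RunConfig",
    "read_protein_table",
    "write_protein_table",
    "read_annotation",
    "write_annotation",
    "read_abundance_table",
    "write_abundance_table",
    "write_de_results",
    "write_comparison_result",
    "write_report",
]

_RESERVED_COLUMNS = ("protein_id", "peptide_count", "contaminant")


@dataclass
class RunConfig:
    """All stage configurations plus global run settings.

    Defaults are the pipeline's reference analysis conditions: peptide
    filter 2, identification filters 8/9/8, downshift imputation 2.5/0.3
    over 20 cycles, significance curve p_max 0.05 at |log2FC| asymptote 1
    with curve factor 0.1, 1% rare-taxon lumping, 1000 permutations.
    """

    filter: FilterConfig = field(default_factory=FilterConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    curve: SignificanceCurveConfig = field(default_factory=SignificanceCurveConfig)
    proteome_sim: ProteomeSimConfig = field(default_factory=ProteomeSimConfig)
    microbiome_sim: MicrobiomeSimConfig = field(default_factory=MicrobiomeSimConfig)
    lump_threshold_percent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        version = raw.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema_version {version}")
        cfg = cls(schema_version=version)
        sections = {
            "filter": FilterConfig,
            "imputation": ImputationConfig,
            "curve": SignificanceCurveConfig,
            "proteome_sim": ProteomeSimConfig,
            "microbiome_sim": MicrobiomeSimConfig,
        }
        for name, klass in sections.items():
            if name in raw:
                params = raw.pop(name) or {}
                base = asdict(getattr(cfg, name))
                unknown = set(params) - set(base)
                if unknown:
                    raise ValueError(f"unknown keys in {name!r}: {sorted(unknown)}")
                base.update(params)
                # tuples round-trip through YAML as lists
                for k, v in base.items():
                    if isinstance(v, list):
                        base[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                setattr(cfg, name, klass(**base))
        for key in ("lump_threshold_percent", "n_permutations", "seed"):
            if key in raw:
                setattr(cfg, key, raw.pop(key))
        if raw:
            raise ValueError(f"unknown top-level config keys: {sorted(raw)}")
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        Path(path).write_text(
            yaml.safe_dump(data, sort_keys=False, default_flow_style=None),
            encoding="utf-8",
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def read_protein_table(path, scale: str = "raw") -> ProteinGroupTable:
    """Read a wide protein-group TSV; empty intensity cells become missing."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for col in _RESERVED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"protein table missing required column {col!r}")
    if df["protein_id"].duplicated().any():
        dup = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise ValueError(f"duplicate protein id: {dup!r}")
    df = df.set_index("protein_id")
    sample_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    if not sample_cols:
        raise ValueError("protein table has no intensity columns")
    intens = df[sample_cols].apply(pd.to_numeric, errors="raise")
    intens.columns.name = "sample_id"
    return ProteinGroupTable(
        intensities=intens,
        peptide_counts=df["peptide_count"].astype(int),
        contaminant=df["contaminant"].astype(bool),
        scale=scale,
    )


def write_protein_table(table: ProteinGroupTable, path) -> None:
    out = pd.concat(
        [
            table.peptide_counts.rename("peptide_count"),
            table.contaminant.rename("contaminant"),
            table.intensities,
        ],
        axis=1,
    )
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    return SampleAnnotation(df)


def write_annotation(ann: SampleAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t")


def read_abundance_table(path, unit: str = "percent") -> TaxonAbundanceTable:
    """Read a merged profiler-style abundance TSV (lineage rows, sample cols).

    Rows whose first field is not a rank-prefixed lineage are skipped with a
    warning reporting the count.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    prefixes = tuple(RANK_PREFIXES.values())
    parseable = [any(part.startswith(prefixes) for part in str(lin).split("|"))
                 for lin in df.index]
    n_bad = len(df) - sum(parseable)
    if n_bad:
        warnings.warn(f"skipped {n_bad} rows with unparseable lineage strings")
    df = df.loc[parseable].apply(pd.to_numeric, errors="raise")
    return TaxonAbundanceTable(df, unit=unit)


def write_abundance_table(table: TaxonAbundanceTable, path) -> None:
    out = table.abundances.copy()
    out.index.name = "lineage"
    out.to_csv(path, sep="\t")


def _provenance(config: RunConfig | None, seed: int | None) -> dict:
    block = {"package_version": __version__}
    if config is not None:
        block["config_hash"] = config.config_hash()
    if seed is not None:
        block["seed"] = seed
    return block


def write_de_results(de: DEResultTable, out_dir, config: RunConfig | None = None,
                     seed: int | None = None, extra_report: dict | None = None) -> dict:
    """Write the DE table, per-cycle calls, and a provenance-bearing report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tbl = de.table.copy()
    tbl.index.name = "protein_id"
    tbl.to_csv(out_dir / "de_results.tsv", sep="\t")
    if de.cycle_calls is not None:
        cc = de.cycle_calls.copy()
        cc.index.name = "protein_id"
        cc.columns = [f"cycle_{c}" for c in cc.columns]
        cc.to_csv(out_dir / "cycle_calls.tsv", sep="\t")
    report = {
        "provenance": _provenance(config, seed),
        "d0_hat": de.d0_hat,
        "s0sq_hat": de.s0sq_hat,
        "n_significant": de.n_significant,
        "n_stable": de.n_stable,
        "params": de.params,
    }
    if extra_report:
        report.update(extra_report)
    write_report(report, out_dir / "report.json")
    return report


def write_comparison_result(res: GroupComparisonResult, path) -> None:
    payload = {
        "statistic_name": res.statistic_name,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "group_summaries": res.group_summaries,
        "metadata": res.metadata,
    }
    write_report(payload, path)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n",
                          encoding="utf-8")
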