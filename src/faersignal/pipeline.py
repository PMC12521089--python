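"""End-to-end orchestration: raw tables → clean cases → signal/TTO outputs.

The pipeline is deterministic for fixed inputs and records a manifest of row
counts at every stage (read → dedup → drug-selected → analyzed) together
with every configuration value, so each output row is traceable and repeat
runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from . import cleaning, onset, signals
from .io import LookupTables, RawReportTables, read_lookups
from .signals import CriteriaConfig

__all__ = ["PipelineConfig", "PipelineResult", "analyze_tables", "run_pipeline"]


class PipelineConfigError(ValueError):
    """The pipeline configuration is incomplete or inconsistent."""


@dataclasses.dataclass
class PipelineConfig:
    """File-based pipeline configuration (see ``analyze_tables`` for the core).

    ``tables_dir`` must contain DEMO.txt … INDI.txt in the ``$``-delimited
    dialect; the lookup paths are the user-supplied CSVs (PT→SOC map, IME
    list, drug-label list, synonym list).
    """

    tables_dir: str | Path
    pt_to_soc: str | Path
    synonyms: str | Path
    ime_list: str | Path | None = None
    label_list: str | Path | None = None
    out_dir: str | Path | None = None
    required_role: str | None = "PS"
    substring_match: bool = False
    counting: str = "pair"
    level: str = "both"
    top_k: int = 5
    yates: bool = False
    bin_edges: tuple[int, ...] = onset.DEFAULT_BIN_EDGES
    criteria: CriteriaConfig = dataclasses.field(default_factory=CriteriaConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        crit = CriteriaConfig(**raw.pop("criteria", {}))
        if "bin_edges" in raw:
            raw["bin_edges"] = tuple(raw["bin_edges"])
        return cls(criteria=crit, **raw)

    def validate(self) -> None:
        for field in ("tables_dir", "pt_to_soc", "synonyms"):
            value = getattr(self, field)
            if value is None:
                raise PipelineConfigError(f"config field {field!r} is required")
            if not Path(value).exists():
                raise PipelineConfigError(f"config field {field!r}: {value} does not exist")
        for field in ("ime_list", "label_list"):
            value = getattr(self, field)
            if value is not None and not Path(value).exists():
                raise PipelineConfigError(f"config field {field!r}: {value} does not exist")
        if self.level not in ("pt", "soc", "both"):
            raise PipelineConfigError("level must be 'pt', 'soc' or 'both'")


@dataclasses.dataclass
class PipelineResult:
    clean: cleaning.CleanCases
    signal_pt: pd.DataFrame
    signal_soc: pd.DataFrame
    signal_ime: pd.DataFrame
    onset: pd.DataFrame
    tto_summary: onset.OnsetSummary
    demographics: dict[str, pd.DataFrame]
    manifest: dict[str, object]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.clean.cases.to_csv(out / "clean_cases.csv", index=False)
        self.clean.events.to_csv(out / "clean_case_events.csv", index=False)
        self.signal_pt.to_csv(out / "signals_pt.csv", index=False)
        self.signal_soc.to_csv(out / "signals_soc.csv", index=False)
        self.signal_ime.to_csv(out / "signals_ime.csv", index=False)
        self.onset.to_csv(out / "onset_records.csv", index=False)
        self.tto_summary.to_frame().to_csv(out / "tto_bins.csv", index=False)
        for name, frame in self.demographics.items():
            frame.to_csv(out / f"demographics_{name}.csv", index=False)
        with open(out / "manifest.txt", "w") as fh:
            for key in sorted(self.manifest):
                fh.write(f"{key} = {self.manifest[key]}\n")


SIGNAL_COLUMNS = [
    "term", "soc", "n", "a", "b", "c", "d", "E",
    "ror", "ror_lo", "ror_hi", "prr", "chi2",
    "ebgm", "ebgm05", "ic", "ic025",
    "ror_sig", "prr_sig", "bcpnn_sig", "ebgm_sig", "consensus",
    "is_ime", "is_unlabeled",
]


def _order_columns(frame: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in SIGNAL_COLUMNS if c in frame.columns]
    return frame[cols + [c for c in frame.columns if c not in cols]]


def analyze_tables(
    tables: RawReportTables,
    lookups: LookupTables,
    *,
    required_role: str | None = "PS",
    substring_match: bool = False,
    counting: str = "pair",
    level: str = "both",
    criteria: CriteriaConfig | None = None,
    bin_edges: tuple[int, ...] = onset.DEFAULT_BIN_EDGES,
    top_k: int = 5,
    yates: bool = False,
) -> PipelineResult:
    """Run cleaning, disproportionality, TTO and demographics in memory."""
    criteria = criteria or CriteriaConfig()
    manifest: dict[str, object] = {
        "config.required_role": required_role,
        "config.substring_match": substring_match,
        "config.counting": counting,
        "config.level": level,
        "config.top_k": top_k,
        "config.yates": yates,
        "config.bin_edges": list(bin_edges),
    }
    for key, value in dataclasses.asdict(criteria).items():
        manifest[f"config.criteria.{key}"] = value
    manifest["rows.demo"] = len(tables.demo)
    manifest["cases.raw"] = tables.demo["caseid"].nunique()

    retained = cleaning.deduplicate(tables.demo)
    manifest["cases.after_dedup"] = len(retained)
    manifest["exclusions.duplicate_versions"] = len(tables.demo) - len(retained)

    selected = cleaning.select_drug_reports(
        tables.drug,
        lookups.synonyms,
        required_role=required_role,
        substring=substring_match,
    )
    manifest["reports.drug_selected"] = len(selected)
    target_ids = retained & selected
    manifest["cases.analyzed"] = len(target_ids)

    clean = cleaning.build_clean_cases(tables, lookups, retained, selected)
    manifest["exclusions.unmapped_event_rows"] = clean.cases.attrs.get(
        "n_unmapped_events", 0
    )

    # disproportionality universe: all retained reports, target flagged
    reac_kept = tables.reac[tables.reac["primaryid"].isin(retained)]
    all_events = cleaning.standardize_events(reac_kept, lookups)
    all_events = all_events.assign(is_target=all_events["primaryid"].isin(target_ids))
    manifest["pairs.universe_pt"] = len(all_events)

    empty_cols = [c for c in SIGNAL_COLUMNS]
    signal_pt = pd.DataFrame(columns=empty_cols)
    signal_soc = pd.DataFrame(columns=empty_cols)
    if level in ("pt", "both"):
        pt_events = all_events.rename(columns={"pt": "term"})
        signal_pt = _order_columns(
            signals.score_signals(
                pt_events, cfg=criteria, counting=counting, yates=yates
            )
        )
    if level in ("soc", "both"):
        soc_events = all_events.rename(columns={"soc": "term"})[
            ["primaryid", "term", "is_target"]
        ]
        signal_soc = _order_columns(
            signals.score_signals(
                soc_events, cfg=criteria, counting=counting, yates=yates
            )
        )
    if "is_ime" in signal_pt.columns and len(signal_pt):
        signal_ime = signal_pt[
            signal_pt["consensus"] & signal_pt["is_ime"].fillna(False)
        ].reset_index(drop=True)
    else:
        signal_ime = pd.DataFrame(columns=signal_pt.columns)
    manifest["signals.pt_terms"] = len(signal_pt)
    manifest["signals.pt_consensus"] = int(signal_pt["consensus"].sum()) if len(signal_pt) else 0
    manifest["signals.soc_terms"] = len(signal_soc)
    manifest["signals.ime_consensus"] = len(signal_ime)

    drug_in_target = tables.drug[tables.drug["primaryid"].isin(target_ids)]
    name_mask = cleaning.match_drug_names(
        drug_in_target, lookups.synonyms, substring=substring_match
    )
    target_drug_rows = drug_in_target[name_mask] if len(drug_in_target) else drug_in_target
    onset_records = onset.compute_tto(clean.cases, tables.ther, target_drug_rows)
    clean.cases = clean.cases.merge(
        onset_records[["caseid", "onset_days", "included", "exclusion_reason"]],
        on="caseid",
        how="left",
    )
    tto_summary = onset.summarize_tto(onset_records, bin_edges=bin_edges)
    reasons = onset_records["exclusion_reason"].value_counts()
    manifest["tto.included"] = int(tto_summary.n_included)
    manifest["tto.excluded_missing_date"] = int(reasons.get("missing_date", 0))
    manifest["tto.excluded_negative"] = int(reasons.get("negative", 0))

    demographics = onset.summarize_demographics(clean, top_k=top_k)
    return PipelineResult(
        clean=clean,
        signal_pt=signal_pt,
        signal_soc=signal_soc,
        signal_ime=signal_ime,
        onset=onset_records,
        tto_summary=tto_summary,
        demographics=demographics,
        manifest=manifest,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: read tables and lookups, analyze, write outputs."""
    config.validate()
    tables = RawReportTables.read(config.tables_dir)
    lookups = read_lookups(
        config.pt_to_soc,
        ime_list=config.ime_list,
        label_list=config.label_list,
        synonyms=config.synonyms,
    )
    result = analyze_tables(
        tables,
        lookups,
        required_role=config.required_role,
        substring_match=config.substring_match,
        counting=config.counting,
        level=config.level,
        criteria=config.criteria,
        bin_edges=config.bin_edges,
        top_k=config.top_k,
        yates=config.yates,
    )
    if config.out_dir is not None:
        result.write(config.out_dir)
    return result
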