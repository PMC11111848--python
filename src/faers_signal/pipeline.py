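"""End-to-end pipeline: ingest -> dedup -> case set -> signals -> TTO.

Runs from a flat key-value configuration document and writes the standard
output tables: a demographics table, SOC- and PT-level signal tables
(including rankings by report count and by signal strength), a
head-to-head comparator table, the time-to-onset summary and monthly
histogram, plus a run log whose counters satisfy the conservation
identities of the upstream stages.  Re-running with identical inputs
produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import ingest
from .disproportionality import DisproportionalityModel, comparator_odds_ratio, rank_signals
from .exceptions import ConfigurationError, FaersSignalError, InputError, SmallSampleError
from .tto import WeibullTTOModel, extract_tto_samples, tto_descriptives

__all__ = ["RunConfig", "run_pipeline", "write_table"]

logger = logging.getLogger("faers_signal.pipeline")

ROUND2 = ("ror", "ror_ci_low", "ror_ci_high", "ic", "ic025", "or", "or_ci_low", "or_ci_high")


@dataclass
class RunConfig:
    """Flat run configuration; every default is recorded in the run log."""

    input_dir: str
    output_dir: str
    target_names: list[str] = field(default_factory=lambda: ["LUMATEPERONE"])
    comparator_names: list[str] = field(default_factory=lambda: ["RISPERIDONE"])
    meddra_map: str = ""
    quarters: list[str] | None = None
    role: str = "PS"
    min_n: int = 3
    z: float = 1.96
    ic_variant: str = "noren"
    ic_sigma: float = 1.0
    stratify_by: str | None = "sex"
    comparator_terms: list[str] | None = None
    tto_min_n: int = 10
    tto_bin_days: int = 30
    top_k: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_names:
            raise ConfigurationError("target_names must be non-empty")
        if self.min_n < 1 or self.z <= 0 or self.tto_min_n < 1 or self.top_k < 1:
            raise ConfigurationError("thresholds must be positive")
        if self.quarters is not None and not self.quarters:
            raise ConfigurationError("quarter list must be non-empty when given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        with open(p, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{p}: expected a flat key-value document")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"{p}: unknown config keys {sorted(unknown)}")
        return cls(**data)


def write_table(rows, schema: Sequence[str], path: str | Path) -> Path:
    """Write rows as a UTF-8 CSV with the given column order.

    Disproportionality statistics (ror/ic and their bounds) are printed
    with 2 decimals; row order is preserved from the input, so callers
    sort deterministically first.
    """
    frame = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows.copy()
    if frame.empty:
        frame = pd.DataFrame({c: pd.Series(dtype=object) for c in schema})
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"rows lack schema columns {missing}")
    frame = frame[list(schema)]
    for col in frame.columns:
        if col in ROUND2:
            frame[col] = frame[col].map(
                lambda v: "" if pd.isna(v) else f"{float(v):.2f}"
            )
    out = Path(path)
    try:
        frame.to_csv(out, index=False, lineterminator="\n", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write {out}: {exc}") from exc
    return out


SIGNAL_SCHEMA = [
    "level", "term", "soc", "n", "ror", "ror_ci_low", "ror_ci_high",
    "ic", "ic025", "is_signal", "stratum", "variant",
]


def _signal_csv(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["stratum"] = out["stratum"].fillna("pooled") if len(out) else out.get("stratum")
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the output tables.

    Any stage error is re-raised with the stage name; partially written
    outputs are removed first.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def _write(rows, schema, name) -> Path:
        p = write_table(rows, schema, out_dir / name)
        written.append(p)
        return p

    log_lines: list[str] = ["run configuration:"]
    for k, v in asdict(config).items():
        log_lines.append(f"  {k} = {v!r}")

    try:
        stage = "ingest"
        raw = ingest.load_quarters(config.input_dir, config.quarters)
        n_reports = len(raw.demo)
        orphans = raw.orphan_counts()

        stage = "deduplicate"
        survivors = ingest.deduplicate(raw.demo)
        n_surv = len(survivors)

        stage = "select_cases"
        cases = ingest.select_cases(raw, config.target_names, config.role, survivors)

        stage = "map_events"
        if not config.meddra_map:
            raise ConfigurationError("meddra_map path is required")
        meddra = ingest.read_meddra_map(config.meddra_map)
        cases = ingest.map_events(cases, meddra)

        stage = "demographics"
        demo_summary = ingest.summarize_demographics(cases)
        _write(demo_summary.to_frame(), ["section", "category", "count", "pct"],
               "demographics.csv")

        stage = "disproportionality"
        pairs = ingest.event_pairs(raw, survivors)
        lut = {str(k).upper().strip(): v for k, v in meddra.items()}
        target_ids = set(cases.report_ids)

        sex = (
            raw.demo.drop_duplicates("PRIMARYID").set_index("PRIMARYID")["SEX"]
            .str.upper().str.strip().map({"M": "male", "F": "female"})
        )
        sex = sex[sex.index.isin(set(survivors))].dropna()

        pt_model = DisproportionalityModel(
            pairs, target_ids, level="PT", term_soc=lut,
            min_n=config.min_n, z=config.z, ic_variant=config.ic_variant,
            ic_sigma=config.ic_sigma,
            strata=sex if config.stratify_by == "sex" else None,
        )
        pt_res = pt_model.fit()
        target_terms = set(pairs[pairs["report_id"].isin(target_ids)]["pt"])
        pt_pooled = pt_res.pooled
        pt_target = pt_pooled[pt_pooled["term"].isin(target_terms)].reset_index(drop=True)
        _write(_signal_csv(pt_target), SIGNAL_SCHEMA, "pt_signals.csv")
        _write(_signal_csv(rank_signals(pt_target, "frequency", config.top_k)),
               SIGNAL_SCHEMA, "pt_signals_by_frequency.csv")
        _write(_signal_csv(rank_signals(pt_target, "strength", config.top_k)),
               SIGNAL_SCHEMA, "pt_signals_by_strength.csv")
        if config.stratify_by == "sex":
            strat = pt_res.table[pt_res.table["stratum"].notna()]
            strat = strat[strat["term"].isin(target_terms)]
            _write(_signal_csv(strat), SIGNAL_SCHEMA, "pt_signals_by_sex.csv")

        soc_pairs = pairs.assign(
            term=pairs["pt"].map(lambda t: lut.get(t, "UNMAPPED"))
        )[["report_id", "term"]].drop_duplicates()
        soc_pairs = soc_pairs.rename(columns={"term": "pt"})
        soc_res = DisproportionalityModel(
            soc_pairs, target_ids, level="SOC",
            min_n=config.min_n, z=config.z, ic_variant=config.ic_variant,
            ic_sigma=config.ic_sigma,
        ).fit()
        soc_target_terms = set(soc_pairs[soc_pairs["report_id"].isin(target_ids)]["pt"])
        soc_table = soc_res.pooled
        soc_table = soc_table[soc_table["term"].isin(soc_target_terms)]
        soc_table = soc_table.sort_values(
            ["n", "term"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        _write(_signal_csv(soc_table), SIGNAL_SCHEMA, "soc_signals.csv")

        stage = "comparator"
        comp_cases = ingest.select_cases(raw, config.comparator_names, config.role, survivors)
        if len(comp_cases) == 0:
            raise InputError(
                f"comparator drug {config.comparator_names} absent from the dataset"
            )
        terms = config.comparator_terms
        if terms is None:
            terms = sorted(pt_target.loc[pt_target["is_signal"], "term"])
        comp_rows = []
        for term in terms:
            res = comparator_odds_ratio(cases.events, comp_cases.events,
                                        term.upper().strip(), z=config.z)
            comp_rows.append(
                {
                    "term": term.upper().strip(),
                    "or": res.ror, "or_ci_low": res.ci_low, "or_ci_high": res.ci_high,
                    "n_target": res.n, "defined": res.defined,
                }
            )
        _write(comp_rows, ["term", "or", "or_ci_low", "or_ci_high", "n_target", "defined"],
               "comparator.csv")

        stage = "time_to_onset"
        samples, tto_counters = extract_tto_samples(cases)
        _write(samples, ["report_id", "onset_days"], "tto_samples.csv")
        tto_note = ""
        if len(samples) >= config.tto_min_n:
            results = WeibullTTOModel(samples, min_n=config.tto_min_n).fit(z=config.z)
            _write(results.to_frame(),
                   ["n", "median_days", "q1_days", "q3_days", "scale", "scale_ci_low",
                    "scale_ci_high", "shape", "shape_ci_low", "shape_ci_high",
                    "classification"],
                   "tto_summary.csv")
            desc = results.descriptives(bin_days=config.tto_bin_days)
            _write(desc.histogram, ["bin_start_day", "bin_end_day", "count"],
                   "tto_histogram.csv")
        else:
            tto_note = (
                f"time-to-onset skipped: {len(samples)} usable intervals "
                f"< tto_min_n={config.tto_min_n}"
            )

        stage = "run_log"
        log_lines += [
            "counters:",
            f"  reports_parsed = {n_reports}",
            f"  malformed_rows_skipped = {raw.skipped_rows}",
            f"  orphan_rows = {orphans}",
            f"  surviving_reports = {n_surv}",
            f"  duplicates_removed = {n_reports - n_surv}",
            f"  target_cases = {len(cases)}",
            f"  non_case_reports = {n_surv - len(cases)}",
            f"  unmapped_event_pts = {cases.unmapped_pts}",
            f"  comparator_cases = {len(comp_cases)}",
            f"  tto = {tto_counters}",
        ]
        if tto_note:
            log_lines.append(f"  note = {tto_note!r}")
        log_path = out_dir / "run_log.txt"
        log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        written.append(log_path)
    except FaersSignalError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise FaersSignalError(f"[stage: {stage}] {exc}") from exc

    return {p.stem: p for p in written}
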