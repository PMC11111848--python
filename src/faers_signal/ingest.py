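"""Parsing, deduplication and case extraction for FAERS quarterly extracts.

FAERS quarterly ASCII files are '$'-delimited with a header line; a case
(one patient at one point in time) may appear under several PRIMARYIDs as
follow-up versions sharing a CASEID.  The cleaning rule keeps, per
CASEID, the report with the most recent FDA_DT, breaking ties by the
higher PRIMARYID.  Cases for the analysis are the surviving reports that
list the target drug as primary suspect (ROLE_COD "PS" by default), with
drug names compared after uppercasing and trimming.

Counts of skipped malformed rows, orphan rows (rows in DRUG/REAC/... with
no DEMO record) and unmapped preferred terms are logged to standard error
and kept on the returned objects so pipeline conservation identities can
be checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = [
    "RawQuarter",
    "CaseSet",
    "DemographicsSummary",
    "parse_quarter",
    "load_quarters",
    "concat_quarters",
    "deduplicate",
    "event_pairs",
    "select_cases",
    "read_meddra_map",
    "map_events",
    "summarize_demographics",
]

logger = logging.getLogger("faers_signal.ingest")

TABLES = ("demo", "drug", "reac", "ther", "indi", "outc")

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "HO": "Hospitalization (initial or prolonged)",
    "DS": "Disability",
    "RI": "Required Intervention to Prevent Permanent Impairment/Damage",
    "OT": "Other Serious medical events",
}

REPORTER_LABELS = {
    "HP": "Health professional",
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "LW": "Lawyer",
    "": "Missing",
}


@dataclass
class RawQuarter:
    """Parsed FAERS tables for one or more quarters (string dtype)."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame
    skipped_rows: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def orphan_counts(self) -> dict[str, int]:
        """Rows in satellite tables whose PRIMARYID never appears in DEMO."""
        known = set(self.demo["PRIMARYID"])
        return {
            name: int((~self.table(name)["PRIMARYID"].isin(known)).sum())
            for name in TABLES
            if name != "demo"
        }


@dataclass
class CaseSet:
    """Deduplicated reports with the target drug as suspect.

    ``events`` has one row per (report_id, pt) pair (collapsed); after
    :func:`map_events` it carries a ``soc`` column.  ``ther`` is limited
    to therapy rows of the suspect drug.
    """

    report_ids: np.ndarray
    demo: pd.DataFrame  # indexed by report id
    events: pd.DataFrame  # columns: report_id, pt[, soc]
    ther: pd.DataFrame  # columns: report_id, start_dt
    indications: pd.DataFrame  # columns: report_id, indi_pt
    outcomes: pd.DataFrame  # columns: report_id, outc_cod
    unmapped_pts: int = 0

    def __len__(self) -> int:
        return len(self.report_ids)


def _read_dollar_table(path: Path) -> tuple[pd.DataFrame, int]:
    """Parse one '$'-delimited file; rows with the wrong field count are
    skipped and counted."""
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        header = fh.readline().rstrip("\n\r")
        if not header:
            raise InputError(f"{path}: empty file (no header)")
        cols = header.split("$")
        width = len(cols)
        rows, skipped = [], 0
        for line in fh:
            fields = line.rstrip("\n\r").split("$")
            if len(fields) != width:
                skipped += 1
                continue
            rows.append(fields)
    frame = pd.DataFrame(rows, columns=cols, dtype=str) if rows else pd.DataFrame(
        {c: pd.Series(dtype=str) for c in cols}
    )
    return frame, skipped


def parse_quarter(path: str | Path, quarter: str | None = None) -> RawQuarter:
    """Parse the six FAERS tables of one quarter from a directory.

    ``quarter`` is the label embedded in the file names (e.g. "22Q1");
    when omitted the directory must contain exactly one quarter.  A
    missing mandatory table raises an input error naming the file.
    """
    root = Path(path)
    if not root.is_dir():
        raise InputError(f"not a directory: {root}")
    if quarter is None:
        demos = sorted(root.glob("DEMO*.txt"))
        if len(demos) != 1:
            raise InputError(
                f"{root}: expected exactly one DEMO file when no quarter is given, "
                f"found {len(demos)}"
            )
        quarter = demos[0].stem[4:]
    frames: dict[str, pd.DataFrame] = {}
    skipped: dict[str, int] = {}
    for name in TABLES:
        f = root / f"{name.upper()}{quarter}.txt"
        if not f.exists():
            raise InputError(f"missing mandatory table file: {f}")
        frames[name], skipped[name] = _read_dollar_table(f)
        if skipped[name]:
            logger.warning("%s: skipped %d malformed rows", f.name, skipped[name])
    return RawQuarter(**frames, skipped_rows=skipped)


def concat_quarters(quarters: Sequence[RawQuarter]) -> RawQuarter:
    """Concatenate quarters (before deduplication; duplicates cross quarters)."""
    if not quarters:
        raise InputError("no quarters to concatenate")
    merged = {
        name: pd.concat([q.table(name) for q in quarters], ignore_index=True)
        for name in TABLES
    }
    skipped: dict[str, int] = {}
    for q in quarters:
        for k, v in q.skipped_rows.items():
            skipped[k] = skipped.get(k, 0) + v
    return RawQuarter(**merged, skipped_rows=skipped)


def load_quarters(path: str | Path, quarters: Iterable[str] | None = None) -> RawQuarter:
    """Parse and concatenate every quarter found under ``path``."""
    root = Path(path)
    if quarters is None:
        quarters = sorted(f.stem[4:] for f in root.glob("DEMO*.txt"))
    labels = list(quarters)
    if not labels:
        raise InputError(f"{root}: no DEMO files found")
    return concat_quarters([parse_quarter(root, q) for q in labels])


def _fda_key(values: pd.Series) -> pd.Series:
    """Sortable receipt-date key; unparseable dates sort earliest (-1)."""
    key = pd.to_numeric(values, errors="coerce")
    bad = key.isna() | (values.astype(str).str.len() != 8)
    return key.mask(bad, -1).astype(np.int64)


def deduplicate(demo: pd.DataFrame) -> np.ndarray:
    """Surviving PRIMARYIDs: per CASEID the latest FDA_DT, ties to the
    higher PRIMARYID.  Idempotent; singletons survive as themselves."""
    if demo.empty:
        return np.array([], dtype=object)
    work = demo[["PRIMARYID", "CASEID", "FDA_DT"]].copy()
    work["_fda"] = _fda_key(work["FDA_DT"])
    work["_pid"] = pd.to_numeric(work["PRIMARYID"], errors="coerce").fillna(-1)
    work = work.sort_values(["_fda", "_pid"], kind="mergesort")
    survivors = work.groupby("CASEID", sort=False).tail(1)["PRIMARYID"]
    return survivors.to_numpy()


def event_pairs(raw: RawQuarter, report_ids: Iterable) -> pd.DataFrame:
    """Distinct (report_id, pt) pairs for the given reports."""
    keep = set(report_ids)
    reac = raw.reac[raw.reac["PRIMARYID"].isin(keep)]
    pairs = reac.rename(columns={"PRIMARYID": "report_id", "PT": "pt"})
    pairs = pairs.assign(pt=pairs["pt"].str.upper().str.strip())
    return pairs[["report_id", "pt"]].drop_duplicates().reset_index(drop=True)


def select_cases(
    raw: RawQuarter,
    name_list: Sequence[str],
    role: str = "PS",
    survivors: Iterable | None = None,
) -> CaseSet:
    """Extract the deduplicated case set for the target drug.

    A surviving report is a case iff some drug row has the configured
    role code and its DRUGNAME or PROD_AI, uppercased and trimmed,
    exactly matches one of ``name_list``.  Events, suspect-drug therapy
    rows, indications and outcomes are attached by PRIMARYID.
    """
    if not name_list:
        raise ConfigurationError("target drug name list is empty")
    names = {n.upper().strip() for n in name_list}
    if survivors is None:
        survivors = deduplicate(raw.demo)
    surv = set(survivors)

    drug = raw.drug
    role_ok = drug["ROLE_COD"].str.upper().str.strip() == role.upper().strip()
    name_ok = drug["DRUGNAME"].str.upper().str.strip().isin(names) | drug[
        "PROD_AI"
    ].str.upper().str.strip().isin(names)
    hits = drug[role_ok & name_ok & drug["PRIMARYID"].isin(surv)]
    case_ids = np.array(sorted(set(hits["PRIMARYID"]), key=str), dtype=object)
    case_set = set(case_ids)

    demo = raw.demo[raw.demo["PRIMARYID"].isin(case_set)].drop_duplicates(
        "PRIMARYID"
    ).set_index("PRIMARYID")

    events = event_pairs(raw, case_set)

    # therapy rows of the suspect drug: DSG_DRUG_SEQ joins DRUG_SEQ
    key = hits[["PRIMARYID", "DRUG_SEQ"]].drop_duplicates()
    ther = raw.ther.merge(
        key,
        left_on=["PRIMARYID", "DSG_DRUG_SEQ"],
        right_on=["PRIMARYID", "DRUG_SEQ"],
        how="inner",
    )[["PRIMARYID", "START_DT"]].rename(
        columns={"PRIMARYID": "report_id", "START_DT": "start_dt"}
    )

    indi = raw.indi[raw.indi["PRIMARYID"].isin(case_set)].rename(
        columns={"PRIMARYID": "report_id", "INDI_PT": "indi_pt"}
    )[["report_id", "indi_pt"]]
    outc = raw.outc[raw.outc["PRIMARYID"].isin(case_set)].rename(
        columns={"PRIMARYID": "report_id", "OUTC_COD": "outc_cod"}
    )[["report_id", "outc_cod"]]

    return CaseSet(
        report_ids=case_ids,
        demo=demo,
        events=events,
        ther=ther.reset_index(drop=True),
        indications=indi.reset_index(drop=True),
        outcomes=outc.reset_index(drop=True),
    )


def read_meddra_map(path: str | Path) -> dict[str, str]:
    """Read a two-column PT -> SOC mapping (tab, comma or '$' delimited)."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"MedDRA map not found: {p}")
    with open(p, "r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ("$" if "$" in first else ",")
    frame = pd.read_csv(p, sep=sep, dtype=str).iloc[:, :2]
    frame.columns = ["PT", "SOC"]
    frame["PT"] = frame["PT"].str.upper().str.strip()
    if frame["PT"].duplicated().any():
        dups = frame.loc[frame["PT"].duplicated(), "PT"].tolist()
        raise ConfigurationError(f"duplicate PT keys in MedDRA map: {dups[:5]}")
    return dict(zip(frame["PT"], frame["SOC"].str.strip()))


def map_events(case_set: CaseSet, meddra_map: Mapping[str, str]) -> CaseSet:
    """Annotate each event PT with its system organ class.

    PTs absent from the map become "UNMAPPED" (counted and logged); the
    pipeline continues.
    """
    lut = {str(k).upper().strip(): v for k, v in meddra_map.items()}
    if len(lut) != len(meddra_map):
        raise ConfigurationError("duplicate PT keys in MedDRA map after normalisation")
    soc = case_set.events["pt"].map(lut)
    n_unmapped = int(soc.isna().sum())
    if n_unmapped:
        logger.warning("%d event PTs have no SOC mapping", n_unmapped)
    events = case_set.events.assign(soc=soc.fillna("UNMAPPED"))
    return replace(case_set, events=events, unmapped_pts=n_unmapped)


# ---------------------------------------------------------------------------
# demographics


def _pct(n: int, total: int) -> float:
    return round(100.0 * n / total, 1) if total else float("nan")


def _age_years(age: str, cod: str) -> float:
    try:
        v = float(age)
    except (TypeError, ValueError):
        return float("nan")
    cod = (cod or "").upper().strip()
    if cod in ("", "YR"):
        return v
    if cod == "DEC":
        return v * 10.0
    if cod == "MON":
        return v / 12.0
    if cod == "WK":
        return v / 52.18
    if cod == "DY":
        return v / 365.25
    return float("nan")


def _age_band(years: float) -> str:
    if np.isnan(years):
        return "Unknown"
    if years < 18:
        return "<18"
    if years <= 64:
        return "18-64"
    if years <= 85:
        return "65-85"
    return "Unknown"


@dataclass
class DemographicsSummary:
    """Counts and percentages describing the case set (Table-1 shape)."""

    total_cases: int
    total_events: int
    mean_events_per_case: float
    sections: dict[str, pd.DataFrame]  # section -> (category, count, pct)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for section, frame in self.sections.items():
            parts.append(frame.assign(section=section))
        out = pd.concat(parts, ignore_index=True)
        return out[["section", "category", "count", "pct"]]

    def summary(self) -> str:
        lines = [
            f"Cases: {self.total_cases}   events: {self.total_events}   "
            f"mean events/case: {self.mean_events_per_case}",
        ]
        for section, frame in self.sections.items():
            lines.append(section)
            for _, r in frame.iterrows():
                lines.append(f"  {r['category']:<55}{r['count']:>8}  {r['pct']:>5.1f}%")
        return "\n".join(lines)


def _count_section(values: pd.Series, total: int, order: Sequence[str] | None = None) -> pd.DataFrame:
    counts = values.value_counts()
    if order is not None:
        counts = counts.reindex([o for o in order if o in counts.index]).dropna().astype(int)
    return pd.DataFrame(
        {
            "category": counts.index.astype(str),
            "count": counts.to_numpy(dtype=int),
            "pct": [_pct(int(c), total) for c in counts],
        }
    )


def summarize_demographics(case_set: CaseSet, top_k_indications: int = 5) -> DemographicsSummary:
    """Tabulate sex, age band, country, reporter type, reporting year,
    top indications and serious outcomes with percentages of total cases."""
    if len(case_set) == 0:
        raise InputError("empty case set")
    total = len(case_set)
    demo = case_set.demo
    n_events = len(case_set.events)

    sex = demo["SEX"].str.upper().str.strip().replace({"": "Unknown", "UNK": "Unknown"})
    sex = sex.map({"M": "Male", "F": "Female"}).fillna("Unknown")

    ages = [
        _age_band(_age_years(a, c)) for a, c in zip(demo["AGE"], demo["AGE_COD"])
    ]
    years = demo["FDA_DT"].str[:4]

    reporter = (
        demo["OCCP_COD"].str.upper().str.strip().map(REPORTER_LABELS).fillna("Missing")
    )
    country = demo["OCCR_COUNTRY"].str.strip().replace({"": "Missing"})

    indi = case_set.indications.drop_duplicates()
    indi_counts = indi["indi_pt"].value_counts().head(top_k_indications)
    indi_frame = pd.DataFrame(
        {
            "category": indi_counts.index.astype(str),
            "count": indi_counts.to_numpy(dtype=int),
            "pct": [_pct(int(c), total) for c in indi_counts],
        }
    )

    outc = case_set.outcomes.drop_duplicates()
    outc_labels = outc["outc_cod"].str.upper().str.strip().map(OUTCOME_LABELS).dropna()
    outc_frame = _count_section(outc_labels, total, order=list(OUTCOME_LABELS.values()))
    n_with_outcome = outc["report_id"].nunique()
    missing_outc = total - n_with_outcome
    outc_frame = pd.concat(
        [
            outc_frame,
            pd.DataFrame(
                {"category": ["Missing"], "count": [missing_outc],
                 "pct": [_pct(missing_outc, total)]}
            ),
        ],
        ignore_index=True,
    )

    sections = {
        "Gender": _count_section(sex, total, order=["Female", "Male", "Unknown"]),
        "Age": _count_section(pd.Series(ages), total, order=["<18", "18-64", "65-85", "Unknown"]),
        "Reported Countries": _count_section(country, total),
        "Reported Person": _count_section(reporter, total),
        "Reporting year": _count_section(years, total, order=sorted(years.unique())),
        "Indications (TOP five)": indi_frame,
        "Serious outcome": outc_frame,
    }
    return DemographicsSummary(
        total_cases=total,
        total_events=n_events,
        mean_events_per_case=round(n_events / total, 1),
        sections=sections,
    )
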