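"""Synthetic FAERS-dialect data with known ground truth.

Emulates the structure of the FDA quarterly ASCII extracts at a scale a
test suite can afford: '$'-delimited DEMO/DRUG/REAC/THER/INDI/OUTC tables,
one file per table per quarter, with

* a target drug appearing as primary suspect with elevated reporting
  rates for a configurable set of planted preferred terms (PTs) against a
  Zipf-distributed multinomial background of other drug-event pairs,
* duplicate CASEIDs (a cloned report with a higher PRIMARYID and a
  same-or-later FDA_DT, so both branches of the deduplication rule are
  exercised),
* partially missing EVENT_DT / START_DT in the four FAERS precision
  classes (full CCYYMMDD, CCYYMM, CCYY, absent),
* Weibull-distributed true onset intervals between therapy start and
  event date, recorded before date masking.

The returned :class:`GroundTruth` carries exact per-PT contingency
counts, the duplicate groups with their intended survivors, and the true
onset intervals, so every downstream stage can be checked against an
oracle that never touches the ingest code path.

Planted terms replace mid-rank background PTs; the target drug's event
distribution multiplies those baseline probabilities by the configured
rate multiplier and rescales the unplanted remainder, so the expected
target-to-background rate ratio of a planted PT equals its multiplier.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .disproportionality import ContingencyTable
from .exceptions import ConfigurationError, InputError

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "DuplicateGroup",
    "generate_reports",
    "generate_quarters",
    "expected_contingency",
    "SOC_NAMES",
    "TABLE_COLUMNS",
]

# MedDRA v26 System Organ Classes (the 26 observed for the study drug).
SOC_NAMES = (
    "Nervous system disorders",
    "Psychiatric disorders",
    "General disorders and administration site conditions",
    "Gastrointestinal disorders",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Skin and subcutaneous tissue disorders",
    "Musculoskeletal and connective tissue disorders",
    "Eye disorders",
    "Vascular disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Metabolism and nutrition disorders",
    "Cardiac disorders",
    "Renal and urinary disorders",
    "Immune system disorders",
    "Social circumstances",
    "Infections and infestations",
    "Reproductive system and breast disorders",
    "Ear and labyrinth disorders",
    "Surgical and medical procedures",
    "Product issues",
    "Endocrine disorders",
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Blood and lymphatic system disorders",
    "Hepatobiliary disorders",
    "Pregnancy, puerperium and perinatal conditions",
)

_PLANTED_SOC = {
    "MANIA": "Psychiatric disorders",
    "HYPOMANIA": "Psychiatric disorders",
    "SEDATION": "Nervous system disorders",
    "SEROTONIN SYNDROME": "Nervous system disorders",
    "URINARY RETENTION": "Renal and urinary disorders",
    "PSEUDOSTROKE": "Nervous system disorders",
}

_INDICATIONS = (
    "BIPOLAR DISORDER",
    "SCHIZOPHRENIA",
    "BIPOLAR II DISORDER",
    "BIPOLAR I DISORDER",
    "SCHIZOAFFECTIVE DISORDER",
)
_INDICATION_W = (0.45, 0.30, 0.10, 0.08, 0.07)

# Serious-outcome codes with per-report marginal probabilities; a report
# may carry several codes.
_OUTCOME_P = {"DE": 0.013, "LT": 0.003, "HO": 0.089, "DS": 0.008, "RI": 0.002, "OT": 0.219}

TABLE_COLUMNS = {
    "demo": ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE", "AGE_COD",
             "OCCR_COUNTRY", "OCCP_COD"],
    "drug": ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"],
    "reac": ["PRIMARYID", "PT"],
    "ther": ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"],
    "indi": ["PRIMARYID", "INDI_PT"],
    "outc": ["PRIMARYID", "OUTC_COD"],
}


def _default_mix() -> dict:
    return {
        "sex": {"F": 0.552, "M": 0.326, "UNK": 0.122},
        "age_missing": 0.628,
        "country": {"US": 0.999, "PL": 0.001},
        "reporter": {"HP": 0.415, "CN": 0.353, "MD": 0.214, "PH": 0.011, "": 0.007},
    }


def _default_quarters() -> tuple[str, ...]:
    out = ["19Q4"]
    for yy in (20, 21, 22):
        out += [f"{yy}Q{q}" for q in (1, 2, 3, 4)]
    out += ["23Q1", "23Q2", "23Q3"]
    return tuple(out)


@dataclass
class SynthConfig:
    """Parameters of the synthetic spontaneous-report corpus.

    Defaults emulate the study conditions for the target drug: 1,693
    target reports spread over 2019Q4-2023Q3 with the observed yearly
    reporting profile, demographics matching the published case mix,
    onset intervals drawn from Weibull(shape 0.59, scale 25.61 days), and
    date completeness tuned so that roughly 8% of reports yield a usable
    onset interval.  The background corpus is a scaled-down stand-in for
    "all other drugs": 50,000 reports over Zipf-distributed drug and PT
    marginals with independent pairing except for the planted signals.
    """

    seed: int = 0
    n_background_reports: int = 50_000
    background_drugs: int = 200
    background_pts: int = 300
    target_drug_name: str = "LUMATEPERONE"
    comparator_drug_name: str = "RISPERIDONE"
    planted_signals: tuple[tuple[str, float], ...] = (
        ("MANIA", 20.0),
        ("SEDATION", 15.0),
        ("SEROTONIN SYNDROME", 10.0),
    )
    n_target_reports: int = 1_693
    duplicate_fraction: float = 0.10
    # (full, month-only, year-only, absent) applied independently to
    # EVENT_DT and START_DT
    date_missing_probs: tuple[float, float, float, float] = (0.22, 0.07, 0.11, 0.60)
    tto_shape: float = 0.59
    tto_scale: float = 25.61
    demographic_mix: dict = field(default_factory=_default_mix)
    quarters: tuple[str, ...] = field(default_factory=_default_quarters)
    year_weights: dict = field(
        default_factory=lambda: {2019: 0.0, 2020: 0.074, 2021: 0.195, 2022: 0.497, 2023: 0.234}
    )
    zipf_exponent: float = 1.0
    mean_events_per_report: float = 2.8
    max_events_per_report: int = 8

    def validate(self) -> None:
        def _check_probs(vec, name):
            if any(p < 0 or p > 1 for p in vec):
                raise ConfigurationError(f"{name}: proportions must lie in [0, 1]")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name}: probabilities must sum to 1")

        _check_probs(self.date_missing_probs, "date_missing_probs")
        _check_probs(self.demographic_mix["sex"].values(), "demographic_mix.sex")
        _check_probs(self.demographic_mix["country"].values(), "demographic_mix.country")
        _check_probs(self.demographic_mix["reporter"].values(), "demographic_mix.reporter")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ConfigurationError("duplicate_fraction must lie in [0, 1]")
        if not 0.0 <= self.demographic_mix["age_missing"] <= 1.0:
            raise ConfigurationError("age_missing must lie in [0, 1]")
        for pt, mult in self.planted_signals:
            if mult < 1.0:
                raise ConfigurationError(f"rate multiplier for {pt!r} must be >= 1")
        if self.tto_shape <= 0 or self.tto_scale <= 0:
            raise ConfigurationError("Weibull onset parameters must be positive")
        if self.n_target_reports < 1 or self.n_background_reports < 1:
            raise ConfigurationError("report counts must be positive")
        if self.background_pts < 2 * max(1, len(self.planted_signals)):
            raise ConfigurationError("background_pts too small for the planted signals")


@dataclass(frozen=True)
class DuplicateGroup:
    caseid: int
    primaryids: tuple[int, ...]
    survivor: int


@dataclass
class GroundTruth:
    """Oracle bookkeeping recorded while the corpus is generated."""

    config: SynthConfig
    pt_names: tuple[str, ...]
    pt_soc: dict[str, str]
    target_pt_counts: pd.Series  # distinct target reports per PT (a)
    background_pt_counts: pd.Series  # distinct non-target reports per PT (c)
    comparator_pt_counts: pd.Series
    total_target_pairs: int
    total_background_pairs: int
    total_comparator_pairs: int
    duplicate_groups: list[DuplicateGroup]
    survivor_primaryids: np.ndarray
    onset_days_true: pd.Series  # target primaryid -> continuous Weibull draw
    expected_tto: pd.Series  # target primaryid -> onset days recoverable post-masking
    row_counts: dict[str, int]  # rows per table across all quarters
    n_target_cases: int

    def expected_contingency(self, pt: str) -> ContingencyTable:
        return expected_contingency(self, pt)


def expected_contingency(truth: GroundTruth, pt: str) -> ContingencyTable:
    """2x2 table for one PT from ground-truth assignments alone."""
    if pt not in truth.pt_names:
        raise KeyError(f"unknown preferred term {pt!r}")
    a = int(truth.target_pt_counts.get(pt, 0))
    c = int(truth.background_pt_counts.get(pt, 0))
    return ContingencyTable(
        a, truth.total_target_pairs - a, c, truth.total_background_pairs - c
    )


# ---------------------------------------------------------------------------
# calendar helpers


def _quarter_bounds(label: str) -> tuple[np.datetime64, np.datetime64]:
    yy, q = int(label[:2]), int(label[3])
    year = 2000 + yy
    start_month = 3 * (q - 1) + 1
    start = np.datetime64(f"{year:04d}-{start_month:02d}-01")
    if q == 4:
        end = np.datetime64(f"{year + 1:04d}-01-01")
    else:
        end = np.datetime64(f"{year:04d}-{start_month + 3:02d}-01")
    return start, end


def quarter_label(date: np.datetime64) -> str:
    ts = pd.Timestamp(date)
    return f"{ts.year % 100:02d}Q{(ts.month - 1) // 3 + 1}"


def _format_dates(dates: np.ndarray, mask_class: np.ndarray) -> np.ndarray:
    """Render dates as FAERS text at four precision classes.

    mask_class: 0 full CCYYMMDD, 1 CCYYMM, 2 CCYY, 3 absent.
    """
    full = pd.DatetimeIndex(dates).strftime("%Y%m%d").to_numpy(dtype=object)
    out = full.copy()
    out[mask_class == 1] = [s[:6] for s in full[mask_class == 1]]
    out[mask_class == 2] = [s[:4] for s in full[mask_class == 2]]
    out[mask_class == 3] = ""
    return out


def _choice(rng: np.random.Generator, options: Sequence, probs: Sequence[float], n: int):
    p = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(options, dtype=object), size=n, p=p / p.sum())


# ---------------------------------------------------------------------------
# generation


def generate_reports(config: SynthConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Build the full corpus in memory; see :func:`generate_quarters`."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t, n_b = config.n_target_reports, config.n_background_reports
    n = n_t + n_b

    # --- vocabularies ----------------------------------------------------
    n_pts = config.background_pts
    pt_names = np.array([f"PT_{i:04d}" for i in range(n_pts)], dtype=object)
    planted_idx: dict[str, int] = {}
    for j, (name, _mult) in enumerate(config.planted_signals):
        idx = n_pts // 2 + j
        pt_names[idx] = name.upper()
        planted_idx[name.upper()] = idx
    ranks = np.arange(1, n_pts + 1, dtype=float)
    p_bg = ranks ** -config.zipf_exponent
    p_bg /= p_bg.sum()

    p_tgt = p_bg.copy()
    planted_mass = 0.0
    baseline_mass = 0.0
    for name, mult in config.planted_signals:
        i = planted_idx[name.upper()]
        baseline_mass += p_bg[i]
        p_tgt[i] = mult * p_bg[i]
        planted_mass += p_tgt[i]
    if planted_mass >= 1.0:
        raise ConfigurationError("planted signal mass exceeds 1; lower the multipliers")
    if config.planted_signals:
        others = np.ones(n_pts, dtype=bool)
        others[list(planted_idx.values())] = False
        p_tgt[others] *= (1.0 - planted_mass) / (1.0 - baseline_mass)

    n_drugs = config.background_drugs
    drug_names = np.array(
        [config.comparator_drug_name.upper()]
        + [f"BG_DRUG_{i:04d}" for i in range(1, n_drugs)],
        dtype=object,
    )
    drug_ranks = np.arange(1, n_drugs + 1, dtype=float)
    p_drug = drug_ranks ** -config.zipf_exponent
    p_drug /= p_drug.sum()

    soc_map = {
        str(pt): _PLANTED_SOC.get(str(pt), SOC_NAMES[i % len(SOC_NAMES)])
        for i, pt in enumerate(pt_names)
    }

    # --- report-level attributes -----------------------------------------
    primaryid = 10_000_001 + np.arange(n)
    caseid = 5_000_001 + np.arange(n)
    is_target = np.zeros(n, dtype=bool)
    is_target[:n_t] = True

    ps_drug = np.empty(n, dtype=object)
    ps_drug[:n_t] = config.target_drug_name.upper()
    ps_drug[n_t:] = drug_names[rng.choice(n_drugs, size=n_b, p=p_drug)]

    # FDA receipt dates follow the configured yearly reporting profile
    years = sorted({2000 + int(q[:2]) for q in config.quarters})
    yw = np.array([config.year_weights.get(y, 0.0) for y in years], dtype=float)
    if yw.sum() <= 0:
        raise ConfigurationError("year_weights assign no mass to the configured quarters")
    yw /= yw.sum()
    year_of = rng.choice(np.array(years), size=n, p=yw)
    q_by_year = {y: [q for q in config.quarters if 2000 + int(q[:2]) == y] for y in years}
    fda_dt = np.empty(n, dtype="datetime64[D]")
    for y in years:
        sel = year_of == y
        if not sel.any():
            continue
        qs = q_by_year[y]
        q_pick = rng.integers(0, len(qs), size=int(sel.sum()))
        starts = np.array([_quarter_bounds(q)[0] for q in qs], dtype="datetime64[D]")
        ends = np.array([_quarter_bounds(q)[1] for q in qs], dtype="datetime64[D]")
        spans = (ends - starts).astype(int)
        offs = (rng.random(int(sel.sum())) * spans[q_pick]).astype(int)
        fda_dt[sel] = starts[q_pick] + offs

    onset_true = config.tto_scale * rng.weibull(config.tto_shape, size=n)
    onset_days = np.maximum(1, np.ceil(onset_true)).astype(int)
    report_lag = rng.integers(0, 46, size=n)
    event_dt = fda_dt - report_lag.astype("timedelta64[D]")
    start_dt = event_dt - onset_days.astype("timedelta64[D]")

    mask_p = np.asarray(config.date_missing_probs, dtype=float)
    event_mask = rng.choice(4, size=n, p=mask_p)
    start_mask = rng.choice(4, size=n, p=mask_p)

    mix = config.demographic_mix
    sex = _choice(rng, list(mix["sex"]), list(mix["sex"].values()), n)
    age_missing = rng.random(n) < mix["age_missing"]
    age_val = np.clip(np.round(rng.normal(40.98, 14.78, size=n)), 6, 85).astype(int)
    age = np.array([("" if m else str(v)) for m, v in zip(age_missing, age_val)], dtype=object)
    age_cod = np.where(age == "", "", "YR").astype(object)
    country = _choice(rng, list(mix["country"]), list(mix["country"].values()), n)
    reporter = _choice(rng, list(mix["reporter"]), list(mix["reporter"].values()), n)

    # --- events -----------------------------------------------------------
    geo_p = 1.0 / config.mean_events_per_report
    k = np.minimum(rng.geometric(geo_p, size=n), config.max_events_per_report)
    rep_idx = np.repeat(np.arange(n), k)
    pt_draw = np.empty(rep_idx.shape[0], dtype=np.int64)
    tgt_rows = is_target[rep_idx]
    pt_draw[tgt_rows] = rng.choice(n_pts, size=int(tgt_rows.sum()), p=p_tgt)
    pt_draw[~tgt_rows] = rng.choice(n_pts, size=int((~tgt_rows).sum()), p=p_bg)
    pairs = pd.DataFrame({"report": rep_idx, "pt": pt_draw}).drop_duplicates()

    # --- ground-truth counts (computed on the de-duplicated universe) -----
    tgt_pairs = pairs[is_target[pairs["report"].to_numpy()]]
    bg_pairs = pairs[~is_target[pairs["report"].to_numpy()]]
    comp_reports = np.flatnonzero(ps_drug == config.comparator_drug_name.upper())
    comp_pairs = pairs[pairs["report"].isin(comp_reports)]

    def _pt_counts(sub: pd.DataFrame) -> pd.Series:
        counts = sub.groupby("pt").size()
        out = counts.reindex(np.arange(n_pts), fill_value=0)
        out.index = pt_names
        return out.astype(int)

    target_counts = _pt_counts(tgt_pairs)
    background_counts = _pt_counts(bg_pairs)
    comparator_counts = _pt_counts(comp_pairs)

    # --- duplicates --------------------------------------------------------
    n_dup = int(round(config.duplicate_fraction * n))
    dup_src = np.sort(rng.choice(n, size=n_dup, replace=False)) if n_dup else np.array([], int)
    dup_primaryid = 10_000_001 + n + np.arange(n_dup)
    advance = rng.integers(1, 91, size=n_dup)
    same_dt = rng.random(n_dup) < 0.2
    window_end = max(_quarter_bounds(q)[1] for q in config.quarters) - np.timedelta64(1, "D")
    dup_fda = np.minimum(
        fda_dt[dup_src] + np.where(same_dt, 0, advance).astype("timedelta64[D]"), window_end
    )
    groups = [
        DuplicateGroup(int(caseid[s]), (int(primaryid[s]), int(pid)), int(pid))
        for s, pid in zip(dup_src, dup_primaryid)
    ]
    survivors = primaryid.astype(np.int64).copy()
    survivors[dup_src] = dup_primaryid  # clone replaces its source
    survivor_ids = np.sort(survivors)

    # --- assemble tables ----------------------------------------------------
    def _with_dups(values: np.ndarray) -> np.ndarray:
        return np.concatenate([values, values[dup_src]]) if n_dup else values

    all_pid = np.concatenate([primaryid, dup_primaryid]) if n_dup else primaryid
    all_fda = np.concatenate([fda_dt, dup_fda]) if n_dup else fda_dt

    demo = pd.DataFrame(
        {
            "PRIMARYID": all_pid,
            "CASEID": _with_dups(caseid),
            "FDA_DT": pd.DatetimeIndex(all_fda).strftime("%Y%m%d"),
            "EVENT_DT": _format_dates(_with_dups(event_dt), _with_dups(event_mask)),
            "SEX": _with_dups(sex),
            "AGE": _with_dups(age),
            "AGE_COD": _with_dups(age_cod),
            "OCCR_COUNTRY": _with_dups(country),
            "OCCP_COD": _with_dups(reporter),
        }
    )

    n_conc = np.minimum(rng.poisson(0.5, size=n), 2)
    conc_rep = np.repeat(np.arange(n), n_conc)
    conc_drug = drug_names[rng.choice(n_drugs, size=conc_rep.shape[0], p=p_drug)]
    conc_seq = np.concatenate([np.arange(2, 2 + m) for m in n_conc]) if n_conc.sum() else np.array([], int)
    drug_core = pd.DataFrame(
        {
            "PRIMARYID": np.concatenate([primaryid, primaryid[conc_rep]]),
            "DRUG_SEQ": np.concatenate([np.ones(n, dtype=int), conc_seq]),
            "ROLE_COD": np.concatenate([np.full(n, "PS", dtype=object),
                                        np.full(conc_rep.shape[0], "C", dtype=object)]),
            "DRUGNAME": np.concatenate([ps_drug, conc_drug]),
            "PROD_AI": np.concatenate([ps_drug, conc_drug]),
        }
    )

    reac_core = pd.DataFrame(
        {"PRIMARYID": primaryid[pairs["report"].to_numpy()],
         "PT": pt_names[pairs["pt"].to_numpy()]}
    )
    ther_core = pd.DataFrame(
        {
            "PRIMARYID": primaryid,
            "DSG_DRUG_SEQ": np.ones(n, dtype=int),
            "START_DT": _format_dates(start_dt, start_mask),
        }
    )
    indi_core = pd.DataFrame(
        {"PRIMARYID": primaryid, "INDI_PT": _choice(rng, _INDICATIONS, _INDICATION_W, n)}
    )
    outc_rows = []
    for code, prob in _OUTCOME_P.items():
        hit = np.flatnonzero(rng.random(n) < prob)
        outc_rows.append(pd.DataFrame({"PRIMARYID": primaryid[hit], "OUTC_COD": code}))
    outc_core = pd.concat(outc_rows, ignore_index=True)

    def _clone(tab: pd.DataFrame) -> pd.DataFrame:
        if not n_dup:
            return tab
        src_pid = primaryid[dup_src]
        remap = dict(zip(src_pid, dup_primaryid))
        extra = tab[tab["PRIMARYID"].isin(remap)].copy()
        extra["PRIMARYID"] = extra["PRIMARYID"].map(remap)
        return pd.concat([tab, extra], ignore_index=True)

    tables = {
        "demo": demo,
        "drug": _clone(drug_core),
        "reac": _clone(reac_core),
        "ther": _clone(ther_core),
        "indi": _clone(indi_core),
        "outc": _clone(outc_core),
    }
    for name, tab in tables.items():
        sort_cols = [c for c in ("PRIMARYID", "DRUG_SEQ", "PT", "OUTC_COD") if c in tab.columns]
        tables[name] = tab.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)

    # --- onset oracle -------------------------------------------------------
    def _resolve(dt: np.datetime64, mask: int):
        if mask == 0:
            return pd.Timestamp(dt)
        if mask == 1:
            ts = pd.Timestamp(dt)
            return pd.Timestamp(year=ts.year, month=ts.month, day=15)
        return None

    tto_pid, tto_days = [], []
    for i in range(n_t):
        s = _resolve(start_dt[i], int(start_mask[i]))
        e = _resolve(event_dt[i], int(event_mask[i]))
        if s is None or e is None:
            continue
        delta = (e - s).days
        if delta > 0:
            tto_pid.append(int(survivors[i]))
            tto_days.append(delta)

    truth = GroundTruth(
        config=config,
        pt_names=tuple(str(x) for x in pt_names),
        pt_soc=soc_map,
        target_pt_counts=target_counts,
        background_pt_counts=background_counts,
        comparator_pt_counts=comparator_counts,
        total_target_pairs=int(len(tgt_pairs)),
        total_background_pairs=int(len(bg_pairs)),
        total_comparator_pairs=int(len(comp_pairs)),
        duplicate_groups=groups,
        survivor_primaryids=survivor_ids,
        onset_days_true=pd.Series(onset_true[:n_t], index=survivors[:n_t], name="onset_true"),
        expected_tto=pd.Series(tto_days, index=tto_pid, dtype=float, name="onset_days"),
        row_counts={k: len(v) for k, v in tables.items()},
        n_target_cases=n_t,
    )
    return tables, truth


def write_meddra_map(soc_map: Mapping[str, str], path: Path) -> None:
    frame = pd.DataFrame(sorted(soc_map.items()), columns=["PT", "SOC"])
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def generate_quarters(config: SynthConfig, out_dir: str | Path) -> GroundTruth:
    """Write '$'-delimited quarterly FAERS-dialect files plus a PT->SOC map.

    One DEMO/DRUG/REAC/THER/INDI/OUTC file per configured quarter (named
    like ``DEMO22Q1.txt``); rows are routed to the quarter of the
    report's FDA_DT.  Identical seed and config give byte-identical
    files.  Returns the :class:`GroundTruth` oracle for the corpus.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}: {exc}") from exc
    tables, truth = generate_reports(config)

    demo = tables["demo"]
    qlabel = (
        demo["FDA_DT"].str[2:4]
        + "Q"
        + ((demo["FDA_DT"].str[4:6].astype(int) - 1) // 3 + 1).astype(str)
    )
    pid_quarter = pd.Series(qlabel.to_numpy(), index=demo["PRIMARYID"].to_numpy())

    for q in config.quarters:
        for name, tab in tables.items():
            sel = tab[tab["PRIMARYID"].map(pid_quarter) == q]
            sel.to_csv(
                out / f"{name.upper()}{q}.txt",
                sep="$",
                index=False,
                lineterminator="\n",
                columns=TABLE_COLUMNS[name],
            )
    write_meddra_map(truth.pt_soc, out / "pt_soc_map.txt")
    return truth


def checksum_dir(path: str | Path) -> str:
    """SHA-256 over the sorted file names and contents (determinism checks)."""
    h = hashlib.sha256()
    for f in sorted(Path(path).glob("*.txt")):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()
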