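"""Disproportionality statistics for spontaneous-report databases.

Implements the case/non-case design used in pharmacovigilance signal
detection: every drug-event pair is summarised by a 2x2 contingency table

    =============  =========  ==============
                   event       other events
    =============  =========  ==============
    target drug    a           b
    other drugs    c           d
    =============  =========  ==============

from which the reporting odds ratio (ROR, with Woolf log-scale confidence
interval) and the Bayesian confidence propagation neural network (BCPNN)
information component (IC, with its lower credibility bound IC025) are
computed.  An event is declared a signal only when both methods cross their
conventional thresholds simultaneously: at least ``min_n`` case reports,
ROR lower confidence limit above 1, and IC025 above 0.

Counting is at report level: a report listing the same preferred term
twice contributes one count, and ``b`` / ``d`` are the remaining
report-event *pairs* for the arm (not report totals), so that the four
cells always sum to the number of distinct report-event pairs in the
dataset at the chosen MedDRA level.

The module exposes a statsmodels-flavoured interface:
:class:`DisproportionalityModel` is built from a table of report-event
pairs plus the set of target-drug report ids, and its :meth:`fit` returns
a :class:`DisproportionalityResults` carrying one row per term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = [
    "ContingencyTable",
    "RORResult",
    "ICResult",
    "SignalRow",
    "ror_with_ci",
    "ic_with_ci",
    "flag_signal",
    "build_contingency",
    "comparator_odds_ratio",
    "stratified_signals",
    "rank_signals",
    "DisproportionalityModel",
    "DisproportionalityResults",
]

IC_VARIANTS = ("noren", "bate1998", "fixed_z")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report-event counts (a, b, c, d); see module docstring."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        n = self.n
        if n == 0:
            return math.nan
        return (self.a + self.b) * (self.a + self.c) / n

    def swapped(self) -> "ContingencyTable":
        """Exchange the roles of target and background."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class RORResult:
    """Reporting odds ratio with Woolf 95% confidence interval.

    ``defined`` is False when any cell of the 2x2 table is zero; no
    continuity correction is applied and the point estimate and bounds
    are NaN in that case.
    """

    ror: float
    ci_low: float
    ci_high: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class ICResult:
    """BCPNN information component (log2 scale) and lower 95% bound."""

    ic: float
    ic025: float
    variant: str


@dataclass(frozen=True)
class SignalRow:
    """One term's full disproportionality record."""

    level: str
    term: str
    soc: str
    table: ContingencyTable
    ror: RORResult
    ic: ICResult
    is_signal: bool
    stratum: str | None = None


def ror_with_ci(table: ContingencyTable, z: float = 1.96) -> RORResult:
    """Reporting odds ratio (a*d)/(b*c) with Woolf log-scale CI.

    Any zero cell makes the estimator undefined; the result is flagged
    rather than corrected (a >= 3 is required for signals anyway, so the
    zero-cell case never contributes a signal).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return RORResult(math.nan, math.nan, math.nan, a, defined=False)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RORResult(ror, ror * math.exp(-z * se), ror * math.exp(z * se), a)


def _ic_noren(a: float, e: float) -> tuple[float, float]:
    ic = math.log2((a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return ic, ic025


def _ic_bate1998(table: ContingencyTable, z: float) -> tuple[float, float]:
    # Posterior-moment approximation of the original BCPNN formulation
    # with the customary priors alpha1 = beta1 = 1, alpha = beta = 2.
    cxy, cx, cy, n = table.a, table.a + table.b, table.a + table.c, table.n
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    g = g11 * (n + al) * (n + be) / ((cx + a1) * (cy + b1))
    e_ic = math.log2((cxy + g11) * (n + al) * (n + be) / ((n + g) * (cx + a1) * (cy + b1)))
    v_ic = (1.0 / math.log(2)) ** 2 * (
        (n - cxy + g - g11) / ((cxy + g11) * (1 + n + g))
        + (n - cx + al - a1) / ((cx + a1) * (1 + n + al))
        + (n - cy + be - b1) / ((cy + b1) * (1 + n + be))
    )
    return e_ic, e_ic - z * math.sqrt(v_ic)


def ic_with_ci(
    table: ContingencyTable,
    variant: str = "noren",
    z: float = 1.96,
    sigma: float = 1.0,
) -> ICResult:
    """Information component with its lower 95% credibility bound.

    Variants:

    * ``noren`` (default): shrinkage point estimate
      ``IC = log2((a + 0.5) / (E + 0.5))`` with ``E = (a+b)(a+c)/N``, and
      the closed-form lower bound
      ``IC025 = IC - 3.3 (a+0.5)^(-1/2) - 2 (a+0.5)^(-3/2)``.
    * ``bate1998``: posterior-moment mean and variance of the original
      BCPNN, ``IC025 = E(IC) - z sqrt(V(IC))``.
    * ``fixed_z``: the noren point estimate with a caller-supplied
      constant-width bound ``IC025 = IC - z * sigma`` (for sensitivity
      experiments only; not a calibrated credibility interval).
    """
    if variant not in IC_VARIANTS:
        raise ConfigurationError(
            f"unknown IC variant {variant!r}; expected one of {IC_VARIANTS}"
        )
    if table.n <= 0:
        raise ValueError("empty contingency table")
    if variant == "bate1998":
        ic, ic025 = _ic_bate1998(table, z)
    else:
        ic, ic025 = _ic_noren(table.a, table.expected)
        if variant == "fixed_z":
            ic025 = ic - z * sigma
    return ICResult(ic, ic025, variant)


def flag_signal(ror: RORResult, ic: ICResult, a: int, min_n: int = 3) -> bool:
    """Dual-criterion signal flag: a >= min_n, ROR ci_low > 1, IC025 > 0.

    Undefined statistics (NaN) never flag.
    """
    if not ror.defined or math.isnan(ic.ic025):
        return False
    return a >= min_n and ror.ci_low > 1.0 and ic.ic025 > 0.0


def _dedup_pairs(events: pd.DataFrame, term_col: str = "term") -> pd.DataFrame:
    """Collapse to distinct (report_id, term) pairs.

    Accepts frames that name the event column "pt" (the ingest output)
    as well as the generic "term"."""
    if term_col not in events.columns and "pt" in events.columns:
        events = events.rename(columns={"pt": term_col})
    return events[["report_id", term_col]].drop_duplicates()


def build_contingency(
    events: pd.DataFrame,
    target_ids: Iterable,
    term: str,
    term_col: str = "term",
) -> ContingencyTable:
    """2x2 table for one term from a table of report-event pairs.

    ``events`` must cover the whole dataset (target and background
    reports) at the desired MedDRA level, with columns ``report_id`` and
    ``term_col``.  Repeated identical terms within a report count once.
    A term observed nowhere yields an a = c = 0 table (callers treat the
    statistics as undefined).
    """
    pairs = _dedup_pairs(events, term_col)
    is_target = pairs["report_id"].isin(set(target_ids)).to_numpy()
    is_term = (pairs[term_col] == term).to_numpy()
    a = int((is_target & is_term).sum())
    b = int((is_target & ~is_term).sum())
    c = int((~is_target & is_term).sum())
    d = int((~is_target & ~is_term).sum())
    return ContingencyTable(a, b, c, d)


def comparator_odds_ratio(
    case_events: pd.DataFrame,
    comparator_events: pd.DataFrame,
    term: str,
    z: float = 1.96,
    term_col: str = "term",
) -> RORResult:
    """Head-to-head odds ratio of one event between two suspect drugs.

    Both inputs are report-event pair tables restricted to reports whose
    primary suspect is, respectively, the target and the comparator drug.
    a = target reports with the term, b = remaining target pairs, and
    c, d analogously for the comparator.  A zero cell (e.g. the
    comparator never reported the term) yields an undefined marker.
    """
    if len(comparator_events) == 0:
        raise InputError("comparator drug has no reports in the dataset")
    tp = _dedup_pairs(case_events, term_col)
    cp = _dedup_pairs(comparator_events, term_col)
    a = int(tp[term_col].eq(term).sum())
    b = len(tp) - a
    c = int(cp[term_col].eq(term).sum())
    d = len(cp) - c
    return ror_with_ci(ContingencyTable(a, b, c, d), z=z)


def _contingency_frame(pairs: pd.DataFrame, target_ids: set, term_col: str) -> pd.DataFrame:
    """Vectorised per-term 2x2 cells over distinct report-event pairs."""
    is_target = pairs["report_id"].isin(target_ids)
    tgt = pairs.loc[is_target, term_col].value_counts()
    bg = pairs.loc[~is_target, term_col].value_counts()
    total_t = int(is_target.sum())
    total_b = len(pairs) - total_t
    terms = tgt.index.union(bg.index)
    a = tgt.reindex(terms, fill_value=0).astype(int)
    c = bg.reindex(terms, fill_value=0).astype(int)
    out = pd.DataFrame({"a": a, "c": c})
    out["b"] = total_t - out["a"]
    out["d"] = total_b - out["c"]
    out.index.name = "term"
    return out[["a", "b", "c", "d"]]


class DisproportionalityModel:
    """Case/non-case disproportionality model over report-event pairs.

    Parameters
    ----------
    events : DataFrame
        Columns ``report_id`` and ``term`` (the event at the chosen
        MedDRA level); must cover target and background reports after
        deduplication.  Repeated identical terms in one report collapse.
    target_ids : iterable
        Report ids whose primary suspect is the target drug.
    level : str
        Label recorded in the output ("PT" or "SOC").
    term_soc : mapping, optional
        PT -> SOC annotation copied into the results (PT level only).
    min_n, z, ic_variant, ic_sigma :
        Signal thresholds; see :func:`flag_signal` and :func:`ic_with_ci`.
    strata : Series, optional
        report_id -> stratum label (e.g. sex); reports missing from the
        series are excluded from stratified fits.
    """

    def __init__(
        self,
        events: pd.DataFrame,
        target_ids: Iterable,
        *,
        level: str = "PT",
        term_soc: Mapping[str, str] | None = None,
        min_n: int = 3,
        z: float = 1.96,
        ic_variant: str = "noren",
        ic_sigma: float = 1.0,
        strata: pd.Series | None = None,
    ) -> None:
        if ic_variant not in IC_VARIANTS:
            raise ConfigurationError(f"unknown IC variant {ic_variant!r}")
        if min_n < 1:
            raise ConfigurationError("min_n must be a positive count")
        self.events = events
        self.target_ids = set(target_ids)
        self.level = level
        self.term_soc = dict(term_soc) if term_soc is not None else {}
        self.min_n = min_n
        self.z = z
        self.ic_variant = ic_variant
        self.ic_sigma = ic_sigma
        self.strata = strata

    # -- fitting ---------------------------------------------------------
    def _fit_frame(self, pairs: pd.DataFrame, stratum: str | None) -> pd.DataFrame:
        cells = _contingency_frame(pairs, self.target_ids, "term")
        rows = []
        for term, (a, b, c, d) in cells.iterrows():
            tab = ContingencyTable(int(a), int(b), int(c), int(d))
            ror = ror_with_ci(tab, z=self.z)
            ic = ic_with_ci(tab, self.ic_variant, z=self.z, sigma=self.ic_sigma)
            rows.append(
                {
                    "level": self.level,
                    "term": term,
                    "soc": self.term_soc.get(term, term if self.level == "SOC" else "UNMAPPED"),
                    "a": tab.a,
                    "b": tab.b,
                    "c": tab.c,
                    "d": tab.d,
                    "n": tab.a,
                    "ror": ror.ror,
                    "ror_ci_low": ror.ci_low,
                    "ror_ci_high": ror.ci_high,
                    "ic": ic.ic,
                    "ic025": ic.ic025,
                    "is_signal": flag_signal(ror, ic, tab.a, self.min_n),
                    "stratum": stratum,
                    "variant": self.ic_variant,
                }
            )
        frame = pd.DataFrame(rows)
        if len(frame):
            frame = frame.sort_values("term", kind="mergesort").reset_index(drop=True)
        return frame

    def fit(self) -> "DisproportionalityResults":
        pairs = _dedup_pairs(self.events)
        frames = [self._fit_frame(pairs, None)]
        if self.strata is not None:
            for label in sorted(self.strata.dropna().unique()):
                ids = set(self.strata.index[self.strata == label])
                sub = pairs[pairs["report_id"].isin(ids)]
                if not sub["report_id"].isin(self.target_ids).any():
                    continue
                frames.append(self._fit_frame(sub, str(label)))
        table = pd.concat(frames, ignore_index=True)
        return DisproportionalityResults(self, table)


class DisproportionalityResults:
    """Fitted signal table; one row per term (and per stratum if any)."""

    def __init__(self, model: DisproportionalityModel, table: pd.DataFrame) -> None:
        self.model = model
        self.table = table

    @property
    def pooled(self) -> pd.DataFrame:
        return self.table[self.table["stratum"].isna()].reset_index(drop=True)

    def stratum(self, label: str) -> pd.DataFrame:
        return self.table[self.table["stratum"] == label].reset_index(drop=True)

    @property
    def signals(self) -> pd.DataFrame:
        return self.table[self.table["is_signal"]].reset_index(drop=True)

    def contingency(self, term: str, stratum: str | None = None) -> ContingencyTable:
        sub = self.pooled if stratum is None else self.stratum(stratum)
        row = sub[sub["term"] == term]
        if row.empty:
            raise KeyError(term)
        r = row.iloc[0]
        return ContingencyTable(int(r["a"]), int(r["b"]), int(r["c"]), int(r["d"]))

    def rank(self, key: str = "frequency", k: int = 20, stratum: str | None = None) -> pd.DataFrame:
        return rank_signals(self.pooled if stratum is None else self.stratum(stratum), key, k)

    def summary(self, k: int = 20) -> str:
        """Plain-text summary of the top-k terms by report count."""
        pooled = self.pooled
        n_sig = int(pooled["is_signal"].sum())
        lines = [
            f"Disproportionality analysis ({self.model.level} level, "
            f"IC variant {self.model.ic_variant})",
            f"terms: {len(pooled)}   dual-criterion signals: {n_sig}",
            f"{'term':<40}{'n':>6}{'ROR':>9}{'95% CI':>18}{'IC':>7}{'IC025':>8}  signal",
        ]
        for _, r in self.rank("frequency", k).iterrows():
            ci = (
                f"({r.ror_ci_low:.2f},{r.ror_ci_high:.2f})"
                if np.isfinite(r.ror)
                else "(undef)"
            )
            ror = f"{r.ror:.2f}" if np.isfinite(r.ror) else "undef"
            lines.append(
                f"{r.term[:39]:<40}{r.n:>6}{ror:>9}{ci:>18}"
                f"{r.ic:>7.2f}{r.ic025:>8.2f}  {'*' if r.is_signal else ''}"
            )
        return "\n".join(lines)


def stratified_signals(
    events: pd.DataFrame,
    target_ids: Iterable,
    strata: pd.Series,
    **model_kw,
) -> dict[str, pd.DataFrame]:
    """Per-stratum signal tables (the gender-subgroup design).

    ``strata`` maps report_id to a stratum label; reports with missing
    labels are excluded.  Within each stratum the background is all
    non-target reports of the same stratum and the same dual criterion
    applies.  Strata with no target reports yield an empty table.
    """
    res = DisproportionalityModel(events, target_ids, strata=strata, **model_kw).fit()
    out: dict[str, pd.DataFrame] = {}
    for label in sorted(strata.dropna().unique()):
        out[str(label)] = res.stratum(str(label))
    return out


def rank_signals(rows: pd.DataFrame, key: str = "frequency", k: int = 20) -> pd.DataFrame:
    """Top-k rows by report count ("frequency") or by ROR ("strength").

    Ties break on the other key (descending) and then on the term name,
    so the ordering is total and deterministic.  k beyond the row count
    clamps to all rows.
    """
    if k <= 0:
        raise ConfigurationError("k must be a positive count")
    if key == "frequency":
        by = ["n", "ror", "term"]
    elif key == "strength":
        by = ["ror", "n", "term"]
    else:
        raise ConfigurationError(f"unknown ranking key {key!r}")
    ordered = rows.sort_values(
        by, ascending=[False, False, True], kind="mergesort", na_position="last"
    )
    return ordered.head(k).reset_index(drop=True)
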