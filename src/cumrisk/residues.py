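"""Supervised residue-trial summarization.

Field trials measure pesticide concentrations (mg/kg) in a crop at fixed
pre-harvest intervals across several sites.  The regulatory summaries of such
trials are the supervised trial median residue (STMR, the sample median at a
given interval) and the highest residue (HR, the sample maximum), which feed
both MRL compliance screening and downstream dietary exposure work.

Censored measurements (below the analytical limit of quantification, LOQ) are
handled by substitution; the default surrogate is the full LOQ, a conservative
upper bound consistent with risk maximization.  ``loq``- and ``half``-based
alternatives are available through :func:`impute_censored`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResidueObservation",
    "TrialSummary",
    "MrlRecord",
    "MrlCheck",
    "impute_censored",
    "compute_stmr",
    "compute_hr",
    "summarize_trials",
    "check_mrl",
    "read_residue_csv",
    "residues_to_frame",
]

#: supported surrogates for below-LOQ measurements
CENSOR_RULES = ("loq", "half", "zero")


@dataclass(frozen=True)
class ResidueObservation:
    """One field-trial residue measurement.

    ``concentration`` is the measured value in mg/kg, or the imputed LOQ
    surrogate when ``below_loq`` is set (a censored record never carries a
    measured value).
    """

    analyte: str
    site: str
    interval_days: int
    concentration: float
    below_loq: bool = False
    loq: float = float("nan")

    def __post_init__(self) -> None:
        if self.interval_days < 0:
            raise ValueError(f"interval_days must be >= 0, got {self.interval_days}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


@dataclass(frozen=True)
class TrialSummary:
    """STMR/HR summary for one analyte at one pre-harvest interval."""

    analyte: str
    interval_days: int
    stmr: float
    hr: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("summary requires n >= 1 observations")
        if self.stmr > self.hr + 1e-12:
            raise ValueError(f"STMR {self.stmr} exceeds HR {self.hr}")


@dataclass(frozen=True)
class MrlRecord:
    """A jurisdiction-specific maximum residue limit for a commodity."""

    analyte: str
    jurisdiction: str
    commodity: str
    mrl: float

    def __post_init__(self) -> None:
        if not self.mrl > 0:
            raise ValueError(f"MRL must be positive, got {self.mrl}")


@dataclass(frozen=True)
class MrlCheck:
    """Outcome of screening one trial summary against one MRL.

    ``compliant`` is None when no limit exists for the analyte (reported
    explicitly, never treated as a silent pass).  ``margin`` is mrl − hr.
    """

    analyte: str
    interval_days: int
    jurisdiction: str
    commodity: str
    mrl: float | None
    hr: float
    compliant: bool | None
    margin: float | None


def impute_censored(
    obs: ResidueObservation, rule: str = "loq"
) -> ResidueObservation:
    """Return ``obs`` with a censored concentration replaced by a surrogate.

    Rules: ``"loq"`` (full LOQ, default), ``"half"`` (LOQ/2), ``"zero"``.
    Uncensored observations pass through unchanged.
    """
    if rule not in CENSOR_RULES:
        raise ValueError(f"unknown censoring rule {rule!r}; choose from {CENSOR_RULES}")
    if not obs.below_loq:
        return obs
    if not np.isfinite(obs.loq):
        raise ValueError(f"censored observation lacks an LOQ: {obs!r}")
    surrogate = {"loq": obs.loq, "half": obs.loq / 2.0, "zero": 0.0}[rule]
    return replace(obs, concentration=surrogate)


def _check_homogeneous(observations: Sequence[ResidueObservation]) -> None:
    if not observations:
        raise ValueError("empty observation list")
    analytes = {o.analyte for o in observations}
    intervals = {o.interval_days for o in observations}
    if len(analytes) > 1:
        raise ValueError(f"mixed analytes in one summary: {sorted(analytes)}")
    if len(intervals) > 1:
        raise ValueError(f"mixed intervals in one summary: {sorted(intervals)}")


def compute_stmr(observations: Sequence[ResidueObservation]) -> float:
    """Supervised trial median residue: the sample median concentration.

    Even-sized samples use the arithmetic mean of the two central order
    statistics.  Full floating precision is retained; rounding is a
    presentation concern.
    """
    _check_homogeneous(observations)
    return float(np.median([o.concentration for o in observations]))


def compute_hr(observations: Sequence[ResidueObservation]) -> float:
    """Highest residue: the maximum observed concentration."""
    _check_homogeneous(observations)
    return float(max(o.concentration for o in observations))


def summarize_trials(
    observations: Iterable[ResidueObservation], censor_rule: str = "loq"
) -> list[TrialSummary]:
    """Group observations by analyte × interval and compute STMR/HR for each.

    Replicates at a site are treated as independent observations, so a
    four-site, two-replicate design yields n = 8 per interval.
    """
    imputed = [impute_censored(o, censor_rule) for o in observations]
    groups: dict[tuple[str, int], list[ResidueObservation]] = {}
    for o in imputed:
        groups.setdefault((o.analyte, o.interval_days), []).append(o)
    return [
        TrialSummary(
            analyte=analyte,
            interval_days=interval,
            stmr=compute_stmr(obs),
            hr=compute_hr(obs),
            n=len(obs),
        )
        for (analyte, interval), obs in sorted(groups.items())
    ]


def check_mrl(summary: TrialSummary, mrls: Sequence[MrlRecord]) -> list[MrlCheck]:
    """Screen a trial summary against every limit on record for its analyte.

    Compliance is the strict inequality HR < MRL.  An analyte with no MRL in
    any jurisdiction yields a single explicit missing-standard entry.
    """
    relevant = [m for m in mrls if m.analyte == summary.analyte]
    if not relevant:
        return [
            MrlCheck(
                analyte=summary.analyte,
                interval_days=summary.interval_days,
                jurisdiction="(none)",
                commodity="(none)",
                mrl=None,
                hr=summary.hr,
                compliant=None,
                margin=None,
            )
        ]
    return [
        MrlCheck(
            analyte=summary.analyte,
            interval_days=summary.interval_days,
            jurisdiction=m.jurisdiction,
            commodity=m.commodity,
            mrl=m.mrl,
            hr=summary.hr,
            compliant=summary.hr < m.mrl,
            margin=m.mrl - summary.hr,
        )
        for m in relevant
    ]


def read_residue_csv(source: str | io.TextIOBase) -> list[ResidueObservation]:
    """Read residue observations from CSV.

    Expected columns: ``analyte, site, interval_days, concentration`` and
    optionally ``below_loq, loq``.  Concentration strings of the form
    ``"<0.001"`` are parsed as censored at that LOQ.
    """
    df = pd.read_csv(source, dtype={"concentration": str})
    required = {"analyte", "site", "interval_days", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"residue CSV missing columns: {sorted(missing)}")
    out: list[ResidueObservation] = []
    for idx, row in df.iterrows():
        raw = str(row["concentration"]).strip()
        below = False
        loq = float(row["loq"]) if "loq" in df.columns and pd.notna(row["loq"]) else float("nan")
        if raw.startswith("<"):
            below = True
            loq = float(raw[1:])
            conc = loq
        else:
            try:
                conc = float(raw)
            except ValueError as err:
                raise ValueError(
                    f"line {idx + 2}: unparseable concentration {raw!r}"
                ) from err
            if "below_loq" in df.columns and bool(row["below_loq"]):
                below = True
                conc = loq
        out.append(
            ResidueObservation(
                analyte=str(row["analyte"]),
                site=str(row["site"]),
                interval_days=int(row["interval_days"]),
                concentration=conc,
                below_loq=below,
                loq=loq,
            )
        )
    return out


def residues_to_frame(observations: Iterable[ResidueObservation]) -> pd.DataFrame:
    """Tabulate observations as a tidy DataFrame (round-trips with the CSV)."""
    return pd.DataFrame(
        [
            {
                "analyte": o.analyte,
                "site": o.site,
                "interval_days": o.interval_days,
                "concentration": o.concentration,
                "below_loq": o.below_loq,
                "loq": o.loq,
            }
            for o in observations
        ]
    )
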