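"""Dispensing-record adherence phenotyping: MPR, PDC, and the 80% cutoff.

Two standard pharmacy-claims metrics over a 12-month observation window:

* MPR (medication possession ratio) — total dispensed days of supply divided
  by the span from the first fill to the end of the last refill's supply.
  Early refills can push the raw value above 1, so it is capped at 1.0 for
  classification (the raw value is retained).
* PDC (proportion of days covered) — fraction of observation days on which
  the patient actually possessed medication; bounded by 1.  Under the default
  shift-forward policy an early refill's supply starts when the previous
  supply runs out; a pure-union policy is available.

Non-adherence on either measure is strictly ``metric < 0.80`` (a patient at
exactly 0.80 is adherent).  Coverage intervals are half-open day ranges
``[fill_day, fill_day + days_supply)`` with 0-based day indices; supply is
truncated at the window end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NONADHERENCE_CUTOFF = 0.80

PHENOTYPE_COLUMNS = [
    "patient_id", "mpr", "mpr_raw", "pdc",
    "nonadherent_mpr80", "nonadherent_pdc80", "n_fills", "first_fill_day",
]


class UndefinedPhenotypeError(ValueError):
    """Raised when a patient has no fill inside the observation window."""


@dataclass(frozen=True)
class ObservationWindow:
    """Half-open day range ``[start_day, end_day)``; default one year."""

    start_day: int = 0
    end_day: int = 365

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ValueError(
                f"end_day ({self.end_day}) must exceed start_day ({self.start_day})"
            )

    @property
    def length(self) -> int:
        return self.end_day - self.start_day


def _in_window(records: pd.DataFrame, window: ObservationWindow) -> pd.DataFrame:
    fills = records[
        (records["fill_day"] >= window.start_day)
        & (records["fill_day"] < window.end_day)
    ]
    return fills.sort_values(["fill_day", "days_supply"], kind="stable")


def compute_pdc(
    records: pd.DataFrame,
    window: ObservationWindow,
    overlap_policy: str = "shift",
    anchor: str = "first_fill",
) -> float:
    """Proportion of days covered for one patient's fills.

    Parameters
    ----------
    records : DataFrame
        Fill events for a single patient (``fill_day``, ``days_supply``).
    window : ObservationWindow
    overlap_policy : {"shift", "union"}
        "shift": an early refill's supply is queued to start when the current
        supply exhausts (the standard PDC convention).  "union": covered days
        are the plain union of the per-fill intervals.
    anchor : {"first_fill", "window_start"}
        Denominator start: the first in-window fill day (default) or the
        window start.

    Raises
    ------
    UndefinedPhenotypeError
        If the patient has no fill inside the window.
    """
    fills = _in_window(records, window)
    if len(fills) == 0:
        raise UndefinedPhenotypeError("no fills within observation window")
    if overlap_policy not in ("shift", "union"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    if anchor not in ("first_fill", "window_start"):
        raise ValueError(f"unknown anchor {anchor!r}")
    first_fill = int(fills["fill_day"].iloc[0])
    start = first_fill if anchor == "first_fill" else window.start_day
    end = window.end_day

    covered = 0
    if overlap_policy == "shift":
        cov_end = start  # first uncovered day
        for day, supply in zip(fills["fill_day"], fills["days_supply"]):
            seg_start = max(int(day), cov_end)
            seg_end = seg_start + int(supply)
            covered += max(0, min(seg_end, end) - max(seg_start, start))
            cov_end = max(cov_end, seg_end)
    else:
        intervals = sorted(
            (int(d), int(d) + int(s))
            for d, s in zip(fills["fill_day"], fills["days_supply"])
        )
        cur_s, cur_e = intervals[0]
        merged = []
        for s, e in intervals[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        covered = sum(max(0, min(e, end) - max(s, start)) for s, e in merged)

    return covered / (end - start)


def compute_mpr(
    records: pd.DataFrame,
    window: ObservationWindow,
    cap: bool = True,
    truncate_at_window_end: bool = True,
) -> float:
    """Medication possession ratio for one patient's fills.

    Numerator: summed days of supply of in-window fills.  Denominator: span
    from the first fill day to the end of the last refill's supply, truncated
    at the window end by default.  Capped at 1.0 unless ``cap=False``.
    """
    fills = _in_window(records, window)
    if len(fills) == 0:
        raise UndefinedPhenotypeError("no fills within observation window")
    days = fills["fill_day"].to_numpy(int)
    supplies = fills["days_supply"].to_numpy(int)
    end = window.end_day
    if truncate_at_window_end:
        numer = int(np.minimum(supplies, end - days).sum())
        denom = min(int((days + supplies).max()), end) - int(days[0])
    else:
        numer = int(supplies.sum())
        denom = int((days + supplies).max()) - int(days[0])
    raw = numer / denom
    return min(raw, 1.0) if cap else raw


def compute_phenotypes(
    records: pd.DataFrame,
    window: ObservationWindow | None = None,
    overlap_policy: str = "shift",
    anchor: str = "first_fill",
    pooling: str = "any",
) -> pd.DataFrame:
    """Per-patient adherence phenotypes for a dispensing table.

    With ``pooling="any"`` (default) all medication-class fills count as
    interchangeable coverage, yielding one MPR and one PDC per patient; with
    ``"per-class"`` metrics are computed per medication class and one row is
    emitted per (patient, class).  Patients with no in-window fill are
    excluded and logged.
    """
    window = window or ObservationWindow()
    if pooling not in ("any", "per-class"):
        raise ValueError(f"unknown pooling {pooling!r}")
    group_cols = ["patient_id"] if pooling == "any" else ["patient_id", "med_class"]
    rows, excluded = [], []
    for key, grp in records.groupby(group_cols, sort=True):
        try:
            pdc = compute_pdc(grp, window, overlap_policy=overlap_policy, anchor=anchor)
            mpr_raw = compute_mpr(grp, window, cap=False)
        except UndefinedPhenotypeError:
            excluded.append(key)
            continue
        fills = _in_window(grp, window)
        mpr = min(mpr_raw, 1.0)
        row = {
            "patient_id": key[0] if isinstance(key, tuple) else key,
            "mpr": mpr,
            "mpr_raw": mpr_raw,
            "pdc": pdc,
            "nonadherent_mpr80": bool(mpr < NONADHERENCE_CUTOFF),
            "nonadherent_pdc80": bool(pdc < NONADHERENCE_CUTOFF),
            "n_fills": int(len(fills)),
            "first_fill_day": int(fills["fill_day"].iloc[0]),
        }
        if pooling == "per-class":
            row["med_class"] = key[1]
        rows.append(row)
    if excluded:
        logger.warning(
            "excluded %d patient(s) with no in-window fills: %s",
            len(excluded), excluded,
        )
    cols = PHENOTYPE_COLUMNS + (["med_class"] if pooling == "per-class" else [])
    return pd.DataFrame(rows, columns=cols)


def classify_cohort(phenotypes: pd.DataFrame) -> dict:
    """Case/control labels for both measures plus cross-measure concordance.

    Cases are non-adherent patients.  Returns per-measure label Series and the
    counts of patients non-adherent on both measures and adherent on both.
    """
    if len(phenotypes) == 0:
        raise ValueError("phenotypes table is empty")
    idx = pd.Index(phenotypes["patient_id"], name="patient_id")
    pdc80 = pd.Series(phenotypes["nonadherent_pdc80"].astype(int).to_numpy(), index=idx)
    mpr80 = pd.Series(phenotypes["nonadherent_mpr80"].astype(int).to_numpy(), index=idx)
    both_cases = int(((pdc80 == 1) & (mpr80 == 1)).sum())
    both_controls = int(((pdc80 == 0) & (mpr80 == 0)).sum())
    return {
        "pdc80": pdc80,
        "mpr80": mpr80,
        "n_nonadherent_both": both_cases,
        "n_adherent_both": both_controls,
        "n_concordant": both_cases + both_controls,
    }


def prevalence_table(
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    age_breaks: tuple[float, float] = (40.0, 65.0),
) -> pd.DataFrame:
    """Stratified non-adherence counts and percentages (total, sex, age band).

    Percentages are kept to one decimal in the ``*_pct`` columns and rounded
    to whole percent in the ``*_display`` columns.  Age bands are
    ``[age_breaks[0], age_breaks[1])`` and ``>= age_breaks[1]``.
    """
    merged = phenotypes.merge(covariates, on="patient_id", how="left", validate="1:1")
    missing = merged.loc[merged["age"].isna() | merged["sex"].isna(), "patient_id"]
    if len(missing):
        raise ValueError(
            f"missing covariates for patients: {sorted(missing.tolist())}"
        )
    lo, hi = age_breaks
    strata = {
        "total": np.ones(len(merged), dtype=bool),
        "male": (merged["sex"] == "M").to_numpy(),
        "female": (merged["sex"] == "F").to_numpy(),
        f"age_{int(lo)}_{int(hi) - 1}": ((merged["age"] >= lo) & (merged["age"] < hi)).to_numpy(),
        f"age_{int(hi)}_plus": (merged["age"] >= hi).to_numpy(),
    }
    rows = []
    for measure, col in (("pdc80", "nonadherent_pdc80"), ("mpr80", "nonadherent_mpr80")):
        for stratum, mask in strata.items():
            n = int(mask.sum())
            cases = int(merged.loc[mask, col].sum())
            pct = round(100.0 * cases / n, 1) if n else float("nan")
            # display rounds half away from zero (66.5% -> 67%)
            rows.append(
                {
                    "measure": measure,
                    "stratum": stratum,
                    "n": n,
                    "n_nonadherent": cases,
                    "pct_nonadherent": pct,
                    "pct_display": int(np.floor(pct + 0.5)) if n else None,
                }
            )
    return pd.DataFrame(rows)


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path) -> None:
    """Write the phenotype table in the documented TSV dialect."""
    out = phenotypes[
        ["patient_id", "mpr", "pdc", "nonadherent_mpr80", "nonadherent_pdc80"]
    ].copy()
    out["mpr"] = out["mpr"].map(lambda v: f"{v:.6f}")
    out["pdc"] = out["pdc"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
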