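"""Prescription-register TRD phenotyping.

Builds antidepressant treatment episodes from pharmacy dispensing records
and assigns treatment-resistant-depression labels under three definitions
of increasing stringency:

* ``broad``    — TRD iff the patient ever received ECT.
* ``narrow_1`` — TRD iff ECT was preceded by >=1 distinct antidepressant
  with an adequate treatment episode; non-TRD requires no ECT, at least
  one antidepressant dispense, and <=2 adequate distinct antidepressants.
* ``narrow_2`` — as narrow_1 with >=2 adequate distinct antidepressants
  required on the TRD side.

An episode is a maximal run of dispenses of one drug (full ATC code) in
which consecutive dispenses are no more than ``gap_days`` apart; its
duration is last-minus-first dispense date and it is *adequate* when that
span reaches ``min_adequate_days`` (6 weeks by default). Only dispenses
strictly before the first ECT date count toward the TRD-side criteria.

Dates are integer day numbers throughout; converting calendar dates to
day offsets is an I/O concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ATC_ANTIDEPRESSANT_PREFIX = "N06A"
ATC_LITHIUM = "N05AN01"

DEFINITIONS = ("broad", "narrow_1", "narrow_2")

TRD = "TRD"
NON_TRD = "non-TRD"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class TreatmentEpisode:
    patient_id: str
    atc: str
    start: int
    end: int
    duration_days: int
    adequate: bool


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "atc", "date"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"dispensing records missing columns: {sorted(missing)}")
    return records


def build_episodes(
    records: pd.DataFrame,
    gap_days: int = 120,
    min_adequate_days: int = 42,
    censor_date=None,
) -> pd.DataFrame:
    """Group dispenses into treatment episodes per (patient, ATC code).

    Parameters
    ----------
    records
        Columns ``patient_id``, ``atc``, ``date`` (integer day numbers).
        May be unsorted and contain duplicates; same-day duplicates of the
        same drug are collapsed.
    gap_days
        Two consecutive dispenses of the same drug belong to the same
        episode iff their gap is <= ``gap_days`` (inclusive: a gap of
        exactly 120 days joins, 121 splits).
    min_adequate_days
        An episode is adequate iff ``end - start >= min_adequate_days``.
        A single-dispense episode has duration 0 and is never adequate.
    censor_date
        If given, only dispenses with ``date`` strictly below the censor
        enter the build. Either a scalar day number applied to everyone,
        or a mapping/Series ``patient_id -> day``; patients absent from
        the mapping are not censored.

    Returns
    -------
    DataFrame with columns ``patient_id, atc, start, end, duration_days,
    adequate``, sorted by (patient_id, atc, start).
    """
    if gap_days <= 0 or min_adequate_days <= 0:
        raise ValueError("gap_days and min_adequate_days must be positive")
    _check_records(records)
    if len(records) == 0:
        return pd.DataFrame(
            columns=["patient_id", "atc", "start", "end", "duration_days", "adequate"]
        )

    recs = records[["patient_id", "atc", "date"]].copy()
    if censor_date is not None:
        if np.isscalar(censor_date):
            recs = recs[recs["date"] < censor_date]
        else:
            censor = pd.Series(censor_date)
            limit = recs["patient_id"].map(censor)
            recs = recs[limit.isna() | (recs["date"] < limit)]

    rows: list[tuple] = []
    for (pid, atc), grp in recs.groupby(["patient_id", "atc"], sort=True):
        dates = np.unique(grp["date"].to_numpy())  # sorted, same-day collapsed
        if dates.size == 0:
            continue
        # new episode wherever the gap to the previous dispense exceeds gap_days
        breaks = np.flatnonzero(np.diff(dates) > gap_days) + 1
        for chunk in np.split(dates, breaks):
            start, end = int(chunk[0]), int(chunk[-1])
            duration = end - start
            rows.append((pid, atc, start, end, duration, duration >= min_adequate_days))
    out = pd.DataFrame(
        rows, columns=["patient_id", "atc", "start", "end", "duration_days", "adequate"]
    )
    return out.sort_values(["patient_id", "atc", "start"], ignore_index=True)


def count_adequate_antidepressants(
    episodes: pd.DataFrame, atc_prefix: str = ATC_ANTIDEPRESSANT_PREFIX
) -> pd.Series:
    """Count, per patient, DISTINCT full ATC codes with >=1 adequate episode.

    "Two different antidepressants" means two different substances (full
    7-character codes), not two episodes; codes outside ``atc_prefix``
    (lithium, say) do not count.
    """
    if len(episodes) == 0:
        return pd.Series(dtype=int, name="n_adequate")
    mask = episodes["adequate"] & episodes["atc"].str.startswith(atc_prefix)
    sub = episodes[mask]
    counts = sub.groupby("patient_id")["atc"].nunique()
    counts.name = "n_adequate"
    return counts


def flag_lithium_users(records: pd.DataFrame) -> pd.Series:
    """Per-patient flag: at least one lithium (N05AN01) dispense ever."""
    if len(records) == 0:
        return pd.Series(dtype=bool, name="lithium_user")
    flags = (
        records.assign(is_li=records["atc"] == ATC_LITHIUM)
        .groupby("patient_id")["is_li"]
        .any()
    )
    flags.name = "lithium_user"
    return flags


def first_ect_dates(ect: pd.DataFrame) -> pd.Series:
    """Reduce an ECT register to the first treatment date per patient."""
    if len(ect) == 0:
        return pd.Series(dtype=float, name="first_ect")
    s = ect.groupby("patient_id")["date"].min()
    s.name = "first_ect"
    return s


def classify(
    patients,
    records: pd.DataFrame,
    ect: pd.DataFrame,
    definition: str,
    gap_days: int = 120,
    min_adequate_days: int = 42,
) -> pd.DataFrame:
    """Assign TRD / non-TRD / excluded labels under one definition.

    ``patients`` is the full MDD case list (an input, not derived from the
    registers); every patient with an ECT record must appear in it.

    Returns one row per patient with columns ``patient_id, definition,
    status, n_adequate, any_antidepressant_before_ect, lithium_user,
    ever_ect``. Under the narrow definitions ``n_adequate`` is the
    ECT-censored count for ECT patients and the uncensored count
    otherwise, i.e. the count the classification rule actually used.
    """
    if definition not in DEFINITIONS:
        raise ValueError(f"unknown definition {definition!r}; expected one of {DEFINITIONS}")
    patients = pd.Index(patients, name="patient_id")
    if patients.has_duplicates:
        raise ValueError("duplicate patient ids in patient list")
    _check_records(records)

    first_ect = first_ect_dates(ect)
    unknown = first_ect.index.difference(patients)
    if len(unknown) > 0:
        raise ValueError(
            f"ECT records for patients absent from the patient list: {list(unknown)[:5]}"
        )
    ever_ect = pd.Series(False, index=patients)
    ever_ect.loc[first_ect.index] = True

    is_ad = records["atc"].str.startswith(ATC_ANTIDEPRESSANT_PREFIX)
    any_ad = pd.Series(False, index=patients)
    got = records.loc[is_ad].groupby("patient_id").size()
    any_ad[any_ad.index.intersection(got.index)] = True

    before = records.loc[is_ad].merge(
        first_ect.rename("first_ect"), left_on="patient_id", right_index=True
    )
    ad_before_ect = pd.Series(False, index=patients)
    pre = before[before["date"] < before["first_ect"]]["patient_id"].unique()
    ad_before_ect.loc[pre] = True
    # for non-ECT patients the "before first ECT" qualifier is vacuous
    ad_before_ect = ad_before_ect.where(ever_ect, any_ad)

    epis_cens = build_episodes(records, gap_days, min_adequate_days, censor_date=first_ect)
    epis_full = build_episodes(records, gap_days, min_adequate_days)
    n_cens = count_adequate_antidepressants(epis_cens).reindex(patients, fill_value=0)
    n_full = count_adequate_antidepressants(epis_full).reindex(patients, fill_value=0)

    lithium = flag_lithium_users(records).reindex(patients, fill_value=False)

    if definition == "broad":
        status = np.where(ever_ect, TRD, NON_TRD)
        n_used = n_full
    else:
        need = 1 if definition == "narrow_1" else 2
        is_trd = ever_ect & (n_cens >= need)
        is_non = ~ever_ect & any_ad & (n_full <= 2)
        status = np.where(is_trd, TRD, np.where(is_non, NON_TRD, EXCLUDED))
        n_used = n_cens.where(ever_ect, n_full)

    return pd.DataFrame(
        {
            "patient_id": patients,
            "definition": definition,
            "status": status,
            "n_adequate": n_used.to_numpy(),
            "any_antidepressant_before_ect": ad_before_ect.to_numpy(),
            "lithium_user": lithium.to_numpy(),
            "ever_ect": ever_ect.to_numpy(),
        }
    )


def assign_labels(
    patients,
    records: pd.DataFrame,
    ect: pd.DataFrame,
    gap_days: int = 120,
    min_adequate_days: int = 42,
    definitions=DEFINITIONS,
) -> pd.DataFrame:
    """Labels under several definitions, stacked long (one row per patient per definition)."""
    frames = [
        classify(patients, records, ect, d, gap_days, min_adequate_days)
        for d in definitions
    ]
    return pd.concat(frames, ignore_index=True)
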