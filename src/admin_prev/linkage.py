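"""Deterministic linkage of administrative sources and case-finding.

The three event-level databases share one anonymised person identifier, so
linkage is an exact merge: records are aggregated per person and source into
a person profile carrying per-source record counts and the capture pattern.
Case-finding is the ">= k records during the study window" rule; k counts
events, not distinct databases, so two hospital rows satisfy k = 2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .caprecap import CaptureTable
from .synth import SOURCES

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "person_id", "n_records_total",
    *[f"n_{s}" for s in SOURCES],
    *[f"cap_{s}" for s in SOURCES],
    "resident", "sex", "birth_year", "area",
]


def link_sources(records: pd.DataFrame,
                 persons: pd.DataFrame | None = None,
                 on_unknown: str = "warn") -> pd.DataFrame:
    """Aggregate event records into one profile per person.

    Parameters
    ----------
    records
        Event rows with columns ``person_id``, ``source`` (one of
        hospital/drug/outpatient), ``year``, ``code``, ``area``.
    persons
        Optional person attribute table (``person_id``, ``sex``,
        ``birth_year``, ``area``, ``resident``); attributes are joined onto
        the profiles.  Records whose id is absent from this table are kept
        with a logged warning by default, or rejected with
        ``on_unknown="fail"``.
    """
    if on_unknown not in ("warn", "fail"):
        raise ValueError("on_unknown must be 'warn' or 'fail'")
    if records.empty:
        profiles = pd.DataFrame(columns=PROFILE_COLUMNS)
        return profiles.astype({"person_id": np.int64}, errors="ignore")

    bad = ~records["source"].isin(SOURCES)
    if bad.any():
        raise ValueError(
            f"unknown source values: {sorted(records.loc[bad, 'source'].unique())}"
        )

    counts = (
        records.groupby(["person_id", "source"], sort=True)
        .size()
        .unstack("source", fill_value=0)
        .reindex(columns=list(SOURCES), fill_value=0)
    )
    profiles = counts.reset_index()
    profiles.columns = ["person_id"] + [f"n_{s}" for s in SOURCES]
    profiles["n_records_total"] = sum(
        profiles[f"n_{s}"] for s in SOURCES
    )
    for s in SOURCES:
        profiles[f"cap_{s}"] = (profiles[f"n_{s}"] >= 1).astype(np.int8)

    if persons is not None:
        attrs = persons.set_index("person_id")[
            ["sex", "birth_year", "area", "resident"]
        ]
        unknown = ~profiles["person_id"].isin(attrs.index)
        n_unknown = int(unknown.sum())
        if n_unknown:
            msg = f"{n_unknown} record person_id(s) missing from person table"
            if on_unknown == "fail":
                raise ValueError(msg)
            logger.warning(msg)
        profiles = profiles.merge(
            attrs, how="left", left_on="person_id", right_index=True
        )
    else:
        for col in ("sex", "birth_year", "area"):
            profiles[col] = pd.NA
        profiles["resident"] = True
    return profiles[PROFILE_COLUMNS]


def filter_residents(profiles: pd.DataFrame) -> pd.DataFrame:
    """Drop profiles of persons not resident in the region."""
    resident = profiles["resident"].fillna(False).astype(bool)
    removed = int((~resident).sum())
    if removed:
        logger.info("filtered out %d non-resident profile(s)", removed)
    return profiles.loc[resident].reset_index(drop=True)


def apply_algorithm(profiles: pd.DataFrame, min_records: int = 1
                    ) -> np.ndarray:
    """Case-finding rule: ids with at least ``min_records`` records.

    Monotone: the k+1 case set is a subset of the k case set.
    """
    if min_records < 1:
        raise ValueError("min_records must be >= 1")
    hit = profiles["n_records_total"] >= min_records
    return np.sort(profiles.loc[hit, "person_id"].to_numpy())


def venn_partition(case_profiles: pd.DataFrame) -> CaptureTable:
    """The 7-cell source-overlap table of the identified cases."""
    pats = case_profiles[[f"cap_{s}" for s in SOURCES]].to_numpy()
    if (pats.sum(axis=1) == 0).any():
        raise ValueError("case profile with empty capture pattern")
    return CaptureTable.from_patterns(map(tuple, pats))


def dedupe_exact(records: pd.DataFrame) -> pd.DataFrame:
    """Optionally drop byte-identical record rows (off by default: repeated
    identical claims are legitimate in refund data)."""
    return records.drop_duplicates(ignore_index=True)
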