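"""Donor-to-recipient virus transfer tracking across the FMT time course.

Every virus (HV group or singleton) ever detected in a recipient is assigned
exactly one baseline-defined category:

* ``shared_preFMT``  — present in both recipient and paired donor at week 0;
* ``unique_preFMT``  — present in the recipient at week 0 but not the donor;
* ``invading``       — present in the donor at week 0, absent from the
  recipient at week 0, and detected in the recipient after FMT;
* ``new``            — detected after FMT but present in neither baseline.

Controls received their own stool, so their donor baseline is empty by
construction and only ``unique_preFMT``/``new`` can occur.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AbundanceMatrix, StudyDesign, RECIPIENT_ROLES, TREATED_ROLES

logger = logging.getLogger(__name__)

CATEGORIES = ("shared_preFMT", "unique_preFMT", "invading", "new")


def _present_set(presence: pd.DataFrame, sample: str | None) -> set[str]:
    if sample is None:
        return set()
    return set(presence.index[presence[sample]])


def classify_categories(presence: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Assign one transfer category per (recipient, ever-present virus).

    ``presence`` is a virus x sample boolean mask (presence rule already
    applied). Raises if a recipient, or a treated recipient's donor, lacks a
    week-0 sample.
    """
    records: list[tuple[str, str, str]] = []
    for recipient in design.subjects(RECIPIENT_ROLES):
        s0 = design.sample_id(recipient, 0)
        if s0 is None:
            raise ValueError(f"recipient {recipient!r} has no week-0 sample")
        r0 = _present_set(presence, s0)
        donor = design.donor_of(recipient)
        if design.roles[recipient] in TREATED_ROLES:
            d0_sample = design.sample_id(donor, 0)
            if d0_sample is None:
                raise ValueError(
                    f"donor {donor!r} of recipient {recipient!r} has no week-0 sample"
                )
            d0 = _present_set(presence, d0_sample)
        else:
            d0 = set()  # self-stool transplant: no external donor baseline
        post: set[str] = set()
        for week in design.weeks_of(recipient):
            if week > 0:
                post |= _present_set(presence, design.sample_id(recipient, week))

        for virus in r0 & d0:
            records.append((recipient, virus, "shared_preFMT"))
        for virus in r0 - d0:
            records.append((recipient, virus, "unique_preFMT"))
        for virus in (d0 - r0) & post:
            records.append((recipient, virus, "invading"))
        for virus in post - r0 - d0:
            records.append((recipient, virus, "new"))

    out = pd.DataFrame(records, columns=["recipient", "virus", "category"])
    return out.sort_values(["recipient", "category", "virus"]).reset_index(drop=True)


def category_trajectories(
    rpkm: AbundanceMatrix,
    presence: pd.DataFrame,
    assignment: pd.DataFrame,
    design: StudyDesign,
) -> pd.DataFrame:
    """Per recipient/week cumulative relative abundance of each category.

    The fraction for a category at a week is the summed abundance of that
    category's present viruses divided by the summed abundance of all present
    viruses; weeks with nothing present are emitted as missing.
    """
    rows: list[tuple[str, int, str, float]] = []
    cat_of = {(r, v): c for r, v, c in assignment.itertuples(index=False)}
    for recipient in design.subjects(RECIPIENT_ROLES):
        for week in design.weeks_of(recipient):
            sample = design.sample_id(recipient, week)
            present = _present_set(presence, sample)
            total = float(rpkm.values.loc[sorted(present), sample].sum()) if present else 0.0
            if total <= 0:
                logger.warning("recipient %s week %d: no present viruses; "
                               "fractions undefined", recipient, week)
                for cat in CATEGORIES:
                    rows.append((recipient, week, cat, np.nan))
                continue
            for cat in CATEGORIES:
                members = sorted(
                    v for v in present if cat_of.get((recipient, v)) == cat
                )
                mass = float(rpkm.values.loc[members, sample].sum()) if members else 0.0
                rows.append((recipient, week, cat, mass / total))
    return pd.DataFrame(rows, columns=["recipient", "week", "category", "fraction"])


def invading_dynamics(
    rpkm: AbundanceMatrix,
    presence: pd.DataFrame,
    assignment: pd.DataFrame,
    design: StudyDesign,
) -> tuple[pd.DataFrame, pd.Series]:
    """Invading-virus counts and cumulative abundance per recipient/week.

    Returns a per-week table (n_invading, fraction of present-community
    abundance) and a per-recipient total of distinct invading viruses detected
    in at least one post-FMT time point.
    """
    inv_of: dict[str, set[str]] = {}
    for r, v, c in assignment.itertuples(index=False):
        if c == "invading":
            inv_of.setdefault(r, set()).add(v)
    rows: list[tuple[str, int, int, float]] = []
    totals: dict[str, int] = {}
    for recipient in design.subjects(RECIPIENT_ROLES):
        invaders = inv_of.get(recipient, set())
        totals[recipient] = len(invaders)
        for week in design.weeks_of(recipient):
            sample = design.sample_id(recipient, week)
            present = _present_set(presence, sample)
            here = sorted(invaders & present)
            total = float(rpkm.values.loc[sorted(present), sample].sum()) if present else 0.0
            mass = float(rpkm.values.loc[here, sample].sum()) if here else 0.0
            frac = mass / total if total > 0 else 0.0
            rows.append((recipient, week, len(here), frac))
    per_week = pd.DataFrame(rows, columns=["recipient", "week", "n_invading", "fraction"])
    return per_week, pd.Series(totals, name="n_distinct_invading")


def donor_recipient_abundance_fit(
    rpkm: AbundanceMatrix,
    assignment: pd.DataFrame,
    design: StudyDesign,
    min_viruses: int = 3,
) -> pd.Series:
    """Adjusted R^2 of recipient-vs-donor invading-virus abundance, per recipient.

    For each treated recipient, regresses the mean post-FMT abundance of each
    invading virus in the recipient on its abundance in the paired donor at
    week 0 (OLS). Recipients with fewer than ``min_viruses`` invading viruses,
    or a zero-variance donor profile, are skipped (NaN).
    """
    out: dict[str, float] = {}
    inv_of: dict[str, list[str]] = {}
    for r, v, c in assignment.itertuples(index=False):
        if c == "invading":
            inv_of.setdefault(r, []).append(v)
    for recipient in design.subjects(TREATED_ROLES):
        invaders = sorted(inv_of.get(recipient, []))
        if len(invaders) < min_viruses:
            logger.warning("recipient %s: %d < %d invading viruses; fit skipped",
                           recipient, len(invaders), min_viruses)
            out[recipient] = np.nan
            continue
        donor = design.donor_of(recipient)
        x = rpkm.values.loc[invaders, design.sample_id(donor, 0)].to_numpy(dtype=float)
        post = [design.sample_id(recipient, w) for w in design.weeks_of(recipient) if w > 0]
        y = rpkm.values.loc[invaders, post].mean(axis=1).to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("recipient %s: zero-variance donor abundances; fit skipped",
                           recipient)
            out[recipient] = np.nan
            continue
        n = len(invaders)
        res = sps.linregress(x, y)
        r2 = res.rvalue ** 2
        out[recipient] = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return pd.Series(out, name="adjusted_r2")
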