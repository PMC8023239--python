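"""Outcome-discriminant HV selection, contig scoring, and clinical association.

From the SIMPER decomposition, HV groups that separate responders from
non-responders (cumulative fraction < 0.7 and permutation p < 0.05, both
strict) are selected. Member contigs are scored for assay (qPCR) design with
a responder-enrichment score, HV abundance is related to the %Rd clinical
outcome by OLS, and marker performance is summarized by Mann-Whitney ROC/AUC
and a high/low-marker prevalence contingency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AbundanceMatrix, StudyDesign
from .hv import HVGrouping

logger = logging.getLogger(__name__)


def select_discriminant_hvs(
    simper_records: pd.DataFrame,
    max_cumulative: float = 0.7,
    max_p: float = 0.05,
) -> list[str]:
    """HV ids with cumulative SIMPER fraction < ``max_cumulative`` and
    permutation p < ``max_p`` (both inequalities strict)."""
    keep = (simper_records["cumulative"] < max_cumulative) & (simper_records["p"] < max_p)
    return list(simper_records.loc[keep, "virus_id"])


def _subject_samples(design: StudyDesign, roles: tuple[str, ...]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for subject in design.subjects(roles):
        out[subject] = list(design.samples.loc[
            design.samples["subject_id"] == subject, "sample_id"])
    return out


def score_contigs(
    rpkm: AbundanceMatrix,
    presence: pd.DataFrame,
    design: StudyDesign,
    hv_subset: dict[str, frozenset[str]] | HVGrouping,
) -> pd.DataFrame:
    """Score member contigs of candidate HV groups for assay design.

    R-score = (total RPKM over responder + donor samples) x (number of
    responder/donor subjects in which the contig is present); N-score is the
    analogue over non-responders. Score = R-score / (N-score + 1) x median_r,
    where median_r is the median per-sample abundance of the contig across
    responder + donor samples in which it is present (0 when present in
    none). A subject "has" a contig if it is present in any of its samples.
    Rows are ranked per HV group by descending score.
    """
    groups = hv_subset.groups if isinstance(hv_subset, HVGrouping) else hv_subset
    r_samples = _subject_samples(design, ("responder", "donor"))
    n_samples = _subject_samples(design, ("non_responder",))
    r_all = [s for ss in r_samples.values() for s in ss]
    n_all = [s for ss in n_samples.values() for s in ss]
    if not r_all:
        raise ValueError("no responder or donor samples to score against")

    rows = []
    for hv_id in sorted(groups):
        for contig in sorted(groups[hv_id]):
            if contig not in rpkm.values.index:
                raise KeyError(f"contig {contig!r} of {hv_id} missing from matrix")
            vals = rpkm.values.loc[contig]
            pres = presence.loc[contig]
            r_total = float(vals[r_all].sum())
            n_total = float(vals[n_all].sum())
            n_r = sum(1 for ss in r_samples.values() if pres[ss].any())
            n_n = sum(1 for ss in n_samples.values() if pres[ss].any())
            present_r_vals = vals[[s for s in r_all if pres[s]]]
            median_r = float(present_r_vals.median()) if len(present_r_vals) else 0.0
            r_score = r_total * n_r
            n_score = n_total * n_n
            score = r_score / (n_score + 1.0) * median_r
            rows.append((contig, hv_id, r_total, n_total, n_r, n_n,
                         r_score, n_score, median_r, score))
    out = pd.DataFrame(rows, columns=[
        "contig_id", "hv_id", "r_total_rpkm", "n_total_rpkm",
        "n_r_present", "n_n_present", "r_score", "n_score", "median_r", "score",
    ])
    out = out.sort_values(["hv_id", "score", "contig_id"],
                          ascending=[True, False, True]).reset_index(drop=True)
    out["rank_in_hv"] = out.groupby("hv_id").cumcount() + 1
    return out


@dataclass
class RdModel:
    slope: float
    intercept: float
    adjusted_r2: float
    p: float


def fit_rd_model(
    hv_abundance: pd.Series,
    rd_increase_pct: pd.Series,
    exclusions: tuple[str, ...] = (),
) -> RdModel:
    """OLS of %Rd increase on HV abundance across subjects.

    ``exclusions`` removes named subjects (the trial excluded one outlying
    control from this analysis). Requires >= 4 subjects and a non-degenerate
    predictor.
    """
    subjects = [s for s in hv_abundance.index
                if s in rd_increase_pct.index and s not in exclusions]
    if len(subjects) < 4:
        raise ValueError(f"need >= 4 subjects for the Rd model, have {len(subjects)}")
    x = hv_abundance.loc[subjects].to_numpy(dtype=float)
    y = rd_increase_pct.loc[subjects].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero-variance HV abundance; Rd model is degenerate")
    res = sps.linregress(x, y)
    n = len(subjects)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RdModel(float(res.slope), float(res.intercept), float(adj), float(res.pvalue))


def roc_auc(abundance: pd.Series, responder_flags: pd.Series,
            exact_cutoff: int = 20) -> tuple[float, float]:
    """AUC (rank/Mann-Whitney form, ties counted 1/2) with a U-test p-value.

    The p-value comes from the exact Mann-Whitney null for small samples
    without ties and the normal approximation otherwise (two-sided).
    """
    flags = responder_flags.loc[abundance.index].astype(bool)
    pos = abundance[flags].to_numpy(dtype=float)
    neg = abundance[~flags].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs both responders and non-responders")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    auc = float(u / (len(pos) * len(neg)))
    method = "exact" if (len(pos) + len(neg) <= exact_cutoff
                         and len(np.unique(np.concatenate([pos, neg])))
                         == len(pos) + len(neg)) else "asymptotic"
    p = float(sps.mannwhitneyu(pos, neg, alternative="two-sided", method=method).pvalue)
    return auc, p


def flag_high_hv(
    marker_abundance: pd.DataFrame,
    threshold: float,
    min_markers: int = 2,
) -> pd.Series:
    """Per-subject flag: True iff >= ``min_markers`` marker columns exceed
    ``threshold`` (the paper's 2-of-3-markers rule)."""
    if marker_abundance.shape[1] == 0:
        raise ValueError("marker set must be non-empty")
    n_above = (marker_abundance > threshold).sum(axis=1)
    return n_above >= min_markers


def prevalence_table(high_flags: pd.Series, responder_flags: pd.Series) -> dict:
    """2x2 high-marker x responder contingency with rounded percentages."""
    flags = high_flags.astype(bool)
    resp = responder_flags.loc[flags.index].astype(bool)
    n_high = int(flags.sum())
    n_low = int((~flags).sum())
    resp_high = int((flags & resp).sum())
    resp_low = int((~flags & resp).sum())
    n_total = len(flags)

    def pct(num: int, den: int) -> int | None:
        # round half away from zero, as percentages are conventionally printed
        return int(np.floor(100.0 * num / den + 0.5)) if den else None

    return {
        "n_high": n_high,
        "n_low": n_low,
        "responders_high": resp_high,
        "responders_low": resp_low,
        "pct_responders_high": pct(resp_high, n_high),
        "pct_responders_low": pct(resp_low, n_low),
        "n_total": n_total,
        "responders_total": resp_high + resp_low,
        "pct_responders_total": pct(resp_high + resp_low, n_total),
    }
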