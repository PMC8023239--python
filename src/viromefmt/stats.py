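"""First-principles community ordination statistics.

Bray-Curtis dissimilarity, classical principal coordinates analysis (PCO),
distance-based PERMANOVA with a permutation p-value, and SIMPER
(similarity-percentage) decomposition with per-taxon permutation p-values.
These are implemented directly from their definitions; the permutation
machinery is vectorized and seed-deterministic throughout. Permutation
p-values use the add-one estimator (1 + #{perm >= obs}) / (1 + n_perm), so
p is never zero at finite permutation counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, StudyDesign, TREATED_ROLES
from .hv import HVGrouping

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.ids):
            raise ValueError("ids do not match matrix dimension")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = d

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def bray_curtis(abundance: AbundanceMatrix | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis d(x, y) = sum|x_i - y_i| / sum(x_i + y_i).

    Sample pairs whose profiles are both all-zero get d = 0 (with a warning),
    the conventional limit for empty communities.
    """
    values = abundance.values if isinstance(abundance, AbundanceMatrix) else abundance
    x = values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    n = x.shape[1]
    num = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
    den = (x[:, :, None] + x[:, None, :]).sum(axis=0)
    empty = den == 0
    if empty[np.triu_indices(n, 1)].any():
        logger.warning("sample pair(s) with no abundance at all: distance set to 0")
    den[empty] = 1.0
    d = num / den
    d[empty] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(values.columns))


def pco(d: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -d^2/2, eigendecomposes, and returns the top-``k`` axes
    scaled by the square root of their eigenvalues, together with the full
    eigenvalue spectrum (negative eigenvalues are reported, not corrected).
    """
    dm = d.values
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(1.0, float(abs(eigvals).max(initial=0.0)))
    rank = int((eigvals > tol).sum())
    if k > rank:
        raise ValueError(f"requested {k} axes but positive rank is {rank}")
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    # deterministic axis orientation: largest-magnitude loading positive
    for a in range(k):
        pivot = np.argmax(np.abs(coords[:, a]))
        if coords[pivot, a] < 0:
            coords[:, a] = -coords[:, a]
    frame = pd.DataFrame(coords, index=d.ids,
                         columns=[f"PCO{a + 1}" for a in range(k)])
    if (eigvals < -1e-9).any():
        logger.info("PCO: %d negative eigenvalues (non-Euclidean input)",
                    int((eigvals < -1e-9).sum()))
    return frame, eigvals


def _group_indicators(labels: np.ndarray) -> list[np.ndarray]:
    return [labels == g for g in np.unique(labels)]


def _pseudo_f(d2: np.ndarray, perms: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of ``perms`` (a matrix of integer group labels).

    Uses the distance-based partition SS_total = sum_{i<j} d2 / N and
    SS_within = sum_g sum_{i<j in g} d2 / n_g; F = (SS_between / (a - 1)) /
    (SS_within / (N - a)). Vectorized via quadratic forms.
    """
    n = d2.shape[0]
    a = len(sizes)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = np.zeros(perms.shape[0])
    for g_idx, n_g in enumerate(sizes):
        ind = (perms == g_idx).astype(float)  # P x n
        ss_within += np.einsum("pi,ij,pj->p", ind, d2, ind) / (2.0 * n_g)
    ss_between = ss_total - ss_within
    denom = ss_within / (n - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (a - 1)) / denom
    f[~np.isfinite(f)] = 0.0
    return f


def permanova(
    d: DistanceMatrix,
    labels: pd.Series | dict[str, str],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Distance-based PERMANOVA pseudo-F and permutation p-value.

    Sample labels are permuted freely (no strata); p uses the add-one
    convention. Requires >= 2 groups, each with >= 2 samples, and
    ``n_perm >= 1``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    labels = pd.Series(labels)
    lab = labels.loc[d.ids].to_numpy()
    groups, codes = np.unique(lab, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = groups[sizes < 2]
        raise ValueError(f"group(s) with fewer than 2 samples: {list(small)}")
    d2 = d.values ** 2
    f_obs = float(_pseudo_f(d2, codes[None, :], sizes)[0])
    if d2.max() == 0:
        return 0.0, 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    f_perm = _pseudo_f(d2, perms, sizes)
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)
    return f_obs, float(p)


def simper(
    abundance: AbundanceMatrix | pd.DataFrame,
    labels: pd.Series | dict[str, str],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Similarity-percentage decomposition between exactly two groups.

    Each taxon's contribution is the mean, over all between-group sample
    pairs, of |x_i - y_i| / sum_j (x_j + y_j); contributions sum to the mean
    between-group Bray-Curtis dissimilarity. Rows are sorted by contribution
    (descending, taxon id breaking ties) with their cumulative fraction, and
    each taxon gets a permutation p-value from relabeling samples.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    values = abundance.values if isinstance(abundance, AbundanceMatrix) else abundance
    labels = pd.Series(labels)
    lab = labels.loc[values.columns].to_numpy()
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError(
            f"SIMPER is a two-group contrast; got groups {list(groups)}"
        )
    x = values.to_numpy(dtype=float)
    v, n = x.shape
    # per-pair per-taxon Bray-Curtis terms: C[i, a, b]
    den = (x[:, :, None] + x[:, None, :]).sum(axis=0)
    den[den == 0] = 1.0
    contrib_terms = np.abs(x[:, :, None] - x[:, None, :]) / den[None, :, :]

    is_a = lab == groups[0]
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())

    def contributions(mask_a: np.ndarray) -> np.ndarray:
        w = np.outer(mask_a, ~mask_a).astype(float) / (n_a * n_b)
        return contrib_terms.reshape(v, n * n) @ w.reshape(n * n)

    obs = contributions(is_a)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masks = rng.permuted(np.tile(is_a, (n_perm, 1)), axis=1)
    weights = (masks[:, :, None] & ~masks[:, None, :]).astype(float) / (n_a * n_b)
    perm_contrib = contrib_terms.reshape(v, n * n) @ weights.reshape(n_perm, n * n).T
    p = (1.0 + (perm_contrib >= obs[:, None]).sum(axis=1)) / (1.0 + n_perm)

    total = obs.sum()
    frac = obs / total if total > 0 else np.zeros_like(obs)
    out = pd.DataFrame({
        "virus_id": values.index,
        "contribution": obs,
        "fraction": frac,
        "p": p,
    }).sort_values(["contribution", "virus_id"], ascending=[False, True])
    out["cumulative"] = out["fraction"].cumsum()
    return out.reset_index(drop=True)[
        ["virus_id", "contribution", "fraction", "cumulative", "p"]
    ]


def donor_shared_hvs(
    presence: pd.DataFrame,
    design: StudyDesign,
    grouping: HVGrouping | None = None,
) -> list[str]:
    """HV groups shared by at least one donor-recipient pair.

    A group qualifies when it is present in a donor at week 0 and in that
    donor's paired recipient at any week. Singleton rows are excluded when a
    grouping is supplied.
    """
    shared: set[str] = set()
    for recipient in design.subjects(TREATED_ROLES):
        donor = design.donor_of(recipient)
        d0_sample = design.sample_id(donor, 0)
        if d0_sample is None:
            continue
        d0 = set(presence.index[presence[d0_sample]])
        rec: set[str] = set()
        for week in design.weeks_of(recipient):
            rec |= set(presence.index[presence[design.sample_id(recipient, week)]])
        shared |= d0 & rec
    if grouping is not None:
        shared &= set(grouping.groups)
    return sorted(shared)
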