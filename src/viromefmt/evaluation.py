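"""End-to-end evaluation routines: oracles, calibration, recovery, determinism.

Each function here re-runs a slice of the pipeline from scratch and measures
it against an independent reference: a brute-force oracle (transitive-closure
clustering, exhaustive ROC pair counting, the SIMPER/Bray-Curtis
decomposition identity), the statistical null (permutation and t-test
calibration), the synthetic generator's ground truth (category and
discriminant-HV recovery), or a byte-level rerun (determinism).
"""

from __future__ import annotations

import hashlib
import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import biomarker as bm
from . import hv as hvmod
from . import stats as st
from . import transfer as tr
from .pipeline import load_config, run_pipeline
from .simulate import SimParams, simulate_study, write_fixtures

# ---------------------------------------------------------------------------
# prevalence contingency from the published trial counts
# ---------------------------------------------------------------------------

#: The treated-arm screening cohort: 26 subjects, 12 with high marker-phage
#: levels (10 of them responders), 14 with low levels (7 responders).
TRIAL_COHORT = {"n_high": 12, "responders_high": 10,
                "n_low": 14, "responders_low": 7}


def trial_prevalence() -> dict:
    """Reconstruct the screening cohort subject-by-subject and tabulate it."""
    c = TRIAL_COHORT
    rows = []
    for i in range(c["n_high"]):
        rows.append((f"high_{i}", True, i < c["responders_high"]))
    for i in range(c["n_low"]):
        rows.append((f"low_{i}", False, i < c["responders_low"]))
    subjects = [r[0] for r in rows]
    high = pd.Series([r[1] for r in rows], index=subjects)
    resp = pd.Series([r[2] for r in rows], index=subjects)
    return bm.prevalence_table(high, resp)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def closure_partition(edges: list[tuple[str, str]], nodes: list[str]) -> set[frozenset]:
    """Transitive-closure oracle: merge pairwise until fixpoint."""
    parts: list[set[str]] = [{n} for n in nodes]
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            pa = next(p for p in parts if a in p)
            pb = next(p for p in parts if b in p)
            if pa is not pb:
                pa |= pb
                parts.remove(pb)
                changed = True
    return {frozenset(p) for p in parts}


def clustering_oracle_agreement(n_graphs: int = 100, seed: int = 0,
                                max_nodes: int = 50) -> float:
    """Fraction of random graphs where HV grouping equals the closure oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        nodes = [f"c{i}" for i in range(n)]
        n_edges = int(rng.integers(0, 2 * n))
        edges = []
        for _ in range(n_edges):
            a, b = rng.choice(n, size=2, replace=False)
            edges.append(tuple(sorted((nodes[a], nodes[b]))))
        edges = sorted(set(edges))
        grouping = hvmod.build_hv_groups(edges, nodes)
        got = {frozenset(m) for m in grouping.groups.values()} | {
            frozenset({s}) for s in grouping.singletons}
        agree += got == closure_partition(edges, nodes)
    return agree / n_graphs


def auc_pair_oracle(pos: np.ndarray, neg: np.ndarray) -> float:
    """Exhaustive pair-counting AUC (ties counted 1/2)."""
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def auc_oracle_max_diff(n_trials: int = 100, seed: int = 0,
                        max_subjects: int = 20) -> float:
    """Max |AUC - pair-counting oracle| over random small cohorts (with ties)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        n = int(rng.integers(4, max_subjects + 1))
        n_pos = int(rng.integers(1, n))
        values = np.round(rng.normal(size=n), 1)  # rounding induces ties
        flags = np.zeros(n, bool)
        flags[rng.choice(n, size=n_pos, replace=False)] = True
        abund = pd.Series(values, index=[f"s{i}" for i in range(n)])
        auc, _ = bm.roc_auc(abund, pd.Series(flags, index=abund.index))
        oracle = auc_pair_oracle(values[flags], values[~flags])
        worst = max(worst, abs(auc - oracle))
    return worst


def simper_identity_max_error(n_tables: int = 100, seed: int = 0) -> float:
    """Max |sum of SIMPER contributions - mean between-group Bray-Curtis|."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        n_a = int(rng.integers(2, 5))
        n_b = int(rng.integers(2, 5))
        v = int(rng.integers(2, 9))
        x = rng.lognormal(0, 1, size=(v, n_a + n_b))
        cols = [f"s{i}" for i in range(n_a + n_b)]
        table = pd.DataFrame(x, index=[f"v{i}" for i in range(v)], columns=cols)
        labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=cols)
        records = st.simper(table, labels, n_perm=1, seed=rng)
        d = st.bray_curtis(table).as_frame()
        mean_between = float(d.iloc[:n_a, n_a:].to_numpy().mean())
        worst = max(worst, abs(records["contribution"].sum() - mean_between))
    return worst


# ---------------------------------------------------------------------------
# statistical calibration under the null
# ---------------------------------------------------------------------------

def permanova_null_rejection_rate(n_sims: int = 1000, n_perm: int = 999,
                                  seed: int = 0, n_per_group: int = 6,
                                  n_viruses: int = 10,
                                  alpha: float = 0.05) -> float:
    """Type-I error of the PERMANOVA permutation test on exchangeable data."""
    rng = np.random.default_rng(seed)
    cols = [f"s{i}" for i in range(2 * n_per_group)]
    labels = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=cols)
    reject = 0
    for _ in range(n_sims):
        x = rng.lognormal(0, 1, size=(n_viruses, 2 * n_per_group))
        table = pd.DataFrame(x, index=[f"v{i}" for i in range(n_viruses)],
                             columns=cols)
        _, p = st.permanova(st.bray_curtis(table), labels, n_perm=n_perm, seed=rng)
        reject += p <= alpha
    return reject / n_sims


def ols_null_rejection_rate(n_sims: int = 1000, n_subjects: int = 8,
                            seed: int = 0, alpha: float = 0.05) -> float:
    """Type-I error of the OLS slope t-test with independent Gaussian data."""
    rng = np.random.default_rng(seed)
    reject = 0
    idx = [f"s{i}" for i in range(n_subjects)]
    for _ in range(n_sims):
        x = pd.Series(rng.normal(size=n_subjects), index=idx)
        y = pd.Series(rng.normal(size=n_subjects), index=idx)
        model = bm.fit_rd_model(x, y)
        reject += model.p <= alpha
    return reject / n_sims


# ---------------------------------------------------------------------------
# generator ground-truth recovery
# ---------------------------------------------------------------------------

def _analyze(study, presence_rpkm: float = 7.0, depth: int | None = None,
             seed: int = 0):
    """Minimal in-memory normalization chain shared by the recovery checks."""
    counts = study.counts
    if study.flags_16s:
        counts = ab.drop_16s(counts, set(study.flags_16s))
    if depth is not None:
        counts = ab.subsample_counts(counts, depth=depth, seed=seed)
    rpkm_contig = ab.compute_rpkm(counts)
    presence_contig = ab.apply_presence(rpkm_contig, presence_rpkm)
    gated = rpkm_contig.copy_with(rpkm_contig.values.where(presence_contig, 0.0))
    edges = hvmod.filter_hits(study.hits, study.catalog)
    grouping = hvmod.build_hv_groups(
        edges, [c for c in study.catalog.index if c not in study.flags_16s])
    rpkm_hv = ab.aggregate_to_hv(gated, grouping, include_singletons=True)
    presence_hv = ab.apply_presence(rpkm_hv, presence_rpkm)
    return grouping, rpkm_hv, presence_hv


def _true_id_of_group(members: frozenset[str]) -> str | None:
    """Recovered groups are mapped to generator virus ids via contig names."""
    origins = {c.split("_c")[0] for c in members}
    return origins.pop() if len(origins) == 1 else None


def category_recovery(params: SimParams | None = None) -> tuple[bool, bool]:
    """(HV partition exact, category classification exact) on one study."""
    params = params or SimParams()
    study = simulate_study(params)
    grouping, _, presence_hv = _analyze(study)
    got_partition = {frozenset(m) for m in grouping.groups.values()}
    partition_ok = got_partition == study.truth.partition()

    gmap = {gid: _true_id_of_group(m) for gid, m in grouping.groups.items()}
    gmap.update({s: s for s in grouping.singletons})
    assignment = tr.classify_categories(presence_hv, study.design)
    recovered: dict[str, dict[str, str]] = {}
    for r, v, c in assignment.itertuples(index=False):
        recovered.setdefault(r, {})[gmap.get(v, v)] = c
    truth = {r: dict(v) for r, v in study.truth.categories.items() if v}
    categories_ok = recovered == truth
    return partition_ok, categories_ok


def discriminant_recovery_rate(n_seeds: int = 100, seed: int = 0,
                               n_perm: int = 1000,
                               max_cumulative: float = 0.7,
                               max_p: float = 0.05) -> float:
    """Fraction of seeds where all planted biomarker HVs are selected.

    For each seed, a fresh synthetic study is generated, normalized, reduced
    to the donor-shared HV subset, contrasted responder vs non-responder with
    SIMPER, and the planted biomarker groups are checked for membership in
    the selected discriminant set.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        study = simulate_study(SimParams(seed=int(rng.integers(2 ** 31))))
        grouping, rpkm_hv, presence_hv = _analyze(study)
        shared = st.donor_shared_hvs(presence_hv, study.design, grouping)
        roles = study.design.samples.set_index("sample_id")["role"]
        rn = [s for s in rpkm_hv.values.columns
              if roles[s] in ("responder", "non_responder")]
        table = rpkm_hv.values.loc[shared, rn]
        records = st.simper(table, roles[rn], n_perm=n_perm, seed=rng)
        selected = set(bm.select_discriminant_hvs(records, max_cumulative, max_p))
        gmap = {gid: _true_id_of_group(m) for gid, m in grouping.groups.items()}
        selected_true = {gmap.get(s) for s in selected}
        hits += set(study.truth.biomarker_hv_ids) <= selected_true
    return hits / n_seeds


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def _digest_dir(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(path.iterdir()):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def pipeline_determinism(work_dir: str | Path, seed: int = 0) -> bool:
    """Simulate, then run the full pipeline twice; compare outputs bytewise."""
    work = Path(work_dir)
    study = simulate_study(SimParams(seed=seed))
    fixtures = work / "fixtures"
    write_fixtures(study, fixtures)
    config = load_config(None)
    config["inputs"]["flags_16s"] = "16s_flags.txt"
    run_pipeline(config, seed=seed, out_dir=work / "run1", in_dir=fixtures)
    run_pipeline(config, seed=seed, out_dir=work / "run2", in_dir=fixtures)
    return _digest_dir(work / "run1") == _digest_dir(work / "run2")
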