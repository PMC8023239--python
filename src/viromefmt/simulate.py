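"""Seeded synthetic FMT-virome study generator.

Produces a complete desk-scale study — contig catalog, all-vs-all similarity
hit table, contig x sample read counts, study metadata and ground truth — so
every downstream stage (clustering, normalization, transfer tracking,
ordination, biomarker selection) is testable end to end without external
data.

The forward model, briefly:

* viruses are HV groups (several contigs each) plus singleton contigs;
  within-group contig pairs get similarity hits passing the clustering
  filters, decoy cross-group pairs get only sub-threshold hits;
* each recipient is allocated a disjoint set of viruses, split into the four
  transfer categories per arm (treatment: shared/unique/invading/new;
  control: unique/new only); donors carry the union of their recipients'
  shared + invading viruses plus private extras, sampled at week 0 only;
* per sample, present viruses receive log-normal relative abundances (floored
  so every present virus clears the RPKM presence threshold at the default
  depth), spread over member contigs proportionally to length, and reads are
  allocated by a multinomial at the configured constant depth — optionally
  gamma-overdispersed (0 = pure multinomial);
* the %Rd clinical outcome is baseline + effect x standardized log biomarker
  abundance (week 6) + Gaussian noise, so designated biomarker HV groups —
  planted as shared viruses of every responder and absent from all
  non-responders — carry the outcome signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .io import AbundanceMatrix, StudyDesign

CATEGORY_KEYS = ("shared_preFMT", "unique_preFMT", "invading", "new")

DEFAULT_TREATMENT_MIX = {
    "shared_preFMT": 0.24, "unique_preFMT": 0.35, "invading": 0.16, "new": 0.25,
}
DEFAULT_CONTROL_MIX = {
    "shared_preFMT": 0.0, "unique_preFMT": 0.8, "invading": 0.0, "new": 0.2,
}


@dataclass
class SimParams:
    """Generative parameters of the synthetic study (defaults = study design)."""

    n_donors: int = 5
    n_controls: int = 3
    n_responders: int = 3
    n_non_responders: int = 3
    weeks: tuple[int, ...] = (0, 3, 6, 12, 18)
    n_hv_groups: int = 120
    contigs_per_group: tuple[int, int] = (2, 6)
    singleton_count: int = 60
    contig_length_range: tuple[int, int] = (3000, 40000)
    reads_per_sample: int = 1_367_462
    abundance_lognormal_mu_sigma: tuple[float, float] = (0.0, 1.0)
    viruses_per_recipient: int = 18
    donor_extra_viruses: int = 4
    category_mix: dict = field(default_factory=lambda: {
        "treatment": dict(DEFAULT_TREATMENT_MIX),
        "control": dict(DEFAULT_CONTROL_MIX),
    })
    biomarker_hv_ids: tuple[str, ...] | None = None  # None -> first 3 groups
    biomarker_effect: float = 8.0
    rd_baseline: float = 5.0
    rd_noise_sd: float = 2.0
    noise_overdispersion: float = 0.0
    min_rel_abundance: float = 0.005
    n_16s_contigs: int = 2
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_donors, self.n_controls, self.n_responders,
                  self.n_non_responders, self.n_hv_groups, self.singleton_count,
                  self.viruses_per_recipient, self.donor_extra_viruses,
                  self.n_16s_contigs)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if list(self.weeks) != sorted(set(self.weeks)):
            raise ValueError("weeks must be strictly increasing")
        if 0 not in self.weeks:
            raise ValueError("weeks must include the pre-FMT baseline week 0")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        for arm, mix in self.category_mix.items():
            fracs = [mix.get(c, 0.0) for c in CATEGORY_KEYS]
            if any(f < 0 or f > 1 for f in fracs):
                raise ValueError(f"infeasible category_mix for {arm!r}: "
                                 "fractions must lie in [0, 1]")
            if sum(fracs) > 1 + 1e-9:
                raise ValueError(f"infeasible category_mix for {arm!r}: "
                                 f"fractions sum to {sum(fracs):.3f} > 1")
        ctrl = self.category_mix.get("control", {})
        if ctrl.get("shared_preFMT", 0) or ctrl.get("invading", 0):
            raise ValueError("infeasible category_mix: controls have no donor, "
                             "so shared/invading fractions must be 0")
        if self.noise_overdispersion < 0:
            raise ValueError("noise_overdispersion must be >= 0")
        n_present_max = self.viruses_per_recipient + self.n_16s_contigs
        if n_present_max * self.min_rel_abundance >= 1:
            raise ValueError("min_rel_abundance too large for the community size")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    hv_membership: dict[str, str]          # grouped contig -> true virus id
    singletons: list[str]                  # singleton contig ids
    categories: dict[str, dict[str, str]]  # recipient -> virus -> category
    biomarker_hv_ids: list[str]
    biomarker_rel_abundance: dict[str, float]  # recipient -> week-6 fraction
    rd_increase_pct: dict[str, float]

    def partition(self) -> set[frozenset[str]]:
        """True HV partition as a set of member sets (groups of size >= 2)."""
        by_group: dict[str, set[str]] = {}
        for contig, gid in self.hv_membership.items():
            by_group.setdefault(gid, set()).add(contig)
        return {frozenset(m) for m in by_group.values() if len(m) >= 2}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            hv_membership=dict(d["hv_membership"]),
            singletons=list(d["singletons"]),
            categories={r: dict(v) for r, v in d["categories"].items()},
            biomarker_hv_ids=list(d["biomarker_hv_ids"]),
            biomarker_rel_abundance=dict(d["biomarker_rel_abundance"]),
            rd_increase_pct=dict(d["rd_increase_pct"]),
        )


@dataclass
class SimulatedStudy:
    catalog: pd.Series                # contig -> length (bp)
    hits: pd.DataFrame
    counts: AbundanceMatrix
    design: StudyDesign
    truth: GroundTruth
    flags_16s: list[str]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _category_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n viruses to category fractions."""
    fracs = {c: mix.get(c, 0.0) for c in CATEGORY_KEYS}
    total = sum(fracs.values())
    if total <= 0:
        return {c: 0 for c in CATEGORY_KEYS}
    shares = {c: n * f / total for c, f in fracs.items()}
    counts = {c: int(math.floor(s)) for c, s in shares.items()}
    leftovers = sorted(CATEGORY_KEYS, key=lambda c: shares[c] - counts[c], reverse=True)
    for c in leftovers[: n - sum(counts.values())]:
        counts[c] += 1
    return counts


def _hit_row(q: str, s: str, qlen: float, aln: int, pident: float,
             evalue: float) -> tuple:
    bitscore = round(2.0 * aln * pident / 100.0, 1)
    return (q, s, round(pident, 2), aln, int(aln * (100 - pident) / 100), 0,
            1, aln, 1, aln, evalue, bitscore)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def simulate_study(params: SimParams | None = None) -> SimulatedStudy:
    """Generate the full synthetic study deterministically from the seed."""
    params = params or SimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.contig_length_range
    mu, sigma = params.abundance_lognormal_mu_sigma

    # --- virus universe: HV groups and singleton contigs ------------------
    group_ids = [f"G{i:03d}" for i in range(params.n_hv_groups)]
    group_contigs: dict[str, list[str]] = {}
    lengths: dict[str, int] = {}
    for gid in group_ids:
        k = int(rng.integers(params.contigs_per_group[0],
                             params.contigs_per_group[1] + 1))
        group_contigs[gid] = [f"{gid}_c{j}" for j in range(k)]
        for c in group_contigs[gid]:
            lengths[c] = int(rng.integers(lo, hi + 1))
    singleton_ids = [f"U{i:03d}" for i in range(params.singleton_count)]
    for c in singleton_ids:
        lengths[c] = int(rng.integers(lo, hi + 1))
    flags_16s = [f"X16S_{i}" for i in range(params.n_16s_contigs)]
    for c in flags_16s:
        lengths[c] = int(rng.integers(lo, hi + 1))
    contigs_of = {**group_contigs, **{u: [u] for u in singleton_ids}}

    if params.biomarker_hv_ids is None:
        biomarker_ids: tuple[str, ...] = tuple(group_ids[:3])
    else:
        biomarker_ids = tuple(params.biomarker_hv_ids)
        missing_bm = [b for b in biomarker_ids if b not in group_ids]
        if missing_bm:
            raise ValueError(f"biomarker_hv_ids not among HV groups: {missing_bm}")

    # --- similarity hit table ---------------------------------------------
    hit_rows: list[tuple] = []
    for gid in group_ids:
        members = group_contigs[gid]
        for c in members:
            hit_rows.append(_hit_row(c, c, lengths[c], lengths[c], 100.0, 0.0))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                aln = int(math.ceil(0.8 * min(lengths[a], lengths[b])))
                pident = float(rng.uniform(90, 100))
                ev = 10.0 ** float(-rng.uniform(25, 60))
                # both directions emitted; the shorter-query direction is
                # guaranteed to pass the hsp/query-length filter
                hit_rows.append(_hit_row(a, b, lengths[a], aln, pident, ev))
                hit_rows.append(_hit_row(b, a, lengths[b], aln, pident, ev))
    # decoy cross pairs: strong-but-short and long-but-weak, never qualifying
    all_viruses = group_ids + singleton_ids
    n_decoys = min(params.n_hv_groups, max(0, len(all_viruses) - 1))
    for i in range(n_decoys):
        va, vb = rng.choice(all_viruses, size=2, replace=False)
        a = contigs_of[va][0]
        b = contigs_of[vb][0]
        if i % 2 == 0:  # fails the e-value filter
            aln = int(math.ceil(0.8 * min(lengths[a], lengths[b])))
            ev = 10.0 ** float(-rng.uniform(2, 8))
        else:           # fails the alignment/query-length filter both ways
            aln = max(1, int(math.floor(0.3 * min(lengths[a], lengths[b]))))
            ev = 10.0 ** float(-rng.uniform(25, 40))
        pident = float(rng.uniform(70, 85))
        hit_rows.append(_hit_row(a, b, lengths[a], aln, pident, ev))
        hit_rows.append(_hit_row(b, a, lengths[b], aln, pident, ev))
    hits = pd.DataFrame(hit_rows, columns=vio.HIT_COLUMNS)

    # --- subjects, pairing, sampling schedule ------------------------------
    donors = [f"D{i + 1}" for i in range(params.n_donors)]
    controls = [f"C{i + 1}" for i in range(params.n_controls)]
    non_resp = [f"N{i + 1}" for i in range(params.n_non_responders)]
    responders = [f"R{i + 1}" for i in range(params.n_responders)]
    treated = non_resp + responders
    if treated and not donors:
        raise ValueError("treated recipients require at least one donor")
    pairing = {r: donors[i % len(donors)] for i, r in enumerate(treated)}

    sample_rows = []
    for d in donors:  # donors sampled pre-FMT only
        sample_rows.append((f"{d}_W0", d, "donor", None, 0))
    for subj in controls + treated:
        role = ("control" if subj in controls
                else "non_responder" if subj in non_resp else "responder")
        for w in params.weeks:
            sample_rows.append((f"{subj}_W{w}", subj, role, pairing.get(subj), w))
    samples = pd.DataFrame(sample_rows, columns=[
        "sample_id", "subject_id", "role", "paired_donor_id", "week"])

    # --- allocate viruses to recipients (disjoint; biomarkers reserved) ----
    pool = [v for v in all_viruses if v not in biomarker_ids]
    pool = list(rng.permutation(pool))
    categories: dict[str, dict[str, str]] = {}

    def draw(n: int) -> list[str]:
        take = min(n, len(pool))
        return [pool.pop() for _ in range(take)]

    for subj in controls + treated:
        arm = "control" if subj in controls else "treatment"
        counts = _category_counts(params.category_mix[arm],
                                  params.viruses_per_recipient)
        assigned: dict[str, str] = {}
        if subj in responders:
            for b in biomarker_ids:
                assigned[b] = "shared_preFMT"
            counts["shared_preFMT"] = max(
                0, counts["shared_preFMT"] - len(biomarker_ids))
        for cat in CATEGORY_KEYS:
            for v in draw(counts[cat]):
                assigned[v] = cat
        categories[subj] = assigned

    donor_extras = {d: draw(params.donor_extra_viruses) for d in donors}

    # --- presence schedule --------------------------------------------------
    post_weeks = [w for w in params.weeks if w > 0]
    present: dict[str, list[str]] = {}
    for subj in controls + treated:
        for w in params.weeks:
            here = [v for v, cat in categories[subj].items()
                    if (cat in ("shared_preFMT", "unique_preFMT"))
                    or (w > 0 and cat in ("invading", "new"))]
            present[f"{subj}_W{w}"] = sorted(here)
    for d in donors:
        here = set(donor_extras[d])
        for r, dd in pairing.items():
            if dd == d:
                here |= {v for v, cat in categories[r].items()
                         if cat in ("shared_preFMT", "invading")}
        present[f"{d}_W0"] = sorted(here)

    # --- read counts ---------------------------------------------------------
    all_contigs = ([c for g in group_ids for c in group_contigs[g]]
                   + singleton_ids + flags_16s)
    count_mat = pd.DataFrame(0, index=all_contigs,
                             columns=list(samples["sample_id"]), dtype=np.int64)
    bm_rel: dict[str, float] = {}
    rd_week = 6 if 6 in params.weeks else (post_weeks[0] if post_weeks else 0)

    for sample_id in samples["sample_id"]:
        viruses = present[sample_id]
        cells: list[str] = []
        probs: list[float] = []
        if viruses:
            w = rng.lognormal(mu, sigma, size=len(viruses))
            p = w / w.sum()
            floor = params.min_rel_abundance
            p = p * (1.0 - len(viruses) * floor) + floor
            for v, pv in zip(viruses, p):
                member = contigs_of[v]
                ltot = sum(lengths[c] for c in member)
                for c in member:
                    cells.append(c)
                    probs.append(pv * lengths[c] / ltot)
        for c in flags_16s:  # low-level contaminant in every sample
            cells.append(c)
            probs.append(params.min_rel_abundance)
        if not cells:
            continue
        prob = np.asarray(probs)
        prob = prob / prob.sum()
        if params.noise_overdispersion > 0:
            od = params.noise_overdispersion
            prob = prob * rng.gamma(1.0 / od, od, size=prob.size)
            prob = prob / prob.sum()
        counts_draw = rng.multinomial(params.reads_per_sample, prob)
        count_mat.loc[cells, sample_id] = counts_draw
        subj = sample_id.rsplit("_W", 1)[0]
        week = int(sample_id.rsplit("_W", 1)[1])
        if subj in categories and week == rd_week:
            bm_contigs = [c for b in biomarker_ids
                          for c in contigs_of.get(b, []) if b in viruses]
            bm_rel[subj] = float(counts_draw[[cells.index(c) for c in bm_contigs]].sum()
                                 / params.reads_per_sample) if bm_contigs else 0.0

    # --- clinical outcome ----------------------------------------------------
    recipients = controls + treated
    rd: dict[str, float] = {}
    if recipients:
        logs = np.log10(np.array([bm_rel.get(s, 0.0) for s in recipients]) + 1e-7)
        sd = logs.std()
        z = (logs - logs.mean()) / sd if sd > 0 else np.zeros_like(logs)
        noise = rng.normal(0.0, params.rd_noise_sd, size=len(recipients))
        for subj, zi, ni in zip(recipients, z, noise):
            rd[subj] = float(params.rd_baseline + params.biomarker_effect * zi + ni)

    design = StudyDesign(samples, pd.Series(rd, dtype=float))
    truth = GroundTruth(
        hv_membership={c: g for g in group_ids for c in group_contigs[g]},
        singletons=list(singleton_ids),
        categories=categories,
        biomarker_hv_ids=list(biomarker_ids),
        biomarker_rel_abundance=bm_rel,
        rd_increase_pct=rd,
    )
    catalog = pd.Series({c: float(lengths[c]) for c in all_contigs}, name="length")
    counts = AbundanceMatrix(count_mat, unit="raw_count", lengths=catalog)
    return SimulatedStudy(catalog, hits, counts, design, truth, flags_16s)


def write_fixtures(study: SimulatedStudy, out_dir: str | Path,
                   fasta: bool = False, seed: int = 0) -> dict[str, Path]:
    """Write the study in the pipeline's on-disk formats; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hits": out / "hits.tsv",
        "contigs": out / "contigs.tsv",
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
        "flags_16s": out / "16s_flags.txt",
    }
    vio.write_hits(study.hits, paths["hits"])
    vio.write_contigs(study.catalog, paths["contigs"])
    vio.write_counts(study.counts, paths["counts"])
    vio.write_metadata(study.design, paths["metadata"])
    vio.write_json(study.truth.to_dict(), paths["truth"])
    vio.write_flags(study.flags_16s, paths["flags_16s"])
    if fasta:  # synthetic sequences: random nucleotides of the cataloged length
        rng = np.random.default_rng(seed)
        paths["fasta"] = out / "contigs.fasta"
        with open(paths["fasta"], "w") as fh:
            for contig, length in study.catalog.items():
                seq = "".join(rng.choice(list("ACGT"), size=int(length)))
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
    return paths


def read_fixtures(in_dir: str | Path) -> SimulatedStudy:
    """Round-trip reader for :func:`write_fixtures` output."""
    d = Path(in_dir)
    catalog = vio.read_contigs(d / "contigs.tsv")
    hits = vio.read_hits(d / "hits.tsv")
    counts = vio.read_counts(d / "counts.tsv", lengths=catalog)
    design = vio.read_metadata(d / "metadata.tsv")
    truth = GroundTruth.from_dict(json.loads((d / "truth.json").read_text()))
    flags = sorted(vio.read_flags(d / "16s_flags.txt"))
    return SimulatedStudy(catalog, hits, counts, design, truth, flags)
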