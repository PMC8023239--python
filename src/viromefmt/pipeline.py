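"""Pipeline orchestration: cluster -> abundance -> track -> stats -> biomarker.

All thresholds live in one config mapping (defaults below); no stage
hard-codes them. Every stage writes its outputs as TSV/JSON with stable
formatting, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import biomarker as bm
from . import hv as hvmod
from . import io as vio
from . import stats as st
from . import transfer as tr

logger = logging.getLogger(__name__)

STAGES = ("cluster", "abundance", "track", "stats", "biomarker")

DEFAULT_CONFIG: dict = {
    "inputs": {
        "hits": "hits.tsv",
        "contigs": "contigs.tsv",
        "counts": "counts.tsv",
        "metadata": "metadata.tsv",
        "flags_16s": None,
        "taxa": None,
    },
    "max_evalue": 1e-20,
    "min_hsp_query_ratio": 0.5,
    "min_contig_length": 3000,
    "subsample_depth": 1_367_462,
    "presence_rpkm": 7.0,
    "include_singletons": True,
    "permutations": 1000,
    "simper_max_cumulative": 0.7,
    "simper_max_p": 0.05,
    "responder_rd_threshold": 10.0,
    "rd_week": 6,
    "rd_exclusions": [],
    "n_markers": 3,
    "high_level_min_markers": 2,
    "high_level_threshold": 7.0,
    "require_absent_in_non_responders": False,
    "taxonomy_filter": None,
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config over the defaults and validate it."""
    config = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, value in user.items():
            if key == "inputs":
                config["inputs"].update(value or {})
            else:
                config[key] = value
    if config["permutations"] < 1:
        raise ValueError("permutations must be at least 1")
    return config


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""


def run_pipeline(
    config: dict,
    seed: int = 0,
    out_dir: str | Path = "pipeline_out",
    in_dir: str | Path | None = None,
    through: str = "biomarker",
) -> dict:
    """Execute the stages in order up to ``through``; returns a summary dict.

    ``in_dir``, when given, is prepended to relative input paths. Outputs of
    every executed stage are written under ``out_dir``.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; choose from {STAGES}")
    last = STAGES.index(through)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    summary: dict = {"seed": seed, "config": _jsonable(config), "stages": []}

    def _path(key: str) -> Path | None:
        p = config["inputs"].get(key)
        if p is None:
            return None
        p = Path(p)
        return p if p.is_absolute() or in_dir is None else Path(in_dir) / p

    # ---- load inputs -------------------------------------------------------
    try:
        catalog = vio.read_contigs(_path("contigs"))
        hits = vio.read_hits(_path("hits"))
        counts = vio.read_counts(_path("counts"), lengths=catalog)
        design = vio.read_metadata(_path("metadata"))
        flags = vio.read_flags(_path("flags_16s")) if _path("flags_16s") else set()
        taxa = vio.read_taxa(_path("taxa")) if _path("taxa") else {}
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'load' failed: {exc}") from exc

    # contaminant/length filters define the analysis catalog; raw counts keep
    # all rows until after depth subsampling (reads are rarefied as sequenced,
    # contaminant contigs are eliminated afterwards)
    if flags:
        catalog = ab.drop_16s_catalog(catalog, flags)
    short = catalog[catalog < config["min_contig_length"]].index
    if len(short):
        logger.info("excluding %d contigs below %d bp", len(short),
                    config["min_contig_length"])
        catalog = catalog.drop(index=short)

    results: dict = {}

    def run_stage(name: str, fn) -> None:
        if STAGES.index(name) > last:
            return
        try:
            fn()
            summary["stages"].append(name)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # ---- cluster -----------------------------------------------------------
    def _cluster() -> None:
        edges = hvmod.filter_hits(
            hits, catalog,
            max_evalue=config["max_evalue"],
            min_hsp_query_ratio=config["min_hsp_query_ratio"],
            min_contig_length=config["min_contig_length"],
        )
        grouping = hvmod.build_hv_groups(edges, catalog.index)
        if taxa:
            grouping = hvmod.propagate_taxonomy(grouping, taxa)
        results["grouping"] = grouping
        grouping.as_frame().to_csv(out / "hv_groups.tsv", sep="\t", index=False)
        tax = pd.DataFrame(sorted(grouping.taxonomy.items()),
                           columns=["group_id", "taxon"])
        tax.to_csv(out / "hv_taxonomy.tsv", sep="\t", index=False)
        summary["n_hv_groups"] = len(grouping.groups)
        summary["n_singletons"] = len(grouping.singletons)

    # ---- abundance ---------------------------------------------------------
    def _abundance() -> None:
        sub = ab.subsample_counts(counts, depth=config["subsample_depth"], seed=rng)
        drop = [c for c in sub.values.index if c not in catalog.index]
        if drop:
            sub = vio.AbundanceMatrix(sub.values.drop(index=drop), "raw_count", catalog)
        rpkm_contig = ab.compute_rpkm(sub)
        presence_contig = ab.apply_presence(rpkm_contig, config["presence_rpkm"])
        # presence gating at the contig level: absent contigs contribute no mass
        gated = rpkm_contig.copy_with(rpkm_contig.values.where(presence_contig, 0.0))
        rpkm_hv = ab.aggregate_to_hv(gated, results["grouping"],
                                     include_singletons=config["include_singletons"])
        presence_hv = ab.apply_presence(rpkm_hv, config["presence_rpkm"])
        results["rpkm_contig"] = rpkm_contig
        results["presence_contig"] = presence_contig
        results["rpkm_hv"] = rpkm_hv
        results["presence_hv"] = presence_hv
        vio.write_matrix(rpkm_contig.values, out / "rpkm_contig.tsv", "contig_id")
        vio.write_matrix(rpkm_hv.values, out / "rpkm_hv.tsv", "virus_id")
        vio.write_matrix(presence_hv.astype(int), out / "presence_hv.tsv", "virus_id")

    # ---- track -------------------------------------------------------------
    def _track() -> None:
        assignment = tr.classify_categories(results["presence_hv"], design)
        trajectories = tr.category_trajectories(
            results["rpkm_hv"], results["presence_hv"], assignment, design)
        invading, totals = tr.invading_dynamics(
            results["rpkm_hv"], results["presence_hv"], assignment, design)
        fits = tr.donor_recipient_abundance_fit(results["rpkm_hv"], assignment, design)
        results["assignment"] = assignment
        assignment.to_csv(out / "categories.tsv", sep="\t", index=False)
        trajectories.to_csv(out / "trajectories.tsv", sep="\t", index=False,
                            float_format="%.10g")
        invading.to_csv(out / "invading.tsv", sep="\t", index=False,
                        float_format="%.10g")
        totals.rename_axis("recipient").to_csv(out / "invading_totals.tsv", sep="\t")
        fits.rename_axis("recipient").to_csv(out / "donor_recipient_r2.tsv",
                                             sep="\t", float_format="%.10g")

    # ---- stats -------------------------------------------------------------
    def _stats() -> None:
        shared = st.donor_shared_hvs(results["presence_hv"], design,
                                     results["grouping"])
        summary["n_donor_shared_hvs"] = len(shared)
        cohort = design.samples[design.samples["role"].isin(
            ("donor", "responder", "non_responder"))]["sample_id"]
        table = results["rpkm_hv"].values.loc[shared, cohort]
        roles = pd.Series(design.samples.set_index("sample_id")["role"])
        if len(shared) == 0:
            logger.warning("no donor-shared HV groups; ordination skipped")
            vio.write_json({"note": "no donor-shared HV groups"}, out / "permanova.json")
            pd.DataFrame(columns=["virus_id", "contribution", "fraction",
                                  "cumulative", "p"]).to_csv(
                out / "simper.tsv", sep="\t", index=False)
            results["simper"] = None
            return
        dmat = st.bray_curtis(table)
        coords, eigvals = st.pco(dmat, k=min(2, max(1, len(cohort) - 1)))
        perma: dict = {}
        for a, b in (("responder", "non_responder"), ("responder", "donor"),
                     ("non_responder", "donor")):
            ids = [s for s in dmat.ids if roles[s] in (a, b)]
            sub = st.DistanceMatrix(
                dmat.as_frame().loc[ids, ids].to_numpy(), ids)
            f, p = st.permanova(sub, roles, n_perm=config["permutations"], seed=rng)
            perma[f"{a}-{b}"] = {"pseudo_F": f, "p": p}
        rn_samples = [s for s in table.columns
                      if roles[s] in ("responder", "non_responder")]
        simper_table = st.simper(table[rn_samples], roles,
                                 n_perm=config["permutations"], seed=rng)
        results["simper"] = simper_table
        vio.write_matrix(dmat.as_frame(), out / "distances.tsv", "sample_id")
        vio.write_matrix(coords, out / "pco_coords.tsv", "sample_id")
        vio.write_json(perma, out / "permanova.json")
        simper_table.to_csv(out / "simper.tsv", sep="\t", index=False,
                            float_format="%.10g")

    # ---- biomarker ---------------------------------------------------------
    def _biomarker() -> None:
        simper_table = results.get("simper")
        grouping = results["grouping"]
        presence_hv = results["presence_hv"]
        rpkm_hv = results["rpkm_hv"]
        if simper_table is None or simper_table.empty:
            selected: list[str] = []
        else:
            selected = bm.select_discriminant_hvs(
                simper_table, config["simper_max_cumulative"], config["simper_max_p"])
        summary["n_discriminant_hvs"] = len(selected)

        nr_samples = design.samples.loc[
            design.samples["role"] == "non_responder", "sample_id"]
        markers = list(selected)
        if config["require_absent_in_non_responders"] and len(nr_samples):
            markers = [h for h in markers
                       if not presence_hv.loc[h, nr_samples].any()]
        if config["taxonomy_filter"] is not None:
            markers = [h for h in markers
                       if grouping.taxonomy.get(h) == config["taxonomy_filter"]]
        markers = markers[: config["n_markers"]]
        summary["marker_hvs"] = markers

        pd.DataFrame({"hv_id": selected}).to_csv(
            out / "discriminant_hvs.tsv", sep="\t", index=False)
        subset = {g: grouping.groups[g] for g in selected if g in grouping.groups}
        if subset:
            scores = bm.score_contigs(results["rpkm_contig"],
                                      results["presence_contig"], design, subset)
        else:
            scores = pd.DataFrame(columns=[
                "contig_id", "hv_id", "r_total_rpkm", "n_total_rpkm",
                "n_r_present", "n_n_present", "r_score", "n_score",
                "median_r", "score", "rank_in_hv"])
        scores.to_csv(out / "contig_scores.tsv", sep="\t", index=False,
                      float_format="%.10g")

        recipients = [s for s in design.rd_increase_pct.index]
        rd_models: dict = {}
        roc: dict = {}
        for hv_id in markers:
            week_samples = {r: design.sample_id(r, config["rd_week"])
                            for r in recipients}
            abund = pd.Series({r: float(rpkm_hv.values.at[hv_id, s])
                               for r, s in week_samples.items() if s is not None})
            try:
                model = bm.fit_rd_model(abund, design.rd_increase_pct,
                                        tuple(config["rd_exclusions"]))
                rd_models[hv_id] = asdict(model)
            except ValueError as exc:
                rd_models[hv_id] = {"skipped": str(exc)}
            treated = design.subjects(("responder", "non_responder"))
            base = pd.Series({r: float(rpkm_hv.values.at[hv_id, design.sample_id(r, 0)])
                              for r in treated if design.sample_id(r, 0)})
            resp = pd.Series({r: design.roles[r] == "responder" for r in base.index})
            try:
                auc, p = bm.roc_auc(base, resp)
                roc[hv_id] = {"auc": auc, "p": p}
            except ValueError as exc:
                roc[hv_id] = {"skipped": str(exc)}
        vio.write_json(rd_models, out / "rd_models.json")
        vio.write_json(roc, out / "roc.json")

        prevalence: dict = {"note": "no marker HV groups selected"}
        if markers:
            treated = design.subjects(("responder", "non_responder"))
            marker_abund = pd.DataFrame({
                h: {r: float(rpkm_hv.values.at[h, design.sample_id(r, 0)])
                    for r in treated if design.sample_id(r, 0)}
                for h in markers})
            high = bm.flag_high_hv(marker_abund, config["high_level_threshold"],
                                   config["high_level_min_markers"])
            resp = pd.Series({r: design.roles[r] == "responder"
                              for r in marker_abund.index})
            prevalence = bm.prevalence_table(high, resp)
        vio.write_json(prevalence, out / "prevalence.json")

    run_stage("cluster", _cluster)
    run_stage("abundance", _abundance)
    run_stage("track", _track)
    run_stage("stats", _stats)
    run_stage("biomarker", _biomarker)
    vio.write_json(summary, out / "summary.json")
    logger.info("pipeline complete: stages %s, seed %d", summary["stages"], seed)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
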