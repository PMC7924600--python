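"""End-to-end analysis pipeline: the full association battery on one cohort.

Given a count table, a metabolite table and sample metadata, ``run_all``
executes, in order: alpha/beta diversity; cross-sectional health-status
tests on first-time-point samples plus the health-status balance;
longitudinal dynamics tests and the dynamics balance (last time points);
neurological-scale mixed models; metabolite-microbiome balances;
therapy/diagnosis mixed models; and ANCOVA on first-to-last changes.  All
result tables, balance JSONs and a machine-readable run manifest are
written to the output directory.  A single seed drives every stochastic
stage through derived per-stage substreams.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import balance_selection as bsel
from .compositional import alpha_diversity_chao1, clr_transform, impute_zeros_bm
from .metabolites import log_transform
from .tables_io import (CountTable, MetaboliteTable, SampleMetadata,
                        aggregate_to_rank, read_count_table, read_metabolites,
                        read_metadata)

DEFAULT_RANKS = ("order", "family", "genus", "species")


@dataclass
class PipelineConfig:
    """All pipeline knobs; ``seed`` is mandatory for reproducibility."""

    seed: int
    counts_path: str | None = None
    metadata_path: str | None = None
    metabolites_path: str | None = None
    output_dir: str = "results"
    rarefaction_depth: int = 3000
    pseudocount: float = 0.001
    ranks: tuple[str, ...] = DEFAULT_RANKS
    fdr_threshold: float = 0.05
    cv_folds: int = 5
    cv_repeats: int = 10
    reproducibility_threshold: float = 50.0
    r2_threshold: float = 0.2
    min_diagnosis_size: int = 5
    max_balance_size: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if not (0 <= self.reproducibility_threshold <= 100):
            raise ValueError("reproducibility threshold must be a percentage")
        if self.cv_folds < 2 or self.cv_repeats < 1:
            raise ValueError("invalid CV scheme")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        bad = set(d) - set(cls.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        d.update(overrides)
        if "ranks" in d:
            d["ranks"] = tuple(d["ranks"])
        return cls(**d)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    # independent substreams, each below 2**31 so they stay plain ints
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def run_all(cfg: PipelineConfig,
            counts: CountTable | None = None,
            metadata: SampleMetadata | None = None,
            metabolites: MetaboliteTable | None = None) -> dict:
    """Run the full battery; returns a dict of result objects.

    Inputs are read from the configured paths unless passed in directly.
    Any stage failure aborts with the stage name; outputs written before
    the failure are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now().strftime("%H:%M:%S")
        log_lines.append(f"[{stamp}] {msg}")

    seeds = _stage_seeds(cfg.seed)
    stage = "load_inputs"
    try:
        if counts is None:
            counts = read_count_table(cfg.counts_path)
        if metadata is None:
            metadata = read_metadata(cfg.metadata_path)
        if metabolites is None:
            metabolites = read_metabolites(cfg.metabolites_path)
        counts = counts.drop_empty_taxa()
        log(f"loaded {len(counts.taxon_ids)} taxa x "
            f"{len(counts.sample_ids)} samples, seed={cfg.seed}")

        meta = metadata.frame
        cci_samples = meta.index[meta["cohort"] == "CCI"]
        first = metadata.first_timepoint_samples()
        last_cci = pd.Index([s for s in metadata.last_timepoint_samples()
                             if s in set(cci_samples)])
        first_cci = pd.Index([s for s in first if s in set(cci_samples)])

        # per-rank compositions and clr matrices (aggregate -> impute -> clr)
        stage = "compositional"
        ranks = [r for r in cfg.ranks if r in _aggregable_ranks(counts)]
        comps: dict[str, pd.DataFrame] = {}
        clrs: dict[str, pd.DataFrame] = {}
        for rank in ranks:
            agg = aggregate_to_rank(counts, rank).drop_empty_taxa()
            comp = impute_zeros_bm(agg)
            comps[rank] = comp
            clrs[rank] = clr_transform(comp)
            log(f"rank {rank}: {comp.shape[1]} taxa")

        metab_log = log_transform(metabolites.concentrations)

        results: list[pd.DataFrame] = []
        artifacts: dict = {"config": cfg, "ranks": ranks}

        # --- stage 1: diversity -------------------------------------------
        stage = "diversity"
        div = alpha_diversity_chao1(counts, depth=cfg.rarefaction_depth,
                                    seed=seeds[0])
        div.to_csv(out / "alpha_diversity.tsv", sep="\t")
        excluded = div.index[~div["included"]].tolist()
        log(f"alpha diversity: {len(excluded)} sample(s) below "
            f"{cfg.rarefaction_depth} reads excluded: {excluded}")
        artifacts["alpha_diversity"] = div

        # --- stage 2: health status (first time point) --------------------
        stage = "health_status"
        fr = meta.loc[first]
        y_health = (fr["cohort"] == "CCI").astype(int).to_numpy()
        for rank in ranks:
            results.append(assoc.fit_cross_sectional(
                clrs[rank].loc[first], y_health, feature_kind="taxon",
                rank=rank, outcome_name="health_status",
                metadata_group="health_status"))
        results.append(assoc.fit_cross_sectional(
            metab_log.loc[first], y_health, feature_kind="metabolite",
            outcome_name="health_status", metadata_group="health_status"))

        health_df = assoc.adjust_by_family(pd.concat(results, ignore_index=True))
        results = [health_df]
        taxon_health = health_df[health_df["feature_kind"] == "taxon"]
        health_rank = bsel.choose_rank({
            r: taxon_health.loc[taxon_health["rank"] == r, "fdr"]
            for r in ranks})
        log(f"health-status balance rank: {health_rank}")
        health_bal = bsel.cross_validated_selection(
            comps[health_rank].loc[first], y_health, folds=cfg.cv_folds,
            repeats=cfg.cv_repeats, seed=seeds[1],
            max_size=cfg.max_balance_size, rank=health_rank)
        health_bal.to_json(out / "balance_health_status.json")
        health_bal.reproducibility.to_csv(
            out / "reproducibility_health_status.tsv", sep="\t", index=False)
        artifacts["health_balance"] = health_bal

        # --- stage 3: dynamics (longitudinal + balance at last point) -----
        stage = "dynamics"
        dyn = meta.loc[cci_samples, "dynamics"]
        y_dyn_all = dyn.map({"positive": 1.0, "negative": 0.0})
        subj_cci = meta.loc[cci_samples, "subject_id"]
        dyn_results = []
        for rank in ranks:
            dyn_results.append(assoc.fit_longitudinal(
                clrs[rank].loc[cci_samples], y_dyn_all, subj_cci,
                feature_kind="taxon", rank=rank, outcome_name="dynamics",
                metadata_group="dynamics"))
        dyn_results.append(assoc.fit_longitudinal(
            metab_log.loc[cci_samples], y_dyn_all, subj_cci,
            feature_kind="metabolite", outcome_name="dynamics",
            metadata_group="dynamics"))
        div_vals = div.loc[cci_samples, "chao1"]
        keep = div_vals.notna()
        dyn_results.append(assoc.fit_longitudinal(
            div_vals[keep].to_frame("chao1"), y_dyn_all[keep],
            subj_cci[keep], feature_kind="alpha_diversity",
            outcome_name="dynamics", metadata_group="dynamics"))
        dyn_df = assoc.adjust_by_family(pd.concat(dyn_results,
                                                  ignore_index=True))
        results.append(dyn_df)

        y_dyn_last = meta.loc[last_cci, "dynamics"].map(
            {"positive": 1.0, "negative": 0.0})
        ok = y_dyn_last.notna()
        dyn_taxa = dyn_df[dyn_df["feature_kind"] == "taxon"]
        dyn_rank = bsel.choose_rank({
            r: dyn_taxa.loc[dyn_taxa["rank"] == r, "fdr"] for r in ranks})
        log(f"dynamics balance rank: {dyn_rank}")
        dyn_bal = None
        if (ok.sum() >= 6 and y_dyn_last[ok].nunique() == 2
                and y_dyn_last[ok].value_counts().min() >= cfg.cv_folds):
            dyn_bal = bsel.cross_validated_selection(
                comps[dyn_rank].loc[last_cci[ok]], y_dyn_last[ok].to_numpy(),
                folds=cfg.cv_folds, repeats=cfg.cv_repeats, seed=seeds[2],
                max_size=cfg.max_balance_size, rank=dyn_rank)
            dyn_bal.to_json(out / "balance_dynamics.json")
            dyn_bal.reproducibility.to_csv(
                out / "reproducibility_dynamics.tsv", sep="\t", index=False)
        artifacts["dynamics_balance"] = dyn_bal

        # --- stage 4: neurological scales (mixed models) -------------------
        stage = "neurological_scales"
        scale_results = []
        for scale in ("gcs", "rankin", "rivermead", "nihss"):
            if scale not in meta.columns:
                continue
            y = pd.to_numeric(meta.loc[cci_samples, scale], errors="coerce")
            if y.dropna().nunique() < 2:
                continue
            for rank in ranks:
                scale_results.append(assoc.fit_longitudinal(
                    clrs[rank].loc[cci_samples], y, subj_cci,
                    feature_kind="taxon", rank=rank, outcome_name=scale,
                    metadata_group="neurological_scales"))
            scale_results.append(assoc.fit_longitudinal(
                metab_log.loc[cci_samples], y, subj_cci,
                feature_kind="metabolite", outcome_name=scale,
                metadata_group="neurological_scales"))
        if scale_results:
            results.append(assoc.adjust_by_family(
                pd.concat(scale_results, ignore_index=True)))

        # --- stage 5: metabolite-microbiome balances (last time point) ----
        stage = "metabolite_balances"
        metab_balances = {}
        met_last = metab_log.loc[last_cci]
        lin_rows = []
        for m in met_last.columns:
            ym = met_last[m].to_numpy()
            if np.unique(ym).size < 2:
                continue
            for rank in ranks:
                lin_rows.append(assoc.fit_cross_sectional_continuous(
                    clrs[rank].loc[last_cci], ym, feature_kind="taxon",
                    rank=rank, outcome_name=m, metadata_group="metabolites"))
        met_lin = assoc.adjust_by_family(pd.concat(lin_rows,
                                                   ignore_index=True))
        results.append(met_lin)
        for m in met_last.columns:
            ym = met_last[m].to_numpy()
            if np.unique(ym).size < 2:
                continue
            sub = met_lin[met_lin["outcome"] == m]
            m_rank = bsel.choose_rank({
                r: sub.loc[sub["rank"] == r, "fdr"] for r in ranks})
            res = bsel.cross_validated_selection(
                comps[m_rank].loc[last_cci], ym, folds=cfg.cv_folds,
                repeats=cfg.cv_repeats, seed=seeds[3],
                max_size=cfg.max_balance_size, rank=m_rank)
            metab_balances[m] = res
        reliable_rows = []
        for m, res in metab_balances.items():
            rel = res.reliable_taxa(cfg.reproducibility_threshold,
                                    cfg.r2_threshold)
            for _, r in rel.iterrows():
                reliable_rows.append(dict(
                    metabolite=m, taxon=r["taxon"], side=r["side"],
                    reproducibility=r["percent"], r2=res.final_r2,
                    rank=res.rank))
        pd.DataFrame(reliable_rows, columns=[
            "metabolite", "taxon", "side", "reproducibility", "r2", "rank",
        ]).to_csv(out / "metabolite_balance_reliable.tsv", sep="\t",
                  index=False)
        artifacts["metabolite_balances"] = metab_balances

        # --- stage 6: therapy and diagnosis (mixed models) -----------------
        stage = "therapy_diagnosis"
        ther_results = []
        for col, group in (("antibiotics", "therapy"), ("nutrition", "therapy"),
                           ("infection", "therapy")):
            if col not in meta.columns:
                continue
            levels = meta.loc[cci_samples, col].dropna().unique()
            if len(levels) != 2:
                continue
            y = (meta.loc[cci_samples, col] == sorted(levels)[1]).astype(float)
            for rank in ranks:
                ther_results.append(assoc.fit_longitudinal(
                    clrs[rank].loc[cci_samples], y, subj_cci,
                    feature_kind="taxon", rank=rank, outcome_name=col,
                    metadata_group=group))
        if "diagnosis" in meta.columns:
            diag = meta.loc[cci_samples, "diagnosis"]
            contrasts = assoc.one_vs_rest(diag.dropna(),
                                          min_size=cfg.min_diagnosis_size)
            for cat, ind in contrasts.items():
                y = pd.Series(np.nan, index=cci_samples)
                y.loc[diag.dropna().index] = ind
                for rank in ranks:
                    ther_results.append(assoc.fit_longitudinal(
                        clrs[rank].loc[cci_samples], y, subj_cci,
                        feature_kind="taxon", rank=rank,
                        outcome_name=f"diagnosis:{cat}",
                        metadata_group="diagnosis"))
        if ther_results:
            results.append(assoc.adjust_by_family(
                pd.concat(ther_results, ignore_index=True)))

        # --- stage 7: ANCOVA on first-to-last changes ----------------------
        stage = "ancova"
        multi = metadata.subjects_with_min_timepoints(2)
        multi = [s for s in multi
                 if meta.loc[meta["subject_id"] == s, "cohort"].iloc[0] == "CCI"]
        anc_results = []
        if multi:
            sub = meta[meta["subject_id"].isin(multi)]
            firsts = sub.groupby("subject_id")["time_point"].idxmin()
            lasts = sub.groupby("subject_id")["time_point"].idxmax()
            g = sub.groupby("subject_id")["dynamics"].first()
            ok = g.notna()
            if ok.sum() >= 4 and g[ok].nunique() == 2:
                gy = (g[ok] == "positive").astype(int).to_numpy()
                f_ids = firsts[ok].to_numpy()
                l_ids = lasts[ok].to_numpy()
                for rank in ranks:
                    anc_results.append(assoc.ancova_first_last(
                        clrs[rank], gy, f_ids, l_ids, feature_kind="taxon",
                        rank=rank, metadata_group="dynamics_delta"))
                anc_results.append(assoc.ancova_first_last(
                    metab_log, gy, f_ids, l_ids, feature_kind="metabolite",
                    metadata_group="dynamics_delta"))
        if anc_results:
            anc = pd.concat(anc_results, ignore_index=True)
            if len(anc):
                results.append(assoc.adjust_by_family(anc))

        # --- outputs --------------------------------------------------------
        stage = "write_outputs"
        all_results = pd.concat(results, ignore_index=True)
        all_results.to_csv(out / "association_results.tsv", sep="\t",
                           index=False, float_format="%.10g")
        family_sizes = (all_results.groupby(
            ["metadata_group", "feature_kind"]).size().to_dict())
        manifest = {
            "seed": cfg.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
            "ranks": ranks,
            "n_samples": len(meta),
            "n_taxa": len(counts.taxon_ids),
            "health_balance_rank": health_rank,
            "dynamics_balance_rank": dyn_rank,
            "excluded_from_diversity": excluded,
            "fdr_family_sizes": {f"{a}|{b}": int(n)
                                 for (a, b), n in family_sizes.items()},
            "n_significant": int((all_results["fdr"]
                                  < cfg.fdr_threshold).sum()),
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        log("pipeline complete")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        artifacts["results"] = all_results
        artifacts["manifest"] = manifest
        return artifacts
    except PipelineError:
        raise
    except Exception as e:
        (out / "run_log.txt").write_text("\n".join(log_lines)
                                         + f"\nFAILED at {stage}: {e}\n")
        raise PipelineError(stage, e) from e


def _aggregable_ranks(counts: CountTable) -> set[str]:
    from .tables_io import RANKS, _rank_depth

    depth = _rank_depth(counts.rank)
    return {r for r in RANKS if _rank_depth(r) <= depth}


def simulate(cfg_path_or_seed, output_dir: str = "synthetic") -> dict:
    """Generate a synthetic cohort on disk in the pipeline's TSV dialects."""
    from .synthetic_data import default_config, generate_cohort
    from .tables_io import write_count_table, write_metabolites, write_metadata

    if isinstance(cfg_path_or_seed, int):
        cfg = default_config(seed=cfg_path_or_seed)
    else:
        with open(cfg_path_or_seed) as fh:
            d = yaml.safe_load(fh)
        cfg = default_config(**d)
    cohort = generate_cohort(cfg)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_table(cohort.counts, outdir / "counts.tsv")
    write_metadata(cohort.metadata, outdir / "metadata.tsv")
    write_metabolites(cohort.metabolites, outdir / "metabolites.tsv")
    cohort.truth.to_json(outdir / "truth.json")
    return {"dir": str(outdir), "n_samples": len(cohort.metadata.sample_ids)}


def report(output_dir: str, fdr_threshold: float = 0.05) -> str:
    """Human-readable summary of significant associations per family."""
    path = Path(output_dir) / "association_results.tsv"
    df = pd.read_csv(path, sep="\t")
    sig = df[df["fdr"] < fdr_threshold]
    lines = [f"Associations at FDR < {fdr_threshold}"]
    if sig.empty:
        lines.append("no significant associations")
    else:
        for (group, kind), sub in sig.groupby(["metadata_group",
                                               "feature_kind"]):
            lines.append(f"\n[{group} | {kind}] {len(sub)} significant")
            view = sub.sort_values("fdr")[
                ["feature", "outcome", "rank", "p_value", "fdr",
                 "coefficient", "model_kind", "n"]]
            lines.append(view.to_string(index=False))
    lines.append(f"\ntotal rows: {len(df)}, significant: {len(sig)}")
    return "\n".join(lines)
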