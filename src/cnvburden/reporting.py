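"""Cohort descriptives and end-to-end pipeline orchestration."""

from __future__ import annotations

from dataclasses import asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import DOSAGES, SIDES, annotate_cnvs, build_profiles
from .errors import CnvBurdenError, ConfigError
from .filters import FilterParams, apply_filters, exclude_recurrent
from .models import ModelSpec, bonferroni_gate, estimates_frame, fit_model
from .resampling import bootstrap_cis, matched_null
from .simulate import SimulationConfig, simulate_cohort, simulate_genome, simulate_panel


def carrier_percent(n_carriers: int, n_total: int) -> float:
    """100 * n_carriers / n_total rounded half-up to two decimals."""
    if n_total <= 0:
        raise ConfigError("cannot compute a carrier percentage over an empty cohort")
    if not (0 <= n_carriers <= n_total):
        raise ConfigError("carrier count must lie in [0, n_total]")
    pct = Decimal(100 * n_carriers) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def carrier_stats(
    profiles: pd.DataFrame,
    phenotypes: pd.DataFrame,
    dosage: str,
    set_label: str,
) -> pd.DataFrame:
    """Carrier counts and percentages per cohort for one (dosage, set) cell.

    A sample carries (dosage, set) iff its profile gene count for that
    cell is > 0; percentages are over all samples in the cohort.
    """
    if dosage not in DOSAGES or set_label not in SIDES:
        raise ConfigError(f"dosage must be in {DOSAGES} and set_label in {SIDES}")
    col = f"{dosage}_{set_label}_n_genes"
    ph = phenotypes.copy()
    ph["sample_id"] = ph["sample_id"].astype(str)
    cohorts = ph["cohort"] if "cohort" in ph.columns else pd.Series("cohort", index=ph.index)
    carrier = profiles[col].reindex(ph["sample_id"]).to_numpy() > 0
    rows = []
    for cohort, grp_idx in ph.groupby(cohorts).groups.items():
        n_total = len(grp_idx)
        n_carriers = int(carrier[ph.index.get_indexer(grp_idx)].sum())
        rows.append(
            {
                "cohort": cohort,
                "dosage": dosage,
                "set": set_label,
                "n_carriers": n_carriers,
                "n_total": n_total,
                "percent": carrier_percent(n_carriers, n_total),
            }
        )
    return pd.DataFrame(rows)


def carrier_table(profiles: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """All (cohort x dosage x target/other) carrier rows."""
    parts = [
        carrier_stats(profiles, phenotypes, dosage, side)
        for dosage in DOSAGES
        for side in SIDES
    ]
    return pd.concat(parts, ignore_index=True)


DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "outdir": "cnvburden_run",
    "genome": {},            # simulate_genome kwargs
    "cohort": {},            # SimulationConfig kwargs
    "panel": {},             # simulate_panel kwargs
    "filter": {},            # FilterParams kwargs
    "exclude_recurrent": False,
    "target_set": "union",
    "gene_rule": "contained",
    "models": [
        {"model_id": 1, "outcome": "case_status", "weighting": "count"},
        {"model_id": 2, "outcome": "case_status", "weighting": "inv_loeuf"},
        {"model_id": 3, "outcome": "sleep_duration_min", "weighting": "count"},
        {"model_id": 4, "outcome": "insomnia_traits", "weighting": "count"},
    ],
    "bootstrap": {"enabled": False, "n_iter": 200, "model": 0},
    "matched_null": {"enabled": False, "n_resamples": 200, "gene_count_tolerance": 1,
                     "score_bins": 5},
    "stages": ["simulate", "filter", "annotate", "descriptives", "fit"],
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None) -> dict:
    """Run simulate -> filter -> annotate -> descriptives -> models ->
    resampling per config; returns a result bundle and writes artifacts
    plus a manifest under config["outdir"].

    Every stage is skippable via the "stages" list; a stage failure
    raises with the stage name after upstream outputs are persisted.
    """
    from .io_tables import write_cnv_table, write_gene_table, write_phenotypes

    cfg = _merge(DEFAULT_PIPELINE_CONFIG, config or {})
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    seed = int(cfg["seed"])
    bundle: dict = {"config": cfg}
    stage = "init"
    try:
        stage = "simulate"
        genome = simulate_genome(seed=seed, **cfg["genome"])
        sim_cfg = SimulationConfig(seed=seed + 1, **cfg["cohort"])
        calls, phenotypes = simulate_cohort(genome, sim_cfg)
        panel = simulate_panel(genome, seed=seed + 2, **cfg["panel"])
        bundle.update(genome=genome, calls=calls, phenotypes=phenotypes, panel=panel)
        if "simulate" in stages:
            write_gene_table(genome.genes, outdir / "genes.tsv")
            write_cnv_table(calls, outdir / "cnv_calls.tsv")
            write_phenotypes(phenotypes, outdir / "phenotypes.tsv")

        stage = "filter"
        surviving = calls
        if "filter" in stages:
            params = FilterParams(**cfg["filter"])
            surviving, tally = apply_filters(calls, panel, genome.mask_intervals, params)
            if cfg["exclude_recurrent"]:
                surviving = exclude_recurrent(surviving, genome.recurrent_regions)
            bundle["filter_tally"] = tally
            write_cnv_table(surviving, outdir / "cnv_calls.filtered.tsv")
            pd.Series(tally).to_json(outdir / "filter_tally.json")
        bundle["surviving_calls"] = surviving

        stage = "annotate"
        annotated = annotate_cnvs(
            surviving, genome.genes, target_set=cfg["target_set"], rule=cfg["gene_rule"]
        )
        profiles = build_profiles(annotated, phenotypes["sample_id"].tolist())
        bundle.update(annotated=annotated, profiles=profiles)
        if "annotate" in stages:
            profiles.to_csv(outdir / "burden_profiles.tsv", sep="\t")

        if "descriptives" in stages:
            stage = "descriptives"
            table = carrier_table(profiles, phenotypes)
            bundle["carrier_table"] = table
            table.to_csv(outdir / "carrier_table.tsv", sep="\t", index=False)

        if "fit" in stages:
            stage = "fit"
            fits = {}
            for m in cfg["models"]:
                spec = ModelSpec(target_set=cfg["target_set"], **m)
                ests = bonferroni_gate(fit_model(profiles, phenotypes, spec))
                key = f"model{spec.model_id}_{spec.weighting}"
                fits[key] = ests
                estimates_frame(ests).to_csv(outdir / f"estimates_{key}.tsv", sep="\t", index=False)
            bundle["fits"] = fits

        if cfg["bootstrap"]["enabled"]:
            stage = "bootstrap"
            m = cfg["models"][int(cfg["bootstrap"].get("model", 0))]
            spec = ModelSpec(target_set=cfg["target_set"], **m)
            boot = bootstrap_cis(
                profiles, phenotypes, spec,
                n_iter=int(cfg["bootstrap"]["n_iter"]), seed=seed + 3,
            )
            bundle["bootstrap"] = boot

        if cfg["matched_null"]["enabled"]:
            stage = "matched_null"
            case_ids = set(
                phenotypes.loc[phenotypes["case_status"] == 1, "sample_id"].astype(str)
            )
            case_cnvs = [a for a in annotated if a.call.sample_id in case_ids and a.total_genes > 0]
            pool = [a for a in annotated if a.total_genes > 0]
            mn = cfg["matched_null"]
            bundle["matched_null"] = matched_null(
                case_cnvs, pool,
                n_resamples=int(mn["n_resamples"]),
                gene_count_tolerance=int(mn["gene_count_tolerance"]),
                score_bins=int(mn["score_bins"]),
                seed=seed + 4,
            )
    except CnvBurdenError:
        raise
    except Exception as e:
        raise CnvBurdenError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest = {
        "package": "cnvburden",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "n_calls": len(bundle.get("calls", [])),
        "n_surviving": len(bundle.get("surviving_calls", [])),
        "n_samples": len(bundle["phenotypes"]) if "phenotypes" in bundle else 0,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
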