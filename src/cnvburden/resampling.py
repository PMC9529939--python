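"""Bootstrap confidence intervals and the matched random-CNV null.

Two resampling procedures back the sensitivity analyses:

* ``bootstrap_cis`` resamples individuals with replacement (stratified by
  case status for binary outcomes), refits the requested burden model,
  and reports percentile 95% intervals per term. Comparing whether the
  intervals of the sleep-gene and other-gene terms overlap asks whether
  sleep-gene CNVs are *better* predictors, not merely significant ones.

* ``matched_null`` asks whether the target-set gene content observed in
  case CNVs exceeds what genome-wide CNVs of the same size profile would
  carry: each case CNV is replaced by a randomly drawn pool CNV matched
  on total gene count (within a tolerance) and on Σ1/LOEUF (same
  quantile bin), and the target-set gene count of the resampled sets
  forms the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import AnnotatedCnv
from .errors import DiagnosticError, MatchingError
from .models import ModelSpec, fit_model

# ---------------------------------------------------------------- bootstrap


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap intervals per model term."""

    estimates: dict  # term -> (point, ci_low, ci_high)
    n_iterations: int
    n_failed: int
    seed: int


def _resample_frames(profiles, phenotypes, idx):
    """Materialize one bootstrap replicate with fresh unique sample ids."""
    ph = phenotypes.iloc[idx].reset_index(drop=True).copy()
    new_ids = [f"B{i:07d}" for i in range(len(idx))]
    old_ids = ph["sample_id"].astype(str).to_numpy()
    ph["sample_id"] = new_ids
    prof = profiles.loc[old_ids].copy()
    prof.index = pd.Index(new_ids, name="sample_id")
    return prof, ph


def bootstrap_cis(
    profiles: pd.DataFrame,
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    n_iter: int = 1000,
    seed: int = 0,
    max_failed_fraction: float = 0.1,
) -> BootstrapResult:
    """Percentile 95% bootstrap intervals for every term of one model.

    Individuals are resampled with replacement; for a binary outcome the
    resampling is stratified by case status so every replicate keeps the
    observed case/control split. Replicates whose refit fails (e.g.
    separation) are skipped and counted; more than ``max_failed_fraction``
    failures raises DiagnosticError.
    """
    rng = np.random.default_rng(seed)
    full = {e.term: e.beta for e in fit_model(profiles, phenotypes, spec)}

    outcome = phenotypes[spec.outcome] if spec.outcome in phenotypes.columns else None
    binary = outcome is not None and set(pd.unique(outcome.dropna())) <= {0, 1}
    n = len(phenotypes)
    if binary:
        strata = [np.flatnonzero(outcome.to_numpy() == v) for v in (0, 1)]
    else:
        strata = [np.arange(n)]

    draws: dict[str, list[float]] = {t: [] for t in full}
    n_failed = 0
    for _ in range(n_iter):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        prof, ph = _resample_frames(profiles, phenotypes, idx)
        try:
            ests = fit_model(prof, ph, spec)
        except Exception:
            n_failed += 1
            continue
        got = {e.term: e.beta for e in ests}
        for t in draws:
            if t in got:
                draws[t].append(got[t])
    if n_failed > max_failed_fraction * n_iter:
        raise DiagnosticError(
            f"{n_failed}/{n_iter} bootstrap refits failed; the model is unstable "
            "under resampling (consider prior_mode='weakly_informative')"
        )
    estimates = {}
    for t, vals in draws.items():
        if vals:
            lo, hi = np.percentile(vals, [2.5, 97.5])
        else:
            lo = hi = full[t]
        estimates[t] = (float(full[t]), float(lo), float(hi))
    return BootstrapResult(estimates=estimates, n_iterations=n_iter, n_failed=n_failed, seed=seed)


def compare_cis(a: tuple[float, float, float], b: tuple[float, float, float]) -> str:
    """"distinct" iff the two closed 95% intervals share no point.

    Accepts (point, ci_low, ci_high) triples as stored in
    BootstrapResult.estimates; touching endpoints count as overlapping.
    """
    _, a_lo, a_hi = a
    _, b_lo, b_hi = b
    return "overlapping" if (a_lo <= b_hi and b_lo <= a_hi) else "distinct"


# -------------------------------------------------------------- matched null


@dataclass(frozen=True)
class MatchedNullResult:
    """Observed target-set statistic and its matched-resampling null."""

    observed: float
    null_values: tuple[float, ...]
    empirical_p: float
    n_resamples: int
    seed: int
    match_distances: tuple[int, ...] = ()  # per case CNV: |pool gene count - case gene count| best case
    candidate_counts: tuple[int, ...] = ()


def matched_null(
    case_cnvs: list[AnnotatedCnv],
    pool: list[AnnotatedCnv],
    n_resamples: int = 1000,
    gene_count_tolerance: int = 0,
    score_bins: int = 10,
    seed: int = 0,
    replace: bool = True,
    statistic: str = "target_n_genes",
) -> MatchedNullResult:
    """Matched random-CNV null for a target-set enrichment statistic.

    For each resample, every case CNV is replaced by a pool CNV whose
    total gene count matches within ``gene_count_tolerance`` and whose
    Σ1/LOEUF falls in the same pool-quantile bin (``score_bins`` bins);
    the statistic (total target-set gene count, or Σ1/LOEUF with
    statistic="target_inv_loeuf") over the replacement set is one null
    draw. The empirical p uses the add-one rule
    ``(1 + #{null >= observed}) / (1 + n_resamples)``.
    """
    if statistic == "target_n_genes":
        stat_of = lambda a: float(a.target.n_genes)  # noqa: E731
    elif statistic == "target_inv_loeuf":
        stat_of = lambda a: float(a.target.inv_loeuf)  # noqa: E731
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if not case_cnvs:
        raise MatchingError("no case CNVs to match")
    if not pool:
        raise MatchingError("empty matching pool")

    pool_counts = np.array([a.total_genes for a in pool])
    pool_scores = np.array([a.total_inv_loeuf for a in pool])
    # quantile bin edges over the pool; exact matching on a continuous
    # score is measure-zero, so Σ1/LOEUF is matched within deciles
    qs = np.quantile(pool_scores, np.linspace(0, 1, score_bins + 1))
    edges = np.unique(qs)[1:-1]
    pool_bins = np.digitize(pool_scores, edges)

    rng = np.random.default_rng(seed)
    candidates: list[np.ndarray] = []
    distances: list[int] = []
    unmatched = []
    for a in case_cnvs:
        bin_i = int(np.digitize([a.total_inv_loeuf], edges)[0])
        ok = np.flatnonzero(
            (np.abs(pool_counts - a.total_genes) <= gene_count_tolerance)
            & (pool_bins == bin_i)
        )
        if len(ok) == 0:
            unmatched.append(a)
            candidates.append(ok)
            distances.append(-1)
        else:
            candidates.append(ok)
            distances.append(int(np.abs(pool_counts[ok] - a.total_genes).min()))
    if unmatched:
        desc = [
            f"{a.call.interval.chrom}:{a.call.interval.start}-{a.call.interval.end}"
            f" ({a.total_genes} genes, Σ1/LOEUF={a.total_inv_loeuf:.2f})"
            for a in unmatched[:10]
        ]
        raise MatchingError(
            f"{len(unmatched)} case CNVs have no admissible pool match "
            f"(tolerance={gene_count_tolerance}, bins={score_bins}): {desc}",
            unmatched,
        )

    pool_stats = np.array([stat_of(a) for a in pool])
    observed = float(sum(stat_of(a) for a in case_cnvs))
    null_values = np.empty(n_resamples)
    for r in range(n_resamples):
        total = 0.0
        if replace:
            for ok in candidates:
                total += pool_stats[int(rng.choice(ok))]
        else:
            used: set[int] = set()
            for ok in candidates:
                avail = [i for i in ok if i not in used]
                if not avail:
                    avail = list(ok)  # fall back to reuse rather than fail
                pick = int(rng.choice(avail))
                used.add(pick)
                total += pool_stats[pick]
        null_values[r] = total
    empirical_p = (1.0 + float((null_values >= observed).sum())) / (1.0 + n_resamples)
    return MatchedNullResult(
        observed=observed,
        null_values=tuple(float(v) for v in null_values),
        empirical_p=empirical_p,
        n_resamples=n_resamples,
        seed=seed,
        match_distances=tuple(distances),
        candidate_counts=tuple(len(c) for c in candidates),
    )
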