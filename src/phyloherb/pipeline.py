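"""End-to-end analysis: filter -> graft -> per-plant metrics -> mixed models.

The chain runs once per guild scope ("all", "endophage", "exophage") and,
for each of the four responses, performs the interaction likelihood-ratio
test, the singular-fit fallback, and the R² bookkeeping.  All outputs are
tidy data frames so the CLI can serialize them as CSV.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import datasets, glmm, metrics
from .datasets import Assemblage
from .glmm import ModelSpec
from .phylo import Phylogeny, graft_all

logger = logging.getLogger(__name__)

SCOPES = ("all", "endophage", "exophage")
RESPONSES = ("richness", "mean_jaccard", "mean_simpson", "mean_dprime")


class PipelineError(RuntimeError):
    pass


def prepare_scope(
    assemblages: list[Assemblage], scope: str
) -> tuple[list[Assemblage], pd.DataFrame, list[datasets.RemovalLogEntry]]:
    """Filter (and for guild scopes, split) assemblages for one scope.

    The "all" scope keeps only assemblages passing every eligibility
    criterion.  Guild scopes are derived from those survivors; after the
    split an assemblage is kept if it retains at least two plants of mixed
    origin and one herbivore, and its post-split eligibility is recorded
    (``eligible_after_split``) rather than enforced.
    """
    kept: list[Assemblage] = []
    removals: list[datasets.RemovalLogEntry] = []
    reports = []
    for a in assemblages:
        cleaned, log = datasets.drop_unusable_plants(a)
        removals.extend(log)
        rep = datasets.check_eligibility(cleaned)
        if not rep.passed:
            reports.append({**dataclasses.asdict(rep), "scope": "all", "kept": False})
            continue
        if scope == "all":
            reports.append({**dataclasses.asdict(rep), "scope": scope, "kept": True})
            kept.append(cleaned)
            continue
        sub = datasets.split_by_guild(cleaned)[scope]
        sub_rep = datasets.check_eligibility(sub)
        origins = {p.origin for p in sub.table.plants}
        usable = (
            sub.table.n_plants >= 2
            and sub.table.n_herbivores >= 1
            and {"native", "exotic"} <= origins
        )
        sub.metadata["eligible_after_split"] = sub_rep.passed
        reports.append({**dataclasses.asdict(sub_rep), "scope": scope, "kept": usable})
        if usable:
            kept.append(sub)
    report_frame = pd.DataFrame(
        reports,
        columns=["assemblage_id", "passed", "n_plants", "n_herbivores",
                 "n_exotic", "n_native", "reasons", "scope", "kept"],
    )
    return kept, report_frame, removals


def scope_metrics(
    assemblages: list[Assemblage], phy: Phylogeny, scope: str
) -> pd.DataFrame:
    """Graft any missing plants, then stack per-plant metric tables."""
    grafted, reports = graft_all(phy, assemblages)
    failed = {r.species_name for r in reports if r.attachment_level == "failed"}
    if failed:
        logger.warning("graft failed for %d species; their plants are excluded: %s",
                       len(failed), sorted(failed))
    frames = []
    for a in assemblages:
        if failed:
            keep = np.array([p.species not in failed for p in a.table.plants])
            if not keep.all():
                a = Assemblage(
                    a.assemblage_id,
                    a.table.subset(keep, np.ones(a.table.n_herbivores, bool)),
                    dict(a.metadata),
                )
                a, _ = datasets.drop_unusable_plants(a)
        df = metrics.build_plant_metrics(a, grafted, guild_scope=scope)
        df["assemblage_richness"] = a.table.n_herbivores
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=metrics.PLANT_METRIC_COLUMNS + ["assemblage_richness"])
    return pd.concat(frames, ignore_index=True)


def fit_scope(
    plant_metrics: pd.DataFrame,
    scope: str,
    alpha: float = 0.05,
    responses: tuple[str, ...] = RESPONSES,
    fallback_rule: str = "lrt",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fit the four models for one scope; returns (models, lrt, r2) frames."""
    model_rows, lrt_rows, r2_rows = [], [], []
    for response in responses:
        spec = ModelSpec(response=response, alpha=alpha, fallback_rule=fallback_rule)
        try:
            lrt, fit = glmm.fit_response(plant_metrics, spec)
        except (glmm.FitError, ValueError) as exc:
            logger.warning("scope %s response %s failed: %s", scope, response, exc)
            continue
        for i, term in enumerate(fit.terms):
            model_rows.append(
                {
                    "scope": scope,
                    "response": response,
                    "term": term,
                    "estimate": fit.estimates[i],
                    "se": fit.se[i],
                    "statistic": fit.statistics[i],
                    "stat_label": fit.stat_label,
                    "p": fit.pvalues[i],
                    "sigma_u": fit.sigma_u,
                    "sigma_resid": fit.sigma_resid,
                    "loglik": fit.loglik,
                    "n_obs": fit.n_obs,
                    "n_groups": fit.n_groups,
                }
            )
        lrt_rows.append(
            {
                "scope": scope,
                "response": response,
                "chi_squared": lrt.chi_squared,
                "df": lrt.df,
                "p": lrt.p_value,
                "kept_interaction": lrt.keep_interaction,
            }
        )
        r2_rows.append(
            {
                "scope": scope,
                "response": response,
                "r2_marginal": np.nan if fit.r2_marginal is None else fit.r2_marginal,
                "r2_conditional": np.nan if fit.r2_conditional is None else fit.r2_conditional,
                "mcfadden": np.nan if fit.mcfadden is None else fit.mcfadden,
                "fallback_used": fit.fallback_used,
            }
        )
    return pd.DataFrame(model_rows), pd.DataFrame(lrt_rows), pd.DataFrame(r2_rows)


def run_full_analysis(
    assemblages: list[Assemblage],
    phy: Phylogeny,
    scopes: tuple[str, ...] = SCOPES,
    alpha: float = 0.05,
    fallback_rule: str = "lrt",
) -> dict:
    """Run every scope; returns a bundle of tidy frames plus a text summary."""
    all_metrics, models, lrts, r2s, reports, removals = [], [], [], [], [], []
    for scope in scopes:
        kept, report, removal = prepare_scope(assemblages, scope)
        reports.append(report)
        removals.extend(removal)
        if not kept:
            logger.warning("no usable assemblages for scope %s", scope)
            continue
        pm = scope_metrics(kept, phy, scope)
        all_metrics.append(pm)
        m, l, r = fit_scope(pm, scope, alpha=alpha, fallback_rule=fallback_rule)
        models.append(m)
        lrts.append(l)
        r2s.append(r)
    if not all_metrics:
        raise PipelineError("no eligible assemblages in any scope")

    def _cat(frames):
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    bundle = {
        "plant_metrics": _cat(all_metrics),
        "models": _cat(models),
        "lrt": _cat(lrts),
        "r2": _cat(r2s),
        "eligibility": _cat(reports),
        "removals": datasets.removal_log_frame(removals),
    }
    bundle["summary"] = summarize_effects(bundle["models"])
    return bundle


def summarize_effects(models: pd.DataFrame) -> str:
    """Plain-text digest of effect signs and significance per scope."""
    if models.empty:
        return "no models fitted\n"
    lines = []
    for (scope, response), grp in models.groupby(["scope", "response"], sort=False):
        parts = []
        for term in ("PI", "PO", "PI:PO"):
            row = grp[grp["term"] == term]
            if row.empty:
                continue
            est = float(row["estimate"].iloc[0])
            p = float(row["p"].iloc[0])
            sig = "significant" if p < 0.05 else "ns"
            parts.append(f"{term} {'+' if est >= 0 else '-'} ({sig}, p={p:.3g})")
        lines.append(f"[{scope}] {response}: " + "; ".join(parts))
    return "\n".join(lines) + "\n"
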