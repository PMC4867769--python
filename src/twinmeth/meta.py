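"""Fixed-effects mean-difference meta-analysis for candidate-probe replication.

Candidate positions from the twin discovery scan are tested in independent
case-control cohorts summarized as per-group means and SDs of beta.  Per
cohort the effect is the raw mean difference ``MD = mean_case -
mean_control`` (beta is already a common scale, so no standardization) with
``SE = sqrt(sd_case^2/n_case + sd_control^2/n_control)``.  Cohorts are
pooled by inverse-variance weights ``w_k = 1/SE_k^2``:

    pooled MD = sum(w_k MD_k) / sum(w_k),   pooled SE = 1/sqrt(sum w_k)

with normal-approximation z inference, Cochran's heterogeneity statistic
``Q = sum w_k (MD_k - pooled)^2`` on ``k - 1`` df, and
``I^2 = max(0, (Q - df)/Q) * 100`` — the percentage of the variability in
effect estimates due to heterogeneity rather than sampling error.  P values
across the candidate set are Bonferroni-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .core_io import CohortSummary, MetaResult
from .enrichment import bonferroni


def cohort_mean_difference(summary: CohortSummary) -> tuple[float, float]:
    """(MD, SE) of the case-minus-control beta difference for one cohort."""
    md = summary.mean_case - summary.mean_control
    se = float(np.sqrt(summary.sd_case**2 / summary.n_case + summary.sd_control**2 / summary.n_control))
    return float(md), se


def fixed_effects_meta(effects: Sequence[tuple[float, float]], cohort_ids: Sequence[str] | None = None) -> MetaResult:
    """Inverse-variance fixed-effects pooling of (MD, SE) pairs."""
    if not effects:
        raise ValueError("need at least one cohort")
    md = np.array([e[0] for e in effects], dtype=float)
    se = np.array([e[1] for e in effects], dtype=float)
    if np.any(se <= 0):
        raise ValueError("every cohort SE must be positive")
    if cohort_ids is None:
        cohort_ids = [f"cohort{k + 1}" for k in range(len(effects))]
    w = 1.0 / se**2
    pooled_md = float(np.sum(w * md) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled_md / pooled_se
    p = float(2.0 * norm.sf(abs(z)))
    q = float(np.sum(w * (md - pooled_md) ** 2))
    het_df = len(effects) - 1
    het_p = float(chi2.sf(q, df=het_df)) if het_df > 0 else 1.0
    i2 = 0.0 if q <= 0 else max(0.0, (q - het_df) / q) * 100.0
    return MetaResult(
        per_cohort=[
            {"cohort_id": cid, "md": float(m), "se": float(s), "weight": float(wk)}
            for cid, m, s, wk in zip(cohort_ids, md, se, w)
        ],
        pooled_md=pooled_md,
        pooled_se=pooled_se,
        z_stat=float(z),
        p_value=p,
        q_stat=q,
        het_df=het_df,
        het_p=het_p,
        i_squared=float(i2),
    )


def meta_analyze_summaries(cohorts: Sequence[CohortSummary]) -> MetaResult:
    """Fixed-effects meta-analysis straight from cohort group summaries."""
    effects = [cohort_mean_difference(c) for c in cohorts]
    return fixed_effects_meta(effects, cohort_ids=[c.cohort_id for c in cohorts])


def candidate_replication(
    summaries: Mapping[str, Sequence[CohortSummary]],
    candidate_probe_ids: Sequence[str],
    n_tests: int | None = None,
) -> tuple[pd.DataFrame, dict[str, MetaResult]]:
    """Per-candidate meta-analysis with candidate-set Bonferroni adjustment.

    ``n_tests`` overrides the Bonferroni denominator (defaults to the number
    of candidates analysed).  Candidates absent from the summaries are
    excluded with a warning.  Returns the results table (sorted by P) and
    the per-probe :class:`MetaResult` objects (forest-plot data included).
    """
    results: dict[str, MetaResult] = {}
    for probe in candidate_probe_ids:
        if probe not in summaries or not summaries[probe]:
            warnings.warn(f"candidate {probe!r} missing from cohort summaries; excluded")
            continue
        results[probe] = meta_analyze_summaries(summaries[probe])
    if not results:
        raise ValueError("no candidate probe has cohort summaries")
    table = pd.DataFrame(
        {
            "pooled_md": {p: r.pooled_md for p, r in results.items()},
            "pooled_se": {p: r.pooled_se for p, r in results.items()},
            "z_stat": {p: r.z_stat for p, r in results.items()},
            "p_value": {p: r.p_value for p, r in results.items()},
            "q_stat": {p: r.q_stat for p, r in results.items()},
            "het_p": {p: r.het_p for p, r in results.items()},
            "i_squared": {p: r.i_squared for p, r in results.items()},
        }
    )
    table.index.name = "probe_id"
    table["bonferroni_p"] = bonferroni(
        table["p_value"].to_numpy(), n_tests=n_tests if n_tests is not None else len(table)
    )
    return table.sort_values("p_value", kind="mergesort"), results


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------


class FixedEffectsMeta:
    """Candidate-probe replication model over summary-level cohorts."""

    def __init__(
        self,
        summaries: Mapping[str, Sequence[CohortSummary]],
        candidate_probe_ids: Sequence[str] | None = None,
        n_tests: int | None = None,
    ) -> None:
        self.summaries = dict(summaries)
        self.candidates = list(candidate_probe_ids or self.summaries.keys())
        self.n_tests = n_tests

    def fit(self) -> "MetaReplicationResults":
        table, per_probe = candidate_replication(self.summaries, self.candidates, self.n_tests)
        return MetaReplicationResults(model=self, table=table, per_probe=per_probe)


@dataclass
class MetaReplicationResults:
    model: FixedEffectsMeta
    table: pd.DataFrame
    per_probe: dict[str, MetaResult]

    def forest_frame(self, probe_id: str) -> pd.DataFrame:
        return self.per_probe[probe_id].forest_frame()

    def summary(self, n: int = 13) -> str:
        lines = [
            "Fixed-effects replication meta-analysis",
            "=" * 57,
            f"candidates: {len(self.table)}   Bonferroni denominator: "
            f"{self.model.n_tests if self.model.n_tests is not None else len(self.table)}",
            self.table.head(n)[
                ["pooled_md", "pooled_se", "z_stat", "p_value", "bonferroni_p", "q_stat", "i_squared"]
            ].to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def plot_forest(self, probe_id: str, ax=None):
        """Forest plot: per-cohort MDs with 95% CIs and the pooled diamond."""
        import matplotlib.pyplot as plt

        frame = self.forest_frame(probe_id)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.6 * len(frame) + 1))
        y = np.arange(len(frame))[::-1]
        for yi, (_, row) in zip(y, frame.iterrows()):
            pooled = row["cohort"].startswith("pooled")
            color = "tab:blue" if pooled else "black"
            marker = "D" if pooled else "s"
            ax.plot([row["ci_lower"], row["ci_upper"]], [yi, yi], color=color, lw=1.2)
            ax.plot(row["md"], yi, marker, color=color)
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(frame["cohort"])
        ax.set_xlabel("mean $\\beta$ difference (case $-$ control)")
        ax.set_title(probe_id)
        return ax
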