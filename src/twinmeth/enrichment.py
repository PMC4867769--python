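"""Probe-bias-corrected gene-set enrichment.

Array-based gene-set testing is biased: a gene covered by many probes has
more chances to be annotated to a significant position.  The correction
follows the probability-weighting-function approach: regress the per-gene
"differentially methylated" indicator on the per-gene probe count with a
monotone (isotonic / pool-adjacent-violators) fit, giving each gene an
estimated selection probability; a category's over-representation P is then
the upper tail of the Wallenius noncentral hypergeometric distribution —
biased sampling without replacement — with the odds in favour of in-category
genes derived from the mean weight inside vs outside the category.  With
constant weights the odds are 1 and the test collapses to the one-sided
Fisher/hypergeometric tail exactly.

Gene universe: all genes with at least one retained probe (the correction is
defined only on measurable genes).  A gene is "DE" when it is annotated to
at least one position passing the chosen discovery threshold.  One-sided
over-representation only; Bonferroni adjustment across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, nchypergeom_wallenius
from sklearn.isotonic import IsotonicRegression

from .core_io import ProbeAnnotation


def probe_count_bias(annotation: ProbeAnnotation, retained_probe_ids: Sequence[str]) -> pd.Series:
    """Retained-probe count per gene symbol (the bias covariate).

    A probe annotated to several genes contributes one count to each; genes
    with zero retained probes are excluded (they are not measurable).
    """
    frame = annotation.frame.loc[list(retained_probe_ids)]
    counts: dict[str, int] = {}
    for genes in frame["gene_labels"]:
        for gene in genes:
            counts[gene] = counts.get(gene, 0) + 1
    if not counts:
        return pd.Series(dtype=int, name="probe_count")
    series = pd.Series(counts, name="probe_count").sort_index()
    series.index.name = "gene"
    return series


def genes_hit(
    annotation: ProbeAnnotation, significant_probe_ids: Iterable[str]
) -> set[str]:
    """Genes annotated to at least one significant probe."""
    hits: set[str] = set()
    index = annotation.frame.index
    for probe in significant_probe_ids:
        if probe in index:
            hits.update(annotation.frame.at[probe, "gene_labels"])
    return hits


def fit_pwf(de_flags: pd.Series, bias: pd.Series) -> pd.DataFrame:
    """Monotone probability weighting function: P(DE) as a function of bias.

    Isotonic regression of the 0/1 DE indicator on probe count, clipped to
    [1/(2N), 1 - 1/(2N)] so no gene has weight exactly 0 or 1.  Constant
    bias yields the constant fit mean(de_flag).  Returns a frame indexed by
    gene with columns bias, de_flag, pwf.
    """
    genes = de_flags.index
    if not genes.equals(bias.index):
        bias = bias.reindex(genes)
        if bias.isna().any():
            raise ValueError("bias missing for some genes")
    n = len(genes)
    if n < 20:
        raise ValueError("need >= 20 genes to fit a weighting function")
    flags = de_flags.astype(float)
    if flags.sum() == 0:
        raise ValueError("no DE gene: nothing to enrich")
    if flags.sum() == n:
        raise ValueError("every gene is DE: weighting function degenerate")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    order = np.argsort(bias.to_numpy(), kind="mergesort")
    x = bias.to_numpy(dtype=float)[order]
    y = flags.to_numpy()[order]
    fitted = iso.fit_transform(x, y)
    pwf = np.empty(n)
    pwf[order] = fitted
    pwf = np.clip(pwf, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    return pd.DataFrame(
        {"bias": bias.to_numpy(), "de_flag": de_flags.astype(bool).to_numpy(), "pwf": pwf},
        index=pd.Index(genes, name="gene"),
    )


def _wallenius_tail(n_universe: int, n_term: int, n_de: int, x: int, odds: float) -> float:
    """P(X >= x) for DE genes falling in the term under biased sampling."""
    if x <= 0:
        return 1.0
    if abs(odds - 1.0) < 1e-12:
        return float(hypergeom.sf(x - 1, n_universe, n_term, n_de))
    return float(nchypergeom_wallenius.sf(x - 1, n_universe, n_term, n_de, odds))


def category_test(
    gene_sets: Mapping[str, Iterable[str]],
    pwf_table: pd.DataFrame,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Wallenius over-representation test per category.

    For each term the observed count of DE genes inside it is compared with
    the Wallenius noncentral hypergeometric upper tail at odds
    ``(w_in/(1-w_in)) / (w_out/(1-w_out))`` where ``w_in``/``w_out`` are the
    mean weighting-function values inside/outside the term (restricted to
    the gene universe).  Returns term, set size in universe, DE count, odds,
    nominal P and Bonferroni-adjusted P, sorted by nominal P.
    """
    universe = set(pwf_table.index)
    n_universe = len(universe)
    n_de = int(pwf_table["de_flag"].sum())
    rows = []
    for term, genes in gene_sets.items():
        members = sorted(universe.intersection(genes))
        if len(members) < min_set_size:
            continue
        if len(members) == n_universe:
            raise ValueError(f"term {term!r} covers the whole gene universe")
        inside = pwf_table.loc[members]
        outside = pwf_table.drop(index=members)
        w_in = float(inside["pwf"].mean())
        w_out = float(outside["pwf"].mean())
        odds = (w_in / (1.0 - w_in)) / (w_out / (1.0 - w_out))
        x = int(inside["de_flag"].sum())
        p = _wallenius_tail(n_universe, len(members), n_de, x, odds)
        rows.append(
            {
                "term": term,
                "set_size": len(members),
                "n_de": x,
                "odds": odds,
                "p_value": min(p, 1.0),
            }
        )
    if not rows:
        raise ValueError("no gene set intersects the gene universe")
    table = pd.DataFrame(rows).set_index("term")
    table["bonferroni_p"] = bonferroni(table["p_value"].to_numpy())
    return table.sort_values("p_value", kind="mergesort")


def bonferroni(p_values: np.ndarray | Sequence[float], n_tests: int | None = None) -> np.ndarray:
    """min(1, P * n_tests); n_tests defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    n = n_tests if n_tests is not None else len(p)
    return np.minimum(1.0, p * n)


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------


class GeneSetEnrichment:
    """Probe-bias-corrected over-representation analysis.

    Parameters
    ----------
    annotation : ProbeAnnotation
        Probe-to-gene mapping for the retained probes.
    retained_probe_ids : sequence of str
        Probes surviving QC (defines the measurable gene universe).
    significant_probe_ids : sequence of str
        Discovery positions (e.g. the extended-threshold table) whose genes
        form the DE set.
    gene_sets : mapping term -> genes
    """

    def __init__(
        self,
        annotation: ProbeAnnotation,
        retained_probe_ids: Sequence[str],
        significant_probe_ids: Sequence[str],
        gene_sets: Mapping[str, Iterable[str]],
    ) -> None:
        self.annotation = annotation
        self.retained_probe_ids = list(retained_probe_ids)
        self.significant_probe_ids = list(significant_probe_ids)
        self.gene_sets = dict(gene_sets)

    def fit(self) -> "EnrichmentResults":
        bias = probe_count_bias(self.annotation, self.retained_probe_ids)
        hits = genes_hit(self.annotation, self.significant_probe_ids)
        de_flags = pd.Series(
            [g in hits for g in bias.index], index=bias.index, dtype=bool, name="de_flag"
        )
        pwf = fit_pwf(de_flags, bias)
        table = category_test(self.gene_sets, pwf)
        return EnrichmentResults(model=self, pwf=pwf, table=table)


@dataclass
class EnrichmentResults:
    model: "GeneSetEnrichment"
    pwf: pd.DataFrame
    table: pd.DataFrame

    def summary(self, n: int = 10) -> str:
        n_de = int(self.pwf["de_flag"].sum())
        lines = [
            "Gene-set over-representation (probe-count bias corrected)",
            "=" * 57,
            f"gene universe: {len(self.pwf)}   DE genes: {n_de}   terms tested: {len(self.table)}",
            f"terms at nominal P < 0.05: {int((self.table['p_value'] < 0.05).sum())}, "
            f"Bonferroni-significant: {int((self.table['bonferroni_p'] < 0.05).sum())}",
            self.table.head(n).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
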