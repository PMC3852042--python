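"""Per-GO-term fractionation trends.

For every functional category the analysis asks: does the fraction of
homology sets annotated with the term rise or fall with fractionation score?
Because high-score sets contain more genes and therefore hit more terms, raw
hit counts are biased upward with score; the normalised proportion divides,
at each score, the number of sets hitting the term by the number of sets
hitting *any* term of the same namespace root.  The per-term trend is an
ordinary least-squares regression of the set-level presence indicator on
fractionation score over that same namespace population; a significantly
negative slope marks a fractionation-prone category, a significantly
positive slope a fractionation-resistant one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import OntologyDAG

__all__ = [
    "TrendModel",
    "TrendResults",
    "normalized_proportion",
    "term_regression",
    "cross_group_consistency",
    "compare_to_background",
]


def _namespace_of_sets(
    set_annotations: Mapping[str, frozenset[str]], dag: OntologyDAG
) -> dict[str, set[str]]:
    """Namespaces hit by each set (annotation assumed ancestor-closed)."""
    return {
        sid: {dag.namespace[t] for t in terms if t in dag.namespace}
        for sid, terms in set_annotations.items()
    }


def normalized_proportion(
    term: str,
    score: int,
    set_annotations: Mapping[str, frozenset[str]],
    scores: Mapping[str, int],
    dag: OntologyDAG,
) -> dict:
    """Hits / namespace denominator for one term at one fractionation score.

    ``hits`` counts sets at this score annotated with the term; ``denom``
    counts sets at this score hitting at least one term under the same
    namespace root.  ``proportion`` is None when the denominator is 0 (the
    point is undefined and should be omitted from plots).
    """
    ns = dag.namespace[term]
    hits = 0
    denom = 0
    for sid, terms in set_annotations.items():
        if scores.get(sid) != score:
            continue
        if any(t in dag.namespace and dag.namespace[t] == ns for t in terms):
            denom += 1
            if term in terms:
                hits += 1
    prop = hits / denom if denom else None
    return {
        "term_id": term,
        "score": score,
        "hits": hits,
        "denom": denom,
        "proportion": prop,
    }


def term_regression(
    term: str,
    set_annotations: Mapping[str, frozenset[str]],
    scores: Mapping[str, int],
    dag: OntologyDAG,
    alpha_level: float = 0.05,
) -> dict:
    """OLS regression of the term-presence indicator on fractionation score.

    Data points are all sets hitting at least one term of the term's
    namespace (the same population as the normalisation denominator); y is
    the 0/1 presence of the term, x the set's score.  The slope's two-sided
    t-test decides the call: prone (negative, significant), resistant
    (positive, significant), else neutral.
    """
    ns = dag.namespace[term]
    x, y = [], []
    for sid, terms in set_annotations.items():
        if sid not in scores:
            continue
        if any(t in dag.namespace and dag.namespace[t] == ns for t in terms):
            x.append(scores[sid])
            y.append(1.0 if term in terms else 0.0)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(np.unique(x)) < 2:
        raise ValueError(
            f"term {term}: regression needs >=3 points with >=2 distinct scores"
        )
    if np.all(y == y[0]):  # constant indicator: slope 0 by construction
        slope, pval = 0.0, 1.0
    else:
        reg = stats.linregress(x, y)
        slope, pval = float(reg.slope), float(reg.pvalue)
    if pval < alpha_level and slope < 0:
        call = "prone"
    elif pval < alpha_level and slope > 0:
        call = "resistant"
    else:
        call = "neutral"
    return {
        "term_id": term,
        "namespace": ns,
        "slope": slope,
        "p_value": pval,
        "n_points": n,
        "call": call,
    }


class TrendModel:
    """Per-term trend regressions over a collection of scored homology sets.

    Parameters
    ----------
    set_annotations
        Mapping set_id -> ancestor-closed GO term set.
    scores
        Mapping set_id -> fractionation score.
    dag
        The loaded ontology.
    terms
        Terms to analyse; defaults to the high-level terms (direct children
        of the namespace roots) present in at least one set.
    alpha_level
        Significance threshold for the prone/resistant call.
    """

    def __init__(
        self,
        set_annotations: Mapping[str, frozenset[str]],
        scores: Mapping[str, int],
        dag: OntologyDAG,
        terms: Optional[Iterable[str]] = None,
        alpha_level: float = 0.05,
        group_name: str = "group",
    ):
        # sets with no GO hit at all are excluded up front
        self.set_annotations = {
            k: v for k, v in set_annotations.items() if v and k in scores
        }
        self.n_excluded_no_hit = sum(
            1 for k, v in set_annotations.items() if not v
        )
        self.scores = dict(scores)
        self.dag = dag
        self.alpha_level = float(alpha_level)
        self.group_name = group_name
        if terms is None:
            present = set().union(*self.set_annotations.values()) if self.set_annotations else set()
            terms = sorted(dag.high_level_terms() & present)
        self.terms = list(terms)

    def fit(self, correction: Optional[str] = None) -> "TrendResults":
        """Run all per-term regressions.

        ``correction="bh"`` applies Benjamini-Hochberg across terms before
        the prone/resistant call (off by default).
        """
        rows = []
        for t in self.terms:
            try:
                rows.append(
                    term_regression(
                        t, self.set_annotations, self.scores, self.dag,
                        self.alpha_level,
                    )
                )
            except ValueError:
                continue
        table = pd.DataFrame(
            rows,
            columns=["term_id", "namespace", "slope", "p_value", "n_points", "call"],
        )
        if correction == "bh" and len(table):
            from statsmodels.stats.multitest import multipletests

            rej, padj, *_ = multipletests(
                table["p_value"], alpha=self.alpha_level, method="fdr_bh"
            )
            table["p_adjusted"] = padj
            table["call"] = np.where(
                rej & (table["slope"] < 0),
                "prone",
                np.where(rej & (table["slope"] > 0), "resistant", "neutral"),
            )
        return TrendResults(model=self, table=table)

    def trend_points(self, term: str) -> pd.DataFrame:
        """Normalised proportion of ``term`` at every observed score."""
        rows = [
            normalized_proportion(term, s, self.set_annotations, self.scores, self.dag)
            for s in sorted(set(self.scores[k] for k in self.set_annotations))
        ]
        return pd.DataFrame(rows)


@dataclass
class TrendResults:
    model: TrendModel
    table: pd.DataFrame

    def summary(self) -> str:
        t = self.table
        lines = [
            f"Fractionation trends: {self.model.group_name}",
            "=" * 60,
            f"sets analysed:      {len(self.model.set_annotations)}"
            f" (excluded, no GO hit: {self.model.n_excluded_no_hit})",
            f"terms analysed:     {len(t)}",
            f"alpha level:        {self.model.alpha_level}",
            f"prone:              {(t['call'] == 'prone').sum()}",
            f"resistant:          {(t['call'] == 'resistant').sum()}",
            f"neutral:            {(t['call'] == 'neutral').sum()}",
        ]
        return "\n".join(lines)

    def trend_points(self, term: str) -> pd.DataFrame:
        return self.model.trend_points(term)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, terms: Optional[Sequence[str]] = None, ax=None):
        """Proportion-vs-score curves, thick lines for significant terms."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        table = self.table.set_index("term_id")
        if terms is None:
            terms = list(table.index)
        for term in terms:
            pts = self.trend_points(term).dropna(subset=["proportion"])
            call = table.loc[term, "call"] if term in table.index else "neutral"
            lw = 2.8 if call != "neutral" else 1.0
            color = {"prone": "black", "resistant": "red"}.get(call, "grey")
            label = self.model.dag.name.get(term) or term
            ax.plot(pts["score"], pts["proportion"], lw=lw, color=color, label=label)
        ax.set_xlabel("fractionation score")
        ax.set_ylabel("normalised proportion of sets")
        ax.set_title(self.model.group_name)
        ax.legend(fontsize=7)
        return ax


def cross_group_consistency(results: Sequence[TrendResults]) -> pd.DataFrame:
    """Compare per-term calls across independently analysed species groups.

    A term is ``consistent`` when it is significant in at least one group
    and every group that measured it agrees on the slope sign;
    ``conflicting`` when it is significant in opposite directions in two or
    more groups; otherwise ``unclassified``.
    """
    if len(results) < 2:
        raise ValueError("need at least two group trend tables")
    tables = {r.model.group_name: r.table.set_index("term_id") for r in results}
    universe = sorted(set().union(*(set(t.index) for t in tables.values())))
    rows = []
    for term in universe:
        slopes, calls = {}, {}
        for gname, t in tables.items():
            if term in t.index:
                slopes[gname] = float(t.loc[term, "slope"])
                calls[gname] = t.loc[term, "call"]
        sig_dirs = {np.sign(s) for g, s in slopes.items() if calls[g] != "neutral"}
        n_groups = len(slopes)
        all_signs = {np.sign(s) for s in slopes.values() if s != 0}
        if len(sig_dirs) >= 2:
            flag = "conflicting"
        elif (
            n_groups == len(tables)
            and len(sig_dirs) == 1
            and len(all_signs) <= 1
        ):
            flag = "consistent"
        else:
            flag = "unclassified"
        row = {"term_id": term, "flag": flag}
        for gname in tables:
            row[f"slope_{gname}"] = slopes.get(gname, np.nan)
            row[f"call_{gname}"] = calls.get(gname, "absent")
        rows.append(row)
    return pd.DataFrame(rows)


def compare_to_background(
    set_annotations: Mapping[str, frozenset[str]],
    background_gene_annotations: Mapping[str, frozenset[str]],
    dag: OntologyDAG,
    terms: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Compare term proportions in homology sets against a background sample.

    The background is a collection of genes annotated and ancestor-closed
    exactly like sets (each gene acting as a one-member set), e.g. a random
    sample drawn from the extant genomes unconstrained by synteny.  For each
    term the namespace-normalised proportion is computed in both
    collections; the difference is tested with a two-proportion z-test.
    """
    if not background_gene_annotations:
        raise ValueError("background annotation table is empty")
    from statsmodels.stats.proportion import proportions_ztest

    if terms is None:
        present = set().union(*set_annotations.values()) if set_annotations else set()
        terms = sorted(dag.high_level_terms() & present)

    def tally(annotations, term, ns):
        hits = denom = 0
        for t_set in annotations.values():
            if any(t in dag.namespace and dag.namespace[t] == ns for t in t_set):
                denom += 1
                if term in t_set:
                    hits += 1
        return hits, denom

    rows = []
    for term in terms:
        ns = dag.namespace[term]
        h1, d1 = tally(set_annotations, term, ns)
        h2, d2 = tally(background_gene_annotations, term, ns)
        if d1 == 0 or d2 == 0:
            continue
        p1, p2 = h1 / d1, h2 / d2
        if (h1 + h2) in (0, d1 + d2):  # identical degenerate proportions
            pval = 1.0
        else:
            _, pval = proportions_ztest([h1, h2], [d1, d2])
        rows.append(
            {
                "term_id": term,
                "namespace": ns,
                "prop_sets": p1,
                "prop_background": p2,
                "difference": p1 - p2,
                "p_value": float(pval),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id", "namespace", "prop_sets", "prop_background",
            "difference", "p_value",
        ],
    )
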