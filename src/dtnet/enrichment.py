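"""Hypergeometric over-representation analysis of node sets.

Given a query set of nodes (a community, a hub's target set, a retained
drug subset) and a user-supplied annotation table mapping terms (disease
classes, pathways) to nodes, each term is scored with the upper-tail
hypergeometric probability of observing at least the seen number of
annotated query nodes, with optional Benjamini-Hochberg adjustment.  The
background set is an explicit required input -- results are only
interpretable relative to the stated universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AnnotationMap:
    """term -> annotated node set, plus the annotation universe."""

    terms: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} annotates no nodes")
            stray = members - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} annotates nodes outside the background: "
                    f"{sorted(stray)[:5]}"
                )


def read_annotation_table(
    path: Union[str, Path], background: Iterable[str] | None = None
) -> AnnotationMap:
    """Read a two-column TSV (term, node_id) into an AnnotationMap.

    When ``background`` is omitted it defaults to the union of all
    annotated nodes.
    """
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["term", "node"], dtype=str
    )
    terms: dict[str, set[str]] = {}
    for term, node in frame.itertuples(index=False):
        terms.setdefault(term, set()).add(node)
    bg = (
        frozenset(background)
        if background is not None
        else frozenset().union(*terms.values())
    )
    return AnnotationMap(
        terms={t: frozenset(m) for t, m in terms.items()}, background=bg
    )


def enrich(
    query: Iterable[str],
    annotations: AnnotationMap,
    correction: str = "bh",
) -> pd.DataFrame:
    """Over-representation test of ``query`` against every annotation term.

    Returns a DataFrame with columns term, query_hits, term_size,
    background_size, query_size, p_value, adjusted_p, sorted by adjusted_p
    (ties by term).  ``correction`` is ``"bh"`` (Benjamini-Hochberg step-up)
    or ``"none"`` (adjusted_p = p_value).
    """
    query_set = set(query)
    stray = query_set - annotations.background
    if stray:
        raise ValueError(
            f"query nodes outside the background: {sorted(stray)[:10]}"
        )
    if correction not in {"bh", "none"}:
        raise ValueError(f"unknown correction {correction!r}")

    m_bg = len(annotations.background)
    n_query = len(query_set)
    rows = []
    for term in sorted(annotations.terms):
        members = annotations.terms[term]
        hits = len(members & query_set)
        # P(X >= hits), X ~ Hypergeom(M=m_bg, n=|term|, N=n_query)
        p = float(stats.hypergeom.sf(hits - 1, m_bg, len(members), n_query))
        p = min(p, 1.0)
        rows.append((term, hits, len(members), m_bg, n_query, p))
    table = pd.DataFrame(
        rows,
        columns=[
            "term",
            "query_hits",
            "term_size",
            "background_size",
            "query_size",
            "p_value",
        ],
    )
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        _, adjusted, _, _ = multipletests(
            table["p_value"].to_numpy(), method="fdr_bh"
        )
        table["adjusted_p"] = adjusted
    else:
        table["adjusted_p"] = table["p_value"]
    table = table.sort_values(
        ["adjusted_p", "p_value", "term"], kind="mergesort"
    ).reset_index(drop=True)
    return table
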