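"""Gene strand bias vs leading-strand AT skew across species, using
phylogenetically independent terminal-node-pair contrasts.

For each species a strand-bias index and a whole-genome leading-strand AT
skew are summarized; differences (contrasts) are then taken between disjoint
terminal-node pairs of a phylogeny, which avoids pseudo-replication from
shared ancestry.  If strand bias drives positive AT skew, contrasts should
regress with a positive slope through the origin, and the signs of the two
deltas should agree more often than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genome import GeneAnnotation, ReplichoreMap


def strand_bias_index(
    annotations: list[GeneAnnotation],
    replichore_map: ReplichoreMap,
    method: str = "leading_fraction",
) -> float:
    """Degree of gene co-orientation with the replication fork.

    ``leading_fraction`` (the tested default) is 100 * (leading-strand coding
    bases) / (total coding bases), a 0-100 index where 50 means no bias.
    ``gespi`` refers to the gene-strand-preference index of de Carvalho &
    Ferreira (2007); its formula is not transcribable here, so requesting it
    raises NotImplementedError rather than guessing.
    """
    genes = [g for g in annotations if g.kind == "CDS"]
    if not genes:
        raise ValueError("no genes")
    if method == "leading_fraction":
        total = sum(g.length for g in genes)
        leading = sum(g.length for g in genes if replichore_map.gene_is_leading(g))
        return 100.0 * leading / total
    if method == "gespi":
        raise NotImplementedError(
            "the gespi index is defined in de Carvalho & Ferreira (2007), which is "
            "not available to transcribe; use method='leading_fraction'"
        )
    raise ValueError(f"unknown method {method!r}")


def _split_node(field: str) -> list[str]:
    return [s.strip() for s in str(field).replace(";", ",").split(",") if s.strip()]


def make_contrasts(pairs: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-pair deltas of strand bias and leading AT skew.

    ``pairs`` has columns ``node_a`` and ``node_b``; each field lists one or
    more species ids (comma/semicolon separated), averaged within a node.
    ``summaries`` has columns ``species_id``, ``strand_bias``,
    ``leading_at_skew``.  Deltas are node_a - node_b in the table's row
    order.  Pairs must be disjoint (no species reused), else the contrasts
    are not independent.
    """
    lookup = summaries.set_index("species_id")
    seen: set[str] = set()
    rows = []
    for k, row in pairs.reset_index(drop=True).iterrows():
        a_species = _split_node(row["node_a"])
        b_species = _split_node(row["node_b"])
        this_pair = set(a_species) | set(b_species)
        overlap = this_pair & seen
        if overlap:
            raise ValueError(f"species {sorted(overlap)} appear in more than one pair")
        seen |= this_pair
        for sp in this_pair:
            if sp not in lookup.index:
                raise KeyError(f"no summary for species {sp!r}")
        a = lookup.loc[a_species]
        b = lookup.loc[b_species]
        rows.append(
            {
                "pair": k,
                "node_a": ",".join(a_species),
                "node_b": ",".join(b_species),
                "d_bias": float(a["strand_bias"].mean() - b["strand_bias"].mean()),
                "d_skew": float(a["leading_at_skew"].mean() - b["leading_at_skew"].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ContrastRegression:
    slope: float
    intercept: float
    r_squared: float
    slope_P: float
    intercept_P: float
    sign_test_P: float
    n: int
    n_sign_informative: int


def contrast_regression(contrasts: pd.DataFrame) -> ContrastRegression:
    """OLS of d_skew on d_bias plus a one-sided binomial sign test.

    The regression keeps an intercept so its consistency with zero can be
    tested.  The sign test asks whether positive d_bias predicts positive
    d_skew: pairs with either delta exactly zero are dropped, and agreement
    is tested against Binomial(n, 1/2), one-sided.
    """
    if len(contrasts) < 3:
        raise ValueError("need at least 3 contrasts")
    x = contrasts["d_bias"].to_numpy(dtype=float)
    y = contrasts["d_skew"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("d_bias has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    informative = (x != 0) & (y != 0)
    agree = int((np.sign(x[informative]) == np.sign(y[informative])).sum())
    n_inf = int(informative.sum())
    sign_p = float(stats.binomtest(agree, n_inf, 0.5, alternative="greater").pvalue) if n_inf else float("nan")
    return ContrastRegression(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        slope_P=float(model.pvalues[1]),
        intercept_P=float(model.pvalues[0]),
        sign_test_P=sign_p,
        n=len(contrasts),
        n_sign_informative=n_inf,
    )


def validate_pairs_with_tree(pairs: pd.DataFrame, tree_path: str) -> None:
    """Check that every species in the pairs table is a terminal taxon of the
    newick tree and that no species is reused across pairs."""
    from Bio import Phylo

    tree = Phylo.read(tree_path, "newick")
    tips = {t.name for t in tree.get_terminals()}
    seen: set[str] = set()
    for _, row in pairs.iterrows():
        this_pair = set(_split_node(row["node_a"])) | set(_split_node(row["node_b"]))
        for sp in this_pair:
            if sp not in tips:
                raise ValueError(f"species {sp!r} is not a terminal taxon of the tree")
        overlap = this_pair & seen
        if overlap:
            raise ValueError(f"species {sorted(overlap)} appear in more than one pair")
        seen |= this_pair
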