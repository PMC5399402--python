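"""Fisher-exact over/under-representation of functional bins.

For each bin with at least one background gene, the number of list
genes in the bin k ~ Hypergeom(N, K, n) under the null; p_over is the
upper tail P(X >= k), p_under the lower tail P(X <= k).  Both one-sided
tests are reported separately (over- and under-representation carry
distinct biological meaning), Bonferroni-corrected across the bins
actually tested.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

ALPHA = 0.05


def fisher_ora(
    gene_list: Iterable[str],
    background: Iterable[str],
    annotation: pd.DataFrame,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Hypergeometric enrichment of annotation bins in a gene list.

    ``annotation`` has columns ``gene_id`` and ``bin_path``; a gene may
    map to several bins.  Returns one row per tested bin sorted by
    ``p_over``, with Bonferroni-adjusted p values and a direction call
    ('over', 'under' or 'none') from the smaller adjusted tail at
    ``alpha``.
    """
    genes = set(gene_list)
    bg = set(background)
    outside = genes - bg
    if outside:
        raise ValidationError(
            "gene(s) in list absent from background: "
            + ", ".join(sorted(outside)[:10])
        )
    N = len(bg)
    n = len(genes)
    ann = annotation.loc[annotation["gene_id"].isin(bg)]
    rows = []
    for bin_path, grp in ann.groupby("bin_path", sort=True):
        members = set(grp["gene_id"])
        K = len(members)
        k = len(members & genes)
        p_over = float(hypergeom.sf(k - 1, N, K, n))
        p_under = float(hypergeom.cdf(k, N, K, n))
        rows.append((bin_path, k, n, K, N, p_over, p_under))
    if not rows:
        raise ValidationError("no bins with background members to test")
    table = pd.DataFrame(
        rows, columns=["bin", "k", "n", "K", "N", "p_over", "p_under"]
    )
    table["adj_p_over"] = multipletests(table["p_over"], method="bonferroni")[1]
    table["adj_p_under"] = multipletests(table["p_under"], method="bonferroni")[1]

    def _direction(row) -> str:
        if row["adj_p_over"] < row["adj_p_under"] and row["adj_p_over"] < alpha:
            return "over"
        if row["adj_p_under"] < row["adj_p_over"] and row["adj_p_under"] < alpha:
            return "under"
        return "none"

    table["direction"] = table.apply(_direction, axis=1)
    table = table.sort_values(
        ["p_over", "bin"], kind="mergesort", ignore_index=True
    )
    return table
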