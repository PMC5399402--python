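"""Gene filtering, autoscaling, and response (Y) construction.

The expression filter keeps a gene only if (a) at least one
(treatment, storage-day) cell has a replicate sum above the RPKM
threshold and (b) the gene is detected (replicate sum > 0) in at least
two such cells.  Metabolite blocks are not filtered.

Autoscaling is the chemometrics convention: mean centre each variable,
then divide by its sample standard deviation (n-1 denominator).
Zero-variance variables cannot be scaled and are dropped with a report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import OmicsBlock, TREATMENTS
from .errors import ValidationError

RPKM_THRESHOLD = 5.0

RULE_ABUNDANCE = "cell_sum_threshold"
RULE_DETECTION = "single_cell_detection"


@dataclass
class FilterReport:
    """Which genes were removed and by which rule."""

    table: pd.DataFrame  # columns: gene_id, rule_failed
    n_input: int
    n_kept: int

    @property
    def removed_by_rule(self) -> dict[str, int]:
        return self.table["rule_failed"].value_counts().to_dict()


def filter_genes(
    expr: OmicsBlock,
    meta: pd.DataFrame,
    threshold: float = RPKM_THRESHOLD,
) -> tuple[OmicsBlock, FilterReport]:
    """Apply the two-rule RPKM expression filter.

    Rule (a): some (treatment, day) cell has replicate sum > ``threshold``.
    Rule (b): replicate sum > 0 in at least two cells ("detected at more
    than one treatment/storage duration combination").
    Genes failing (a) are reported under that rule even if they also
    fail (b).
    """
    missing = set(expr.sample_ids) - set(meta["sample_id"])
    if missing:
        raise ValidationError(
            "samples absent from metadata: " + ", ".join(sorted(missing)[:10])
        )
    cell = meta.set_index("sample_id").loc[expr.sample_ids]
    cell_key = cell["treatment"].astype(str) + "@" + cell["day"].astype(str)
    sums = expr.data.groupby(cell_key.to_numpy()).sum()  # cells x genes
    rule_a = (sums > threshold).any(axis=0)
    rule_b = (sums > 0).sum(axis=0) >= 2
    keep = rule_a & rule_b
    removed = []
    for gene in expr.data.columns[~keep]:
        rule = RULE_ABUNDANCE if not rule_a[gene] else RULE_DETECTION
        removed.append((gene, rule))
    report = FilterReport(
        table=pd.DataFrame(removed, columns=["gene_id", "rule_failed"]),
        n_input=expr.n_variables,
        n_kept=int(keep.sum()),
    )
    filtered = OmicsBlock(expr.name, expr.data.loc[:, keep[keep].index])
    return filtered, report


@dataclass
class AutoscaleResult:
    """Autoscaled block plus the statistics needed to invert the transform."""

    block: OmicsBlock
    means: pd.Series
    sds: pd.Series
    dropped: list[str]

    def inverse(self, scaled: OmicsBlock | None = None) -> OmicsBlock:
        blk = self.block if scaled is None else scaled
        raw = blk.data * self.sds + self.means
        return OmicsBlock(blk.name, raw)


def autoscale(block: OmicsBlock) -> AutoscaleResult:
    """Mean-centre and unit-variance scale every variable (sd with n-1).

    Constant (zero-variance) variables are dropped and listed in the
    result rather than raising.
    """
    if block.n_samples < 2:
        raise ValidationError("autoscaling requires at least 2 samples")
    means = block.data.mean(axis=0)
    sds = block.data.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = list(block.data.columns[~keep])
    data = (block.data.loc[:, keep] - means[keep]) / sds[keep]
    return AutoscaleResult(
        block=OmicsBlock(block.name, data),
        means=means[keep],
        sds=sds[keep],
        dropped=dropped,
    )


def log2_transform(block: OmicsBlock, pseudocount: float = 1.0) -> OmicsBlock:
    """Optional log2(x + pseudocount) pre-transform for abundance blocks."""
    if (block.values < 0).any():
        raise ValidationError("log2 transform requires non-negative values")
    return OmicsBlock(block.name, np.log2(block.data + pseudocount))


@dataclass
class ResponseDesign:
    """The Y matrix: treatment indicators, storage day, scald severity.

    ``raw`` holds the dummy-coded/continuous columns before scaling;
    ``data`` the autoscaled version actually used for model fitting
    (same convention as the X blocks, so both sides share a scale).
    """

    raw: pd.DataFrame
    data: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)


def build_response(
    meta: pd.DataFrame, treatments: tuple[str, ...] = TREATMENTS
) -> ResponseDesign:
    """Dummy-code treatment and append continuous day and scald columns."""
    unknown = sorted(set(meta["treatment"]) - set(treatments))
    if unknown:
        raise ValidationError("unknown treatment label(s): " + ", ".join(unknown))
    raw = pd.DataFrame(index=pd.Index(meta["sample_id"], name="sample_id"))
    for t in treatments:
        raw[t] = (meta["treatment"] == t).astype(float).to_numpy()
    raw["day"] = meta["day"].astype(float).to_numpy()
    raw["scald"] = meta["scald"].astype(float).to_numpy()
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    if (sds == 0).any():
        const = list(raw.columns[sds == 0])
        raise ValidationError(
            "constant response column(s): " + ", ".join(const)
        )
    data = (raw - means) / sds
    return ResponseDesign(raw=raw, data=data, means=means, sds=sds)
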