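"""Core data container and TSV readers/writers.

The on-disk convention follows the usual omics layout: expression and
metabolite tables are written with *variables as rows* (genes/metabolites)
and *samples as columns*.  In memory an :class:`OmicsBlock` holds the
transposed samples x variables matrix, which is the orientation every
multivariate routine in this package expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DuplicateIdError, ValidationError

TREATMENTS = ("control", "DPA", "MCP")
META_COLUMNS = ("sample_id", "treatment", "day", "replicate", "scald")


@dataclass
class OmicsBlock:
    """One data block (samples x variables) of the multi-block model.

    Parameters
    ----------
    name:
        Block label, e.g. ``"transcriptome"`` or ``"metabolome"``.
    data:
        DataFrame indexed by sample id with one column per variable.
        Values must be finite; RPKM for expression, relative abundance
        for metabolites (both non-negative on the raw scale; scaled
        blocks may of course be negative).
    """

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique()
            raise DuplicateIdError("sample", dup)
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique()
            raise DuplicateIdError("variable", dup)
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError(
                f"block '{self.name}' contains non-numeric values"
            )
        if not np.isfinite(values).all():
            bad = self.data.columns[~np.isfinite(values).all(axis=0)]
            raise ValidationError(
                f"block '{self.name}' has non-finite values in: "
                + ", ".join(map(str, bad[:10]))
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_variables(self, ids: Sequence[str]) -> "OmicsBlock":
        return OmicsBlock(self.name, self.data.loc[:, list(ids)])

    def select_samples(self, ids: Sequence[str]) -> "OmicsBlock":
        return OmicsBlock(self.name, self.data.loc[list(ids), :])


def check_aligned(blocks: Iterable[OmicsBlock]) -> list[str]:
    """Verify all blocks share the same sample ids in the same order."""
    blocks = list(blocks)
    ref = blocks[0].sample_ids
    for blk in blocks[1:]:
        if blk.sample_ids != ref:
            raise AlignmentError(
                f"block '{blk.name}' samples differ from '{blocks[0].name}'"
            )
    return ref


def read_block(path: str | Path, block_name: str) -> OmicsBlock:
    """Read a variables-as-rows TSV into an :class:`OmicsBlock`.

    Validation problems (duplicate ids, non-numeric cells) are aggregated
    and raised together, naming the offending entries.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    problems: list[str] = []
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()
        problems.append("duplicate variable id(s): " + ", ".join(map(str, dup)))
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique()
        problems.append("duplicate sample id(s): " + ", ".join(map(str, dup)))
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        cells = [f"({df.index[r]}, {df.columns[c]})" for r, c in zip(rows[:10], cols[:10])]
        problems.append("non-numeric cell(s) at: " + ", ".join(cells))
    if numeric.isna().to_numpy().any() and not bad.to_numpy().any():
        problems.append("missing values present; inputs must be complete")
    if problems:
        raise ValidationError(
            f"invalid block table '{path}': " + "; ".join(problems)
        )
    return OmicsBlock(block_name, numeric.T)


def write_block(block: OmicsBlock, path: str | Path, index_label: str = "id") -> None:
    block.data.T.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(
    path: str | Path, treatments: Sequence[str] = TREATMENTS
) -> pd.DataFrame:
    """Read and validate the sample metadata table.

    Columns: sample_id, treatment, day, replicate, scald.  Scald is the
    ordinal 1-4 severity score (1 = no scald ... 4 = >50% coverage).
    """
    meta = pd.read_csv(path, sep="\t")
    return validate_metadata(meta, treatments)


def validate_metadata(
    meta: pd.DataFrame, treatments: Sequence[str] = TREATMENTS
) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError("metadata missing column(s): " + ", ".join(missing))
    meta = meta.loc[:, list(META_COLUMNS)].copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].unique()
        raise DuplicateIdError("sample", dup)
    unknown = sorted(set(meta["treatment"]) - set(treatments))
    if unknown:
        raise ValidationError("unknown treatment label(s): " + ", ".join(unknown))
    cell = meta[["treatment", "day", "replicate"]].apply(tuple, axis=1)
    if cell.duplicated().any():
        raise ValidationError("duplicate (treatment, day, replicate) rows")
    if not meta["scald"].isin([1, 2, 3, 4]).all():
        raise ValidationError("scald scores must be within the ordinal 1-4 scale")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the functional-bin annotation table (gene_id, bin_path).

    ``bin_path`` is a '.'-separated hierarchical bin label; a gene may
    appear in several rows if it maps to several bins.
    """
    ann = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "bin_path"):
        if col not in ann.columns:
            raise ValidationError(f"annotation table missing column '{col}'")
    return ann.loc[:, ["gene_id", "bin_path"]]


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)
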