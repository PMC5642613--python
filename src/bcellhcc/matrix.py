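"""Expression-matrix container.

The central in-memory object of the pipeline: a genes x samples grid of
log-scale expression values with optional per-sample annotations (tumor
entity, array platform, tissue type, patient link). Values are held in a
pandas DataFrame; the wrapper enforces the invariants every stage assumes
(unique ids, matching dimensions, finite values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

TUMOR = "tumor"
NON_TUMOR = "non_tumor"

#: annotation columns recognised by the pipeline
ANNOTATION_COLUMNS = ("entity", "platform", "tissue", "patient_id")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression grid.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns,
        log-scale expression values.
    annotations
        Optional DataFrame indexed by sample id. Recognised columns:
        ``entity``, ``platform``, ``tissue`` (``"tumor"``/``"non_tumor"``)
        and ``patient_id``. Extra columns are carried along untouched.
    log_base
        Base of the logarithm the values are on; used only when a linear
        scale is required (fold changes). Default 2.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None
    log_base: float = 2.0

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {v.index[i]!r}, "
                f"sample {v.columns[j]!r}"
            )
        if self.annotations is not None:
            missing = [s for s in v.columns if s not in self.annotations.index]
            if missing:
                raise ValidationError(
                    f"samples without annotation: {missing[:5]}"
                )
            # keep annotation order aligned with the value columns
            self.annotations = self.annotations.loc[v.columns]

    # -- basic accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- subsetting ------------------------------------------------------

    def subset_genes(self, gene_ids: Iterable) -> "ExpressionMatrix":
        ids = [g for g in gene_ids if g in self.values.index]
        if not ids:
            raise ValidationError("gene subset is empty")
        return ExpressionMatrix(self.values.loc[ids].copy(),
                                self._ann_copy(), self.log_base)

    def subset_samples(self, sample_ids: Sequence) -> "ExpressionMatrix":
        ids = [s for s in sample_ids if s in self.values.columns]
        if not ids:
            raise ValidationError("sample subset is empty")
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[ids].copy()
        return ExpressionMatrix(self.values[ids].copy(), ann, self.log_base)

    def samples_with(self, **criteria) -> list:
        """Sample ids whose annotation matches all ``column=value`` pairs."""
        if self.annotations is None:
            raise ValidationError("matrix has no sample annotations")
        mask = pd.Series(True, index=self.annotations.index)
        for col, val in criteria.items():
            if col not in self.annotations.columns:
                raise ValidationError(f"unknown annotation column {col!r}")
            mask &= self.annotations[col] == val
        return self.annotations.index[mask].tolist()

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """New matrix with the same annotations but different values."""
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[values.columns].copy()
        return ExpressionMatrix(values, ann, self.log_base)

    def _ann_copy(self) -> pd.DataFrame | None:
        return None if self.annotations is None else self.annotations.copy()


def make_annotations(sample_ids: Sequence, *, entity=None, platform=None,
                     tissue=None, patient_id=None) -> pd.DataFrame:
    """Build an annotation frame from per-sample sequences (or scalars)."""
    data = {}
    for name, col in (("entity", entity), ("platform", platform),
                      ("tissue", tissue), ("patient_id", patient_id)):
        if col is not None:
            data[name] = col
    return pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))
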