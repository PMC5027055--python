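"""Expression-matrix container shared by every analysis stage.

Holds log2 signal intensities (genes x samples) together with a per-gene
biotype label (``LncRNA``/``mRNA``) and sample labels of the form
``d<day>_r<replicate>`` (e.g. ``d7_r2``).  Backed by a pandas DataFrame;
the class adds the time-point bookkeeping every stage needs (grouping
columns by day, per-time means, pooling) plus the TSV dialect the
synthetic generator writes.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "BIOTYPES"]

BIOTYPES = ("LncRNA", "mRNA")

_SAMPLE_RE = re.compile(r"^d(?P<day>\d+(?:\.\d+)?)_r(?P<rep>\d+)$")


def _fmt_day(day: float) -> str:
    return f"{day:g}"


def sample_label(day: float, replicate: int) -> str:
    return f"d{_fmt_day(day)}_r{replicate}"


@dataclass
class ExpressionMatrix:
    """log2 expression values with biotype and time-point metadata.

    Parameters
    ----------
    values
        DataFrame, index = gene ids, columns = ``d<day>_r<rep>`` labels.
    biotype
        Series mapping gene id to ``LncRNA`` or ``mRNA``.
    """

    values: pd.DataFrame
    biotype: pd.Series
    _sample_meta: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")
        meta = []
        for col in self.values.columns:
            m = _SAMPLE_RE.match(str(col))
            if m is None:
                raise ValueError(
                    f"sample label {col!r} does not parse as d<day>_r<replicate>"
                )
            meta.append((col, float(m.group("day")), int(m.group("rep"))))
        self._sample_meta = pd.DataFrame(meta, columns=["sample", "time_day", "replicate"])
        self.biotype = self.biotype.reindex(self.values.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()].tolist()
            raise ValueError(f"genes without biotype: {missing[:5]}")
        bad = set(self.biotype.unique()) - set(BIOTYPES)
        if bad:
            raise ValueError(f"unknown biotype labels: {sorted(bad)}; expected {BIOTYPES}")

    # -- metadata ----------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return len(self.values)

    @property
    def time_points(self) -> list[float]:
        return sorted(self._sample_meta["time_day"].unique())

    def columns_at(self, time_day: float) -> list[str]:
        sel = self._sample_meta[self._sample_meta["time_day"] == float(time_day)]
        if sel.empty:
            raise KeyError(
                f"time point {time_day} not in matrix; available: {self.time_points}"
            )
        return sel["sample"].tolist()

    @property
    def is_pooled(self) -> bool:
        """True when every time point carries a single column (no replicates)."""
        return bool((self._sample_meta.groupby("time_day").size() == 1).all())

    # -- views -------------------------------------------------------------
    def time_means(self, genes: Iterable[str] | None = None) -> pd.DataFrame:
        """Per-gene mean log2 signal per time point (columns sorted by day)."""
        vals = self.values if genes is None else self.restrict(genes).values
        cols = {day: vals[self.columns_at(day)].mean(axis=1) for day in self.time_points}
        return pd.DataFrame(cols)

    def restrict(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.biotype.loc[genes].copy())

    def pooled(self) -> "ExpressionMatrix":
        """Average replicates into one column per time point (emulates
        equal-mass RNA pooling before hybridisation)."""
        means = self.time_means()
        means.columns = [sample_label(day, 1) for day in means.columns]
        return ExpressionMatrix(means, self.biotype.copy())

    # -- io ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "biotype", self.biotype)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        if "biotype" not in df.columns:
            raise ValueError(f"{path}: missing 'biotype' column")
        biotype = df.pop("biotype")
        return cls(df.astype(float), biotype)

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Sequence[str],
        biotypes: Sequence[str],
        time_points: Sequence[float],
        data: np.ndarray,
        replicates: int,
    ) -> "ExpressionMatrix":
        """Assemble from a (genes, time*replicates) array laid out
        time-major (all replicates of the first time point first)."""
        cols = [
            sample_label(day, r + 1) for day in time_points for r in range(replicates)
        ]
        values = pd.DataFrame(np.asarray(data, dtype=float), index=list(gene_ids), columns=cols)
        return cls(values, pd.Series(list(biotypes), index=list(gene_ids)))
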