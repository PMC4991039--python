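"""Coded genotype matrices for pseudo-testcross mapping.

In an outbred F1 family, a marker heterozygous in exactly one parent
segregates 1:1 among the progeny and is coded ``aa``/``ab`` relative to
that parent's alleles: progeny carrying only the shared allele are ``aa``,
progeny carrying the informative parent's second allele are ``ab``.
Maternal-informative markers (segregation type ``abxaa``) build the
maternal map; paternal-informative markers (``aaxab``) the paternal map.

Calls are stored as an int8 array with codes ``AA=0``, ``AB=1``,
``MISSING=-1``; marker metadata (locus id, contig, position, segregation
type, QC statistics) lives in a parallel :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
AA = np.int8(0)
AB = np.int8(1)

#: segregation types of 1:1 markers; the first parent is the mother
SEG_MATERNAL = "abxaa"   # mother heterozygous, father homozygous
SEG_PATERNAL = "aaxab"   # father heterozygous, mother homozygous
SEG_BOTH_HET = "abxab"   # both heterozygous: not 1:1, excluded from mapping
SEG_MONOMORPHIC = "both-homozygous"
SEG_UNTYPED = "untyped"

MAPPABLE_SEG_TYPES = (SEG_MATERNAL, SEG_PATERNAL)

_CALL_CHARS = {AA: "a", AB: "b", MISSING: "-"}
_CHAR_CALLS = {v: k for k, v in _CALL_CHARS.items()}


@dataclass
class GenotypeMatrix:
    """Markers x progeny coded calls plus per-marker metadata.

    Parameters
    ----------
    markers
        One row per marker, indexed by marker id. Expected columns include
        ``contig``, ``pos`` (1-based within-contig), ``seg_type`` and,
        when available, ``chrom``/``chrom_pos`` (genome-level physical
        coordinates) and QC columns ``chi2``, ``p``, ``missing_frac``.
    calls
        int8 array of shape (n_markers, n_progeny) over {0, 1, -1}.
    progeny
        Progeny sample names, in call-column order.
    """

    markers: pd.DataFrame
    calls: np.ndarray
    progeny: list[str]
    dp: np.ndarray | None = field(default=None, repr=False)
    gq: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array (markers x progeny)")
        if self.calls.shape != (len(self.markers), len(self.progeny)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.progeny)} progeny"
            )
        bad = ~np.isin(self.calls, (AA, AB, MISSING))
        if bad.any():
            raise ValueError("calls contain codes outside {aa, ab, missing}")

    # ------------------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_progeny(self) -> int:
        return len(self.progeny)

    @property
    def marker_ids(self) -> pd.Index:
        return self.markers.index

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing progeny calls."""
        return (self.calls == MISSING).mean(axis=1)

    def segregation_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-marker (n_aa, n_ab) counts over observed progeny."""
        return (self.calls == AA).sum(axis=1), (self.calls == AB).sum(axis=1)

    # ------------------------------------------------------------------
    def take(self, index) -> "GenotypeMatrix":
        """Subset markers by positional index or boolean mask (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            markers=self.markers.iloc[index],
            calls=self.calls[index],
            dp=None if self.dp is None else self.dp[index],
            gq=None if self.gq is None else self.gq[index],
        )

    def select_ids(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = self.markers.index.get_indexer(ids)
        if (pos < 0).any():
            missing_ids = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"unknown marker ids: {missing_ids[:5]}")
        return self.take(pos)

    def by_seg_type(self, seg_type: str) -> "GenotypeMatrix":
        return self.take((self.markers["seg_type"] == seg_type).to_numpy())

    # ------------------------------------------------------------------
    def calls_as_strings(self) -> list[str]:
        """Compact one-character-per-progeny encoding (a/b/-)."""
        lut = np.empty(3, dtype="U1")
        lut[AA], lut[AB], lut[MISSING % 3] = "a", "b", "-"
        return ["".join(lut[row % 3]) for row in self.calls]

    @staticmethod
    def calls_from_strings(rows: Sequence[str]) -> np.ndarray:
        out = np.empty((len(rows), len(rows[0]) if rows else 0), dtype=np.int8)
        for i, s in enumerate(rows):
            out[i] = [_CHAR_CALLS[c] for c in s]
        return out

    def to_table(self) -> pd.DataFrame:
        """Marker table with calls flattened to an a/b/- string column."""
        table = self.markers.copy()
        table["genotypes"] = self.calls_as_strings()
        return table

    @classmethod
    def from_table(cls, table: pd.DataFrame, progeny: list[str]) -> "GenotypeMatrix":
        calls = cls.calls_from_strings(table["genotypes"].tolist())
        return cls(table.drop(columns="genotypes"), calls, list(progeny))
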