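"""Core containers shared by every pipeline stage.

The universal currency of the package is the :class:`GenotypeMatrix`:
integer dosage calls (0 = hom-ref, 1 = het, 2 = hom-alt, ``MISSING`` = no
call) for a rectangular loci x samples block. Per-locus metadata travels in
a *variant catalog* (a pandas DataFrame indexed by locus id) and sample
metadata in a *panel definition* DataFrame; both schemas are validated by
the helpers below rather than wrapped in bespoke classes, which keeps them
directly usable with the ordinary pandas toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Dosage code for a missing genotype call.
MISSING: int = -1

#: Chromosome label conventionally holding unanchored sequence; excluded
#: from genome-wide density and LD summaries.
UNANCHORED: str = "chr0"

CATALOG_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "source",
                   "genic_class", "candidate_gene_id"]

PANEL_COLUMNS = ["species", "role", "group", "replicate_of", "admixed"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as percentage tables are printed."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to *decimals*.

    Raises ``ZeroDivisionError`` for a zero denominator: a rate with an
    empty denominator is a caller error, not 0%.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


@dataclass
class GenotypeMatrix:
    """Rectangular dosage calls, loci as rows, samples as columns.

    ``calls`` is an int8 array with values in {0, 1, 2, MISSING}. Loci and
    samples are identified by string ids; the arrays are positional and the
    id order is authoritative.
    """

    calls: np.ndarray
    locus_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (loci x samples)")
        if self.calls.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.locus_ids)} loci x {len(self.sample_ids)} samples")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,MISSING}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")

    # -- shape -----------------------------------------------------------
    @property
    def n_loci(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    # -- lookup ----------------------------------------------------------
    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero(self.sample_ids == sample_id)
        if idx.size == 0:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(idx[0])

    def sample_calls(self, sample_id: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample_id)]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(self.calls[:, idx].copy(),
                              self.locus_ids.copy(),
                              np.asarray(list(sample_ids), dtype=object))

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset by boolean mask or array of locus ids (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {l: i for i, l in enumerate(self.locus_ids)}
            idx = np.array([pos[l] for l in keep], dtype=int)
        return GenotypeMatrix(self.calls[idx].copy(),
                              self.locus_ids[idx].copy(),
                              self.sample_ids.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.locus_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        return cls(frame.to_numpy(dtype=np.int8),
                   frame.index.to_numpy(dtype=object),
                   frame.columns.to_numpy(dtype=object))


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Check the variant-catalog schema: unique locus index, unique
    (chrom, pos), required columns present."""
    missing_cols = [c for c in ("chrom", "pos") if c not in catalog.columns]
    if missing_cols:
        raise ValueError(f"catalog lacks required columns {missing_cols}")
    if catalog.index.has_duplicates:
        raise ValueError("catalog locus ids are not unique")
    if catalog.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("catalog has duplicated (chrom, pos)")
    return catalog


def validate_panel(panel: pd.DataFrame,
                   matrix: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Check the panel definition: every matrix sample mapped, and every
    ``replicate_of`` reference resolvable."""
    if "species" not in panel.columns or "role" not in panel.columns:
        raise ValueError("panel needs 'species' and 'role' columns")
    if matrix is not None:
        unmapped = set(matrix.sample_ids) - set(panel.index)
        if unmapped:
            raise ValueError(f"samples not in panel: {sorted(unmapped)}")
    if "replicate_of" in panel.columns:
        refs = panel["replicate_of"].dropna()
        refs = refs[refs != ""]
        unknown = set(refs) - set(panel.index)
        if unknown:
            raise ValueError(f"replicate_of points at unknown samples: "
                             f"{sorted(unknown)}")
    return panel


def samples_of(panel: pd.DataFrame, species: str | None = None,
               role: str | None = None) -> list[str]:
    """Sample ids filtered by species and/or role."""
    mask = pd.Series(True, index=panel.index)
    if species is not None:
        mask &= panel["species"] == species
    if role is not None:
        mask &= panel["role"] == role
    return list(panel.index[mask])
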